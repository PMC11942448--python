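import numpy as np
import pandas as pd
import pytest

from cspic.genodata import GenotypeMatrix
from cspic.simulate import (
    ConfigurationError,
    SimulationConfig,
    TraitArchitecture,
    f1_haplotypes,
    gamete,
    make_genetic_map,
    sample_architecture,
    sample_crossovers,
    simulate_cspic,
    simulate_dh_population,
    simulate_founders,
    simulate_phenotypes,
)
from conftest import make_matrix


def hudson_fst(pa, na, pb, nb):
    """Brute-force Hudson estimator from sample allele frequencies."""
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())


class TestFounders:
    def test_homozygous_and_group_assignment(self):
        cfg = SimulationConfig(seed=4)
        founders, groups = simulate_founders(cfg)
        assert founders.individual_het_rate().max() == 0.0
        assert set(np.unique(founders.dosage)) <= {0, 2}
        assert groups["C783"] == "X"

    def test_duplicate_founder_ids_rejected(self):
        cfg = SimulationConfig(founder_spec=[("A", "g1"), ("A", "g2")])
        with pytest.raises(ConfigurationError, match="duplicate"):
            simulate_founders(cfg)

    def test_low_divergence_gives_low_fst(self):
        spec = [(f"A{i}", "g1") for i in range(15)] + [
            (f"B{i}", "g2") for i in range(15)
        ]
        cfg = SimulationConfig(
            seed=8, group_divergence=0.02, founder_spec=spec,
            dh_pop_spec=[], hybrid_pop_spec=[], n_loci=2000,
        )
        founders, groups = simulate_founders(cfg)
        a = founders.subset_individuals([i for i in founders.ids if i.startswith("A")])
        b = founders.subset_individuals([i for i in founders.ids if i.startswith("B")])
        f = hudson_fst(a.allele_freq(), 15, b.allele_freq(), 15)
        assert abs(f) < 0.1

    def test_fst_matches_brute_force_oracle(self):
        from cspic.relatedness import fst

        spec = [(f"A{i}", "g1") for i in range(20)] + [
            (f"B{i}", "g2") for i in range(20)
        ]
        cfg = SimulationConfig(
            seed=9, group_divergence=0.3, founder_spec=spec,
            dh_pop_spec=[], hybrid_pop_spec=[], n_loci=2000,
        )
        founders, _ = simulate_founders(cfg)
        a = founders.subset_individuals([i for i in founders.ids if i.startswith("A")])
        b = founders.subset_individuals([i for i in founders.ids if i.startswith("B")])
        implemented = fst(a, b)
        oracle = hudson_fst(a.allele_freq(), 20, b.allele_freq(), 20)
        assert implemented == pytest.approx(oracle, abs=0.1)
        # divergence parameter is in the right neighbourhood
        assert 0.1 < implemented < 0.6


class TestMeiosis:
    def test_homozygous_parent_gamete_identical(self, rng):
        map_df = make_genetic_map(2, 100.0, 50, rng)
        hap = np.zeros(50, dtype=np.int8)
        out = gamete((hap, hap), map_df, rng)
        np.testing.assert_array_equal(out, hap)

    def test_unsorted_map_rejected(self, rng):
        map_df = pd.DataFrame({"chrom": ["1", "1"], "cm": [10.0, 5.0]})
        h = np.array([0, 0], dtype=np.int8)
        with pytest.raises(ValueError, match="unsorted"):
            gamete((h, np.array([1, 1], dtype=np.int8)), map_df, rng)

    def test_crossover_count_poisson_mean(self, rng):
        counts = [len(sample_crossovers(100.0, rng)) for _ in range(10_000)]
        assert np.mean(counts) == pytest.approx(1.0, abs=0.05)

    def test_haldane_recombination_fraction(self, rng):
        map_df = pd.DataFrame({"chrom": ["1", "1"], "cm": [0.0, 50.0]})
        h0 = np.array([0, 0], dtype=np.int8)
        h1 = np.array([1, 1], dtype=np.int8)
        rec = 0
        n = 10_000
        for _ in range(n):
            g = gamete((h0, h1), map_df, rng)
            rec += g[0] != g[1]
        expected = (1 - np.exp(-1.0)) / 2
        assert rec / n == pytest.approx(expected, abs=0.02)


class TestDHPopulation:
    def test_lines_homozygous_and_segregation(self, rng):
        map_df = make_genetic_map(3, 100.0, 120, rng)
        p1 = np.zeros(120, dtype=np.int8)
        p2 = np.full(120, 2, dtype=np.int8)
        pop = simulate_dh_population(p1, p2, 1000, map_df, rng)
        assert pop.individual_het_rate().max() == 0.0
        freqs = pop.allele_freq()
        assert np.all(np.abs(freqs - 0.5) < 0.05)

    def test_shared_parent_allele_monomorphic(self, rng):
        map_df = make_genetic_map(1, 80.0, 40, rng)
        p1 = np.full(40, 2, dtype=np.int8)
        p2 = np.full(40, 2, dtype=np.int8)
        p2[::2] = 0  # differ at even loci only
        pop = simulate_dh_population(p1, p2, 200, map_df, rng)
        poly = pop.polymorphic_mask()
        assert not poly[1::2].any()

    def test_n_lines_validation(self, rng):
        map_df = make_genetic_map(1, 50.0, 10, rng)
        with pytest.raises(ValueError):
            simulate_dh_population(
                np.zeros(10, np.int8), np.full(10, 2, np.int8), 0, map_df, rng
            )

    def test_heterozygous_parent_rejected(self):
        with pytest.raises(ValueError, match="homozygous"):
            f1_haplotypes(np.array([1, 0]), np.array([0, 2]))


class TestPhenotypes:
    def _panel(self, rng, n=50, m=40):
        dos = (rng.random((n, m)) < 0.5).astype(np.int8) * 2
        return make_matrix(dos)

    def test_noise_free_records_exact(self, rng):
        g = self._panel(rng)
        arch = sample_architecture("T", 40, 10, 0.0, rng, intercept=5.0)
        rec, truth, _ = simulate_phenotypes(g, arch, 2, 2, rng, variances=(0, 0, 0))
        merged = rec.merge(truth.rename("g").rename_axis("genotype_id"), on="genotype_id")
        assert np.allclose(merged["value"], merged["g"])

    def test_plugin_heritability_matches_target(self, rng):
        g = self._panel(rng, n=300)
        arch = sample_architecture("T", 40, 15, 0.0, rng)
        rec, truth, comp = simulate_phenotypes(g, arch, 3, 2, rng, heritability=0.7)
        h2 = comp["Vg"] / (comp["Vg"] + comp["Ve"] / 3)
        assert h2 == pytest.approx(0.7, abs=1e-12)

    def test_zero_genetic_variance_with_target_rejected(self, rng):
        g = self._panel(rng)
        arch = TraitArchitecture("T", np.array([0]), np.array([0.0]), np.array([0.0]))
        assert np.var(arch.genetic_values(g)) == 0.0
        with pytest.raises(ValueError, match="zero genetic variance"):
            simulate_phenotypes(g, arch, 2, 2, rng, heritability=0.5)

    def test_duplicate_qtl_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TraitArchitecture("T", np.array([1, 1]), np.zeros(2), np.zeros(2))


class TestCspic:
    def test_default_design_counts(self, small_dataset):
        ds = small_dataset
        assert len(ds.dh_pops) == 5
        assert len(ds.hybrid_pops) == 15
        total = sum(g.n_individuals for g in ds.hybrid_pops.values())
        expected = sum(
            ds.dh_pops[spec.dh_pop].n_individuals
            for spec in ds.design.hybrid_pops.values()
        )
        assert total == expected

    def test_hybrid_heterozygosity_rule(self, small_dataset):
        ds = small_dataset
        hid, spec = next(iter(ds.design.hybrid_pops.items()))
        hyb = ds.hybrid_pops[hid]
        dh = ds.dh_pops[spec.dh_pop]
        tester = ds.founders.row(spec.tester)
        het = hyb.dosage == 1
        differs = np.abs(dh.dosage - tester[None, :]) == 2
        np.testing.assert_array_equal(het, differs)

    def test_dh_truth_reproducible_from_architecture(self, small_dataset):
        ds = small_dataset
        arch = ds.architectures["PH"]
        again = arch.genetic_values(ds.dh_pops["POP2"])
        np.testing.assert_allclose(again, ds.dh_truth.loc["POP2"]["PH"].to_numpy())

    def test_same_seed_reproduces_identical_vcf(self, tmp_path):
        from cspic.io import write_vcf

        cfg = dict(seed=5, n_chrom=2, n_loci=120, map_length_per_chrom=80.0,
                   dh_pop_spec=[("POP1", "C783", "C229", 15),
                                ("POP2", "C783", "UH306", 15),
                                ("POP3", "C783", "EH", 15),
                                ("POP4", "C229", "UH306", 15),
                                ("POP5", "C783", "C116A", 15)])
        a = simulate_cspic(SimulationConfig(**cfg))
        b = simulate_cspic(SimulationConfig(**cfg))
        pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(a.dh_pops["POP3"], pa)
        write_vcf(b.dh_pops["POP3"], pb)
        assert pa.read_bytes() == pb.read_bytes()
        pd.testing.assert_frame_equal(a.dh_phenotypes, b.dh_phenotypes)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(group_divergence=1.5).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                dh_pop_spec=[("POPX", "nobody", "C229", 10)]
            ).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_loci=3, n_chrom=10).validate()

    def test_missing_rate_masks_dh_panels(self):
        cfg = SimulationConfig(
            seed=6, n_chrom=2, n_loci=100, missing_rate=0.1,
            dh_pop_spec=[("POP1", "C783", "C229", 30),
                         ("POP2", "C783", "UH306", 30),
                         ("POP3", "C783", "EH", 30),
                         ("POP4", "C229", "UH306", 30),
                         ("POP5", "C783", "C116A", 30)],
        )
        ds = simulate_cspic(cfg)
        rate = np.mean([g.missing_mask().mean() for g in ds.dh_pops.values()])
        assert 0.05 < rate < 0.15
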
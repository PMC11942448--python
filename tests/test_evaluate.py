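import numpy as np
import pandas as pd
import pytest

from cspic.evaluate import (
    AccuracyResult,
    accuracy_index_correlation,
    cross_population_eval,
    dh_hybrid_accuracy_correlation,
    within_population_cv,
)
from cspic.relatedness import RelatednessIndices
from cspic.simulate import SimulationConfig, simulate_cspic


@pytest.fixture(scope="module")
def noiseless_pop():
    """A compact-genome population where markers capture nearly all of the
    genetic signal — the near-noiseless limit of the CV protocol."""
    cfg = SimulationConfig(
        seed=21, n_chrom=5, map_length_per_chrom=100.0, qtl_per_trait=20
    )
    ds = simulate_cspic(cfg)
    truth = ds.dh_truth.loc["POP1"]["PH"]
    truth.index.name = None
    return ds.dh_pops["POP1"], truth.rename("PH")


class TestAccuracyResult:
    def test_summary_is_median(self):
        res = AccuracyResult("a", "b", "T", "rrblup", [0.1] * 25 + [0.5] * 25, 55, 12, 0)
        assert res.summary == pytest.approx(0.3)

    def test_correlations_bounded(self):
        with pytest.raises(ValueError):
            AccuracyResult("a", "b", "T", "rrblup", [1.5], 10, 5, 0)


class TestWithinPopulation:
    def test_noiseless_phenotype_recovered(self, noiseless_pop):
        geno, truth = noiseless_pop
        res = within_population_cv(geno, truth, model="rrblup", seed=3)
        assert res.summary > 0.9
        assert res.n_repeats == 10

    def test_pure_noise_accuracy_near_zero(self, noiseless_pop):
        # one noise vector yields correlated repeats, so marginalize the
        # null over several independent noise draws
        geno, truth = noiseless_pop
        rng = np.random.default_rng(0)
        summaries = []
        for k in range(5):
            noise = pd.Series(
                rng.normal(size=len(truth)), index=truth.index, name="N"
            )
            res = within_population_cv(geno, noise, model="rrblup", seed=4 + k, repeats=4)
            summaries.append(res.summary)
        assert abs(np.median(summaries)) < 2 / np.sqrt(77)

    def test_same_seed_identical_repeats(self, noiseless_pop):
        geno, truth = noiseless_pop
        r1 = within_population_cv(geno, truth, seed=8)
        r2 = within_population_cv(geno, truth, seed=8)
        assert r1.per_repeat == r2.per_repeat

    def test_small_population_rejected_or_warned(self, noiseless_pop):
        geno, truth = noiseless_pop
        small = geno.subset_individuals(geno.ids[:40])
        with pytest.raises(ValueError, match="phenotyped accessions"):
            within_population_cv(small, truth, seed=1)
        with pytest.warns(UserWarning, match="smaller than n_sample"):
            res = within_population_cv(small, truth, seed=1, allow_small=True)
        assert res.n_repeats == 10


class TestCrossPopulation:
    @pytest.fixture(scope="class")
    def ds(self):
        cfg = SimulationConfig(
            seed=22, n_chrom=5, map_length_per_chrom=100.0, qtl_per_trait=20
        )
        return simulate_cspic(cfg)

    def _truth(self, ds, pop):
        s = ds.dh_truth.loc[pop]["PH"]
        s.index.name = None
        return s.rename("PH")

    def test_disjoint_within_beats_non_sib(self, ds):
        full = cross_population_eval(
            ds.dh_pops["POP1"], self._truth(ds, "POP1"),
            ds.dh_pops["POP1"], self._truth(ds, "POP1"),
            repeats=15, seed=5, train_pop="POP1", test_pop="POP1",
        )
        non_sib = cross_population_eval(
            ds.dh_pops["POP4"], self._truth(ds, "POP4"),
            ds.dh_pops["POP5"], self._truth(ds, "POP5"),
            repeats=15, seed=5, train_pop="POP4", test_pop="POP5",
        )
        assert full.summary > 0
        assert full.summary > non_sib.summary

    def test_permuted_phenotypes_break_accuracy(self, ds):
        # repeats share the permutation, so marginalize over permutations
        rng = np.random.default_rng(1)
        t2 = self._truth(ds, "POP2")
        summaries = []
        for _ in range(6):
            permuted = pd.Series(
                rng.permutation(t2.to_numpy()), index=t2.index, name="PH"
            )
            res = cross_population_eval(
                ds.dh_pops["POP3"], self._truth(ds, "POP3"),
                ds.dh_pops["POP2"], permuted,
                repeats=8, seed=6,
            )
            summaries.append(res.summary)
        assert abs(np.median(summaries)) < 0.25

    def test_determinism(self, ds):
        kw = dict(repeats=6, seed=9)
        r1 = cross_population_eval(
            ds.dh_pops["POP1"], self._truth(ds, "POP1"),
            ds.dh_pops["POP2"], self._truth(ds, "POP2"), **kw,
        )
        r2 = cross_population_eval(
            ds.dh_pops["POP1"], self._truth(ds, "POP1"),
            ds.dh_pops["POP2"], self._truth(ds, "POP2"), **kw,
        )
        assert r1.per_repeat == r2.per_repeat

    def test_subtype_constrained_sampling(self, ds):
        from cspic.design import samedh_subtype

        hyb_a = ds.hybrid_pops["POP5/C229"]
        hyb_b = ds.hybrid_pops["POP5/Z58"]
        ta = ds.hybrid_truth.loc["POP5/C229"]["PH"]
        ta.index.name = None
        tb = ds.hybrid_truth.loc["POP5/Z58"]["PH"]
        tb.index.name = None
        for sub in ("same_DH", "diff_DH", "rand_DH"):
            res = cross_population_eval(
                hyb_a, ta.rename("PH"), hyb_b, tb.rename("PH"),
                repeats=4, seed=13, subtype=sub,
                train_pop="POP5/C229", test_pop="POP5/Z58",
            )
            assert res.subtype == sub
        # infeasible: diff_DH with nearly the whole population required
        with pytest.raises(ValueError, match="infeasible"):
            cross_population_eval(
                hyb_a, ta.rename("PH"), hyb_b, tb.rename("PH"),
                n_train=85, repeats=2, seed=1, subtype="diff_DH",
            )

    def test_population_too_small(self, ds):
        tiny = ds.dh_pops["POP1"].subset_individuals(ds.dh_pops["POP1"].ids[:10])
        with pytest.raises(ValueError, match="too small"):
            cross_population_eval(
                tiny, self._truth(ds, "POP1"),
                ds.dh_pops["POP2"], self._truth(ds, "POP2"),
                repeats=2, seed=0,
            )


class TestCorrelationAnalyses:
    def _results(self, values, trait="T"):
        return [
            AccuracyResult(f"A{i}", f"B{i}", trait, "rrblup", [v], 55, 12, 0)
            for i, v in enumerate(values)
        ]

    def _indices(self, psps):
        return [
            RelatednessIndices(psp=p, nei=0.1, ibs=0.2, fst=0.3) for p in psps
        ]

    def test_accuracy_equal_to_psp_gives_correlation_one(self):
        vals = [0.1, 0.4, 0.7, 0.9]
        table = accuracy_index_correlation(self._results(vals), self._indices(vals))
        psp_row = table[table["index"] == "psp"].iloc[0]
        assert psp_row["r"] == pytest.approx(1.0)
        assert psp_row["p"] < 0.05

    def test_constant_index_flagged_undefined(self):
        table = accuracy_index_correlation(
            self._results([0.1, 0.2, 0.3]), self._indices([0.5, 0.5, 0.5])
        )
        psp_row = table[table["index"] == "psp"].iloc[0]
        assert psp_row["flag"] == "undefined" and np.isnan(psp_row["r"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="three"):
            accuracy_index_correlation(self._results([0.1, 0.2]), self._indices([0.1, 0.2]))

    def test_dh_hybrid_identity_correlation_one(self):
        from cspic.design import default_design

        design = default_design()
        dh = [
            AccuracyResult("POP1", "POP2", "T", "rrblup", [0.5], 55, 12, 0),
            AccuracyResult("POP1", "POP3", "T", "rrblup", [0.2], 55, 12, 0),
            AccuracyResult("POP2", "POP3", "T", "rrblup", [0.8], 55, 12, 0),
        ]
        hy = [
            AccuracyResult("POP1/C116A", "POP2/C116A", "T", "rrblup", [0.5], 55, 12, 0),
            AccuracyResult("POP1/C116A", "POP3/C116A", "T", "rrblup", [0.2], 55, 12, 0),
            AccuracyResult("POP2/C116A", "POP3/C116A", "T", "rrblup", [0.8], 55, 12, 0),
        ]
        out = dh_hybrid_accuracy_correlation(dh, hy, design)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_single_mapped_pair_rejected(self):
        from cspic.design import default_design

        design = default_design()
        dh = [AccuracyResult("POP1", "POP2", "T", "rrblup", [0.5], 55, 12, 0)]
        hy = [AccuracyResult("POP1/C116A", "POP2/C116A", "T", "rrblup", [0.5], 55, 12, 0)]
        with pytest.raises(ValueError, match="fewer than two"):
            dh_hybrid_accuracy_correlation(dh, hy, design)
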
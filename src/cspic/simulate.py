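"""Synthetic founders, DH populations, test-cross hybrids, and phenotypes.

The generator emulates a connected set of biparental doubled-haploid (DH)
populations made by crossing inbred founders from divergent heterotic
groups, each DH population test-crossed to several inbred testers on the
triangular heterotic pattern, with multi-environment plot phenotypes.

Model components
----------------
* Founder genomes: a hierarchical drift (Balding-Nichols) model. Each locus
  has an ancestral alternate-allele frequency; each heterotic group draws
  its own frequency from a Beta distribution around the ancestral one with
  drift parameter ``group_divergence`` (larger = more between-group
  differentiation); each founder is fixed for an allele sampled from its
  group frequency.
* Meiosis: Haldane (no crossover interference) — crossover count per
  chromosome ~ Poisson(map length in Morgans), positions uniform.
* DH production: one F1 gamete, doubled; lines are fully homozygous.
* Hybrids: DH line x tester, deterministic mid-parent dosage.
* Phenotypes: y_ijk = mu + g_i + e_j + b_k(e_j) + eps with the residual
  variance solved so the plot-mean heritability H2 = Vg / (Vg + Ve/l) hits
  its per-trait target exactly at the realized genetic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_DH_POPS,
    DEFAULT_GROUPS,
    DEFAULT_HYBRID_POPS,
    DHPopulationSpec,
    HybridPopulationSpec,
    PopulationDesign,
)
from .genodata import GenotypeMatrix, derive_hybrid_genotypes

DH_TRAITS = ("DTA", "DTS", "PH", "EH")
HYBRID_TRAITS = ("DTA", "DTS", "PH", "EH", "GY")

# Plot-mean heritability targets per trait, chosen inside the 0.64-0.96
# band typical of multi-environment maize trials (flowering < architecture
# traits; yield lowest).
DEFAULT_H2 = {"DTA": 0.85, "DTS": 0.82, "PH": 0.92, "EH": 0.90, "GY": 0.72}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one synthetic dataset."""

    seed: int = 0
    n_chrom: int = 10
    map_length_per_chrom: float = 150.0  # cM
    n_loci: int = 2000
    group_divergence: float = 0.3
    founder_spec: list[tuple[str, str]] = field(
        default_factory=lambda: [(l, g) for l, g in DEFAULT_GROUPS.items()]
    )
    dh_pop_spec: list[tuple[str, str, str, int]] = field(
        default_factory=lambda: list(DEFAULT_DH_POPS)
    )
    hybrid_pop_spec: list[tuple[str, str, str]] = field(
        default_factory=lambda: [
            (f"{p}/{t}", p, t) for p, t in DEFAULT_HYBRID_POPS
        ]
    )
    qtl_per_trait: int = 50
    dominance_ratio: float = 0.5
    n_env: int = 3
    n_blocks_per_env: int = 2
    heritability: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_H2))
    env_var_ratio: float = 2.0  # Venv / Vg
    block_var_ratio: float = 0.25  # Vblock / Vg
    missing_rate: float = 0.0  # optional masking to exercise the filters

    def validate(self) -> None:
        founders = [f for f, _ in self.founder_spec]
        if len(set(founders)) != len(founders):
            raise ConfigurationError("duplicate founder ids")
        if not 0 < self.group_divergence < 1:
            raise ConfigurationError("group_divergence must be in (0, 1)")
        if self.map_length_per_chrom <= 0:
            raise ConfigurationError("map_length_per_chrom must be positive")
        if self.n_loci < self.n_chrom:
            raise ConfigurationError("need at least one locus per chromosome")
        fset = set(founders)
        for pid, p1, p2, n in self.dh_pop_spec:
            if p1 not in fset or p2 not in fset:
                raise ConfigurationError(
                    f"DH population {pid}: parents must be founders"
                )
            if n < 1:
                raise ConfigurationError(f"DH population {pid}: n_lines < 1")
        dh_ids = {pid for pid, *_ in self.dh_pop_spec}
        for hid, dpop, tester in self.hybrid_pop_spec:
            if dpop not in dh_ids:
                raise ConfigurationError(
                    f"hybrid population {hid}: unknown DH population {dpop}"
                )
            if tester not in fset:
                raise ConfigurationError(
                    f"hybrid population {hid}: tester must be a founder"
                )
        for t, h2 in self.heritability.items():
            if not 0 < h2 <= 1:
                raise ConfigurationError(f"heritability target for {t} not in (0,1]")

    def to_design(self) -> PopulationDesign:
        groups = dict(self.founder_spec)
        dh = {
            pid: DHPopulationSpec(pid, p1, p2, n)
            for pid, p1, p2, n in self.dh_pop_spec
        }
        hy = {
            hid: HybridPopulationSpec(hid, dpop, tester)
            for hid, dpop, tester in self.hybrid_pop_spec
        }
        return PopulationDesign(groups=groups, dh_pops=dh, hybrid_pops=hy)


@dataclass
class TraitArchitecture:
    """True genetic architecture of one trait.

    The genetic value of an individual with dosage row ``d`` is
    ``intercept + sum_q a_q * d[q] + sum_q k_q * [d[q] == 1]`` — additive
    dosage effects plus heterozygote (dominance) deviations. Dominance is
    unobservable in fully homozygous material, so DH per-se traits carry
    zero dominance by construction of their genotypes.
    """

    trait: str
    qtl_indices: np.ndarray
    additive: np.ndarray
    dominance: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        if len(np.unique(self.qtl_indices)) != len(self.qtl_indices):
            raise ValueError("duplicate QTL indices")

    def genetic_values(self, g: GenotypeMatrix) -> np.ndarray:
        d = g.dosage[:, self.qtl_indices].astype(float)
        if (d < 0).any():
            raise ValueError("missing dosage at a QTL; impute before scoring")
        return (
            self.intercept
            + d @ self.additive
            + (d == 1.0) @ self.dominance
        )


# ---------------------------------------------------------------------- #
# genetic map and founders


def make_genetic_map(
    n_chrom: int, map_length: float, n_loci: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Loci spread uniformly at random over ``n_chrom`` chromosomes of
    ``map_length`` cM; physical position approximated at 1 Mb per cM."""
    per = np.full(n_chrom, n_loci // n_chrom)
    per[: n_loci - per.sum()] += 1
    rows = []
    for c in range(n_chrom):
        cm = np.sort(rng.uniform(0.0, map_length, size=per[c]))
        for k, x in enumerate(cm):
            rows.append(
                (f"snp_c{c + 1}_{k}", str(c + 1), int(round(x * 1e6)) + 1, x, "A", "T")
            )
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "cm", "ref", "alt"])


def simulate_founders(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Fully homozygous founder genomes under hierarchical drift.

    Per locus: ancestral frequency p ~ U(0.05, 0.95); each heterotic group
    draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``group_divergence`` (Balding-Nichols); each founder is fixed for
    an allele Bernoulli-sampled from its group frequency.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    loci = make_genetic_map(
        config.n_chrom, config.map_length_per_chrom, config.n_loci, rng
    )
    m = len(loci)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    F = config.group_divergence
    scale = (1.0 - F) / F
    groups = sorted({g for _, g in config.founder_spec})
    group_freq = {
        g: rng.beta(p_anc * scale, (1.0 - p_anc) * scale) for g in groups
    }
    ids = []
    rows = []
    group_of = {}
    for founder, g in config.founder_spec:
        allele = rng.random(m) < group_freq[g]
        rows.append(np.where(allele, 2, 0).astype(np.int8))
        ids.append(founder)
        group_of[founder] = g
    return GenotypeMatrix(ids, loci, np.vstack(rows)), group_of


# ---------------------------------------------------------------------- #
# meiosis


def sample_crossovers(
    length_cm: float, rng: np.random.Generator
) -> np.ndarray:
    """Crossover positions (cM) on one chromosome under the Haldane model:
    count ~ Poisson(length in Morgans), positions uniform."""
    k = rng.poisson(length_cm / 100.0)
    return np.sort(rng.uniform(0.0, length_cm, size=k))


def gamete(
    parent_haplotypes: tuple[np.ndarray, np.ndarray],
    map_df: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant haplotype (0/1 alleles) from a phased parent.

    ``parent_haplotypes`` are the two phased haplotypes over all loci of
    ``map_df`` (columns ``chrom`` and ``cm``, positions sorted within each
    chromosome).
    """
    h0, h1 = (np.asarray(h) for h in parent_haplotypes)
    cm = map_df["cm"].to_numpy()
    chrom = map_df["chrom"].to_numpy()
    out = np.empty(len(cm), dtype=h0.dtype)
    for c in pd.unique(chrom):
        sel = chrom == c
        pos = cm[sel]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"map positions unsorted on chromosome {c}")
        length = pos.max() if len(pos) else 0.0
        xo = sample_crossovers(max(length, 1e-9), rng)
        start = int(rng.integers(2))
        origin = (start + np.searchsorted(xo, pos)) % 2
        src = np.where(origin == 0, h0[sel], h1[sel])
        out[sel] = src
    return out


def f1_haplotypes(
    parent1: np.ndarray, parent2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Phased haplotypes of the F1 of two homozygous parents (dosage 0/2)."""
    for p in (parent1, parent2):
        if np.any(p == 1):
            raise ValueError("parents must be fully homozygous")
    return (parent1 // 2).astype(np.int8), (parent2 // 2).astype(np.int8)


def simulate_dh_population(
    parent1: np.ndarray,
    parent2: np.ndarray,
    n_lines: int,
    map_df: pd.DataFrame,
    rng: np.random.Generator,
    pop_id: str = "POP",
    loci: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """DH lines from the F1 of two homozygous parents: each line is a
    single recombinant gamete, doubled."""
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    h0, h1 = f1_haplotypes(np.asarray(parent1), np.asarray(parent2))
    rows = np.empty((n_lines, len(map_df)), dtype=np.int8)
    for i in range(n_lines):
        rows[i] = 2 * gamete((h0, h1), map_df, rng)
    ids = [f"{pop_id}_DH{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(ids, loci if loci is not None else map_df, rows)


# ---------------------------------------------------------------------- #
# phenotypes


def sample_architecture(
    trait: str,
    n_loci: int,
    qtl_per_trait: int,
    dominance_ratio: float,
    rng: np.random.Generator,
    intercept: float = 0.0,
) -> TraitArchitecture:
    qtl = rng.choice(n_loci, size=min(qtl_per_trait, n_loci), replace=False)
    a = rng.normal(0.0, 1.0, size=len(qtl))
    d = dominance_ratio * np.abs(rng.normal(0.0, 1.0, size=len(qtl)))
    return TraitArchitecture(trait, np.sort(qtl), a, d, intercept)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    n_env: int,
    n_blocks_per_env: int,
    rng: np.random.Generator,
    heritability: float | None = None,
    variances: tuple[float, float, float] | None = None,
    env_var_ratio: float = 2.0,
    block_var_ratio: float = 0.25,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Balanced multi-environment plot records for one trait.

    Either a plot-mean ``heritability`` target (residual variance solved
    from the realized genetic variance) or explicit ``variances``
    ``(Venv, Vblock, Ve)`` must be given. Returns the plot records, the
    true genetic values, and the variance components used.
    """
    g = arch.genetic_values(genotypes)
    vg = float(np.var(g))
    if variances is not None:
        venv, vblock, ve = (float(v) for v in variances)
        if min(venv, vblock, ve) < 0:
            raise ValueError("variance targets must be non-negative")
    elif heritability is not None:
        if vg == 0 and heritability > 0:
            raise ValueError(
                "zero genetic variance with a nonzero heritability target"
            )
        ve = n_env * vg * (1.0 - heritability) / heritability
        venv = env_var_ratio * vg
        vblock = block_var_ratio * vg
    else:
        raise ValueError("give either heritability or variances")
    n = genotypes.n_individuals
    env_eff = rng.normal(0.0, np.sqrt(venv), size=n_env)
    block_eff = rng.normal(0.0, np.sqrt(vblock), size=(n_env, n_blocks_per_env))
    eps = rng.normal(0.0, np.sqrt(ve), size=(n, n_env, n_blocks_per_env))
    rows = []
    for j in range(n_env):
        for k in range(n_blocks_per_env):
            y = g + env_eff[j] + block_eff[j, k] + eps[:, j, k]
            rows.append(
                pd.DataFrame(
                    {
                        "genotype_id": genotypes.ids,
                        "env": f"E{j + 1}",
                        "block": f"B{k + 1}",
                        "trait": arch.trait,
                        "value": y,
                    }
                )
            )
    records = pd.concat(rows, ignore_index=True)
    truth = pd.Series(g, index=genotypes.ids, name=arch.trait)
    # identifiable realized components: the mean block effect per
    # environment is confounded with the environment effect (only
    # within-environment block deviations are separable), so the realized
    # environment variance is the variance of e_j + bbar_j minus the
    # expected block-mean contribution
    vblock_real = (
        float(np.mean(np.var(block_eff, axis=1, ddof=1)))
        if n_blocks_per_env > 1
        else 0.0
    )
    env_plus_blockmean = env_eff + block_eff.mean(axis=1)
    venv_real = (
        max(
            float(np.var(env_plus_blockmean, ddof=1))
            - vblock_real / n_blocks_per_env,
            0.0,
        )
        if n_env > 1
        else 0.0
    )
    components = {
        "Vg": vg,
        "Venv": venv,
        "Vblock": vblock,
        "Ve": ve,
        "Venv_realized": venv_real,
        "Vblock_realized": vblock_real,
        "Ve_realized": float(np.var(eps)),
    }
    return records, truth, components


# ---------------------------------------------------------------------- #
# whole-design simulation


@dataclass
class CspicDataset:
    """One simulated connected DH + test-cross dataset."""

    config: SimulationConfig
    design: PopulationDesign
    founders: GenotypeMatrix
    dh_pops: dict[str, GenotypeMatrix]
    hybrid_pops: dict[str, GenotypeMatrix]
    dh_phenotypes: pd.DataFrame  # plot records over all DH populations
    hybrid_phenotypes: pd.DataFrame
    dh_truth: pd.DataFrame  # individuals x traits true genetic values
    hybrid_truth: pd.DataFrame
    architectures: dict[str, TraitArchitecture]
    variance_components: dict[str, dict]

    def pedigree(self) -> pd.DataFrame:
        rows = []
        testers = {t for _, _, t in self.config.hybrid_pop_spec}
        for f, g in self.config.founder_spec:
            role = "tester" if f in testers else "founder"
            rows.append((f, g, role, "", ""))
        for pid, gm in self.dh_pops.items():
            p1, p2 = self.design.dh_parents(pid)
            for iid in gm.ids:
                rows.append((iid, "", "DH", p1, p2))
        for hid, gm in self.hybrid_pops.items():
            spec = self.design.hybrid_pops[hid]
            for iid in gm.ids:
                rows.append((iid, "", "hybrid", iid.rsplit("/", 1)[0], spec.tester))
        return pd.DataFrame(
            rows, columns=["line_id", "group", "role", "parent1", "parent2"]
        )


def _mask_missing(
    g: GenotypeMatrix, rate: float, rng: np.random.Generator
) -> GenotypeMatrix:
    if rate <= 0:
        return g
    mask = rng.random(g.dosage.shape) < rate
    dos = g.dosage.copy()
    dos[mask] = -1
    return GenotypeMatrix(list(g.ids), g.loci.copy(), dos)


def simulate_cspic(config: SimulationConfig | None = None) -> CspicDataset:
    """Simulate the full connected design: founders, DH populations,
    test-cross hybrid populations, and multi-environment phenotypes.

    DH per-se traits are the four agronomic analogues (DTA, DTS, PH, EH);
    hybrid traits add heterozygote (dominance) deviations and a
    yield-analogue trait (GY). Fully deterministic for a fixed seed.
    """
    config = config or SimulationConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed)
    s_founder, s_arch, s_dh, s_pheno, s_mask = root.spawn(5)
    rng_f = np.random.default_rng(s_founder)
    founders, _ = simulate_founders(config, rng_f)
    design = config.to_design()
    map_df = founders.loci

    rng_a = np.random.default_rng(s_arch)
    architectures = {
        t: sample_architecture(
            t,
            founders.n_loci,
            config.qtl_per_trait,
            config.dominance_ratio,
            rng_a,
            intercept={"DTA": 70.0, "DTS": 72.0, "PH": 220.0, "EH": 110.0, "GY": 9.0}.get(t, 0.0),
        )
        for t in HYBRID_TRAITS
    }

    dh_rngs = {
        pid: np.random.default_rng(s)
        for (pid, *_), s in zip(config.dh_pop_spec, s_dh.spawn(len(config.dh_pop_spec)))
    }
    dh_pops: dict[str, GenotypeMatrix] = {}
    for pid, p1, p2, n in config.dh_pop_spec:
        dh_pops[pid] = simulate_dh_population(
            founders.row(p1),
            founders.row(p2),
            n,
            map_df,
            dh_rngs[pid],
            pop_id=pid,
        )

    hybrid_pops: dict[str, GenotypeMatrix] = {}
    for hid, dpop, tester in config.hybrid_pop_spec:
        hybrid_pops[hid] = derive_hybrid_genotypes(
            dh_pops[dpop], founders.row(tester), tester_id=tester
        )

    # phenotypes: one record set per population per trait
    pheno_seeds = s_pheno.spawn(2)
    rng_dh_p = np.random.default_rng(pheno_seeds[0])
    rng_hy_p = np.random.default_rng(pheno_seeds[1])
    vc: dict[str, dict] = {}
    dh_records, dh_truth_cols = [], {}
    for pid, gm in dh_pops.items():
        truths = {}
        for t in DH_TRAITS:
            rec, truth, comp = simulate_phenotypes(
                gm,
                architectures[t],
                config.n_env,
                config.n_blocks_per_env,
                rng_dh_p,
                heritability=config.heritability[t],
                env_var_ratio=config.env_var_ratio,
                block_var_ratio=config.block_var_ratio,
            )
            rec.insert(0, "pop", pid)
            dh_records.append(rec)
            truths[t] = truth
            vc[f"{pid}:{t}"] = comp
        dh_truth_cols[pid] = pd.DataFrame(truths)
    hy_records, hy_truth_cols = [], {}
    for hid, gm in hybrid_pops.items():
        truths = {}
        for t in HYBRID_TRAITS:
            rec, truth, comp = simulate_phenotypes(
                gm,
                architectures[t],
                config.n_env,
                config.n_blocks_per_env,
                rng_hy_p,
                heritability=config.heritability[t],
                env_var_ratio=config.env_var_ratio,
                block_var_ratio=config.block_var_ratio,
            )
            rec.insert(0, "pop", hid)
            hy_records.append(rec)
            truths[t] = truth
            vc[f"{hid}:{t}"] = comp
        hy_truth_cols[hid] = pd.DataFrame(truths)

    if config.missing_rate > 0:
        rng_m = np.random.default_rng(s_mask)
        dh_pops = {
            pid: _mask_missing(gm, config.missing_rate, rng_m)
            for pid, gm in dh_pops.items()
        }

    return CspicDataset(
        config=config,
        design=design,
        founders=founders,
        dh_pops=dh_pops,
        hybrid_pops=hybrid_pops,
        dh_phenotypes=pd.concat(dh_records, ignore_index=True),
        hybrid_phenotypes=pd.concat(hy_records, ignore_index=True),
        dh_truth=pd.concat(dh_truth_cols, names=["pop", "line"]),
        hybrid_truth=pd.concat(hy_truth_cols, names=["pop", "line"]),
        architectures=architectures,
        variance_components=vc,
    )
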
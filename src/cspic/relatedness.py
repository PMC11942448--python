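"""Genotypic affinity indices between a training and a test population.

Four indices summarize how exchangeable two genotype panels are for
cross-population prediction:

* ``psp`` — proportion of shared polymorphisms: loci polymorphic in both
  panels, relative to the locus count of a reference merged panel.
* ``nei`` — Nei's standard genetic distance from allele frequencies.
* ``ibs`` — mean identity-by-state distance over all cross pairs of
  individuals (allele-sharing distance, as computed by TASSEL).
* ``fst`` — Weir & Cockerham's theta for the two populations, combined
  over loci as a ratio of averages.

All four are symmetric in the two populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genodata import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class RelatednessIndices:
    psp: float
    nei: float
    ibs: float
    fst: float
    fst_raw: float = np.nan

    def __post_init__(self) -> None:
        if not (0 <= self.psp <= 1):
            raise ValueError("psp must be in [0, 1]")
        if not (0 <= self.ibs <= 1):
            raise ValueError("ibs must be in [0, 1]")
        if not (0 <= self.fst <= 1):
            raise ValueError("fst must be in [0, 1]")


def psp(
    train: GenotypeMatrix, test: GenotypeMatrix, panel_n: int
) -> float:
    """Shared-polymorphism proportion.

    |{loci polymorphic in train} ∩ {loci polymorphic in test}| / panel_n,
    where ``panel_n`` is the locus count of the reference merged panel.
    """
    if panel_n < 1:
        raise ValueError("panel_n must be >= 1")
    poly_train = set(np.asarray(train.loci["id"])[train.polymorphic_mask()])
    poly_test = set(np.asarray(test.loci["id"])[test.polymorphic_mask()])
    return len(poly_train & poly_test) / panel_n


def _shared_freqs(
    train: GenotypeMatrix, test: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    test_loci = set(test.loci["id"])
    shared = [l for l in train.loci["id"] if l in test_loci]
    if not shared:
        raise ValueError("no shared loci between panels")
    p1 = train.align_loci(shared).allele_freq()
    p2 = test.align_loci(shared).allele_freq()
    ok = np.isfinite(p1) & np.isfinite(p2)
    if not ok.any():
        raise ValueError("no overlapping informative loci")
    return p1[ok], p2[ok]


def nei_distance(train: GenotypeMatrix, test: GenotypeMatrix) -> float:
    """Nei's standard genetic distance D = -ln(Jxy / sqrt(Jx * Jy)).

    J terms are means over loci of allele-identity sums computed from
    allele frequencies (missing calls excluded); +inf when Jxy = 0.
    """
    p1, p2 = _shared_freqs(train, test)
    jx = float(np.mean(p1**2 + (1 - p1) ** 2))
    jy = float(np.mean(p2**2 + (1 - p2) ** 2))
    jxy = float(np.mean(p1 * p2 + (1 - p1) * (1 - p2)))
    if jxy <= 0:
        return np.inf
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def ibs_mean_distance(train: GenotypeMatrix, test: GenotypeMatrix) -> float:
    """Mean allele-sharing distance over all (train, test) individual pairs.

    For one pair, distance = 1 - mean over non-missing loci of the shared
    allele fraction 1 - |d_i - d_j| / 2. Pairs with no jointly called
    locus are skipped with a warning.
    """
    test_loci = set(test.loci["id"])
    shared = [l for l in train.loci["id"] if l in test_loci]
    if not shared:
        raise ValueError("no shared loci between panels")
    A = train.align_loci(shared).dosage
    B = test.align_loci(shared).dosage
    # one-hot by dosage value; matmuls give per-pair counts of each
    # (d_i, d_j) combination, handling missing exactly
    A_hot = [(A == v).astype(float) for v in (0, 1, 2)]
    B_hot = [(B == v).astype(float) for v in (0, 1, 2)]
    num = np.zeros((A.shape[0], B.shape[0]))
    for vi, Ai in zip((0, 1, 2), A_hot):
        for vj, Bj in zip((0, 1, 2), B_hot):
            w = abs(vi - vj) / 2.0
            if w:
                num += w * (Ai @ Bj.T)
    valid_a = (A != MISSING).astype(float)
    valid_b = (B != MISSING).astype(float)
    denom = valid_a @ valid_b.T
    ok = denom > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} individual pairs share no called locus")
    if not ok.any():
        raise ValueError("no individual pair shares a called locus")
    return float(np.mean(num[ok] / denom[ok]))


def fst(
    train: GenotypeMatrix, test: GenotypeMatrix, return_raw: bool = False
):
    """Weir & Cockerham per-locus theta for two populations, combined as a
    ratio of averages (sum of a over sum of a + b + c).

    Negative per-locus estimates stay in the sums; the combined value is
    clamped to [0, 1] for reporting (the raw value is available via
    ``return_raw``).
    """
    test_loci = set(test.loci["id"])
    shared = [l for l in train.loci["id"] if l in test_loci]
    if not shared:
        raise ValueError("no shared loci between panels")
    panels = [train.align_loci(shared), test.align_loci(shared)]
    r = 2
    n_i = np.stack([(p.dosage != MISSING).sum(axis=0).astype(float) for p in panels])
    p_i = np.stack([p.allele_freq() for p in panels])
    h_i = np.stack(
        [
            np.where(
                (p.dosage != MISSING).sum(axis=0) > 0,
                (p.dosage == 1).sum(axis=0)
                / np.maximum((p.dosage != MISSING).sum(axis=0), 1),
                0.0,
            )
            for p in panels
        ]
    )
    ok = (n_i > 0).all(axis=0) & np.isfinite(p_i).all(axis=0)
    n_i, p_i, h_i = n_i[:, ok], p_i[:, ok], h_i[:, ok]
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    informative = np.isfinite(a) & np.isfinite(b) & (pbar > 0) & (pbar < 1)
    if not informative.any():
        raise ValueError("all shared loci monomorphic across the union")
    num = float(a[informative].sum())
    den = float((a + b + c)[informative].sum())
    raw = num / den if den != 0 else np.nan
    clamped = float(np.clip(raw, 0.0, 1.0)) if np.isfinite(raw) else np.nan
    if return_raw:
        return clamped, raw
    return clamped


def relatedness_indices(
    train: GenotypeMatrix, test: GenotypeMatrix, panel_n: int
) -> RelatednessIndices:
    """All four indices for one (training, test) population pair."""
    clamped, raw = fst(train, test, return_raw=True)
    return RelatednessIndices(
        psp=psp(train, test, panel_n),
        nei=nei_distance(train, test),
        ibs=ibs_mean_distance(train, test),
        fst=clamped,
        fst_raw=raw,
    )
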
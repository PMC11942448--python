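"""Genotype containers, SNP filters, population merging, and hybrid synthesis.

Dosages count copies of the alternate allele: 0, 1, 2, with -1 for missing.
Doubled-haploid (DH) lines and inbred founders/testers are fully homozygous,
so their dosages live in {0, 2}; test-cross hybrids may carry 1 at loci where
the DH line and the tester are fixed for opposite alleles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

LOCUS_COLUMNS = ["id", "chrom", "pos", "cm", "ref", "alt"]


class EmptyPanelError(ValueError):
    """All loci or all individuals were removed by a filter."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-dosage matrix with a locus map.

    Parameters
    ----------
    ids
        Individual identifiers (rows).
    loci
        DataFrame with columns ``id, chrom, pos, cm, ref, alt`` (columns
        beyond ``id`` may be absent and are filled with defaults).
    dosage
        ``(n_individuals, n_loci)`` int8 array with entries in
        ``{0, 1, 2, -1}`` (-1 = missing).
    """

    ids: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        loci = self.loci.copy().reset_index(drop=True)
        if "chrom" not in loci:
            loci["chrom"] = "1"
        if "pos" not in loci:
            loci["pos"] = np.arange(1, len(loci) + 1)
        if "cm" not in loci:
            loci["cm"] = np.nan
        if "ref" not in loci:
            loci["ref"] = "A"
        if "alt" not in loci:
            loci["alt"] = "T"
        self.loci = loci[LOCUS_COLUMNS]
        if self.dosage.shape != (len(self.ids), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        if self.loci["id"].duplicated().any():
            dup = self.loci["id"][self.loci["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate locus id: {dup}")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, -1}")

    # ------------------------------------------------------------------ #
    # basic properties

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return self.loci["id"].tolist()

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def locus_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def individual_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def individual_het_rate(self) -> np.ndarray:
        """Fraction of non-missing calls that are heterozygous, per individual."""
        called = ~self.missing_mask()
        n_called = called.sum(axis=1)
        n_het = (self.dosage == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
        return rate

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus, missing calls excluded."""
        d = self.dosage.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def polymorphic_mask(self) -> np.ndarray:
        """Loci with at least two distinct non-missing dosage values."""
        present = np.stack([(self.dosage == v).any(axis=0) for v in (0, 1, 2)])
        return present.sum(axis=0) >= 2

    # ------------------------------------------------------------------ #
    # subsetting / combination

    def subset_individuals(self, sel: Sequence) -> "GenotypeMatrix":
        idx = self._individual_indices(sel)
        return GenotypeMatrix(
            [self.ids[i] for i in idx], self.loci.copy(), self.dosage[idx, :]
        )

    def subset_loci(self, sel) -> "GenotypeMatrix":
        sel = np.asarray(sel)
        if sel.dtype == bool:
            idx = np.flatnonzero(sel)
        elif sel.dtype.kind in "iu":
            idx = sel
        else:
            lookup = {lid: i for i, lid in enumerate(self.loci["id"])}
            idx = np.array([lookup[s] for s in sel], dtype=int)
        return GenotypeMatrix(
            list(self.ids), self.loci.iloc[idx], self.dosage[:, idx]
        )

    def _individual_indices(self, sel: Sequence) -> np.ndarray:
        sel = list(sel)
        if all(isinstance(s, (int, np.integer)) for s in sel):
            return np.asarray(sel, dtype=int)
        lookup = {iid: i for i, iid in enumerate(self.ids)}
        return np.array([lookup[s] for s in sel], dtype=int)

    def align_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        """Reorder/subset columns to ``locus_ids``; error on absent loci."""
        have = set(self.loci["id"])
        missing = [l for l in locus_ids if l not in have]
        if missing:
            raise KeyError(
                f"{len(missing)} loci absent from panel, e.g. {missing[:5]}"
            )
        return self.subset_loci(list(locus_ids))

    def row(self, individual_id: str) -> np.ndarray:
        return self.dosage[self.ids.index(individual_id), :]


@dataclass
class FilterReport:
    """Bookkeeping for one filtering step (counts always reconcile)."""

    n_loci_in: int
    n_loci_out: int
    n_individuals_in: int
    n_individuals_out: int
    removed: dict[str, int] = field(default_factory=dict)
    per_locus_stats: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        loci_removed = sum(
            v for k, v in self.removed.items() if k.startswith("loci_")
        )
        indiv_removed = sum(
            v for k, v in self.removed.items() if k.startswith("individuals_")
        )
        if self.n_loci_in != self.n_loci_out + loci_removed:
            raise ValueError("locus counts do not reconcile")
        if self.n_individuals_in != self.n_individuals_out + indiv_removed:
            raise ValueError("individual counts do not reconcile")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("per_locus_stats")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------- #
# filters


def filter_missing_and_het(
    g: GenotypeMatrix,
    max_locus_missing: float = 0.40,
    max_indiv_missing: float = 0.30,
    max_indiv_het: float = 0.10,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci with too many missing calls, then individuals failing
    missing-rate or heterozygosity thresholds.

    Loci are filtered first (a call with a bad locus should not count
    against an individual), matching the usual PLINK convention.
    """
    for t in (max_locus_missing, max_indiv_missing, max_indiv_het):
        if not 0 <= t <= 1:
            raise ValueError("thresholds must be in [0, 1]")
    keep_loci = g.locus_missing_rate() < max_locus_missing
    g1 = g.subset_loci(keep_loci)
    if g1.n_loci == 0:
        raise EmptyPanelError("no loci left after missing-rate filter")
    bad_miss = g1.individual_missing_rate() >= max_indiv_missing
    bad_het = g1.individual_het_rate() >= max_indiv_het
    keep_ind = ~(bad_miss | bad_het)
    if not keep_ind.any():
        raise EmptyPanelError("no individuals left after filtering")
    g2 = g1.subset_individuals(np.flatnonzero(keep_ind))
    report = FilterReport(
        n_loci_in=g.n_loci,
        n_loci_out=g2.n_loci,
        n_individuals_in=g.n_individuals,
        n_individuals_out=g2.n_individuals,
        removed={
            "loci_missing": int((~keep_loci).sum()),
            "individuals_missing": int((bad_miss & ~bad_het).sum()),
            "individuals_het": int(bad_het.sum()),
        },
    )
    return g2, report


def segregation_filter(
    g: GenotypeMatrix, alpha: float = 0.001
) -> tuple[GenotypeMatrix, FilterReport]:
    """Chi-square test of 1:1 segregation in a DH panel.

    A locus is kept iff the one-degree-of-freedom statistic
    ``(n0 - n2)^2 / (n0 + n2)`` has p >= alpha, where n0/n2 count
    homozygous reference/alternate calls (missing and heterozygous calls
    excluded from the test). Monomorphic loci fall under the same statistic
    and are removed whenever the fixed class is large enough.
    """
    from scipy import stats

    n0 = (g.dosage == 0).sum(axis=0).astype(float)
    n2 = (g.dosage == 2).sum(axis=0).astype(float)
    n_het = int((g.dosage == 1).sum())
    total = n0 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(total > 0, (n0 - n2) ** 2 / np.maximum(total, 1), 0.0)
    pval = stats.chi2.sf(chi2, df=1)
    keep = pval >= alpha
    if not keep.any():
        raise EmptyPanelError("segregation filter removed every locus")
    stats_df = pd.DataFrame(
        {"id": g.loci["id"], "n0": n0, "n2": n2, "chi2": chi2, "p": pval}
    )
    out = g.subset_loci(keep)
    report = FilterReport(
        n_loci_in=g.n_loci,
        n_loci_out=out.n_loci,
        n_individuals_in=g.n_individuals,
        n_individuals_out=g.n_individuals,
        removed={"loci_segregation": int((~keep).sum())},
        per_locus_stats=stats_df,
        notes=(
            [f"{n_het} heterozygous calls excluded from segregation counts"]
            if n_het
            else []
        ),
    )
    return out, report


def drop_nonsegregating(g: GenotypeMatrix) -> GenotypeMatrix:
    """Remove loci showing a single non-missing dosage value.

    Applied to every training-plus-test genotype extraction before model
    fitting: a locus fixed in the extracted panel carries no information.
    """
    keep = g.polymorphic_mask()
    if not keep.any():
        raise EmptyPanelError("panel has no segregating loci")
    return g.subset_loci(keep)


def merge_populations(panels: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Union panel: loci genotyped in every population, plus loci
    polymorphic in at least one; individuals concatenated, with loci absent
    from a population set to missing for its individuals.
    """
    if len(panels) < 2:
        raise ValueError("need at least two panels to merge")
    meta: dict[str, tuple] = {}
    cm_of: dict[str, float] = {}
    for p in panels:
        for rec in p.loci.itertuples(index=False):
            # locus identity is keyed by (chrom, pos, alleles)
            key = (rec.chrom, rec.pos, rec.ref, rec.alt)
            if rec.id in meta and meta[rec.id] != key:
                raise ValueError(f"conflicting metadata for locus {rec.id}")
            meta.setdefault(rec.id, key)
            cm_of.setdefault(rec.id, rec.cm)
    sets = [set(p.loci["id"]) for p in panels]
    shared = set.intersection(*sets)
    poly: set[str] = set()
    for p in panels:
        poly |= set(np.asarray(p.loci["id"])[p.polymorphic_mask()])
    keep = shared | poly
    # deterministic order: chrom, pos
    ordered = sorted(keep, key=lambda lid: (meta[lid][0], meta[lid][1], lid))
    loci = pd.DataFrame(
        [
            (lid, meta[lid][0], meta[lid][1], cm_of[lid], meta[lid][2], meta[lid][3])
            for lid in ordered
        ],
        columns=LOCUS_COLUMNS,
    )
    col_of = {lid: j for j, lid in enumerate(ordered)}
    ids: list[str] = []
    rows = []
    for p in panels:
        block = np.full((p.n_individuals, len(ordered)), MISSING, dtype=np.int8)
        cols = [col_of[lid] for lid in p.loci["id"] if lid in col_of]
        src = [j for j, lid in enumerate(p.loci["id"]) if lid in col_of]
        block[:, cols] = p.dosage[:, src]
        rows.append(block)
        ids.extend(p.ids)
    return GenotypeMatrix(ids, loci, np.vstack(rows))


def derive_hybrid_genotypes(
    dh: GenotypeMatrix, tester: GenotypeMatrix | np.ndarray, tester_id: str | None = None
) -> GenotypeMatrix:
    """Test-cross hybrid genotypes: one gamete from the DH line, one from
    the tester, i.e. the mid-parent dosage ``(d_DH + d_tester) / 2``.

    Both parents must be homozygous (dosage 0/2) at non-missing loci — the
    only case in which the hybrid genotype is deterministic. Missing in
    either parent propagates to the hybrid. Hybrid ids are
    ``"<dh_id>/<tester_id>"``.
    """
    if isinstance(tester, GenotypeMatrix):
        if tester.n_individuals != 1:
            raise ValueError("tester panel must contain exactly one individual")
        t_dos = tester.align_loci(dh.locus_ids).dosage[0]
        tester_id = tester_id or tester.ids[0]
    else:
        t_dos = np.asarray(tester, dtype=np.int8)
        if tester_id is None:
            raise ValueError("tester_id required when tester is a raw vector")
    if (dh.dosage == 1).any() or (t_dos == 1).any():
        raise ValueError("heterozygous parental call: parents must be inbred")
    d = dh.dosage.astype(np.int16)
    t = t_dos.astype(np.int16)[None, :]
    hyb = (d + t) // 2
    miss = (dh.dosage == MISSING) | (t_dos == MISSING)[None, :]
    hyb[miss] = MISSING
    ids = [f"{i}/{tester_id}" for i in dh.ids]
    return GenotypeMatrix(ids, dh.loci.copy(), hyb.astype(np.int8))


def impute_major_dosage(g: GenotypeMatrix) -> GenotypeMatrix:
    """Naive fill of missing calls with the locus's most frequent dosage.

    A deliberately simple stand-in for LD-aware imputation, intended only
    for exercising the filter pipeline on masked data.
    """
    dos = g.dosage.copy()
    for j in range(g.n_loci):
        col = dos[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        vals, counts = np.unique(col[~miss], return_counts=True)
        fill = vals[np.argmax(counts)] if len(vals) else 0
        col[miss] = fill
    return GenotypeMatrix(list(g.ids), g.loci.copy(), dos)
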
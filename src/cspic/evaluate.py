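"""Prediction-accuracy protocols and accuracy-relatedness correlations.

Two sampling protocols mirror common practice for connected biparental
panels:

* within-population — sample 77 accessions, five-fold cross-validation,
  10 repeats; one Pearson correlation per repeat from the pooled
  out-of-fold GEBVs.
* cross-population — sample 55 training and 12 test accessions, fit on
  the training sample, predict the test sample, 50 repeats.

The summary statistic is always the median Pearson correlation over
repeats. All sampling is without replacement with per-repeat RNG
substreams derived from the task seed, so every protocol is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import PopulationDesign, dh_line_of
from .genodata import GenotypeMatrix, drop_nonsegregating, merge_populations
from .models import MarkerDesign, fit_model, predict


@dataclass
class AccuracyResult:
    """Per-repeat Pearson accuracies for one prediction task."""

    train_pop: str
    test_pop: str
    trait: str
    model: str
    per_repeat: list[float]
    n_train: int
    n_test: int
    seed: int
    category: str | None = None
    subtype: str | None = None
    n_skipped: int = 0

    @property
    def summary(self) -> float:
        """Median Pearson correlation over repeats."""
        return float(np.median(self.per_repeat))

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_repeat, dtype=float)
        if len(arr) and (np.nanmax(np.abs(arr)) > 1 + 1e-9):
            raise ValueError("Pearson correlations must lie in [-1, 1]")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _design_from_rows(rows: np.ndarray, panel: GenotypeMatrix) -> MarkerDesign:
    """MarkerDesign straight from pre-extracted float dosage rows (missing
    already handled upstream); avoids re-validating a GenotypeMatrix per
    resampling repeat."""
    miss = rows < 0
    if miss.any():
        rows = rows.copy()
        col_mean = np.where(
            miss.all(axis=0), 0.0, np.nanmean(np.where(miss, np.nan, rows), axis=0)
        )
        rows[miss] = col_mean[np.where(miss)[1]]
    center = rows.mean(axis=0)
    return MarkerDesign(rows - center, center, [], list(panel.loci["id"]))


def _mcmc_kwargs(model: str, rep_seed: int, model_kwargs: dict) -> dict:
    kw = dict(model_kwargs)
    if model in ("bayesb", "rkhs") and "seed" not in model_kwargs:
        kw["seed"] = rep_seed
    return kw


def within_population_cv(
    geno: GenotypeMatrix,
    pheno: pd.Series,
    model: str = "rrblup",
    n_sample: int = 77,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    model_kwargs: dict | None = None,
    allow_small: bool = False,
) -> AccuracyResult:
    """Within-population k-fold cross-validation accuracy.

    Per repeat: sample ``n_sample`` phenotyped accessions without
    replacement, split into ``folds`` folds, fit on the rest, predict the
    held-out fold, pool GEBVs over folds, and take one Pearson r against
    the phenotypes. Summary = median over repeats.
    """
    model_kwargs = model_kwargs or {}
    ids = [i for i in geno.ids if i in pheno.index and np.isfinite(pheno[i])]
    if len(ids) < n_sample:
        if not allow_small:
            raise ValueError(
                f"population has {len(ids)} phenotyped accessions < {n_sample}"
            )
        warnings.warn("population smaller than n_sample: using all accessions")
        n_sample = len(ids)
    panel = drop_nonsegregating(geno.subset_individuals(ids))
    dosage = panel.dosage.astype(float)
    y_vec = pheno.loc[panel.ids].to_numpy(dtype=float)
    rs: list[float] = []
    streams = np.random.SeedSequence(seed).spawn(repeats)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        rep_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        pick = rng.choice(len(panel.ids), size=n_sample, replace=False)
        order = rng.permutation(n_sample)
        fold_of = np.empty(n_sample, dtype=int)
        fold_of[order] = np.arange(n_sample) % folds
        preds = np.empty(n_sample)
        for f in range(folds):
            tr = pick[fold_of != f]
            te = pick[fold_of == f]
            design = _design_from_rows(dosage[tr], panel)
            fit = fit_model(
                model,
                y_vec[tr],
                design,
                **_mcmc_kwargs(model, rep_seed + f, model_kwargs),
            )
            preds[fold_of == f] = predict(fit, dosage[te])
        rs.append(_pearson(preds, y_vec[pick]))
    return AccuracyResult(
        train_pop="within",
        test_pop="within",
        trait=str(pheno.name),
        model=model,
        per_repeat=rs,
        n_train=n_sample - n_sample // folds,
        n_test=n_sample // folds,
        seed=seed,
    )


def _sample_task_ids(
    rng: np.random.Generator,
    train_ids: list[str],
    test_ids: list[str],
    n_train: int,
    n_test: int,
    same_pop: bool,
    subtype: str | None,
) -> tuple[list[str], list[str]]:
    test_pick = list(rng.choice(test_ids, size=n_test, replace=False))
    if same_pop:
        pool = [i for i in train_ids if i not in set(test_pick)]
        if len(pool) < n_train:
            raise ValueError("population too small for disjoint train/test samples")
        return list(rng.choice(pool, size=n_train, replace=False)), test_pick
    if subtype is None or subtype == "rand_DH":
        return list(rng.choice(train_ids, size=n_train, replace=False)), test_pick
    test_dh = {dh_line_of(i) for i in test_pick}
    if subtype == "same_DH":
        required = [i for i in train_ids if dh_line_of(i) in test_dh]
        if {dh_line_of(i) for i in required} != test_dh:
            raise ValueError("same_DH subtype infeasible: DH lines not in training pool")
        if len(required) > n_train:
            raise ValueError("same_DH subtype infeasible for these sample sizes")
        rest = [i for i in train_ids if i not in set(required)]
        extra = list(rng.choice(rest, size=n_train - len(required), replace=False))
        return required + extra, test_pick
    if subtype == "diff_DH":
        pool = [i for i in train_ids if dh_line_of(i) not in test_dh]
        if len(pool) < n_train:
            raise ValueError("diff_DH subtype infeasible for these sample sizes")
        return list(rng.choice(pool, size=n_train, replace=False)), test_pick
    raise ValueError(f"unknown subtype {subtype!r}")


def cross_population_eval(
    train_geno: GenotypeMatrix,
    train_pheno: pd.Series,
    test_geno: GenotypeMatrix,
    test_pheno: pd.Series,
    model: str = "rrblup",
    n_train: int = 55,
    n_test: int = 12,
    repeats: int = 50,
    seed: int = 0,
    model_kwargs: dict | None = None,
    category: str | None = None,
    subtype: str | None = None,
    train_pop: str = "train",
    test_pop: str = "test",
) -> AccuracyResult:
    """Cross-population prediction accuracy.

    Per repeat: sample ``n_train`` training and ``n_test`` test
    accessions, fit on the training sample over the union panel with
    non-segregating loci removed, predict the test sample, and take the
    Pearson r of GEBV against phenotype. When training and test
    populations coincide the sampled sets are kept disjoint. A requested
    Same_DH ``subtype`` (same_DH / rand_DH / diff_DH) constrains the
    DH-line overlap of the samples.
    """
    model_kwargs = model_kwargs or {}
    same_pop = train_geno.ids == test_geno.ids
    tr_ids = [
        i for i in train_geno.ids if i in train_pheno.index and np.isfinite(train_pheno[i])
    ]
    te_ids = [
        i for i in test_geno.ids if i in test_pheno.index and np.isfinite(test_pheno[i])
    ]
    if len(tr_ids) < n_train + (n_test if same_pop else 0):
        raise ValueError("training population too small")
    if len(te_ids) < n_test:
        raise ValueError("test population too small")
    test_loci = set(test_geno.loci["id"])
    shared = [l for l in train_geno.loci["id"] if l in test_loci]
    if same_pop:
        union = drop_nonsegregating(train_geno.subset_individuals(tr_ids))
    else:
        union = drop_nonsegregating(
            merge_populations(
                [
                    train_geno.subset_individuals(tr_ids).align_loci(shared),
                    test_geno.subset_individuals(te_ids).align_loci(shared),
                ]
            )
        )
    dosage = union.dosage.astype(float)
    row_of = {iid: i for i, iid in enumerate(union.ids)}
    rs: list[float] = []
    n_skipped = 0
    streams = np.random.SeedSequence(seed).spawn(repeats)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        rep_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        tr_pick, te_pick = _sample_task_ids(
            rng, tr_ids, te_ids, n_train, n_test, same_pop, subtype
        )
        y_te = test_pheno.loc[te_pick].to_numpy()
        if np.isfinite(y_te).sum() < 3:
            n_skipped += 1
            continue
        design = _design_from_rows(
            dosage[[row_of[i] for i in tr_pick]], union
        )
        fit = fit_model(
            model,
            train_pheno.loc[tr_pick].to_numpy(),
            design,
            **_mcmc_kwargs(model, rep_seed, model_kwargs),
        )
        preds = predict(fit, dosage[[row_of[i] for i in te_pick]])
        r = _pearson(preds, y_te)
        if np.isnan(r):
            n_skipped += 1
            continue
        rs.append(r)
    if n_skipped > repeats / 2:
        raise ValueError(f"{n_skipped}/{repeats} repeats skipped")
    return AccuracyResult(
        train_pop=train_pop,
        test_pop=test_pop,
        trait=str(train_pheno.name),
        model=model,
        per_repeat=rs,
        n_train=n_train,
        n_test=n_test,
        seed=seed,
        category=category,
        subtype=subtype,
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------- #
# correlation analyses


def accuracy_index_correlation(
    results: list[AccuracyResult], indices: list
) -> pd.DataFrame:
    """Pearson correlation of median accuracy with each relatedness index.

    ``indices`` holds one RelatednessIndices per result, in order. Returns
    one row per (trait, index) with r, two-sided p, and n. By the sign
    convention, distances (nei, ibs, fst) are expected to correlate
    negatively with accuracy and psp positively. Index vectors without
    variance are flagged undefined (r = NaN).
    """
    if len(results) != len(indices):
        raise ValueError("results and indices must match one-to-one")
    if len(results) < 3:
        raise ValueError("need at least three matched (accuracy, index) pairs")
    df = pd.DataFrame(
        {
            "trait": [r.trait for r in results],
            "accuracy": [r.summary for r in results],
            "psp": [i.psp for i in indices],
            "nei": [i.nei for i in indices],
            "ibs": [i.ibs for i in indices],
            "fst": [i.fst for i in indices],
        }
    )
    rows = []
    for trait, sub in df.groupby("trait"):
        for index_name in ("psp", "nei", "ibs", "fst"):
            x = sub[index_name].to_numpy()
            y = sub["accuracy"].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append((trait, index_name, np.nan, np.nan, int(ok.sum()), "undefined"))
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append((trait, index_name, float(r), float(p), int(ok.sum()), ""))
    return pd.DataFrame(
        rows, columns=["trait", "index", "r", "p", "n", "flag"]
    )


def dh_hybrid_accuracy_correlation(
    dh_results: list[AccuracyResult],
    hybrid_results: list[AccuracyResult],
    design: PopulationDesign,
) -> pd.DataFrame:
    """Correlation of DH-pair accuracy with the mean accuracy of the
    hybrid-population pairs built on the same DH pair.

    Each hybrid task maps to the ordered (source DH pop of training,
    source DH pop of test) pair; hybrid accuracies are averaged per DH
    pair and Pearson-correlated with the DH-pair accuracies, per trait.
    """
    hyb = pd.DataFrame(
        {
            "dh_pair": [
                (
                    design.hybrid_pops[r.train_pop].dh_pop,
                    design.hybrid_pops[r.test_pop].dh_pop,
                )
                for r in hybrid_results
            ],
            "trait": [r.trait for r in hybrid_results],
            "accuracy": [r.summary for r in hybrid_results],
        }
    )
    hyb_mean = hyb.groupby(["trait", "dh_pair"])["accuracy"].mean()
    rows = []
    for trait in sorted({r.trait for r in dh_results}):
        xs, ys = [], []
        for r in dh_results:
            if r.trait != trait:
                continue
            key = (trait, (r.train_pop, r.test_pop))
            if key not in hyb_mean.index:
                warnings.warn(f"DH pair {key[1]} has no mapped hybrid pair; excluded")
                continue
            xs.append(r.summary)
            ys.append(hyb_mean[key])
        if len(xs) < 2:
            raise ValueError(
                f"trait {trait}: fewer than two mapped DH pairs; correlation undefined"
            )
        r_val, p_val = stats.pearsonr(xs, ys)
        rows.append((trait, float(r_val), float(p_val), len(xs)))
    return pd.DataFrame(rows, columns=["trait", "r", "p", "n_pairs"])


def results_to_frame(results: list[AccuracyResult]) -> pd.DataFrame:
    """Tidy per-repeat table (task, category, trait, model, repeat, r)."""
    rows = []
    for res in results:
        for i, r in enumerate(res.per_repeat):
            rows.append(
                (
                    res.train_pop,
                    res.test_pop,
                    res.category,
                    res.subtype,
                    res.trait,
                    res.model,
                    i,
                    r,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "train_pop",
            "test_pop",
            "category",
            "subtype",
            "trait",
            "model",
            "repeat",
            "r",
        ],
    )


def summarize_results(results: list[AccuracyResult]) -> pd.DataFrame:
    rows = [
        (
            res.train_pop,
            res.test_pop,
            res.category,
            res.subtype,
            res.trait,
            res.model,
            res.n_repeats,
            res.summary,
        )
        for res in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "train_pop",
            "test_pop",
            "category",
            "subtype",
            "trait",
            "model",
            "n_repeats",
            "median_r",
        ],
    )
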
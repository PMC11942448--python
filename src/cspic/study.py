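"""Multi-seed replication of the cross-population prediction study.

Runs the full analysis — simulate the connected design, compute BLUEs,
evaluate within- and cross-population accuracy, compute relatedness
indices — over several independent simulation seeds and aggregates:

* median accuracy per prediction category (DH: full-sib / half-sib /
  non-sib; hybrid: Same_DH / Same_Tester; Same_DH subtypes),
* the correlation between cross-DH-pair accuracy and each relatedness
  index (PSP expected positive, distances negative),
* the correlation between DH-pair accuracy and the mean accuracy of the
  hybrid pairs built on the same DH populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import (
    AccuracyResult,
    accuracy_index_correlation,
    dh_hybrid_accuracy_correlation,
    summarize_results,
)
from .pipeline import (
    compute_population_blues,
    dh_relatedness_table,
    evaluate_cspic,
)
from .relatedness import RelatednessIndices
from .simulate import SimulationConfig, simulate_cspic


@dataclass
class StudyResult:
    """Aggregated multi-seed accuracy and relatedness summaries."""

    category_medians: pd.DataFrame  # seed x category median accuracy
    subtype_medians: pd.DataFrame  # seed x Same_DH subtype
    dh_pair_accuracy: pd.DataFrame  # (seed, train, test) median accuracy
    dh_pair_indices: pd.DataFrame  # (seed, train, test) psp/nei/ibs/fst
    hybrid_pair_accuracy: pd.DataFrame
    n_seeds: int
    trait: str
    model: str

    def category_summary(self) -> pd.Series:
        """Median over seeds of the per-seed category medians."""
        return self.category_medians.median(axis=0)

    def subtype_summary(self) -> pd.Series:
        return self.subtype_medians.median(axis=0)

    def index_accuracy_correlation(self) -> pd.DataFrame:
        """Accuracy-index correlations across DH pairs, seeds averaged."""
        cross = self.dh_pair_accuracy[
            self.dh_pair_accuracy["train_pop"] != self.dh_pair_accuracy["test_pop"]
        ]
        acc = (
            cross.groupby(["train_pop", "test_pop"])["median_r"].mean().sort_index()
        )
        idx = (
            self.dh_pair_indices.groupby(["train_pop", "test_pop"])
            .mean(numeric_only=True)
            .sort_index()
        )
        results = [
            AccuracyResult(a, b, self.trait, self.model, [acc[(a, b)]], 0, 0, 0)
            for a, b in acc.index
        ]
        indices = [
            RelatednessIndices(
                psp=idx.loc[(a, b), "psp"],
                nei=idx.loc[(a, b), "nei"],
                ibs=idx.loc[(a, b), "ibs"],
                fst=idx.loc[(a, b), "fst"],
            )
            for a, b in acc.index
        ]
        return accuracy_index_correlation(results, indices)

    def dh_hybrid_correlation(self, design) -> pd.DataFrame:
        dh_acc = (
            self.dh_pair_accuracy.groupby(["train_pop", "test_pop"])["median_r"]
            .mean()
        )
        hy_acc = (
            self.hybrid_pair_accuracy.groupby(["train_pop", "test_pop"])["median_r"]
            .mean()
        )
        dh_results = [
            AccuracyResult(a, b, self.trait, self.model, [v], 0, 0, 0)
            for (a, b), v in dh_acc.items()
            if a != b
        ]
        hy_results = [
            AccuracyResult(a, b, self.trait, self.model, [v], 0, 0, 0)
            for (a, b), v in hy_acc.items()
        ]
        return dh_hybrid_accuracy_correlation(dh_results, hy_results, design)


def run_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    trait: str = "PH",
    model: str = "rrblup",
    repeats_cross: int = 50,
    include_within: bool = False,
    sim_overrides: dict | None = None,
    model_kwargs: dict | None = None,
) -> StudyResult:
    """Replicate the cross-population analysis over ``n_seeds`` datasets.

    Each seed simulates a fresh connected design under the default
    generator conditions, fits BLUEs, and runs the cross-population
    protocols with RRBLUP by default (the three models give near-identical
    rankings; the fastest keeps replication cheap).
    """
    root = np.random.SeedSequence(base_seed)
    seeds = root.generate_state(n_seeds) % (2**31 - 1)
    cat_rows, sub_rows, acc_rows, idx_rows, hyb_rows = [], [], [], [], []
    design = None
    for si, s in enumerate(seeds):
        cfg = SimulationConfig(seed=int(s), **(sim_overrides or {}))
        ds = simulate_cspic(cfg)
        design = ds.design
        blues_dh = compute_population_blues(ds.dh_phenotypes, [trait])
        blues_hy = compute_population_blues(ds.hybrid_phenotypes, [trait])
        ev = evaluate_cspic(
            ds,
            blues_dh,
            blues_hy,
            model=model,
            traits=(trait,),
            seed=int(s) + 1,
            repeats_cross=repeats_cross,
            include_within=include_within,
            model_kwargs=model_kwargs,
        )
        summary = summarize_results(ev.all_results())
        med = summary.groupby("category")["median_r"].median()
        cat_rows.append(med.rename(si))
        sub = summary[summary["subtype"].notna()]
        sub_rows.append(sub.groupby("subtype")["median_r"].median().rename(si))
        dh_sum = summarize_results(ev.cross_dh)
        for _, row in dh_sum.iterrows():
            acc_rows.append(
                (si, row["train_pop"], row["test_pop"], row["category"], row["median_r"])
            )
        hy_sum = summarize_results(
            [r for r in ev.cross_hybrid if r.category == "Same_Tester"]
        )
        for _, row in hy_sum.iterrows():
            hyb_rows.append(
                (si, row["train_pop"], row["test_pop"], row["median_r"])
            )
        table, _ = dh_relatedness_table(ds)
        table.insert(0, "seed", si)
        idx_rows.append(table)
    return StudyResult(
        category_medians=pd.DataFrame(cat_rows),
        subtype_medians=pd.DataFrame(sub_rows),
        dh_pair_accuracy=pd.DataFrame(
            acc_rows, columns=["seed", "train_pop", "test_pop", "category", "median_r"]
        ),
        dh_pair_indices=pd.concat(idx_rows, ignore_index=True),
        hybrid_pair_accuracy=pd.DataFrame(
            hyb_rows, columns=["seed", "train_pop", "test_pop", "median_r"]
        ),
        n_seeds=n_seeds,
        trait=trait,
        model=model,
    )
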
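"""End-to-end orchestration: simulate -> filter/merge/synthesize -> BLUE ->
classify -> evaluate -> report.

`run_pipeline` drives the full analysis from one config and writes a run
directory with VCFs, phenotype/pedigree CSVs, the design JSON, per-task
accuracy tables, relatedness indices, and a resolved-config copy plus
checksums, so a run is reproducible byte-for-byte from its seed.

The intermediate helpers (`compute_population_blues`, `evaluate_cspic`,
`dh_relatedness_table`) are the programmatic surface used by scripts and
tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .design import (
    classify_dh_pair,
    classify_hybrid_pair,
    dh_label_matrix,
    hybrid_label_matrix,
)
from .evaluate import (
    AccuracyResult,
    accuracy_index_correlation,
    cross_population_eval,
    dh_hybrid_accuracy_correlation,
    results_to_frame,
    summarize_results,
    within_population_cv,
)
from .genodata import (
    GenotypeMatrix,
    derive_hybrid_genotypes,
    filter_missing_and_het,
    merge_populations,
    segregation_filter,
)
from .pheno import fit_lmm_blue
from .relatedness import RelatednessIndices, relatedness_indices
from .simulate import (
    DH_TRAITS,
    CspicDataset,
    SimulationConfig,
    simulate_cspic,
)


# ---------------------------------------------------------------------- #
# BLUE stage


def compute_population_blues(
    records: pd.DataFrame, traits: list[str] | None = None
) -> dict[tuple[str, str], pd.Series]:
    """Per-population, per-trait genotype BLUEs from plot records.

    ``records`` must carry a ``pop`` column alongside the plot columns.
    """
    out: dict[tuple[str, str], pd.Series] = {}
    traits = traits or sorted(records["trait"].unique())
    for (pop, trait), sub in records.groupby(["pop", "trait"]):
        if trait not in traits:
            continue
        blues, _ = fit_lmm_blue(sub, trait)
        out[(pop, trait)] = blues
    return out


# ---------------------------------------------------------------------- #
# filtering stage (mirrors the marker QC a real panel goes through)


def filter_and_merge_dh(
    dh_pops: dict[str, GenotypeMatrix], alpha: float = 0.001
) -> tuple[dict[str, GenotypeMatrix], GenotypeMatrix, dict]:
    """Per-population missing/het + segregation filters, then the merge
    rule (loci genotyped in all populations or polymorphic in at least
    one). Returns cleaned per-population panels restricted to the merged
    locus set, the merged panel, and the filter reports."""
    reports: dict = {}
    cleaned = {}
    for pid, g in dh_pops.items():
        g1, rep1 = filter_missing_and_het(g)
        g2, rep2 = segregation_filter(g1, alpha=alpha)
        cleaned[pid] = g2
        reports[pid] = {"missing_het": rep1.to_dict(), "segregation": rep2.to_dict()}
    merged = merge_populations(list(cleaned.values()))
    merged_ids = set(merged.loci["id"])
    restricted = {
        pid: g.subset_loci([l for l in g.loci["id"] if l in merged_ids])
        for pid, g in cleaned.items()
    }
    reports["merged_n_loci"] = merged.n_loci
    return restricted, merged, reports


# ---------------------------------------------------------------------- #
# evaluation stage


@dataclass
class CspicEvaluation:
    """All accuracy results for one simulated dataset."""

    within_dh: list[AccuracyResult] = field(default_factory=list)
    within_hybrid: list[AccuracyResult] = field(default_factory=list)
    cross_dh: list[AccuracyResult] = field(default_factory=list)
    cross_hybrid: list[AccuracyResult] = field(default_factory=list)
    subtype: list[AccuracyResult] = field(default_factory=list)

    def all_results(self) -> list[AccuracyResult]:
        return (
            self.within_dh
            + self.within_hybrid
            + self.cross_dh
            + self.cross_hybrid
            + self.subtype
        )


def evaluate_cspic(
    dataset: CspicDataset,
    blues_dh: dict[tuple[str, str], pd.Series],
    blues_hybrid: dict[tuple[str, str], pd.Series],
    model: str = "rrblup",
    traits: tuple[str, ...] = ("PH",),
    seed: int = 0,
    repeats_within: int = 10,
    repeats_cross: int = 50,
    n_within: int = 77,
    n_train: int = 55,
    n_test: int = 12,
    include_within: bool = True,
    include_dh: bool = True,
    include_hybrid: bool = True,
    include_subtypes: bool = True,
    hybrid_categories: tuple[str, ...] = ("Same_DH", "Same_Tester"),
    subtype_pairs_per_pop: int = 1,
    model_kwargs: dict | None = None,
) -> CspicEvaluation:
    """Run the within-/cross-population protocols over a simulated design.

    Cross-hybrid tasks are restricted to ``hybrid_categories`` (ordered
    pairs); Same_DH subtype tasks are drawn from the first
    ``subtype_pairs_per_pop`` ordered Same_DH pairs of each DH population.
    """
    design = dataset.design
    out = CspicEvaluation()
    root = np.random.SeedSequence(seed)
    task_seed = iter(root.generate_state(10_000) % (2**31 - 1))

    dh_ids = list(design.dh_pops)
    hy_ids = list(design.hybrid_pops)

    if include_within:
        for pid in dh_ids:
            for t in traits:
                if t not in DH_TRAITS:
                    continue
                res = within_population_cv(
                    dataset.dh_pops[pid],
                    blues_dh[(pid, t)].rename(t),
                    model=model,
                    n_sample=n_within,
                    repeats=repeats_within,
                    seed=int(next(task_seed)),
                    model_kwargs=model_kwargs,
                )
                res.train_pop = res.test_pop = pid
                res.category = "within"
                out.within_dh.append(res)
        for hid in hy_ids:
            for t in traits:
                res = within_population_cv(
                    dataset.hybrid_pops[hid],
                    blues_hybrid[(hid, t)].rename(t),
                    model=model,
                    n_sample=n_within,
                    repeats=repeats_within,
                    seed=int(next(task_seed)),
                    model_kwargs=model_kwargs,
                )
                res.train_pop = res.test_pop = hid
                res.category = "within"
                out.within_hybrid.append(res)

    if include_dh:
        for a in dh_ids:
            for b in dh_ids:
                label = classify_dh_pair(a, b, design)
                for t in traits:
                    if t not in DH_TRAITS:
                        continue
                    res = cross_population_eval(
                        dataset.dh_pops[a],
                        blues_dh[(a, t)].rename(t),
                        dataset.dh_pops[b],
                        blues_dh[(b, t)].rename(t),
                        model=model,
                        n_train=n_train,
                        n_test=n_test,
                        repeats=repeats_cross,
                        seed=int(next(task_seed)),
                        model_kwargs=model_kwargs,
                        category=label.category,
                        train_pop=a,
                        test_pop=b,
                    )
                    out.cross_dh.append(res)

    samedh_pairs: list[tuple[str, str]] = []
    if include_hybrid:
        for a in hy_ids:
            for b in hy_ids:
                if a == b:
                    continue
                cat = classify_hybrid_pair(a, b, design)
                if cat == "Same_DH":
                    samedh_pairs.append((a, b))
                if cat not in hybrid_categories:
                    continue
                for t in traits:
                    res = cross_population_eval(
                        dataset.hybrid_pops[a],
                        blues_hybrid[(a, t)].rename(t),
                        dataset.hybrid_pops[b],
                        blues_hybrid[(b, t)].rename(t),
                        model=model,
                        n_train=n_train,
                        n_test=n_test,
                        repeats=repeats_cross,
                        seed=int(next(task_seed)),
                        model_kwargs=model_kwargs,
                        category=cat,
                        train_pop=a,
                        test_pop=b,
                    )
                    out.cross_hybrid.append(res)

    if include_subtypes:
        chosen: list[tuple[str, str]] = []
        for pid in dh_ids:
            pop_pairs = [
                (a, b)
                for a, b in samedh_pairs
                if design.hybrid_pops[a].dh_pop == pid
            ]
            chosen.extend(pop_pairs[:subtype_pairs_per_pop])
        for a, b in chosen:
            for sub in ("same_DH", "rand_DH", "diff_DH"):
                for t in traits:
                    res = cross_population_eval(
                        dataset.hybrid_pops[a],
                        blues_hybrid[(a, t)].rename(t),
                        dataset.hybrid_pops[b],
                        blues_hybrid[(b, t)].rename(t),
                        model=model,
                        n_train=n_train,
                        n_test=n_test,
                        repeats=repeats_cross,
                        seed=int(next(task_seed)),
                        model_kwargs=model_kwargs,
                        category="Same_DH",
                        subtype=sub,
                        train_pop=a,
                        test_pop=b,
                    )
                    out.subtype.append(res)
    return out


def dh_relatedness_table(
    dataset: CspicDataset, merged: GenotypeMatrix | None = None
) -> tuple[pd.DataFrame, dict[tuple[str, str], RelatednessIndices]]:
    """Relatedness indices for every ordered DH population pair, against
    the merged panel's locus count as the PSP reference."""
    if merged is None:
        merged = merge_populations(list(dataset.dh_pops.values()))
    panel_n = merged.n_loci
    rows = []
    lookup: dict[tuple[str, str], RelatednessIndices] = {}
    pops = list(dataset.dh_pops)
    for a in pops:
        for b in pops:
            if a == b:
                continue
            idx = relatedness_indices(
                dataset.dh_pops[a], dataset.dh_pops[b], panel_n
            )
            lookup[(a, b)] = idx
            rows.append((a, b, idx.psp, idx.nei, idx.ibs, idx.fst))
    table = pd.DataFrame(
        rows, columns=["train_pop", "test_pop", "psp", "nei", "ibs", "fst"]
    )
    return table, lookup


# ---------------------------------------------------------------------- #
# full pipeline


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "cspic_run"
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    model: str = "rrblup"
    traits: list[str] = field(default_factory=lambda: ["PH"])
    repeats_within: int = 10
    repeats_cross: int = 50
    n_within: int = 77
    n_train: int = 55
    n_test: int = 12
    run_filters: bool = True
    run_evaluation: bool = True
    run_relatedness: bool = True
    model_kwargs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in dependency order and write a run
    directory; returns its path. Deterministic under ``config.seed``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
    dataset = simulate_cspic(sim_cfg)
    log.append(f"simulated {len(dataset.dh_pops)} DH and {len(dataset.hybrid_pops)} hybrid populations")

    cio.write_vcf(dataset.founders, out / "founders.vcf")
    for pid, g in dataset.dh_pops.items():
        cio.write_vcf(g, out / f"dh_{pid}.vcf")
    for hid, g in dataset.hybrid_pops.items():
        cio.write_vcf(g, out / f"hybrid_{hid.replace('/', '_')}.vcf")
    cio.write_phenotypes(dataset.dh_phenotypes, out / "dh_phenotypes.csv")
    cio.write_phenotypes(dataset.hybrid_phenotypes, out / "hybrid_phenotypes.csv")
    cio.write_pedigree(dataset.pedigree(), out / "pedigree.csv")
    dataset.design.to_json(out / "design.json")

    dh_label_matrix(dataset.design).to_csv(out / "dh_pair_labels.csv")
    hybrid_label_matrix(dataset.design).to_csv(out / "hybrid_pair_labels.csv")

    dh_panels = dataset.dh_pops
    if config.run_filters:
        dh_panels, merged, reports = filter_and_merge_dh(dataset.dh_pops)
        cio.write_vcf(merged, out / "merged.vcf")
        with open(out / "filter_reports.json", "w") as fh:
            json.dump(reports, fh, indent=2, default=str)
        log.append(f"merged panel: {merged.n_loci} loci")
        # re-synthesize hybrids from the cleaned panels, as a real run would
        founder_col = {l: j for j, l in enumerate(dataset.founders.loci["id"])}
        hybrid_panels = {}
        for hid, spec in dataset.design.hybrid_pops.items():
            panel = dh_panels[spec.dh_pop]
            cols = [founder_col[l] for l in panel.loci["id"]]
            hybrid_panels[hid] = derive_hybrid_genotypes(
                panel,
                dataset.founders.row(spec.tester)[cols],
                tester_id=spec.tester,
            )
        dataset = dataclasses.replace(
            dataset, dh_pops=dh_panels, hybrid_pops=hybrid_panels
        )

    results_frames = []
    if config.run_evaluation:
        blues_dh = compute_population_blues(dataset.dh_phenotypes, config.traits)
        blues_hy = compute_population_blues(dataset.hybrid_phenotypes, config.traits)
        evaluation = evaluate_cspic(
            dataset,
            blues_dh,
            blues_hy,
            model=config.model,
            traits=tuple(config.traits),
            seed=config.seed,
            repeats_within=config.repeats_within,
            repeats_cross=config.repeats_cross,
            n_within=config.n_within,
            n_train=config.n_train,
            n_test=config.n_test,
            model_kwargs=config.model_kwargs or None,
        )
        all_results = evaluation.all_results()
        results_to_frame(all_results).to_csv(out / "accuracy_per_repeat.csv", index=False)
        summarize_results(all_results).to_csv(out / "accuracy_summary.csv", index=False)
        results_frames.append("accuracy_summary.csv")
        log.append(f"evaluated {len(all_results)} prediction tasks")

        if config.run_relatedness:
            table, lookup = dh_relatedness_table(dataset)
            table.to_csv(out / "relatedness_dh_pairs.csv", index=False)
            cross = [r for r in evaluation.cross_dh if r.train_pop != r.test_pop]
            idx = [lookup[(r.train_pop, r.test_pop)] for r in cross]
            if len(cross) >= 3:
                accuracy_index_correlation(cross, idx).to_csv(
                    out / "accuracy_index_correlation.csv", index=False
                )
            same_tester = [
                r for r in evaluation.cross_hybrid if r.category == "Same_Tester"
            ]
            if same_tester and cross:
                try:
                    dh_hybrid_accuracy_correlation(
                        cross, same_tester, dataset.design
                    ).to_csv(out / "dh_hybrid_accuracy_correlation.csv", index=False)
                except ValueError as exc:
                    log.append(f"dh-hybrid correlation skipped: {exc}")
    elif config.run_relatedness:
        table, _ = dh_relatedness_table(dataset)
        table.to_csv(out / "relatedness_dh_pairs.csv", index=False)

    config.to_yaml(out / "resolved_config.yaml")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    checksums = {
        p.name: _checksum(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "checksums.json"
    }
    with open(out / "checksums.json", "w") as fh:
        json.dump(checksums, fh, indent=2)
    return out
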
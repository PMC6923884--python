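"""End-to-end orchestration: expression matrices -> comparison tables.

One seeded configuration drives the whole strategy: Wilcoxon feature
selection on the training partition only, a transductive PSN over all of the
cohort's samples, centrality / module extraction, feature assembly and
z-scoring, the stratified 50/25/25 split, per-family grid searches and the
final statistical comparison. Every stage's outputs and seeds are written to
an output directory together with a manifest, so any record is regenerable
from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from psntopo.classifiers import (
    DnnSpec, RfSpec, SvmSpec, grid_search, stratified_split,
)
from psntopo.evaluation import EvalRecord, best_model, compare_groups
from psntopo.feature_selection import select_features, wilcoxon_pvalues
from psntopo.io_formats import (
    ExpressionMatrix, OutcomeTable, read_expression_matrix, read_outcomes,
    write_feature_matrix, write_graph,
)
from psntopo.psn import build_psn
from psntopo.topology import (
    assemble_features, compute_centralities, fit_scaler, sbm_modules,
    spectral_modules, standardize,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full run.

    ``datasets`` maps a tag to either a loaded ExpressionMatrix or a path to
    an expression TSV; all datasets must cover the same samples (platform
    views of one cohort). Feature sets are any of 'centralities',
    'modularities', 'both'; with two or more datasets each set is also built
    on the concatenation.
    """

    datasets: dict[str, object]  # tag -> ExpressionMatrix | path
    outcomes: object             # OutcomeTable | path
    outcome_name: str = "event"
    alpha: float = 0.05
    fallback_frac: float = 0.05
    beta: int | str = "auto"
    feature_sets: tuple[str, ...] = ("centralities",)
    with_modules: bool = False   # compute spectral+SBM modules per dataset
    families: tuple[str, ...] = ("dnn",)
    dnn_grid: Sequence[DnnSpec] = field(default_factory=lambda: [DnnSpec()])
    svm_grid: Sequence[SvmSpec] = field(
        default_factory=lambda: [SvmSpec(kernel=k, cost_p=p, gamma_p=p)
                                 for k in ("linear", "rbf") for p in (-2, 0, 2)])
    rf_grid: Sequence[RfSpec] = field(
        default_factory=lambda: [RfSpec(n_trees=t) for t in (100, 1000)])
    replicates: int = 10
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        bad = [s for s in self.feature_sets
               if s not in ("centralities", "modularities", "both")]
        if bad:
            raise ValueError(f"unknown feature set token(s): {bad}")
        if any(s != "centralities" for s in self.feature_sets) and not self.with_modules:
            self.with_modules = True


def _load_dataset(obj, tag: str) -> ExpressionMatrix:
    if isinstance(obj, ExpressionMatrix):
        return obj
    return read_expression_matrix(obj, platform_tag=tag)


def run(config: RunConfig) -> dict:
    """Execute the full strategy; returns a report dict (and writes
    artifacts + manifest when ``out_dir`` is set)."""
    t0 = time.time()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    datasets = {tag: _load_dataset(obj, tag)
                for tag, obj in config.datasets.items()}
    outcomes = (config.outcomes if isinstance(config.outcomes, OutcomeTable)
                else read_outcomes(config.outcomes))
    first = next(iter(datasets.values()))
    sample_ids = list(first.sample_ids)
    outcomes = outcomes.aligned_to(sample_ids)
    y = outcomes.labels(config.outcome_name)

    split = stratified_split(outcomes, config.outcome_name,
                             seed=config.master_seed)
    train_pos = {s for s in split.train_ids}
    train_mask = np.array([s in train_pos for s in sample_ids])

    manifest = {
        "outcome": config.outcome_name,
        "alpha": config.alpha,
        "beta": config.beta,
        "master_seed": config.master_seed,
        "feature_sets": list(config.feature_sets),
        "families": list(config.families),
        "replicates": config.replicates,
        "python": platform.python_version(),
        "stages": {},
    }

    parts_by_tag: dict[str, list] = {}
    for tag, expr in datasets.items():
        if list(expr.sample_ids) != sample_ids:
            raise ValueError(f"[{tag}] sample ids differ across datasets")
        ts = time.time()
        X = expr.profiles()  # samples x features
        # selection on training samples only; the PSN then uses all samples
        pv = wilcoxon_pvalues(X[train_mask], y[train_mask])
        sel = select_features(pv, config.alpha, config.fallback_frac)
        Xsel = X[:, sel.selected]
        graph = build_psn(Xsel, sample_ids, beta=config.beta)
        cent = compute_centralities(graph)
        parts = [(cent, tag)]
        module_info = {}
        if config.with_modules:
            spec_mod = spectral_modules(graph, seed=config.master_seed)
            sbm_mod = sbm_modules(graph, seed=config.master_seed)
            parts.extend([(spec_mod, tag), (sbm_mod, tag)])
            module_info = {"spectral_k": spec_mod.k, "sbm_B": sbm_mod.k}
        parts_by_tag[tag] = parts
        manifest["stages"][tag] = {
            "n_selected": int(sel.selected.size),
            "fallback_used": bool(sel.fallback_used),
            "beta": graph.beta, "fit_r2": graph.fit_r2,
            "seconds": round(time.time() - ts, 2), **module_info,
        }
        logger.info("[%s] selected=%d beta=%s r2=%.3f", tag,
                    sel.selected.size, graph.beta, graph.fit_r2)
        if out:
            write_graph(graph, out / f"psn_{tag}.graphml")

    # feature configurations: per dataset and, with >= 2 datasets, concatenated
    tag_combos: list[tuple[str, list]] = [(t, parts_by_tag[t]) for t in datasets]
    if len(datasets) > 1:
        combined = [p for t in datasets for p in parts_by_tag[t]]
        tag_combos.append(("+".join(datasets), combined))

    all_records: list[EvalRecord] = []
    for combo_tag, parts in tag_combos:
        for set_choice in config.feature_sets:
            feats = assemble_features(parts, set_choice)
            scaler = fit_scaler(feats, feats.sample_ids)
            feats_std = standardize(feats, scaler=scaler)
            if out:
                write_feature_matrix(
                    feats_std.values, feats_std.feature_names,
                    feats_std.sample_ids,
                    out / f"topo_{combo_tag}_{set_choice}.tsv")
            for family in config.families:
                grid = {"dnn": config.dnn_grid, "svm": config.svm_grid,
                        "rf": config.rf_grid}[family]
                recs = grid_search(
                    family, feats_std, y, split, grid,
                    replicates=config.replicates,
                    master_seed=config.master_seed, dataset_tag=combo_tag)
                for r in recs:
                    if r.model is not None:
                        r.model.scaler = scaler
                all_records.extend(recs)

    records_df = pd.DataFrame([
        {k: getattr(r, k) for k in
         ("family", "config", "seed", "dataset_tag", "feature_set",
          "eval_bacc", "bacc")}
        for r in all_records
    ])
    report = {
        "n_samples": len(sample_ids),
        "split_sizes": [len(split.train_ids), len(split.eval_ids),
                        len(split.valid_ids)],
        "n_records": len(all_records),
        "records": records_df,
        "manifest": manifest,
        "eval_records": all_records,
    }
    winners = best_model(
        all_records, scope=lambda r: f"{r.dataset_tag}|{r.feature_set}|{r.family}")
    report["best_models"] = {
        k: {"config": v.config, "bacc": v.bacc} for k, v in winners.items()}
    report["best"] = best_model(all_records)
    groups = {(r.dataset_tag, r.feature_set) for r in all_records}
    families = {r.family for r in all_records}
    try:
        if len(groups) >= 2:
            report["comparison"] = compare_groups(
                all_records, lambda r: f"{r.dataset_tag}|{r.feature_set}")
        elif len(families) >= 2:
            report["comparison"] = compare_groups(all_records, "family")
    except ValueError:
        report["comparison"] = None

    manifest["seconds_total"] = round(time.time() - t0, 2)
    if out:
        records_df.to_csv(out / "records.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return report
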
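"""End-to-end orchestration: featurize -> screen -> select -> train -> report.

A run is driven by a :class:`RunConfig` (loadable from YAML). Outputs are
plain text (CSV/JSON) plus a provenance file echoing every parameter and
derived seed, so any number in the tables can be recomputed from the
provenance alone. Re-running with the same config and seed reproduces all
output files byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .classify_eval import (
    FAMILY_ORDER,
    ClassifierGrid,
    EvalReport,
    SplitConfig,
    best_model_table,
    default_grid,
    derive_seed,
    evaluate_dataset,
    grid_search_fit,
    reports_to_frame,
    shared_kmer_analysis,
    shared_kmers_to_frame,
    stratified_split,
    top_kmers,
)
from .feature_select import SelectionConfig
from .kmer_features import seven_datasets
from .repertoire_io import (
    dedupe_clonotypes,
    distributions_to_frame,
    join_annotations,
    length_distribution,
    read_repertoire,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; YAML-serializable."""

    repertoire: str
    metadata: str
    out_dir: str
    chain: str = "BCRH"
    subsets: Sequence[str] | None = None  # None = every subset in the metadata
    ks: Sequence[int] = (2, 3, 4)
    families: Sequence[str] = FAMILY_ORDER
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    selection_mode: str = "split-safe"  # or "pre-split" for comparability
    dedupe_clonotypes: bool = False
    row_unit: str = "sample"
    normalize: bool = False
    train_fraction: float = 0.8
    cv_folds: int = 5
    grid_overrides: Mapping[str, Mapping[str, list]] = field(default_factory=dict)
    n_perm: int = 99
    top_n_shared: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sel = raw.pop("selection", None)
        config = cls(**raw)
        if sel:
            config.selection = SelectionConfig(**sel)
        return config

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subsets"] = list(self.subsets) if self.subsets is not None else None
        d["ks"] = list(self.ks)
        d["families"] = list(self.families)
        return d


def _grids(config: RunConfig) -> dict[str, ClassifierGrid]:
    grids = {}
    for family in config.families:
        override = config.grid_overrides.get(family)
        if override:
            grids[family] = ClassifierGrid(family=family, grid=dict(override),
                                           cv_folds=config.cv_folds)
        else:
            grids[family] = default_grid(family, config.cv_folds)
    return grids


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full run; returns the output directory.

    Per subset: build all 2^|ks|-1 k-mer datasets, evaluate every requested
    classifier family on each, and write the flat results table, the
    best-model table, ROC points, length distributions, per-family reports
    (JSON) and provenance. With >= 2 subsets, the top important k-mers of
    each subset's best model are intersected pairwise.
    """
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, load_report = read_repertoire(config.repertoire, chain=config.chain)
    records, join_report = join_annotations(records, config.metadata)
    if config.dedupe_clonotypes:
        records = dedupe_clonotypes(records)
    if not records:
        raise RuntimeError("stage join_annotations: no records after joining "
                           f"{config.repertoire} with {config.metadata}")
    subsets = (
        list(config.subsets)
        if config.subsets
        else sorted({r.subset for r in records})
    )

    distributions_to_frame(length_distribution(records)).to_csv(
        out / "length_distributions.csv", index=False
    )

    grids = _grids(config)
    all_reports: list[EvalReport] = []
    best_tables = []
    top_by_subset: dict[str, list[tuple[str, float]]] = {}
    provenance_stages = []
    for subset in subsets:
        t_sub = time.perf_counter()
        sub_records = [r for r in records if r.subset == subset]
        if not sub_records:
            raise RuntimeError(f"stage featurize: subset {subset!r} has no records")
        datasets = seven_datasets(sub_records, ks=config.ks, subset=subset,
                                  row_unit=config.row_unit)
        if config.normalize:
            datasets = {name: m.normalized() for name, m in datasets.items()}
        sub_reports: list[EvalReport] = []
        for name, matrix in datasets.items():
            split = SplitConfig(
                train_fraction=config.train_fraction,
                seed=derive_seed(config.seed, subset, name, "split"),
            )
            sub_reports.extend(
                evaluate_dataset(
                    matrix,
                    dataset=name,
                    families=config.families,
                    selection=config.selection,
                    split=split,
                    grids=grids,
                    n_perm=config.n_perm,
                    seed=derive_seed(config.seed, subset),
                    cv_folds=config.cv_folds,
                    selection_mode=config.selection_mode,
                )
            )
        table = best_model_table(sub_reports)
        table.insert(0, "subset", subset)
        best_tables.append(table)
        all_reports.extend(sub_reports)

        # refit the subset's best (dataset, family) on its training split to
        # extract important k-mers for the shared-motif intersection
        best_row = table[table["best"]].iloc[0]
        matrix = datasets[best_row["kmer"]]
        split = SplitConfig(
            train_fraction=config.train_fraction,
            seed=derive_seed(config.seed, subset, best_row["kmer"], "split"),
        )
        tr, _ = stratified_split(matrix.labels, split)
        gs = grid_search_fit(
            matrix.counts[tr], matrix.labels[tr], grids[best_row["Model"]],
            seed=derive_seed(config.seed, subset, best_row["kmer"], best_row["Model"]),
            selection=config.selection,
        )
        top_by_subset[subset] = top_kmers(
            gs.best_estimator_, matrix.feature_space, top_n=config.top_n_shared
        )

        _write_subset_outputs(out, subset, sub_reports)
        logger.info("subset %s done in %.1fs", subset, time.perf_counter() - t_sub)
        provenance_stages.append(
            {"subset": subset, "datasets": list(datasets),
             "n_records": len(sub_records),
             "n_samples": len({r.sample_id for r in sub_records})}
        )

    reports_to_frame(all_reports).to_csv(out / "results_full.csv", index=False)
    pd.concat(best_tables, ignore_index=True).to_csv(
        out / "best_models.csv", index=False
    )
    pd.DataFrame(
        [
            {"subset": s, "rank": i, "kmer": k, "importance": v}
            for s, pairs in top_by_subset.items()
            for i, (k, v) in enumerate(pairs)
        ]
    ).to_csv(out / "top_kmers.csv", index=False)
    if len(top_by_subset) >= 2:
        shared = shared_kmer_analysis(top_by_subset, top_n=config.top_n_shared)
        shared_kmers_to_frame(shared).to_csv(out / "shared_kmers.csv", index=False)

    config_echo = config.to_dict()
    config_echo.pop("out_dir")  # implied by the file's own location
    provenance = {
        "kddc_version": __version__,
        "config": config_echo,
        "load_report": dataclasses.asdict(load_report),
        "join_report": dataclasses.asdict(join_report),
        "subsets": provenance_stages,
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )
    logger.info("run complete in %.1fs -> %s", time.perf_counter() - t0, out)
    return out


def _write_subset_outputs(out: Path, subset: str, reports: Sequence[EvalReport]) -> None:
    (out / f"reports_{subset}.json").write_text(
        json.dumps([r.to_dict() for r in reports], indent=2, sort_keys=True) + "\n"
    )
    roc_rows = [
        {"dataset": r.dataset_name, "family": r.family, "class": c,
         "fpr": float(f), "tpr": float(t)}
        for r in reports
        for c, (fpr, tpr) in r.roc_points.items()
        for f, t in zip(fpr, tpr)
    ]
    pd.DataFrame(
        roc_rows, columns=["dataset", "family", "class", "fpr", "tpr"]
    ).to_csv(out / f"roc_{subset}.csv", index=False)
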
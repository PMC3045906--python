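"""End-to-end orchestration: simulate -> features -> reduce -> classify ->
importance.

A single redundancy-reduced feature set is computed once and shared by all
three classification cases (domain of life, halophilicity, thermophilicity).
Each case gets the repeated-split evaluation, both permutation controls, and
a permutation-importance ranking; the three top-10 lists are combined into
unique-vs-shared case signatures. Every stage derives its randomness from
the one global seed, so a rerun with the same config reproduces the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aaindex import default_index_table, read_index_table
from .evaluation import (
    ClassifierSpec,
    EvaluationConfig,
    EvaluationReport,
    evaluate_case,
    one_against_one_multiclass,
    permutation_control,
)
from .features import build_feature_matrix, write_feature_matrix
from .importance import ImportanceReport, case_signatures, compute_importance
from .proteome_io import CASES, ClassScheme, build_case_labels, read_fasta, read_manifest
from .reduction import reduce_features, write_clustering_report
from .synthetic import default_config, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full-run configuration; `from_yaml`/`to_yaml` round-trip it."""

    seed: int = 0
    out_dir: str = "nichesig_run"
    manifest: str | None = None  # if None, simulate synthetic data
    index_table: str | None = None  # if None, bundled default
    simulate_case: str = "full"
    n_per_class: int = 16
    proteins_per_organism: int = 300
    cases: tuple[str, ...] = tuple(CASES)
    reduction_threshold: float = 0.9
    classifier: str = "tree_ensemble"
    n_trees: int = 1000
    n_repeats: int = 10
    train_fraction: float = 2.0 / 3.0
    normalization: str = "train_minmax"
    thermophile_threshold: float = 55.0
    run_controls: bool = True
    importance_shuffles: int = 3
    top_k: int = 10

    def evaluation_config(self, case_index: int) -> EvaluationConfig:
        return EvaluationConfig(
            train_fraction=self.train_fraction,
            n_repeats=self.n_repeats,
            seed=self.seed + 101 * (case_index + 1),
            classifier=ClassifierSpec(kind=self.classifier, n_trees=self.n_trees),
            normalization=self.normalization,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cases" in raw:
            raw["cases"] = tuple(raw["cases"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cases"] = list(d["cases"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class RunResult:
    out_dir: Path
    reduced_features: pd.DataFrame
    reports: dict[str, EvaluationReport]
    importances: dict[str, ImportanceReport]
    signatures: dict


def _load_or_simulate(config: RunConfig, out: Path):
    scheme = ClassScheme(thermophile_threshold=config.thermophile_threshold)
    if config.manifest is not None:
        manifest = read_manifest(config.manifest, scheme)
        base = Path(config.manifest).parent
        records = [
            read_fasta(base / row.fasta_path, organism_id=row.organism_id)
            for row in manifest.itertuples()
        ]
        return records, manifest
    sim = default_config(
        case=config.simulate_case,
        seed=config.seed,
        proteins_per_organism=config.proteins_per_organism,
        n_per_class=config.n_per_class,
    )
    records, manifest, truth = generate_dataset(sim, out / "data")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "labels": truth.labels,
                "tilted_residues": truth.tilted_residues,
                "target_frequencies": {
                    k: v.tolist() for k, v in truth.target_frequencies.items()
                },
            },
            fh,
            indent=1,
        )
    from .proteome_io import derive_thermo_class

    return records, derive_thermo_class(manifest, scheme)


def run_full(config: RunConfig) -> RunResult:
    """Execute all stages into ``config.out_dir``; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    config.to_yaml(out / "config_used.yaml")

    records, manifest = _load_or_simulate(config, out)
    logger.info("stage data: %d organisms (%.1fs)", len(records), time.time() - t0)

    table = (
        read_index_table(config.index_table)
        if config.index_table is not None
        else default_index_table()
    )
    t = time.time()
    features = build_feature_matrix(records, table)
    write_feature_matrix(features, out / "features.tsv")
    logger.info("stage features: %s matrix (%.1fs)", features.shape, time.time() - t)

    t = time.time()
    reduced, clustering, corr = reduce_features(features, config.reduction_threshold)
    write_feature_matrix(reduced, out / "features_reduced.tsv")
    write_clustering_report(clustering, corr, out / "feature_clusters.tsv")
    logger.info(
        "stage reduce: %d -> %d features (%.1fs)",
        features.shape[1], reduced.shape[1], time.time() - t,
    )

    reports: dict[str, EvaluationReport] = {}
    importances: dict[str, ImportanceReport] = {}
    for ci, case in enumerate(config.cases):
        t = time.time()
        labeled = build_case_labels(manifest, case)
        X = reduced.loc[labeled["organism_id"]]
        y = labeled["label"].to_numpy()
        econf = config.evaluation_config(ci)
        n_classes = labeled["label"].nunique()
        if n_classes == 2:
            report = evaluate_case(X, y, econf, case=case)
        else:
            report = one_against_one_multiclass(X, y, econf, case=case)
        if config.run_controls:
            for mode in ("feature_values", "class_labels"):
                ctrl = permutation_control(X, y, econf, mode, case=case)
                report.control_aucs[mode] = ctrl.mean_auc
        reports[case] = report
        importances[case] = compute_importance(
            X, y, econf, n_shuffles=config.importance_shuffles, k=config.top_k, case=case
        )
        importances[case].to_frame().to_csv(
            out / f"importance_{case}.tsv", sep="\t", index=False
        )
        _write_roc_points(report, out / f"roc_{case}.tsv")
        logger.info(
            "stage classify[%s]: mean AUC %.3f, controls %s (%.1fs)",
            case, report.mean_auc,
            {k: round(v, 3) for k, v in report.control_aucs.items()},
            time.time() - t,
        )

    sig_json: dict = {}
    if len(importances) == 3:
        sigs = case_signatures(importances)
        sig_json = {
            c: {
                "top_k": list(s.top_k),
                "unique_features": list(s.unique_features),
                "shared_features": list(s.shared_features),
            }
            for c, s in sigs.items()
        }
        with open(out / "signatures.json", "w") as fh:
            json.dump(sig_json, fh, indent=1)

    summary = {
        "version": __version__,
        "seed": config.seed,
        "n_organisms": len(records),
        "n_features_full": int(features.shape[1]),
        "n_features_reduced": int(reduced.shape[1]),
        "cases": {c: r.to_dict() for c, r in reports.items()},
        "runtime_seconds": round(time.time() - t0, 1),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return RunResult(
        out_dir=out,
        reduced_features=reduced,
        reports=reports,
        importances=importances,
        signatures=sig_json,
    )


def _write_roc_points(report: EvaluationReport, path: Path) -> None:
    rows = []
    for i, curve in enumerate(report.roc_curves):
        for f, tp in zip(curve.fpr, curve.tpr):
            rows.append({"repeat": i, "fpr": f, "tpr": tp, "auc": curve.auc})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
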
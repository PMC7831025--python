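"""End-to-end experiment orchestration.

Per pipette potential the pipeline runs anomaly detection, cross-validated
KNN classification with and without the anomaly filter, and the latent-space
centroid-distance analysis, then assembles a table with one row per
potential and columns

    Acc without AD | Acc with AD | Dist FH | Dist FE | Dist HE

("AD" = anomaly detection; the distance columns are the pairwise centroid
distances between the fibroblast/hippocampus, fibroblast/endothelium and
hippocampus/endothelium clusters, generalized to initial-letter pairs for
other label sets).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anomaly import AnomalyConfig, detect_anomalies, filter_dataset
from .autoencoder import AutoencoderSpec, TrainHyperparams
from .classify import CVResult, KNNConfig, run_cross_validation
from .errors import StageError
from .gating import Recording
from .latent import embed_and_cluster
from .preprocess import PreprocessConfig, make_cv_folds, preprocess_fold

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    potentials: tuple[float, ...] | None = None  # None: every potential present
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    knn: KNNConfig = field(default_factory=KNNConfig)
    anomaly: AnomalyConfig = field(default_factory=AnomalyConfig)
    embed_spec: AutoencoderSpec = field(default_factory=AutoencoderSpec)
    embed_hyperparams: TrainHyperparams = field(
        default_factory=lambda: TrainHyperparams(epochs=100)
    )
    kmeans_seed: int = 0
    latent_mode: str = "fold-mean"  # or "single-shot"
    run_anomaly_detection: bool = True


def _pair_key(a: str, b: str) -> str:
    """'fibroblast','hippocampus' -> 'FH' (sorted by initial)."""
    initials = sorted([a[0].upper(), b[0].upper()])
    return "".join(initials)


def group_by_class(
    grouped: dict[tuple[str, float], list[Recording]], potential: float
) -> dict[str, list[Recording]]:
    out: dict[str, list[Recording]] = {}
    for (label, u), recs in grouped.items():
        if u == potential:
            out.setdefault(label, []).extend(recs)
    return out


def fold_mean_distances(
    recordings_by_class: dict[str, list[Recording]],
    config: ExperimentConfig,
) -> dict[str, float]:
    """Mean over cross-validation folds of per-fold centroid distances in the
    2-D latent space of the fold's pooled test samples."""
    by_id = {r.recording_id: r for recs in recordings_by_class.values() for r in recs}
    groups = {lab: [r.recording_id for r in recs] for lab, recs in recordings_by_class.items()}
    folds = make_cv_folds(groups)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for fold in folds:
        data = preprocess_fold(fold, by_id, config.preprocess)
        result, _ = embed_and_cluster(
            data.X_test,
            data.y_test,
            spec=config.embed_spec,
            hyperparams=config.embed_hyperparams,
            seed=config.kmeans_seed,
        )
        if not result.distances:
            log.warning("fold %d produced a degenerate cluster map; skipped", fold.fold_id)
            continue
        for (a, b), d in result.distances.items():
            key = _pair_key(a, b)
            sums[key] = sums.get(key, 0.0) + d
            counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def single_shot_distances(
    recordings_by_class: dict[str, list[Recording]],
    config: ExperimentConfig,
) -> dict[str, float]:
    """Centroid distances from one embedding of all recordings' windows."""
    from .preprocess import windows_by_recording

    recs = [r for recs in recordings_by_class.values() for r in recs]
    per_rec = windows_by_recording(sorted(recs, key=lambda r: r.recording_id), config.preprocess)
    label_of = {r.recording_id: r.cell_label for r in recs}
    X = np.vstack([per_rec[rid] for rid in sorted(per_rec)])
    y = np.concatenate(
        [[label_of[rid]] * per_rec[rid].shape[0] for rid in sorted(per_rec)]
    )
    result, _ = embed_and_cluster(
        X, y, spec=config.embed_spec, hyperparams=config.embed_hyperparams,
        seed=config.kmeans_seed,
    )
    if not result.distances:
        raise StageError("single-shot embedding produced a degenerate cluster map")
    return {_pair_key(a, b): d for (a, b), d in result.distances.items()}


def run_experiment(
    grouped: dict[tuple[str, float], list[Recording]],
    config: ExperimentConfig | None = None,
) -> dict:
    """Run the whole analysis; returns a JSON-serializable report."""
    config = config or ExperimentConfig()
    potentials = (
        sorted(config.potentials)
        if config.potentials is not None
        else sorted({u for (_, u) in grouped})
    )
    report: dict = {"potentials": [], "rows": [], "anomaly_reports": [], "audit": []}
    for potential in potentials:
        sub = {cat: recs for cat, recs in grouped.items() if cat[1] == potential}
        by_class_full = group_by_class(sub, potential)
        log.info(
            "potential %+g mV: %s recordings",
            potential,
            {k: len(v) for k, v in sorted(by_class_full.items())},
        )
        cv_without = run_cross_validation(by_class_full, config.preprocess, config.knn)

        if config.run_anomaly_detection:
            reports = detect_anomalies(sub, config.anomaly)
            cleaned, audit = filter_dataset(sub, reports)
            by_class_clean = group_by_class(cleaned, potential)
            cv_with = run_cross_validation(by_class_clean, config.preprocess, config.knn)
            report["anomaly_reports"].extend(r.to_json() for r in reports)
            report["audit"].extend(audit)
        else:
            by_class_clean = by_class_full
            cv_with = cv_without

        if config.latent_mode == "single-shot":
            dists = single_shot_distances(by_class_clean, config)
        else:
            dists = fold_mean_distances(by_class_clean, config)

        row = {
            "potential_mV": potential,
            "acc_without_ad_pct": cv_without.accuracy_pct,
            "acc_with_ad_pct": cv_with.accuracy_pct,
            **{f"dist_{k.lower()}": v for k, v in sorted(dists.items())},
            "confusion_without_ad": cv_without.overall.to_json(),
            "confusion_with_ad": cv_with.overall.to_json(),
            "note": "latent distances are not comparable across potentials",
        }
        report["rows"].append(row)
        report["potentials"].append(potential)
    return report


def report_table(report: dict) -> pd.DataFrame:
    """Flatten the report into the one-row-per-potential summary table."""
    cols = ["potential_mV", "acc_without_ad_pct", "acc_with_ad_pct"]
    dist_cols = sorted(
        {c for row in report["rows"] for c in row if c.startswith("dist_")}
    )
    records = [
        {c: row.get(c) for c in cols + dist_cols} for row in report["rows"]
    ]
    return pd.DataFrame.from_records(records)


def save_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    csv_path = out_dir / "report.csv"
    json_path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    report_table(report).to_csv(csv_path, index=False)
    return json_path, csv_path
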
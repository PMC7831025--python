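"""Autoencoder-based rejection of anomalous recordings.

Within each (cell type, potential) category a bottleneck-2 autoencoder is
trained on all windows pooled (the suspect included), each recording is
scored by the mean reconstruction error J over its own windows, and
recordings whose modified z-score

    (score - median) / (1.4826 * MAD) > threshold      (default 3.5)

are flagged as outliers.  A bottleneck-sweep confirmation compares the
J-versus-bottleneck-dimension curve of a candidate against a typical
recording: a genuine outlier reconstructs worse at every bottleneck width.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .autoencoder import (
    AutoencoderSpec,
    TrainHyperparams,
    bottleneck_sweep,
    reconstruction_error,
    train_autoencoder,
)
from .errors import ConfigError, StageError
from .gating import Recording
from .preprocess import PreprocessConfig, windows_by_recording

log = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 3.5


@dataclass(frozen=True)
class AnomalyConfig:
    threshold: float = DEFAULT_Z_THRESHOLD
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spec: AutoencoderSpec = field(default_factory=AutoencoderSpec)
    hyperparams: TrainHyperparams = field(default_factory=lambda: TrainHyperparams(epochs=100))


@dataclass
class AnomalyReport:
    category: tuple[str, float]  # (cell_label, potential)
    per_recording_scores: dict[str, float]
    flagged: set[str]
    method: str
    threshold: float
    sweep: list | None = None

    def to_json(self) -> dict:
        return {
            "cell_label": self.category[0],
            "potential_mV": self.category[1],
            "scores": {k: float(v) for k, v in sorted(self.per_recording_scores.items())},
            "flagged": sorted(self.flagged),
            "method": self.method,
            "threshold": self.threshold,
        }


def score_category(
    recordings: list[Recording], config: AnomalyConfig | None = None
) -> dict[str, float]:
    """Per-recording mean reconstruction error within one category.

    One autoencoder is trained on the pooled windows of every recording in
    the category (>= 3 required); each recording's score is the mean J over
    its own windows.  Scores do not depend on recording order.
    """
    config = config or AnomalyConfig()
    if len(recordings) < 3:
        raise ConfigError("need >= 3 recordings in a category to score anomalies")
    per_rec = windows_by_recording(
        sorted(recordings, key=lambda r: r.recording_id), config.preprocess
    )
    pooled = np.vstack([per_rec[rid] for rid in sorted(per_rec)])
    spec = config.spec
    if spec.input_dim != pooled.shape[1]:
        spec = AutoencoderSpec(
            (pooled.shape[1],) + spec.layer_widths[1:], spec.linear_output
        )
    model = train_autoencoder(pooled, spec, config.hyperparams)
    return {rid: reconstruction_error(model, per_rec[rid]) for rid in sorted(per_rec)}


#: Relative floor on the robust spread: with as few as three recordings per
#: category the MAD wildly underestimates the recording-to-recording spread of
#: mean reconstruction errors, so the scale is floored at 10% of the median
#: score.  At the default z threshold of 3.5 a recording is then flagged only
#: when its error exceeds the category median by at least ~50% -- "clearly
#: standing out" -- while genuine aberrant patches sit at ~3x the median.
MAD_RELATIVE_FLOOR = 0.10


def flag_outliers(
    scores: dict[str, float], threshold: float = DEFAULT_Z_THRESHOLD
) -> set[str]:
    """Modified z-score rule; never flags when all scores are equal.

    The robust scale is 1.4826 * max(MAD, 0.10 * |median|); when that scale
    is exactly zero with unequal scores the rule falls back to a Tukey fence
    (score > Q3 + 1.5 IQR), logged.
    """
    if len(scores) < 3:
        raise ConfigError("need >= 3 scores to flag outliers")
    ids = sorted(scores)
    vals = np.asarray([scores[i] for i in ids], dtype=float)
    if np.ptp(vals) == 0:
        return set()
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    scale = 1.4826 * max(mad, MAD_RELATIVE_FLOOR * abs(med))
    if scale == 0:
        log.warning("zero robust scale with unequal scores; falling back to IQR rule")
        q1, q3 = np.percentile(vals, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        if q3 == q1:
            fence = q3  # all central mass identical: flag anything above it
        return {i for i, v in zip(ids, vals) if v > fence}
    z = (vals - med) / scale
    return {i for i, v in zip(ids, z) if v > threshold}


def confirm_outlier(
    candidate: Recording,
    typical: Recording,
    dims: list[int],
    config: AnomalyConfig | None = None,
) -> dict:
    """Bottleneck-sweep check: J versus dimension for both recordings.

    Each recording's windows are preprocessed independently; the verdict is
    True when the candidate's curve lies above the typical one at every
    tested dimension.
    """
    config = config or AnomalyConfig()
    if not dims:
        raise ConfigError("dims must be nonempty")
    curves = {}
    for name, rec in (("candidate", candidate), ("typical", typical)):
        wins = windows_by_recording([rec], config.preprocess)[rec.recording_id]
        spec = config.spec
        if spec.input_dim != wins.shape[1]:
            spec = AutoencoderSpec((wins.shape[1],) + spec.layer_widths[1:], spec.linear_output)
        curves[name] = bottleneck_sweep(wins, dims, spec, config.hyperparams)
    verdict = all(
        jc > jt for (_, jc), (_, jt) in zip(curves["candidate"], curves["typical"])
    )
    return {"candidate": curves["candidate"], "typical": curves["typical"], "verdict": verdict}


def detect_anomalies(
    grouped: dict[tuple[str, float], list[Recording]],
    config: AnomalyConfig | None = None,
) -> list[AnomalyReport]:
    """Score and flag every (cell type, potential) category."""
    config = config or AnomalyConfig()
    reports = []
    for category in sorted(grouped):
        scores = score_category(grouped[category], config)
        flagged = flag_outliers(scores, config.threshold)
        reports.append(
            AnomalyReport(
                category=category,
                per_recording_scores=scores,
                flagged=flagged,
                method="robust_z",
                threshold=config.threshold,
            )
        )
    return reports


def filter_dataset(
    grouped: dict[tuple[str, float], list[Recording]],
    reports: list[AnomalyReport],
) -> tuple[dict[tuple[str, float], list[Recording]], list[dict]]:
    """Remove flagged recordings; returns (cleaned groups, audit log).

    Raises when a removal would leave fewer than 2 recordings in a class at
    some potential (leave-one-out cross-validation would be impossible).
    """
    by_category = {r.category: r for r in reports}
    cleaned: dict[tuple[str, float], list[Recording]] = {}
    audit: list[dict] = []
    for category, recs in sorted(grouped.items()):
        report = by_category.get(category)
        if report is None:
            cleaned[category] = list(recs)
            continue
        kept = [r for r in recs if r.recording_id not in report.flagged]
        removed = [r for r in recs if r.recording_id in report.flagged]
        if removed and len(kept) < 2:
            raise StageError(
                f"removing {len(removed)} recording(s) from category {category} "
                f"leaves {len(kept)} < 2; cross-validation impossible"
            )
        cleaned[category] = kept
        for r in removed:
            audit.append(
                {
                    "recording_id": r.recording_id,
                    "cell_label": category[0],
                    "potential_mV": category[1],
                    "score": report.per_recording_scores[r.recording_id],
                    "threshold": report.threshold,
                    "method": report.method,
                }
            )
    # must round-trip as JSON for the audit file
    json.dumps(audit)
    return cleaned, audit
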
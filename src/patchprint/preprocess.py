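"""Recording-to-sample preprocessing and cross-validation fold construction.

The chain is: truncate all recordings to the shortest length, cut each
trace into overlapping windows of ``l`` points at stride ``r`` (exactly
floor((L - l)/r) windows per recording), compress each window to ``w``
points by Piecewise Aggregate Approximation (equal-frame means), and min-max
scale all values into [0, 1].

Cross-validation iterates over every configuration that holds out exactly
one recording per class as the test set; equal truncation makes every
recording contribute the same number of windows, which keeps the classes
balanced.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, StageError
from .gating import Recording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    window_length: int = 1000  # l, points
    stride: int = 200  # r, points
    paa_length: int = 200  # w, points
    normalization_scope: str = "per-fold-train"  # or "joint"

    def __post_init__(self) -> None:
        if not (0 < self.paa_length <= self.window_length):
            raise ConfigError("need 0 < paa_length <= window_length")
        if not (0 < self.stride <= self.window_length):
            raise ConfigError("need 0 < stride <= window_length")
        if self.window_length % self.paa_length != 0:
            raise ConfigError("window_length must be divisible by paa_length")
        if self.normalization_scope not in ("per-fold-train", "joint"):
            raise ConfigError(f"unknown normalization_scope {self.normalization_scope!r}")


def truncate_to_shortest(recordings: list[Recording]) -> list[Recording]:
    """Cut every trace to the length of the shortest one (prefix kept)."""
    if not recordings:
        raise ConfigError("no recordings to truncate")
    n = min(rec.trace.size for rec in recordings)
    out = []
    for rec in recordings:
        if rec.trace.size == n:
            out.append(rec)
        else:
            out.append(
                Recording(
                    recording_id=rec.recording_id,
                    cell_label=rec.cell_label,
                    potential=rec.potential,
                    trace=rec.trace[:n],
                    sampling_rate=rec.sampling_rate,
                    provenance=dict(rec.provenance),
                )
            )
    return out


def split_windows(trace: np.ndarray, window_length: int, stride: int) -> np.ndarray:
    """Windows of length l at 0-based offsets 0, r, 2r, ...

    Exactly floor((L - l)/r) windows are emitted.  L < l yields an empty
    array with a warning.
    """
    trace = np.asarray(trace)
    L = trace.size
    if L < window_length:
        warnings.warn(f"trace of length {L} shorter than window length {window_length}")
        return np.empty((0, window_length), dtype=float)
    n_windows = (L - window_length) // stride
    offsets = np.arange(n_windows) * stride
    return np.stack([trace[o : o + window_length] for o in offsets]) if n_windows else np.empty(
        (0, window_length), dtype=float
    )


def paa(window: np.ndarray, w: int) -> np.ndarray:
    """Piecewise Aggregate Approximation: means of w equal frames.

    Works on a single window (1-D) or a window matrix (2-D, one window per
    row).  The window length must be divisible by w (no partial frames).
    """
    window = np.asarray(window, dtype=float)
    length = window.shape[-1]
    if length % w != 0:
        raise ConfigError(f"window length {length} not divisible by paa length {w}")
    frame = length // w
    return window.reshape(*window.shape[:-1], w, frame).mean(axis=-1)


@dataclass
class ScaleParams:
    minimum: float
    maximum: float
    n_clipped_low: int = 0
    n_clipped_high: int = 0

    def transform(self, x: np.ndarray, clip: bool) -> np.ndarray:
        scaled = (x - self.minimum) / (self.maximum - self.minimum)
        if clip:
            self.n_clipped_low += int(np.sum(scaled < 0))
            self.n_clipped_high += int(np.sum(scaled > 1))
            scaled = np.clip(scaled, 0.0, 1.0)
        return scaled


def minmax_scale(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, ScaleParams]:
    """Affine [0,1] map fitted on the pooled training values, applied
    unchanged to the test set (values outside the training range are clipped
    and counted in the returned ScaleParams)."""
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ConfigError("empty training data")
    mn, mx = float(train.min()), float(train.max())
    if mx <= mn:
        raise StageError("constant training data: min-max scaling undefined")
    params = ScaleParams(mn, mx)
    train_scaled = params.transform(train, clip=False)
    test_scaled = params.transform(np.asarray(test, dtype=float), clip=True) if test is not None else None
    return train_scaled, test_scaled, params


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    test_recordings: tuple[str, ...]  # exactly one per class
    train_recordings: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.test_recordings) & set(self.train_recordings):
            raise ConfigError("test and train recordings overlap")


def make_cv_folds(groups: dict[str, list[str]]) -> list[FoldSplit]:
    """One fold per element of the Cartesian product of per-class recording
    choices, in lexicographic order of recording ids."""
    classes = sorted(groups)
    for label in classes:
        if len(groups[label]) < 2:
            raise ConfigError(
                f"class {label!r} has fewer than 2 recordings; cross-validation impossible"
            )
    per_class = [sorted(groups[label]) for label in classes]
    all_ids = [rid for ids in per_class for rid in ids]
    folds = []
    for i, combo in enumerate(itertools.product(*per_class)):
        test = tuple(combo)
        train = tuple(rid for rid in all_ids if rid not in set(test))
        folds.append(FoldSplit(fold_id=i, test_recordings=test, train_recordings=train))
    return folds


@dataclass
class FoldData:
    X_train: np.ndarray
    y_train: np.ndarray  # class labels, one per window
    meta_train: pd.DataFrame  # recording_id, start_offset
    X_test: np.ndarray
    y_test: np.ndarray
    meta_test: pd.DataFrame
    truncation_length: int
    scale: ScaleParams


def _windows_of(recordings: list[Recording], config: PreprocessConfig):
    """Window + PAA each recording; returns (matrix, labels, meta)."""
    mats, labels, meta = [], [], []
    for rec in recordings:
        wins = split_windows(rec.trace, config.window_length, config.stride)
        if wins.shape[0] == 0:
            continue
        reduced = paa(wins, config.paa_length)
        mats.append(reduced)
        labels.extend([rec.cell_label] * reduced.shape[0])
        offsets = np.arange(reduced.shape[0]) * config.stride
        meta.extend(
            {"recording_id": rec.recording_id, "start_offset": int(o)} for o in offsets
        )
    if not mats:
        raise StageError("no windows produced; recordings shorter than the window length?")
    return np.vstack(mats), np.asarray(labels), pd.DataFrame(meta)


def windows_by_recording(
    recordings: list[Recording], config: PreprocessConfig, scale: bool = True
) -> dict[str, np.ndarray]:
    """Category-level preprocessing (no train/test split): truncate to the
    shortest recording, window, PAA, and (optionally) min-max scale the
    pooled values.  Used by anomaly detection."""
    truncated = truncate_to_shortest(recordings)
    per_rec = {}
    for rec in truncated:
        wins = split_windows(rec.trace, config.window_length, config.stride)
        per_rec[rec.recording_id] = paa(wins, config.paa_length)
    if scale:
        pooled = np.concatenate([m.ravel() for m in per_rec.values()])
        mn, mx = pooled.min(), pooled.max()
        if mx <= mn:
            raise StageError("constant category data: min-max scaling undefined")
        per_rec = {k: (m - mn) / (mx - mn) for k, m in per_rec.items()}
    return per_rec


def preprocess_fold(
    fold: FoldSplit,
    recordings: dict[str, Recording],
    config: PreprocessConfig | None = None,
) -> FoldData:
    """Run the full chain truncate -> window -> PAA -> scale for one fold.

    The truncation length is computed over train and test together (every
    recording ends up with the same number of windows); the [0,1] scaling is
    fitted on training values only and applied (with clipping) to the test
    set, unless ``normalization_scope`` is "joint", in which case train and
    test are pooled before fitting the affine map.
    """
    config = config or PreprocessConfig()
    ordered_ids = list(fold.train_recordings) + list(fold.test_recordings)
    missing = [rid for rid in ordered_ids if rid not in recordings]
    if missing:
        raise StageError(f"fold references unknown recordings: {missing}")
    truncated = truncate_to_shortest([recordings[rid] for rid in ordered_ids])
    by_id = {rec.recording_id: rec for rec in truncated}
    X_train, y_train, meta_train = _windows_of(
        [by_id[rid] for rid in fold.train_recordings], config
    )
    X_test, y_test, meta_test = _windows_of(
        [by_id[rid] for rid in fold.test_recordings], config
    )
    if config.normalization_scope == "joint":
        pooled = np.vstack([X_train, X_test])
        pooled_scaled, _, params = minmax_scale(pooled)
        X_train = pooled_scaled[: X_train.shape[0]]
        X_test = pooled_scaled[X_train.shape[0] :]
    else:
        X_train, X_test, params = minmax_scale(X_train, X_test)
    return FoldData(
        X_train=X_train,
        y_train=y_train,
        meta_train=meta_train,
        X_test=X_test,
        y_test=y_test,
        meta_test=meta_test,
        truncation_length=truncated[0].trace.size,
        scale=params,
    )
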
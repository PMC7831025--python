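"""Basic kinetic analysis of single-channel recordings.

Three quantities are computed per recording / per class:

* the threshold current TC separating conducting from non-conducting
  samples, located at the intersection of two power-law (straight-line)
  fits to the log-log amplitude density estimated with an Epanechnikov
  kernel;
* the open-state probability p_op, the fraction of samples whose current
  magnitude exceeds TC;
* a Boltzmann (sigmoidal) activation curve p_op(U) = p_max / (1 +
  exp(-(U - V_half)/slope)) fitted across pipette potentials.

The power-law detection rule is an explicit, deterministic surrogate for
what is usually done by eye: on each flank of the inter-modal valley of the
log-density we take the widest grid window whose linear fit achieves
R^2 >= ``r2_min``, fit both lines by least squares and intersect them.
When no acceptable window pair exists the estimator falls back to the
arithmetic midpoint of the two density modes (logged as such).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from sklearn.neighbors import KernelDensity

from .errors import DegenerateFitError, StageError, StateSeparationError
from .gating import Recording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdConfig:
    grid_size: int = 512
    bandwidth: float | None = None  # None: Silverman-style rule on log-amplitudes
    r2_min: float = 0.98
    min_window: int = 8  # grid points
    # prominence of a mode in log-density units: the dip separating two
    # genuine conductance modes is many log-units deep, while sparse-tail
    # KDE wiggle stays under ~1, so 1.5 (an e^1.5 ~ 4.5-fold density dip)
    # cleanly separates the two
    peak_prominence: float = 1.5
    # a conductance state must hold at least this fraction of samples
    min_state_fraction: float = 1e-3
    max_kde_points: int = 100_000  # subsample cap for the KDE fit


@dataclass(frozen=True)
class PowerLawSegment:
    exponent: float  # slope in log-log coordinates
    intercept: float
    interval: tuple[float, float]  # amplitude interval (pA)


@dataclass(frozen=True)
class ThresholdEstimate:
    tc: float  # pA
    kde_amplitude: np.ndarray  # grid abscissa, pA
    kde_density: np.ndarray  # density of log-amplitude on the grid
    segments: tuple[PowerLawSegment, PowerLawSegment] | None
    method: str  # "powerlaw_intersection" | "midpoint_fallback"
    bandwidth: float = float("nan")
    grid_size: int = 0


def _log_amplitude(trace: np.ndarray) -> tuple[np.ndarray, float]:
    a = np.abs(np.asarray(trace, dtype=float))
    delta = max(a.max(), 1e-12) / 2048.0  # small offset guarding log(0)
    return np.log(a + delta), delta


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(sd, 1e-3)
    return 0.9 * scale * n ** (-0.2)


def _widest_linear_window(
    x: np.ndarray, y: np.ndarray, r2_min: float, min_window: int
) -> tuple[int, int] | None:
    """Widest [i, j) with a linear fit of y on x reaching R^2 >= r2_min.

    Prefix sums give O(1) fit statistics per window; windows are scanned in
    decreasing length so the first acceptable window is the widest (ties:
    leftmost).
    """
    n = x.size
    if n < min_window:
        return None
    one = np.ones(n)
    cs = {
        "n": np.concatenate([[0], np.cumsum(one)]),
        "x": np.concatenate([[0], np.cumsum(x)]),
        "y": np.concatenate([[0], np.cumsum(y)]),
        "xx": np.concatenate([[0], np.cumsum(x * x)]),
        "yy": np.concatenate([[0], np.cumsum(y * y)]),
        "xy": np.concatenate([[0], np.cumsum(x * y)]),
    }
    for length in range(n, min_window - 1, -1):
        starts = np.arange(0, n - length + 1)
        ends = starts + length
        m = cs["n"][ends] - cs["n"][starts]
        sx = cs["x"][ends] - cs["x"][starts]
        sy = cs["y"][ends] - cs["y"][starts]
        sxx = cs["xx"][ends] - cs["xx"][starts]
        syy = cs["yy"][ends] - cs["yy"][starts]
        sxy = cs["xy"][ends] - cs["xy"][starts]
        sxx_c = sxx - sx * sx / m
        syy_c = syy - sy * sy / m
        sxy_c = sxy - sx * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(
                (sxx_c > 0) & (syy_c > 0), sxy_c**2 / (sxx_c * syy_c), 0.0
            )
        ok = np.nonzero(r2 >= r2_min)[0]
        if ok.size:
            start = int(starts[ok[0]])
            return start, start + length
    return None


def _density_modes(
    log_dens: np.ndarray,
    grid: np.ndarray,
    x: np.ndarray,
    prominence: float,
    min_state_fraction: float,
) -> tuple[int, int]:
    """The two conductance modes of the log-amplitude density, as (low, high)
    grid indices.

    The dominant mode is the global density maximum.  The partner mode is
    the highest local maximum (minimum-padding makes boundary maxima
    visible) whose valley towards the dominant mode dips at least
    ``prominence`` log-units below both peaks AND that keeps at least
    ``min_state_fraction`` of the samples on its own side of the valley —
    KDE raggedness within one mode fails the dip test, and sparse-tail
    wiggle fails the mass test.  Raises when no such partner exists
    (unimodal density).
    """
    floor = log_dens.min() - 1e-9
    padded = np.concatenate([[floor], log_dens, [floor]])
    peaks, _ = find_peaks(padded)
    peaks = np.unique(peaks - 1)
    if peaks.size >= 2:
        order = np.argsort(log_dens[peaks])[::-1]
        main = int(peaks[order[0]])
        for i in order[1:]:
            cand = int(peaks[i])
            p_lo, p_hi = min(main, cand), max(main, cand)
            valley_rel = int(np.argmin(log_dens[p_lo : p_hi + 1]))
            valley = float(log_dens[p_lo + valley_rel])
            if min(log_dens[p_lo], log_dens[p_hi]) - valley < prominence:
                continue
            cut = grid[p_lo + valley_rel]
            side_mass = float(np.mean(x < cut) if cand < main else np.mean(x > cut))
            if side_mass < min_state_fraction:
                continue
            return p_lo, p_hi
    raise StateSeparationError(
        "amplitude density is unimodal: cannot separate conducting and "
        "non-conducting states"
    )


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def estimate_threshold_current(
    recording: Recording | np.ndarray, config: ThresholdConfig | None = None
) -> ThresholdEstimate:
    """Threshold current from the power-law intersection rule.

    Raises :class:`StateSeparationError` when the amplitude density is not
    bimodal and :class:`StageError` when the power-law intersection cannot
    be located inside the inter-modal region (callers wanting the midpoint
    fallback should use :func:`threshold_current`).
    """
    config = config or ThresholdConfig()
    trace = recording.trace if isinstance(recording, Recording) else np.asarray(recording)
    if trace.size < 1000:
        raise StageError("need at least 1000 samples to estimate the threshold current")

    x, delta = _log_amplitude(trace)
    if x.size > config.max_kde_points:
        # deterministic thinning; KDE shape is insensitive to this at 1e5 points
        step = int(np.ceil(x.size / config.max_kde_points))
        x_fit = x[::step]
    else:
        x_fit = x
    bw = config.bandwidth if config.bandwidth is not None else _silverman_bandwidth(x_fit)
    kde = KernelDensity(kernel="epanechnikov", bandwidth=bw)
    kde.fit(x_fit[:, None])
    grid = np.linspace(x.min(), x.max(), config.grid_size)
    log_dens = kde.score_samples(grid[:, None])
    finite = np.isfinite(log_dens)
    floor = log_dens[finite].min() - 10.0 if finite.any() else -50.0
    log_dens = np.where(finite, log_dens, floor)

    p_lo, p_hi = _density_modes(
        log_dens, grid, x, config.peak_prominence, config.min_state_fraction
    )
    valley = p_lo + int(np.argmin(log_dens[p_lo : p_hi + 1]))

    left = _widest_linear_window(
        grid[p_lo : valley + 1], log_dens[p_lo : valley + 1], config.r2_min, config.min_window
    )
    right = _widest_linear_window(
        grid[valley : p_hi + 1], log_dens[valley : p_hi + 1], config.r2_min, config.min_window
    )
    amplitude_grid = np.exp(grid) - delta
    if left is None or right is None:
        raise StageError("no power-law window found flanking the inter-modal region")
    li, lj = left[0] + p_lo, left[1] + p_lo
    ri, rj = right[0] + valley, right[1] + valley
    m1, b1 = _fit_line(grid[li:lj], log_dens[li:lj])
    m2, b2 = _fit_line(grid[ri:rj], log_dens[ri:rj])
    if m1 == m2:
        raise StageError("power-law fits are parallel; no intersection")
    x_star = (b2 - b1) / (m1 - m2)
    if not (grid[p_lo] < x_star < grid[p_hi]):
        raise StageError("power-law intersection lies outside the inter-modal region")
    tc = float(np.exp(x_star) - delta)
    segments = (
        PowerLawSegment(m1, b1, (float(amplitude_grid[li]), float(amplitude_grid[lj - 1]))),
        PowerLawSegment(m2, b2, (float(amplitude_grid[ri]), float(amplitude_grid[rj - 1]))),
    )
    return ThresholdEstimate(
        tc=tc,
        kde_amplitude=amplitude_grid,
        kde_density=np.exp(log_dens),
        segments=segments,
        method="powerlaw_intersection",
        bandwidth=float(bw),
        grid_size=config.grid_size,
    )


def threshold_midpoint(
    recording: Recording | np.ndarray, config: ThresholdConfig | None = None
) -> ThresholdEstimate:
    """Fallback threshold: arithmetic midpoint of the two KDE mode amplitudes."""
    config = config or ThresholdConfig()
    trace = recording.trace if isinstance(recording, Recording) else np.asarray(recording)
    x, delta = _log_amplitude(trace)
    bw = config.bandwidth if config.bandwidth is not None else _silverman_bandwidth(x)
    kde = KernelDensity(kernel="epanechnikov", bandwidth=bw)
    sub = x[:: max(1, int(np.ceil(x.size / config.max_kde_points)))]
    kde.fit(sub[:, None])
    grid = np.linspace(x.min(), x.max(), config.grid_size)
    log_dens = kde.score_samples(grid[:, None])
    log_dens = np.where(np.isfinite(log_dens), log_dens, np.nanmin(log_dens[np.isfinite(log_dens)]) - 10)
    p_lo, p_hi = _density_modes(
        log_dens, grid, x, config.peak_prominence, config.min_state_fraction
    )
    a_lo, a_hi = np.exp(grid[p_lo]) - delta, np.exp(grid[p_hi]) - delta
    return ThresholdEstimate(
        tc=float((a_lo + a_hi) / 2.0),
        kde_amplitude=np.exp(grid) - delta,
        kde_density=np.exp(log_dens),
        segments=None,
        method="midpoint_fallback",
        bandwidth=float(bw),
        grid_size=config.grid_size,
    )


def threshold_current(
    recording: Recording | np.ndarray, config: ThresholdConfig | None = None
) -> ThresholdEstimate:
    """Power-law intersection threshold with the midpoint fallback.

    The fallback triggers when power-law windows cannot be located (e.g.
    noise-free traces whose log-density has no linear flank); its use is
    logged at WARNING level.
    """
    try:
        return estimate_threshold_current(recording, config)
    except StateSeparationError:
        raise
    except StageError as exc:
        log.warning("power-law threshold failed (%s); using mode-midpoint fallback", exc)
        return threshold_midpoint(recording, config)


def open_probability(recording: Recording | np.ndarray, tc: float) -> float:
    """Fraction of samples with |current| > tc; a per-sample census in [0, 1]."""
    trace = recording.trace if isinstance(recording, Recording) else np.asarray(recording)
    return float(np.mean(np.abs(trace) > tc))


def estimate_open_probability(
    recording: Recording | np.ndarray, config: ThresholdConfig | None = None
) -> tuple[float, str]:
    """Open probability with the full threshold pipeline, covering the
    degenerate extremes.

    When the amplitude density is unimodal (the channel effectively never
    leaves one state at this potential) there is no threshold to estimate;
    the recording is then assigned p_op 1.0 when the dominant mode sits at
    open-channel amplitudes (median |I| above half the maximum magnitude)
    and 0.0 when it sits at the baseline.  Returns (p_op, method).
    """
    trace = recording.trace if isinstance(recording, Recording) else np.asarray(recording)
    try:
        est = threshold_current(recording, config)
    except StateSeparationError:
        a = np.abs(trace)
        return (1.0 if np.median(a) > a.max() / 2.0 else 0.0), "unimodal"
    return open_probability(recording, est.tc), est.method


# ---------------------------------------------------------------------------
# Activation-curve fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivationCurve:
    points: list[tuple[float, float, float]]  # (potential, mean p_op, SD)
    v_half: float
    slope: float
    p_max: float
    residual_sum: float

    def predict(self, potential: float) -> float:
        return self.p_max / (1.0 + np.exp(-(potential - self.v_half) / self.slope))


def _boltzmann(params: np.ndarray, u: np.ndarray) -> np.ndarray:
    v_half, slope, p_max = params
    return p_max / (1.0 + np.exp(-(u - v_half) / slope))


def fit_activation_curve(points: list[tuple[float, float]]) -> ActivationCurve:
    """Least-squares Boltzmann fit of p_op against pipette potential.

    ``points`` may contain several replicates per potential; the reported
    per-potential mean and SD aggregate them while the fit uses all raw
    points.  Degenerate inputs (constant p_op) raise
    :class:`DegenerateFitError`; non-convergence raises :class:`StageError`
    carrying the last iterate.
    """
    u = np.asarray([p[0] for p in points], dtype=float)
    p = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(u).size < 4:
        raise StageError("need p_op at >= 4 distinct potentials to fit activation")
    if np.any((p < 0) | (p > 1)):
        raise StageError("open probabilities must lie in [0, 1]")
    if np.ptp(p) < 1e-3:
        raise DegenerateFitError(
            f"p_op is constant ({p.mean():.3f}) across potentials: slope unidentifiable"
        )

    p0 = np.array([np.median(u), 15.0, min(1.0, max(p.max(), 1e-2))])
    lower = np.array([u.min() - 200.0, 0.1, 1e-3])
    upper = np.array([u.max() + 200.0, 500.0, 1.0])
    result = least_squares(
        lambda params: _boltzmann(params, u) - p,
        x0=np.clip(p0, lower, upper),
        bounds=(lower, upper),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not result.success:
        err = StageError(f"activation fit did not converge (status {result.status})")
        err.last_iterate = result.x  # type: ignore[attr-defined]
        raise err
    # trust-region steps stall slightly short of an active p_max bound; a
    # fixed-p_max polish recovers full precision there
    if upper[2] - result.x[2] < 1e-3:
        polish = least_squares(
            lambda params: _boltzmann(np.append(params, upper[2]), u) - p,
            x0=result.x[:2],
            method="lm",
            xtol=1e-15,
            ftol=1e-15,
        )
        if polish.success and np.sum(polish.fun**2) <= np.sum(result.fun**2):
            result = polish
            result.x = np.append(polish.x, upper[2])
    v_half, slope, p_max = result.x

    agg: list[tuple[float, float, float]] = []
    for uu in np.unique(u):
        sel = p[u == uu]
        agg.append((float(uu), float(sel.mean()), float(sel.std(ddof=1)) if sel.size > 1 else 0.0))
    return ActivationCurve(
        points=agg,
        v_half=float(v_half),
        slope=float(slope),
        p_max=float(p_max),
        residual_sum=float(np.sum(result.fun**2)),
    )


def analyze_recordings(
    grouped: dict[tuple[str, float], list[Recording]],
    config: ThresholdConfig | None = None,
) -> tuple["pd.DataFrame", dict[str, ActivationCurve]]:
    """Per-recording TC and p_op plus per-class activation curves.

    Returns a tidy DataFrame (recording_id, cell_label, potential_mV, tc_pA,
    p_open, method) and a map label -> fitted ActivationCurve.
    """
    import pandas as pd

    rows = []
    for (label, potential), recs in sorted(grouped.items()):
        for rec in recs:
            try:
                est = threshold_current(rec, config)
                tc, p, method = est.tc, open_probability(rec, est.tc), est.method
            except StateSeparationError:
                p, method = estimate_open_probability(rec, config)
                tc = float("nan")
            rows.append(
                {
                    "recording_id": rec.recording_id,
                    "cell_label": label,
                    "potential_mV": potential,
                    "tc_pA": tc,
                    "p_open": p,
                    "method": method,
                }
            )
    table = pd.DataFrame(rows)
    curves: dict[str, ActivationCurve] = {}
    for label, sub in table.groupby("cell_label"):
        pts = list(zip(sub["potential_mV"], sub["p_open"]))
        try:
            curves[label] = fit_activation_curve(pts)
        except (DegenerateFitError, StageError) as exc:
            log.warning("activation fit skipped for %s: %s", label, exc)
    return table, curves
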
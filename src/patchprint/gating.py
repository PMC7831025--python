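"""Markov gating simulator for single-channel current recordings.

Single-channel patch-clamp traces are modelled as a continuous-time Markov
chain over channel conformations (at minimum one conducting "open" and one
non-conducting "closed" state).  The chain is simulated exactly (Gillespie
event path, exponential dwell times), sampled at the recording rate with a
zero-order hold, and rendered into a current trace:

    I(t) = baseline + [state conducting] * g * (U - E_rev) + noise,

with single-channel conductance ``g`` (default 300 pS, the hallmark of a
BK-type channel), pipette potential ``U`` in mV and Gaussian instrument
noise, optionally low-pass filtered with a causal single-pole filter.

Voltage dependence enters through per-transition rates of the standard
rate-theory (Boltzmann) form

    k(U) = k0 * exp(+-(U - V_half) / (2 * slope)),

so a two-state scheme with opposite-signed slopes has the sigmoidal
stationary open probability  p_op(U) = 1 / (1 + exp(-(U - V_half)/slope)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.signal import lfilter

from .errors import ConfigError, ReducibleGeneratorError, StageError

#: Pipette potentials (mV) used throughout: the six standard command voltages.
STANDARD_POTENTIALS: tuple[float, ...] = (-60.0, -40.0, -20.0, 20.0, 40.0, 60.0)

#: Default sampling rate of the recordings, Hz.
DEFAULT_SAMPLING_RATE = 4000.0

#: Default number of current values per recording.
DEFAULT_N_POINTS = 200_000


@dataclass(frozen=True)
class Transition:
    """One directed transition of a gating scheme.

    The rate at pipette potential ``U`` (mV) is voltage independent when
    ``slope`` is None, otherwise ``base_rate * exp((U - v_half)/(2*slope))``.
    A negative ``slope`` makes the rate decrease with depolarization.
    """

    source: int
    target: int
    base_rate: float  # s^-1
    v_half: float = 0.0  # mV
    slope: float | None = None  # mV

    def rate(self, potential: float) -> float:
        if self.base_rate < 0:
            raise ConfigError(f"negative rate in transition {self}")
        if self.slope is None:
            return self.base_rate
        return self.base_rate * math.exp((potential - self.v_half) / (2.0 * self.slope))


@dataclass(frozen=True)
class GatingScheme:
    """Markov model of channel gating plus the current-rendering parameters."""

    scheme_id: str
    conducting: tuple[bool, ...]  # per-state conducting tag
    transitions: tuple[Transition, ...]
    conductance_pS: float = 300.0
    reversal_mV: float = 0.0
    baseline_pA: float = 0.0
    noise_sd_pA: float = 0.8
    filter_corner_Hz: float | None = None

    def __post_init__(self) -> None:
        if not any(self.conducting) or all(self.conducting):
            raise ConfigError(
                "scheme needs at least one conducting and one nonconducting state"
            )
        if self.conductance_pS <= 0:
            raise ConfigError("conductance must be positive")
        if self.noise_sd_pA < 0:
            raise ConfigError("noise SD must be nonnegative")
        n = self.n_states
        for tr in self.transitions:
            if not (0 <= tr.source < n and 0 <= tr.target < n) or tr.source == tr.target:
                raise ConfigError(f"transition {tr} references invalid states")
            if tr.base_rate < 0:
                raise ConfigError(f"negative base rate in {tr}")

    @property
    def n_states(self) -> int:
        return len(self.conducting)

    def generator(self, potential: float) -> np.ndarray:
        """Voltage-resolved generator matrix Q (s^-1); rows sum to zero."""
        q = np.zeros((self.n_states, self.n_states))
        for tr in self.transitions:
            r = tr.rate(potential)
            if not math.isfinite(r):
                raise StageError(f"non-finite rate for {tr} at {potential} mV")
            q[tr.source, tr.target] += r
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def open_current_pA(self, potential: float) -> float:
        """Open-channel current level: g * (U - E_rev); pS * mV / 1000 = pA."""
        return self.conductance_pS * (potential - self.reversal_mV) / 1000.0


@dataclass(frozen=True)
class ActivationParams:
    """Designed sigmoidal activation curve p_op(U) = p_max * sigmoid((U-V_half)/slope)."""

    v_half: float  # mV
    slope: float  # mV
    p_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max <= 1.0):
            raise ConfigError("p_max must lie in (0, 1]")

    def p_open(self, potential: float) -> float:
        return self.p_max / (1.0 + math.exp(-(potential - self.v_half) / self.slope))


@dataclass(frozen=True)
class CellProfile:
    """A cell type's gating behaviour: one scheme per pipette potential."""

    label: str
    scheme_per_potential: dict[float, GatingScheme]
    activation: ActivationParams | None = None

    def __post_init__(self) -> None:
        missing = [u for u in STANDARD_POTENTIALS if u not in self.scheme_per_potential]
        if missing:
            raise ConfigError(f"profile {self.label!r} lacks potentials {missing}")

    def scheme(self, potential: float) -> GatingScheme:
        try:
            return self.scheme_per_potential[potential]
        except KeyError:
            raise ConfigError(
                f"profile {self.label!r} has no scheme at {potential} mV"
            ) from None


@dataclass(frozen=True)
class Recording:
    """One labelled current trace with sampling metadata."""

    recording_id: str
    cell_label: str
    potential: float  # mV
    trace: np.ndarray  # pA
    sampling_rate: float  # Hz
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        trace = np.asarray(self.trace, dtype=float)
        object.__setattr__(self, "trace", trace)
        if trace.ndim != 1 or trace.size == 0:
            raise ConfigError("trace must be a nonempty 1-D array")
        if not np.all(np.isfinite(trace)):
            raise ConfigError("trace contains non-finite values")
        if not self.sampling_rate > 0:
            raise ConfigError("sampling_rate must be positive")

    @property
    def is_planted_anomaly(self) -> bool:
        return bool(self.provenance.get("is_planted_anomaly", False))


# ---------------------------------------------------------------------------
# Markov-chain machinery
# ---------------------------------------------------------------------------


def stationary_distribution(scheme: GatingScheme, potential: float) -> np.ndarray:
    """Stationary distribution pi solving pi Q = 0, sum(pi) = 1.

    Raises ReducibleGeneratorError when the generator at this potential does
    not admit a unique stationary distribution (rank(Q) < n-1).
    """
    q = scheme.generator(potential)
    n = scheme.n_states
    if np.linalg.matrix_rank(q) != n - 1:
        raise ReducibleGeneratorError(
            f"generator of {scheme.scheme_id!r} at {potential} mV is reducible/degenerate"
        )
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.any(pi < -1e-9):
        raise ReducibleGeneratorError(
            f"stationary solve produced negative probabilities for {scheme.scheme_id!r}"
        )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def conducting_probability(scheme: GatingScheme, potential: float) -> float:
    """Stationary probability mass on conducting states (the designed p_op)."""
    pi = stationary_distribution(scheme, potential)
    return float(pi[np.asarray(scheme.conducting)].sum())


def simulate_events(
    scheme: GatingScheme,
    potential: float,
    duration_s: float,
    rng: np.random.Generator,
    initial_state: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gillespie event path covering at least ``duration_s`` seconds.

    Returns (states, dwell_s). A state with zero exit rate holds for the
    remaining duration (absorbing). When ``initial_state`` is None it is
    drawn from the stationary distribution, so the sampled path is
    stationary from t = 0.
    """
    q = scheme.generator(potential)
    if not np.all(np.isfinite(q)):
        raise StageError("non-finite rates in generator")
    if initial_state is None:
        pi = stationary_distribution(scheme, potential)
        state = int(rng.choice(scheme.n_states, p=pi))
    else:
        state = int(initial_state)

    exit_rates = -np.diag(q)
    # Per-state cumulative jump probabilities for inverse-CDF sampling.
    jump_cum = []
    for s in range(scheme.n_states):
        if exit_rates[s] > 0:
            probs = q[s].copy()
            probs[s] = 0.0
            probs = probs / exit_rates[s]
            jump_cum.append(np.cumsum(probs))
        else:
            jump_cum.append(None)

    states: list[int] = []
    dwells: list[float] = []
    t = 0.0
    while t < duration_s:
        lam = exit_rates[state]
        if lam <= 0.0:
            states.append(state)
            dwells.append(duration_s - t)
            break
        dwell = rng.exponential(1.0 / lam)
        states.append(state)
        dwells.append(dwell)
        t += dwell
        state = int(np.searchsorted(jump_cum[state], rng.random(), side="right"))
    return np.asarray(states, dtype=np.int64), np.asarray(dwells, dtype=float)


def sample_path(
    states: np.ndarray, dwells: np.ndarray, n_points: int, sampling_rate: float
) -> np.ndarray:
    """Zero-order-hold sampling of an event path at times k / sampling_rate."""
    t = np.arange(n_points) / sampling_rate
    cum = np.cumsum(dwells)
    idx = np.searchsorted(cum, t, side="right")
    idx = np.minimum(idx, len(states) - 1)
    return states[idx]


def simulate_state_path(
    scheme: GatingScheme,
    potential: float,
    n_points: int,
    sampling_rate: float,
    seed: int | np.random.Generator,
    initial_state: int | None = None,
) -> np.ndarray:
    """Per-sample state sequence of length ``n_points``; identical seed,
    identical path."""
    if n_points < 1:
        raise ConfigError("n_points must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else default_rng(seed)
    duration = n_points / sampling_rate
    states, dwells = simulate_events(scheme, potential, duration, rng, initial_state)
    return sample_path(states, dwells, n_points, sampling_rate)


def render_recording(
    path: np.ndarray,
    scheme: GatingScheme,
    potential: float,
    seed: int | np.random.Generator,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    recording_id: str = "synthetic",
    cell_label: str = "unknown",
    provenance: dict | None = None,
) -> Recording:
    """Render a state path into a current trace (pA).

    trace = baseline + conducting level + N(0, noise_sd), then an optional
    causal single-pole low-pass at ``scheme.filter_corner_Hz``.
    """
    path = np.asarray(path)
    if path.size == 0:
        raise ConfigError("state path is empty")
    rng = seed if isinstance(seed, np.random.Generator) else default_rng(seed)
    level = scheme.open_current_pA(potential)
    conducting = np.asarray(scheme.conducting)[path]
    trace = scheme.baseline_pA + np.where(conducting, level, 0.0)
    if scheme.noise_sd_pA > 0:
        trace = trace + rng.normal(0.0, scheme.noise_sd_pA, size=path.size)
    if scheme.filter_corner_Hz is not None:
        alpha = 1.0 - math.exp(-2.0 * math.pi * scheme.filter_corner_Hz / sampling_rate)
        trace = lfilter([alpha], [1.0, alpha - 1.0], trace)
    prov = dict(provenance or {})
    prov.setdefault("scheme_id", scheme.scheme_id)
    return Recording(
        recording_id=recording_id,
        cell_label=cell_label,
        potential=potential,
        trace=np.asarray(trace, dtype=float),
        sampling_rate=sampling_rate,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Profile factories
# ---------------------------------------------------------------------------


def boltzmann_two_state_scheme(
    scheme_id: str,
    v_half: float,
    slope: float,
    tau_open_ms: float,
    **scheme_kwargs,
) -> GatingScheme:
    """Two-state (closed=0, open=1) scheme with Boltzmann voltage dependence.

    Opening rate rises and closing rate falls e-fold per 2*slope mV, giving
    p_op(U) = sigmoid((U - v_half)/slope) and mean open dwell tau_open at
    U = v_half.
    """
    k0 = 1000.0 / tau_open_ms  # s^-1 at U = v_half
    transitions = (
        Transition(0, 1, k0, v_half=v_half, slope=slope),
        Transition(1, 0, k0, v_half=v_half, slope=-slope),
    )
    return GatingScheme(
        scheme_id=scheme_id,
        conducting=(False, True),
        transitions=transitions,
        **scheme_kwargs,
    )


def constant_two_state_scheme(
    scheme_id: str, p_open: float, tau_open_ms: float, **scheme_kwargs
) -> GatingScheme:
    """Two-state scheme with voltage-independent rates and stationary
    open probability ``p_open``."""
    if not (0.0 < p_open < 1.0):
        raise ConfigError("p_open must lie strictly in (0, 1)")
    k_close = 1000.0 / tau_open_ms
    k_open = k_close * p_open / (1.0 - p_open)
    transitions = (Transition(0, 1, k_open), Transition(1, 0, k_close))
    return GatingScheme(
        scheme_id=scheme_id,
        conducting=(False, True),
        transitions=transitions,
        **scheme_kwargs,
    )


def _profile_from_scheme(label, scheme, activation=None) -> CellProfile:
    return CellProfile(
        label=label,
        scheme_per_potential={u: scheme for u in STANDARD_POTENTIALS},
        activation=activation,
    )


def default_profiles(
    noise_sd_pA: float = 0.8, filter_corner_Hz: float | None = None
) -> list[CellProfile]:
    """The three default cell-type profiles.

    All share the 300 pS conductance; they differ in activation midpoint,
    slope and dwell-time scale.  Fibroblast and hippocampus are designed
    kinetically similar (close V_half and dwell times) while endothelium is
    right-shifted and faster — so open probabilities converge at extreme
    potentials yet the dwell-time texture of the traces still differs.
    """
    params = [
        ("endothelium", 5.0, 12.0, 2.0),
        ("fibroblast", -20.0, 14.0, 6.0),
        ("hippocampus", -30.0, 10.0, 4.0),
    ]
    profiles = []
    for label, v_half, slope, tau in params:
        scheme = boltzmann_two_state_scheme(
            f"{label}-2state",
            v_half,
            slope,
            tau,
            noise_sd_pA=noise_sd_pA,
            filter_corner_Hz=filter_corner_Hz,
        )
        profiles.append(
            _profile_from_scheme(label, scheme, ActivationParams(v_half, slope, 1.0))
        )
    return profiles


def well_separated_profiles(
    noise_sd_pA: float = 0.8, filter_corner_Hz: float | None = None
) -> list[CellProfile]:
    """Three classes with widely separated kinetics (p_op 0.1 / 0.5 / 0.9 and
    distinct dwell times at every potential); voltage sets only the current
    amplitude.  Used as the clearly-classifiable benchmark fixture."""
    params = [
        ("endothelium", 0.1, 1.5),
        ("fibroblast", 0.5, 4.0),
        ("hippocampus", 0.9, 10.0),
    ]
    profiles = []
    for label, p, tau in params:
        scheme = constant_two_state_scheme(
            f"{label}-const",
            p,
            tau,
            noise_sd_pA=noise_sd_pA,
            filter_corner_Hz=filter_corner_Hz,
        )
        profiles.append(_profile_from_scheme(label, scheme))
    return profiles


def anomalous_scheme(
    scheme: GatingScheme,
    potential: float,
    p_shift: float = 0.3,
    dwell_factor: float = 5.0,
) -> GatingScheme:
    """A perturbed scheme emulating an aberrant patch.

    The stationary open probability at ``potential`` is shifted by
    ``p_shift`` towards the balanced (maximally fluctuating) regime and the
    dwell-time scale is slowed by ``dwell_factor`` — the signature of a
    channel switching into an unexpected long-lived kinetic mode.
    """
    p = conducting_probability(scheme, potential)
    p_new = p + p_shift if p < 0.5 else p - p_shift
    p_new = float(np.clip(p_new, 0.02, 0.98))
    open_states = [i for i, c in enumerate(scheme.conducting) if c]
    exit_rate = -scheme.generator(potential)[open_states[0], open_states[0]]
    tau_open_ms = 1000.0 / exit_rate if exit_rate > 0 else 5.0
    return constant_two_state_scheme(
        f"{scheme.scheme_id}-anomalous",
        p_new,
        tau_open_ms * dwell_factor,
        conductance_pS=scheme.conductance_pS,
        reversal_mV=scheme.reversal_mV,
        baseline_pA=scheme.baseline_pA,
        noise_sd_pA=scheme.noise_sd_pA,
        filter_corner_Hz=scheme.filter_corner_Hz,
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnomalySpec:
    """Plant ``count`` extra anomalous recordings in one (class, potential)
    category.  ``scheme`` overrides the default perturbation built by
    :func:`anomalous_scheme` with shift ``p_shift``."""

    cell_label: str
    potential: float
    scheme: GatingScheme | None = None
    count: int = 1
    p_shift: float = 0.3
    dwell_factor: float = 5.0


def generate_dataset(
    profiles: list[CellProfile],
    n_recordings_per_class: int = 3,
    n_points: int = DEFAULT_N_POINTS,
    potentials: tuple[float, ...] = STANDARD_POTENTIALS,
    anomaly_spec: AnomalySpec | None = None,
    seed: int = 0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> list[Recording]:
    """Generate one recording per (class, potential, replicate), plus any
    planted anomalies.  Deterministic per seed; anomalies are flagged only in
    ``provenance`` (invisible to the downstream pipeline)."""
    if n_recordings_per_class < 3:
        raise ConfigError("need >= 3 recordings per class for cross-validation")
    jobs = []  # (profile, potential, replicate, scheme, is_anomaly)
    for profile in sorted(profiles, key=lambda p: p.label):
        for potential in potentials:
            scheme = profile.scheme(potential)
            for rep in range(n_recordings_per_class):
                jobs.append((profile.label, potential, rep, scheme, False))
            if (
                anomaly_spec is not None
                and anomaly_spec.cell_label == profile.label
                and anomaly_spec.potential == potential
            ):
                a_scheme = anomaly_spec.scheme or anomalous_scheme(
                    scheme, potential, anomaly_spec.p_shift, anomaly_spec.dwell_factor
                )
                for j in range(anomaly_spec.count):
                    jobs.append(
                        (profile.label, potential, n_recordings_per_class + j, a_scheme, True)
                    )

    recordings: list[Recording] = []
    seen_ids: set[str] = set()
    child_seeds = SeedSequence(seed).spawn(len(jobs))
    for (label, potential, rep, scheme, is_anomaly), ss in zip(jobs, child_seeds):
        rng = default_rng(ss)
        rec_id = f"{label}_{int(potential):+03d}mV_r{rep:02d}"
        if rec_id in seen_ids:
            raise ConfigError(f"duplicate recording_id {rec_id!r}")
        seen_ids.add(rec_id)
        path = simulate_state_path(scheme, potential, n_points, sampling_rate, rng)
        rec = render_recording(
            path,
            scheme,
            potential,
            rng,
            sampling_rate=sampling_rate,
            recording_id=rec_id,
            cell_label=label,
            provenance={
                "seed": int(seed),
                "scheme_id": scheme.scheme_id,
                "is_planted_anomaly": is_anomaly,
            },
        )
        recordings.append(rec)
    return recordings
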
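"""Gating simulator: stationary law, dwell statistics, rendering, datasets."""

import numpy as np
import pytest

from patchprint.errors import ConfigError, ReducibleGeneratorError
from patchprint.gating import (
    STANDARD_POTENTIALS,
    AnomalySpec,
    GatingScheme,
    Transition,
    anomalous_scheme,
    boltzmann_two_state_scheme,
    conducting_probability,
    constant_two_state_scheme,
    default_profiles,
    generate_dataset,
    render_recording,
    sample_path,
    simulate_events,
    simulate_state_path,
    stationary_distribution,
    well_separated_profiles,
)


class TestStationaryDistribution:
    def test_symmetric_two_state_is_half(self):
        scheme = constant_two_state_scheme("sym", 0.5, 5.0)
        pi = stationary_distribution(scheme, 0.0)
        assert pi == pytest.approx([0.5, 0.5])

    def test_two_state_matches_rate_ratio(self):
        # k_open = 300/s, k_close = 100/s -> p_open = 300/400 = 0.75
        scheme = GatingScheme(
            "r", (False, True), (Transition(0, 1, 300.0), Transition(1, 0, 100.0))
        )
        assert conducting_probability(scheme, 0.0) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_three_state_matches_left_eigenvector_oracle(self, seed):
        rng = np.random.default_rng(seed)
        transitions = tuple(
            Transition(i, j, float(rng.uniform(10, 500)))
            for i in range(3)
            for j in range(3)
            if i != j
        )
        scheme = GatingScheme("t3", (False, True, True), transitions)
        q = scheme.generator(0.0)
        # independent oracle: left eigenvector of eigenvalue 0
        w, vl = np.linalg.eig(q.T)
        vec = np.real(vl[:, np.argmin(np.abs(w))])
        vec = np.abs(vec) / np.abs(vec).sum()
        assert stationary_distribution(scheme, 0.0) == pytest.approx(vec, abs=1e-10)

    def test_reducible_generator_rejected(self):
        # two disconnected 2-state blocks: no unique stationary law
        transitions = (Transition(0, 1, 10.0), Transition(1, 0, 10.0),
                       Transition(2, 3, 10.0), Transition(3, 2, 10.0))
        scheme = GatingScheme("red", (False, True, False, True), transitions)
        with pytest.raises(ReducibleGeneratorError):
            stationary_distribution(scheme, 0.0)


class TestSimulation:
    def test_absorbing_state_gives_constant_path(self):
        scheme = GatingScheme("abs", (False, True), (Transition(0, 1, 0.0),))
        path = simulate_state_path(scheme, 0.0, 500, 4000.0, seed=0, initial_state=1)
        assert np.all(path == 1)

    def test_mean_open_dwell_matches_exponential_oracle(self):
        # mean open dwell 5 ms; empirical mean over >= 1e5 points within 5%
        scheme = constant_two_state_scheme("d", 0.5, 5.0)
        rng = np.random.default_rng(42)
        states, dwells = simulate_events(scheme, 0.0, 60.0, rng, initial_state=0)
        open_dwells = dwells[:-1][states[:-1] == 1]  # drop truncated last dwell
        assert open_dwells.size > 2000
        assert np.mean(open_dwells) == pytest.approx(5e-3, rel=0.05)

    def test_conducting_fraction_near_stationary(self):
        scheme = constant_two_state_scheme("f", 0.3, 4.0)
        path = simulate_state_path(scheme, 0.0, 200_000, 4000.0, seed=5)
        frac = np.mean(path == 1)
        # autocorrelation-adjusted binomial SE
        x = (path == 1).astype(float)
        rho = np.corrcoef(x[:-1], x[1:])[0, 1]
        se = np.sqrt(0.3 * 0.7 / (x.size * (1 - rho) / (1 + rho)))
        assert abs(frac - 0.3) < 3 * se

    def test_same_seed_same_path(self):
        scheme = constant_two_state_scheme("s", 0.5, 2.0)
        a = simulate_state_path(scheme, 0.0, 5000, 4000.0, seed=3)
        b = simulate_state_path(scheme, 0.0, 5000, 4000.0, seed=3)
        assert np.array_equal(a, b)

    def test_sample_path_zero_order_hold(self):
        states = np.array([0, 1, 0])
        dwells = np.array([0.5, 0.25, 1.0])
        out = sample_path(states, dwells, 8, 8.0)  # samples at 0, .125, ..., .875
        assert out.tolist() == [0, 0, 0, 0, 1, 1, 0, 0]


class TestRendering:
    def test_open_level_300ps_at_60mV_is_18pA(self):
        scheme = constant_two_state_scheme("a", 0.5, 5.0, noise_sd_pA=0.0)
        path = np.array([0, 1, 0, 1])
        rec = render_recording(path, scheme, 60.0, seed=0)
        assert rec.trace.tolist() == [0.0, 18.0, 0.0, 18.0]

    def test_negative_potential_gives_negative_current(self):
        scheme = constant_two_state_scheme("a", 0.5, 5.0, noise_sd_pA=0.0)
        rec = render_recording(np.array([1, 1]), scheme, -60.0, seed=0)
        assert rec.trace == pytest.approx([-18.0, -18.0])

    def test_noise_sd_recovered_within_dwell(self):
        scheme = constant_two_state_scheme("n", 0.5, 5.0, noise_sd_pA=1.0)
        path = np.ones(20_000, dtype=int)  # one long open dwell
        rec = render_recording(path, scheme, 40.0, seed=1)
        assert np.std(rec.trace) == pytest.approx(1.0, rel=0.1)

    def test_low_pass_filter_reduces_noise_variance(self):
        kw = dict(p_open=0.5, tau_open_ms=5.0, noise_sd_pA=1.0)
        raw = constant_two_state_scheme("r", **kw)
        filt = constant_two_state_scheme("f", **kw, filter_corner_Hz=1000.0)
        path = np.ones(20_000, dtype=int)
        v_raw = np.var(render_recording(path, raw, 40.0, seed=2).trace)
        v_filt = np.var(render_recording(path, filt, 40.0, seed=2).trace)
        assert v_filt < v_raw


class TestDatasets:
    def test_product_count_3x3x6(self, separated_profiles):
        recs = generate_dataset(separated_profiles, 3, 1200, seed=0)
        assert len(recs) == 54

    def test_anomaly_adds_exactly_one_flagged(self, separated_profiles):
        recs = generate_dataset(
            separated_profiles, 3, 1200,
            anomaly_spec=AnomalySpec("fibroblast", 20.0), seed=0,
        )
        assert len(recs) == 55
        assert sum(r.is_planted_anomaly for r in recs) == 1

    def test_same_seed_identical_traces(self, separated_profiles):
        a = generate_dataset(separated_profiles, 3, 1500, potentials=(40.0,), seed=9)
        b = generate_dataset(separated_profiles, 3, 1500, potentials=(40.0,), seed=9)
        for ra, rb in zip(a, b):
            assert ra.recording_id == rb.recording_id
            assert np.array_equal(ra.trace, rb.trace)

    def test_fewer_than_three_replicates_rejected(self, separated_profiles):
        with pytest.raises(ConfigError):
            generate_dataset(separated_profiles, 2, 1000, seed=0)

    def test_designed_activation_monotone(self, boltzmann_profiles):
        for profile in boltzmann_profiles:
            p = [
                conducting_probability(profile.scheme(u), u)
                for u in STANDARD_POTENTIALS
            ]
            assert all(a <= b for a, b in zip(p, p[1:]))

    def test_anomalous_scheme_shifts_p_open(self):
        scheme = constant_two_state_scheme("h", 0.9, 10.0)
        pert = anomalous_scheme(scheme, 40.0, p_shift=0.3)
        assert conducting_probability(pert, 40.0) == pytest.approx(0.6)
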
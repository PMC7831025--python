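"""Windowing, PAA, scaling and cross-validation fold construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchprint.errors import ConfigError, StageError
from patchprint.gating import Recording
from patchprint.preprocess import (
    PreprocessConfig,
    make_cv_folds,
    minmax_scale,
    paa,
    preprocess_fold,
    split_windows,
    truncate_to_shortest,
)


def rec_of(trace, rid, label="fibroblast", u=40.0):
    return Recording(rid, label, u, np.asarray(trace, dtype=float), 4000.0)


class TestTruncate:
    def test_cut_to_shortest(self):
        recs = [rec_of(np.arange(n), f"r{n}") for n in (5, 3, 4)]
        out = truncate_to_shortest(recs)
        assert [r.trace.size for r in out] == [3, 3, 3]

    def test_equal_lengths_unchanged(self):
        recs = [rec_of(np.arange(4), f"r{i}") for i in range(3)]
        out = truncate_to_shortest(recs)
        assert all(o is r for o, r in zip(out, recs))

    def test_prefix_kept(self):
        recs = [rec_of([1.0, 2, 3, 4, 5], "a"), rec_of([9.0, 8, 7], "b")]
        out = truncate_to_shortest(recs)
        assert out[0].trace.tolist() == [1.0, 2.0, 3.0]


class TestSplitWindows:
    def test_count_formula_examples(self):
        assert split_windows(np.arange(2000), 1000, 200).shape == (5, 1000)
        assert split_windows(np.arange(1400), 1000, 200).shape == (2, 1000)

    def test_length_equal_to_window_yields_zero(self):
        assert split_windows(np.arange(1000), 1000, 200).shape[0] == 0

    def test_short_trace_warns_empty(self):
        with pytest.warns(UserWarning):
            out = split_windows(np.arange(10), 1000, 200)
        assert out.shape == (0, 1000)

    @given(
        st.integers(min_value=1, max_value=40).flatmap(
            lambda l: st.tuples(
                st.integers(min_value=l, max_value=300),
                st.just(l),
                st.integers(min_value=1, max_value=l),
            )
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_enumeration_oracle(self, llr):
        L, l, r = llr
        trace = np.arange(L, dtype=float)
        got = split_windows(trace, l, r)
        expected = [trace[o : o + l] for o in range(0, L - l + 1, r)][: (L - l) // r]
        assert got.shape[0] == (L - l) // r
        for w, e in zip(got, expected):
            assert np.array_equal(w, e)


class TestPAA:
    def test_frame_means(self):
        assert paa(np.array([1.0, 2, 3, 4, 5, 6]), 3).tolist() == [1.5, 3.5, 5.5]

    def test_constant_window_unchanged(self):
        assert np.all(paa(np.full(100, 2.5), 10) == 2.5)

    def test_mean_preserved_1000_to_200(self, rng):
        window = rng.normal(size=1000)
        reduced = paa(window, 200)
        assert reduced.shape == (200,)
        assert reduced.mean() == pytest.approx(window.mean())

    def test_identity_when_w_equals_l(self, rng):
        w = rng.normal(size=50)
        assert np.array_equal(paa(w, 50), w)

    def test_non_divisible_rejected(self):
        with pytest.raises(ConfigError):
            paa(np.arange(10, dtype=float), 3)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = int(rng.integers(1, 12))
        frames = int(rng.integers(1, 8))
        window = rng.normal(size=w * frames)
        expected = [window[i * frames : (i + 1) * frames].mean() for i in range(w)]
        assert paa(window, w) == pytest.approx(expected)


class TestMinMaxScale:
    def test_midpoint_maps_to_half(self):
        train = np.array([2.0, 6.0, 4.0])
        scaled, _, _ = minmax_scale(train)
        assert scaled.tolist() == [0.0, 1.0, 0.5]

    def test_test_values_clipped_and_counted(self):
        train = np.array([0.0, 1.0])
        _, test_scaled, params = minmax_scale(train, np.array([-0.5, 0.5, 2.0]))
        assert test_scaled.tolist() == [0.0, 0.5, 1.0]
        assert params.n_clipped_low == 1 and params.n_clipped_high == 1

    def test_constant_training_rejected(self):
        with pytest.raises(StageError):
            minmax_scale(np.full(5, 3.0))


class TestFolds:
    def test_three_cubed_folds(self):
        groups = {c: [f"{c}{i}" for i in range(3)] for c in "ABC"}
        folds = make_cv_folds(groups)
        assert len(folds) == 27

    def test_product_of_unequal_group_sizes(self):
        groups = {"A": ["a0", "a1"], "B": ["b0", "b1", "b2"], "C": list("wxyz")}
        assert len(make_cv_folds(groups)) == 24

    def test_every_fold_partitions_recordings(self):
        groups = {c: [f"{c}{i}" for i in range(3)] for c in "ABC"}
        all_ids = {rid for ids in groups.values() for rid in ids}
        for fold in make_cv_folds(groups):
            assert set(fold.test_recordings) | set(fold.train_recordings) == all_ids
            assert len(fold.test_recordings) == 3

    def test_small_class_named_in_error(self):
        with pytest.raises(ConfigError, match="B"):
            make_cv_folds({"A": ["a0", "a1"], "B": ["b0"]})


class TestPreprocessFold:
    @pytest.fixture()
    def fold_and_recs(self, small_grouped):
        recs = {
            r.recording_id: r
            for (label, u), rs in small_grouped.items()
            if u == 40.0
            for r in rs
        }
        groups = {}
        for r in recs.values():
            groups.setdefault(r.cell_label, []).append(r.recording_id)
        return make_cv_folds(groups)[0], recs

    def test_window_counts_and_range(self, fold_and_recs):
        fold, recs = fold_and_recs
        data = preprocess_fold(fold, recs)
        per_rec = (6000 - 1000) // 200  # 25 windows each
        assert data.X_train.shape == (6 * per_rec, 200)
        assert data.X_test.shape == (3 * per_rec, 200)
        assert data.X_train.min() >= 0.0 and data.X_train.max() <= 1.0
        assert data.X_test.min() >= 0.0 and data.X_test.max() <= 1.0

    def test_balanced_test_classes(self, fold_and_recs):
        fold, recs = fold_and_recs
        data = preprocess_fold(fold, recs)
        _, counts = np.unique(data.y_test, return_counts=True)
        assert len(set(counts)) == 1

    def test_deterministic(self, fold_and_recs):
        fold, recs = fold_and_recs
        a = preprocess_fold(fold, recs)
        b = preprocess_fold(fold, recs)
        assert np.array_equal(a.X_train, b.X_train)
        assert np.array_equal(a.X_test, b.X_test)

    def test_joint_scope_uses_pooled_range(self, fold_and_recs):
        fold, recs = fold_and_recs
        joint = preprocess_fold(
            fold, recs, PreprocessConfig(normalization_scope="joint")
        )
        pooled = np.vstack([joint.X_train, joint.X_test])
        assert pooled.min() == 0.0 and pooled.max() == 1.0
        assert joint.scale.n_clipped_low == joint.scale.n_clipped_high == 0
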
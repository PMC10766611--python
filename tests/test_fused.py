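"""Fusion, the FSLD metric, the learned distance model, and KNN voting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycocast import (
    DistanceModel,
    Standardizer,
    fsld_elementwise,
    fsld_transform,
    fuse,
    knn_predict,
    train_distance_model,
)
from glycocast.fused import FUSED_DIM


class TestFuse:
    def test_full_fusion_is_8209(self):
        out = fuse(np.zeros(4096), np.zeros(4096), np.zeros(17))
        assert out.shape == (FUSED_DIM,) == (8209,)
        assert np.all(out == 0)

    def test_ordering_contract(self):
        H = np.arange(4096, dtype=float)
        out = fuse(np.zeros(4096), H, np.zeros(17))
        assert out[4096] == H[0]
        assert out[-17] == 0.0

    @pytest.mark.parametrize(
        "b, h, d, expected",
        [(True, False, False, 4096), (True, False, True, 4113),
         (True, True, False, 8192), (False, False, True, 17)],
    )
    def test_channel_subsets(self, b, h, d, expected):
        out = fuse(
            np.ones(4096) if b else None,
            np.ones(4096) if h else None,
            np.ones(17) if d else None,
        )
        assert out.shape == (expected,)

    def test_length_mismatch_names_channel(self):
        with pytest.raises(ValueError, match="histogram"):
            fuse(np.zeros(4096), np.zeros(100), np.zeros(17))
        with pytest.raises(ValueError, match="DSP"):
            fuse(None, None, np.zeros(5))

    def test_standardizer_applied_to_dsp_only(self):
        std = Standardizer(np.full(17, 10.0), np.full(17, 2.0))
        out = fuse(None, None, np.full(17, 14.0), std)
        np.testing.assert_allclose(out, 2.0)


class TestFsld:
    def test_identical_inputs_zero(self):
        assert fsld_elementwise(3.3, 3.3, 0.0) == 0.0

    def test_worked_example(self):
        assert fsld_elementwise(2.0, 1.0, 0.5) == pytest.approx(0.5)

    def test_below_threshold_floored(self):
        assert fsld_elementwise(1.0, 1.3, 0.5) == 0.0

    def test_zero_max_degenerate(self):
        assert fsld_elementwise(0.0, 0.0, 0.0) == 0.0

    @settings(derandomize=True, max_examples=300)
    @given(
        st.floats(min_value=0.0, max_value=100.0),
        st.floats(min_value=0.0, max_value=100.0),
        st.floats(min_value=0.0, max_value=5.0),
    )
    def test_nonnegative_inputs_land_in_unit_interval(self, i1, i2, a):
        v = fsld_elementwise(i1, i2, a)
        assert 0.0 <= v <= 1.0
        assert v == fsld_elementwise(i2, i1, a)  # symmetry

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        I1 = rng.normal(size=500)
        I2 = rng.normal(size=500)
        J = fsld_transform(I1, I2, a=0.1)
        expect = [fsld_elementwise(x, y, 0.1) for x, y in zip(I1, I2)]
        np.testing.assert_allclose(J, expect, rtol=1e-12)

    def test_single_discrepant_element(self):
        I1 = np.zeros(10)
        I2 = np.zeros(10)
        I2[4] = 1.0
        J = fsld_transform(I1, I2, a=0.01)
        assert np.count_nonzero(J) == 1 and J[4] == 1.0

    def test_symmetric_transform(self):
        rng = np.random.default_rng(1)
        I1, I2 = rng.normal(size=50), rng.normal(size=50)
        np.testing.assert_array_equal(
            fsld_transform(I1, I2, 0.05), fsld_transform(I2, I1, 0.05)
        )


def _separable_vectors(n_per_class=12, dim=60, seed=0):
    """Two classes with different active blocks, mimicking fused features."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in (0, 1):
        proto = np.zeros(dim)
        proto[c * dim // 2 : (c + 1) * dim // 2] = 2.0
        for _ in range(n_per_class):
            X.append(np.abs(proto + rng.normal(0, 0.2, dim)))
            y.append(c)
    return np.array(X), np.array(y)


class TestDistanceModel:
    def test_separates_held_out_pairs(self):
        X, y = _separable_vectors(seed=0)
        model = train_distance_model(X, y, a=0.01, epochs=80, seed=0)
        Xh, yh = _separable_vectors(seed=99)
        same, diff = [], []
        for i in range(len(Xh)):
            for j in range(i + 1, len(Xh)):
                d = model.distance(Xh[i], Xh[j])
                (same if yh[i] == yh[j] else diff).append(d)
        assert np.mean(same) < np.mean(diff)

    def test_zero_vector_scores_below_half_after_training(self):
        X, y = _separable_vectors(seed=2)
        model = train_distance_model(X, y, a=0.01, epochs=80, seed=0)
        assert model.predict(np.zeros(X.shape[1]))[0] < 0.5

    def test_deterministic(self):
        X, y = _separable_vectors(seed=3)
        a = train_distance_model(X, y, seed=5)
        b = train_distance_model(X, y, seed=5)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_pair_budget_subsampling(self):
        X, y = _separable_vectors(n_per_class=10, seed=4)
        model = train_distance_model(X, y, pair_budget=50, seed=0)
        assert np.all(np.isfinite(model.weights))

    def test_single_class_rejected(self):
        X, _ = _separable_vectors(seed=5)
        with pytest.raises(ValueError, match="2 classes"):
            train_distance_model(X, np.zeros(len(X)), seed=0)

    def test_distance_symmetric(self):
        X, y = _separable_vectors(seed=6)
        model = train_distance_model(X, y, seed=0)
        assert model.distance(X[0], X[15]) == pytest.approx(
            model.distance(X[15], X[0])
        )


def _monotone_gallery(values, classes):
    """1-element feature + padding; distance increases with |query - value|."""
    G = np.zeros((len(values), 3))
    G[:, 0] = values
    model = DistanceModel(np.array([10.0, 0.0, 0.0]), -2.0, threshold_a=0.0)
    return G, np.asarray(classes), model


class TestKnn:
    def test_exact_match_wins_at_k1(self):
        G, y, model = _monotone_gallery([1.0, 2.0, 3.0], [0, 1, 2])
        q = np.array([2.0, 0.0, 0.0])
        assert knn_predict(q, G, y, model, k=1, seed=0) == 1

    def test_majority_vote_six_versus_four(self):
        vals = [1.01, 1.02, 1.03, 1.04, 1.05, 1.06] + [1.2, 1.25, 1.3, 1.35] + [9.0, 9.5]
        cls = [0] * 6 + [1] * 4 + [1] * 2
        G, y, model = _monotone_gallery(vals, cls)
        q = np.array([1.0, 0.0, 0.0])
        assert knn_predict(q, G, y, model, k=10, seed=0) == 0

    def test_five_five_tie_broken_randomly_but_reproducibly(self):
        vals = [1.01, 1.02, 1.03, 1.04, 1.05, 1.2, 1.25, 1.3, 1.35, 1.4, 9.0]
        cls = [0] * 5 + [1] * 5 + [2]
        G, y, model = _monotone_gallery(vals, cls)
        q = np.array([1.0, 0.0, 0.0])
        outcomes = {knn_predict(q, G, y, model, k=10, seed=s) for s in range(30)}
        assert outcomes == {0, 1}
        assert knn_predict(q, G, y, model, k=10, seed=3) == knn_predict(
            q, G, y, model, k=10, seed=3
        )

    def test_small_gallery_rejected(self):
        G, y, model = _monotone_gallery([1.0, 2.0], [0, 1])
        with pytest.raises(ValueError, match="smaller K"):
            knn_predict(np.zeros(3), G, y, model, k=10, seed=0)
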
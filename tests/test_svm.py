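import numpy as np
import pytest

import petstratify as ps
from petstratify.reference import qp_reference_scores
from petstratify.svm import _train_weights


def _separable_instance(rng, n, p, gap=2.0):
    X = rng.standard_normal((n, p))
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    rng.shuffle(y)
    X[y == 1] += gap
    return X, y


class TestTrainSvm:
    def test_symmetric_pair_boundary_at_zero(self):
        # duplicated symmetric 1-D points (minimum trainable size is 4)
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        params = ps.SvmParams(outlier_fraction=0.0, kernel_offset=0.0)
        w, b = _train_weights(X, y, params)
        assert b == pytest.approx(0.0, abs=1e-8)
        scores = X @ w + b
        assert np.all((scores > 0).astype(int) == y)

    def test_agrees_with_qp_oracle(self, rng):
        params = ps.SvmParams(outlier_fraction=0.0)
        for _ in range(10):
            X, y = _separable_instance(rng, int(rng.integers(8, 21)),
                                       int(rng.integers(2, 11)),
                                       gap=float(rng.uniform(0.5, 3.0)))
            w, b = _train_weights(X, y, params)
            s_impl = X @ w + b
            s_ref = qp_reference_scores(X, y, X, params)
            scale = max(1.0e-12, np.max(np.abs(s_ref)))
            assert np.max(np.abs(s_impl - s_ref)) / scale < 1e-4

    def test_label_swap_negates_model(self, rng):
        X, y = _separable_instance(rng, 12, 5)
        params = ps.SvmParams(outlier_fraction=0.0)
        w1, b1 = _train_weights(X, y, params)
        w2, b2 = _train_weights(X, 1 - y, params)
        np.testing.assert_allclose(w2, -w1, atol=1e-7 * np.abs(w1).max())
        assert b2 == pytest.approx(-b1, abs=1e-7 * max(1.0, abs(b1)))

    def test_deterministic(self, tiny_features):
        m1 = ps.train_svm(tiny_features)
        m2 = ps.train_svm(tiny_features)
        assert np.array_equal(m1.weights, m2.weights)
        assert m1.bias == m2.bias

    def test_feature_and_box_rescaling_identity(self, rng):
        """Multiplying features by c and the box constraint by 1/c^2 leaves
        decision labels unchanged (offset 0, standard SVM scaling identity)."""
        X, y = _separable_instance(rng, 16, 6, gap=0.8)
        c = 3.0
        p1 = ps.SvmParams(outlier_fraction=0.0, kernel_offset=0.0, box_constraint=1.0)
        p2 = ps.SvmParams(outlier_fraction=0.0, kernel_offset=0.0,
                          box_constraint=1.0 / c**2)
        w1, b1 = _train_weights(X, y, p1)
        w2, b2 = _train_weights(X * c, y, p2)
        labels1 = (X @ w1 + b1) > 0
        labels2 = ((X * c) @ w2 + b2) > 0
        assert np.array_equal(labels1, labels2)

    def test_kernel_offset_absorbed_into_bias(self, rng):
        """With the dual equality constraint the offset cannot move the
        decision function: scores match the offset-free model."""
        X, y = _separable_instance(rng, 14, 4)
        w0, b0 = _train_weights(X, y, ps.SvmParams(outlier_fraction=0.0, kernel_offset=0.0))
        w1, b1 = _train_weights(X, y, ps.SvmParams(outlier_fraction=0.0, kernel_offset=0.1))
        s0, s1 = X @ w0 + b0, X @ w1 + b1
        np.testing.assert_allclose(s1, s0, atol=1e-6 * np.max(np.abs(s0)))

    def test_outlier_trimming_ignores_flipped_point(self, rng):
        """One mislabeled point inside the opposite class is dropped by the
        5% trimming pass; the refit recovers the clean separator."""
        X, y = _separable_instance(rng, 20, 3, gap=4.0)
        X[0] = X[y == (1 - y[0])][1] + 0.01  # plant an outlier deep in the other class
        w_plain, b_plain = _train_weights(X, y, ps.SvmParams(outlier_fraction=0.0))
        w_trim, b_trim = _train_weights(X, y, ps.SvmParams(outlier_fraction=0.05))
        clean = np.arange(1, 20)
        err_trim = np.mean(((X[clean] @ w_trim + b_trim) > 0).astype(int) != y[clean])
        assert err_trim == 0.0
        assert not np.allclose(w_trim, w_plain)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((6, 3))
        with pytest.raises(ValueError, match="both classes"):
            _train_weights(X, np.zeros(6, dtype=int), ps.SvmParams())

    def test_too_few_subjects_rejected(self, rng):
        X = rng.standard_normal((3, 3))
        with pytest.raises(ValueError, match="at least 4"):
            _train_weights(X, np.array([0, 1, 0]), ps.SvmParams())


class TestSubjectScore:
    def _model(self, weights, bias):
        return ps.HyperplaneModel(weights=np.asarray(weights, float), bias=bias,
                                  params=ps.SvmParams(),
                                  voxel_index=np.zeros((len(weights), 3), dtype=int))

    def test_zero_weights_returns_bias(self, rng):
        m = self._model(np.zeros(5), 0.7)
        assert ps.subject_score(m, rng.random(5)) == pytest.approx(0.7)

    def test_one_hot_weight(self):
        w = np.zeros(4)
        w[2] = 2.0
        m = self._model(w, 0.0)
        x = np.zeros(4)
        x[2] = 3.0
        assert ps.subject_score(m, x) == pytest.approx(6.0)

    def test_affinity(self, rng):
        m = self._model(rng.standard_normal(6), 0.3)
        x1, x2 = rng.random(6), rng.random(6)
        s12 = ps.subject_score(m, x1 + x2)
        assert s12 == pytest.approx(
            ps.subject_score(m, x1) + ps.subject_score(m, x2) - m.bias)

    def test_voxel_count_mismatch_rejected(self):
        m = self._model(np.zeros(5), 0.0)
        with pytest.raises(ValueError, match="voxels"):
            ps.subject_score(m, np.zeros(4))

    def test_normalization_record_mismatch_rejected(self, tiny_model):
        x = np.zeros_like(tiny_model.weights)
        bad = dict(tiny_model.normalization_record, target=99.0)
        with pytest.raises(ValueError, match="normalization record"):
            ps.subject_score(tiny_model, x, normalization_record=bad)


class TestClassify:
    @pytest.mark.parametrize("score,label", [(0.001, 1), (-5.0, 0), (0.0, 0)])
    def test_sign_rule_with_zero_to_stable(self, score, label):
        assert ps.classify(score) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ps.classify(float("nan"))
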
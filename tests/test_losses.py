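"""Loss terms: hand-arithmetic oracles, metric axioms, gradient direction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ndfusion import LossWeights, build_label_adjacency, ce_loss, csdm_loss, ge_loss, total_loss
from ndfusion._autodiff import Adam, Parameter, Tensor
from ndfusion.losses import CSDM_EPSILON


def _hand_kl(p, q, eps):
    return sum(pi * math.log(pi / (qi + eps)) for pi, qi in zip(p, q))


class TestCsdm:
    def test_two_sample_identity_cosine_hand_arithmetic(self):
        """n=2 with orthonormal matching features: similarity matrix is the
        identity, each row softmaxes to (e/(e+1), 1/(e+1)); the loss is the
        mean row KL against the smoothed one-hot, computed by hand."""
        f = Tensor(np.eye(2))
        loss = csdm_loss(f, f, tau=1.0).item()
        p_hit = math.e / (math.e + 1)
        row_kl_0 = _hand_kl([p_hit, 1 - p_hit], [1.0, 0.0], CSDM_EPSILON)
        row_kl_1 = _hand_kl([1 - p_hit, p_hit], [0.0, 1.0], CSDM_EPSILON)
        expected = (2 * (row_kl_0 + row_kl_1)) / 4   # two directions, 1/(2n)
        assert loss == pytest.approx(expected, abs=1e-9)

    def test_symmetric_in_modalities(self):
        rng = np.random.default_rng(0)
        fi, ft = Tensor(rng.normal(size=(4, 6))), Tensor(rng.normal(size=(4, 6)))
        assert csdm_loss(fi, ft, tau=0.5).item() == pytest.approx(
            csdm_loss(ft, fi, tau=0.5).item(), abs=1e-10)

    def test_perfect_alignment_sharp_temperature_vanishes(self):
        f = Tensor(np.eye(3))
        assert csdm_loss(f, f, tau=0.01).item() == pytest.approx(0.0, abs=1e-6)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError, match="temperature"):
            csdm_loss(Tensor(np.eye(2)), Tensor(np.eye(2)), tau=0.0)

    def test_single_sample_degenerates_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="single sample"):
            assert csdm_loss(Tensor([[1.0]]), Tensor([[1.0]])).item() == 0.0

    def test_gradient_step_improves_alignment(self):
        """Ten optimizer steps on mismatched features must increase the
        diagonal cosine and decrease the loss monotonically overall."""
        rng = np.random.default_rng(1)
        fi = Parameter(rng.normal(size=(2, 4)))
        ft = Tensor(rng.normal(size=(2, 4)))
        opt = Adam([fi], lr=0.05)

        def diag_cos():
            a = fi.data / np.linalg.norm(fi.data, axis=1, keepdims=True)
            b = ft.data / np.linalg.norm(ft.data, axis=1, keepdims=True)
            return np.diag(a @ b.T).mean()

        before_cos = diag_cos()
        before_loss = csdm_loss(fi, ft, tau=0.5).item()
        for _ in range(10):
            opt.zero_grad()
            csdm_loss(fi, ft, tau=0.5).backward()
            opt.step()
        assert csdm_loss(fi, ft, tau=0.5).item() < before_loss
        assert diag_cos() > before_cos


class TestLabelAdjacency:
    def test_three_node_example(self):
        np.testing.assert_array_equal(
            build_label_adjacency([1, 1, 0]),
            [[1, 1, 0], [1, 1, 0], [0, 0, 1]])

    def test_uniform_labels_complete_graph(self):
        np.testing.assert_array_equal(build_label_adjacency([1, 1, 1]), np.ones((3, 3)))

    def test_alternating_labels_count_by_enumeration(self):
        y = [0, 1, 0, 1]
        a = build_label_adjacency(y)
        expected = sum(1 for i in range(4) for j in range(4) if y[i] == y[j])
        assert a.sum() == expected == 8


class TestGeLoss:
    def test_equal_matrices_zero(self):
        a = build_label_adjacency([1, 0, 1])
        assert ge_loss(a, a).item() == pytest.approx(0.0, abs=1e-9)

    def test_two_entry_difference_is_sqrt_two(self):
        assert ge_loss(np.ones((2, 2)), np.eye(2)).item() == pytest.approx(
            math.sqrt(2), abs=1e-9)

    def test_matches_loop_summation(self):
        rng = np.random.default_rng(2)
        a = (rng.random((5, 5)) < 0.5).astype(float)
        b = (rng.random((5, 5)) < 0.5).astype(float)
        acc = sum((a[i, j] - b[i, j]) ** 2 for i in range(5) for j in range(5))
        assert ge_loss(a, b).item() == pytest.approx(math.sqrt(acc), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            ge_loss(np.eye(2), np.eye(3))

    @given(st.integers(0, 511), st.integers(0, 511), st.integers(0, 511))
    @settings(max_examples=150, derandomize=True)
    def test_metric_axioms_on_3x3_binaries(self, ia, ib, ic):
        def mat(bits):
            return np.array([(bits >> k) & 1 for k in range(9)], float).reshape(3, 3)

        a, b, c = mat(ia), mat(ib), mat(ic)
        dab, dba = ge_loss(a, b).item(), ge_loss(b, a).item()
        assert dab == pytest.approx(dba, abs=1e-12)          # symmetry
        assert (dab == pytest.approx(0.0, abs=1e-9)) == np.array_equal(a, b)
        assert ge_loss(a, c).item() <= dab + ge_loss(b, c).item() + 1e-9


class TestCeLoss:
    def test_perfect_prediction_near_zero(self):
        probs = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert ce_loss(probs, [0, 1]).item() == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_log_two(self):
        probs = Tensor(np.full((3, 2), 0.5))
        assert ce_loss(probs, [0, 1, 1]).item() == pytest.approx(math.log(2), abs=1e-12)

    def test_hand_arithmetic_example(self):
        probs = Tensor(np.array([[0.9, 0.1], [0.2, 0.8]]))
        expected = -(math.log(0.9) + math.log(0.8)) / 2   # ~0.1643
        assert ce_loss(probs, [0, 1]).item() == pytest.approx(expected, abs=1e-12)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ce_loss(Tensor(np.array([[0.9, 0.9]])), [0])

    def test_nonnegative_for_random_inputs(self):
        rng = np.random.default_rng(3)
        probs = Tensor(rng.dirichlet([1, 1], size=8))
        assert ce_loss(probs, rng.integers(0, 2, 8)).item() >= 0


class TestTotalLoss:
    def test_default_weights_sum_to_one(self):
        assert total_loss(1.0, 1.0, 1.0).item() == pytest.approx(1.0, abs=1e-12)

    def test_ce_only_configuration(self):
        w = LossWeights(0.0, 0.0, 1.0)
        assert total_loss(7.0, 5.0, 3.0, w).item() == pytest.approx(3.0, abs=1e-12)

    def test_single_term_scaling(self):
        assert total_loss(5.0, 0.0, 0.0, LossWeights(0.2, 0.4, 0.4)).item() == \
            pytest.approx(1.0, abs=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0.5, 0.6)

    def test_ablation_masks_disable_terms(self):
        """Zeroing a lambda removes that term's influence entirely."""
        base = total_loss(2.0, 3.0, 4.0, LossWeights(0.0, 0.4, 0.4)).item()
        changed = total_loss(99.0, 3.0, 4.0, LossWeights(0.0, 0.4, 0.4)).item()
        assert base == changed
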
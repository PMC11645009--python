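"""Class-weighted BCE, focal modulation, and their compositions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sefast._autograd import Tensor
from sefast.losses import (
    ClassWeights,
    LossConfig,
    bce_elementwise,
    compute_class_weights,
    cw_loss,
    focal_modulate,
    make_loss,
)


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        assert compute_class_weights((10, 10, 10)).w == pytest.approx((1.0, 1.0, 1.0))

    def test_worked_example(self):
        # counts (30, 10, 20), C=3, total 60 -> w = (2/3, 2, 1)
        cw = compute_class_weights((30, 10, 20))
        assert cw.w == pytest.approx((2 / 3, 2.0, 1.0))

    def test_reference_posture_ordering(self):
        """With the 18:7:7 posture video counts, Standing is down-weighted and
        the two recumbencies share the larger weight."""
        cw = compute_class_weights((18, 7, 7))
        w_standing, w_sternal, w_lateral = cw.w
        assert w_standing < w_sternal
        assert w_sternal == pytest.approx(w_lateral)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="merge or drop"):
            compute_class_weights((5, 0, 3))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 10_000), min_size=2, max_size=6),
           st.integers(2, 9))
    def test_monotone_and_scale_invariant(self, counts, k):
        w = compute_class_weights(counts).w
        for i in range(len(counts)):
            for j in range(len(counts)):
                if counts[i] < counts[j]:
                    assert w[i] > w[j]
        scaled = compute_class_weights([k * c for c in counts]).w
        assert scaled == pytest.approx(w)


class TestCwLoss:
    def test_single_element_reference_value(self):
        """A confident-less prediction (logit 0) of a positive label costs
        −log 0.5 = ln 2."""
        scalar, per_elem = cw_loss([[1.0]], [[0.0]], ClassWeights((1.0,), (1,)))
        assert scalar.item() == pytest.approx(np.log(2.0), rel=1e-9)
        assert per_elem.data[0, 0] == pytest.approx(0.69314718, rel=1e-6)

    def test_unit_weights_reduce_to_plain_bce(self):
        rng = np.random.default_rng(0)
        y = (rng.uniform(size=(6, 4)) < 0.4).astype(float)
        logits = rng.normal(size=(6, 4)) * 3
        scalar, _ = cw_loss(y, logits, ClassWeights((1.0,) * 4, (1,) * 4))
        assert scalar.item() == pytest.approx(bce_elementwise(y, logits).mean().item(),
                                              rel=1e-12)

    def test_perfect_confident_predictions_vanish(self):
        y = np.array([[1.0, 0.0]])
        logits = np.array([[40.0, -40.0]])
        scalar, _ = cw_loss(y, logits, ClassWeights((1.0, 1.0), (1, 1)))
        assert scalar.item() == pytest.approx(0.0, abs=1e-12)

    def test_extreme_logits_stay_finite(self):
        y = np.array([[1.0, 0.0]])
        logits = np.array([[-50.0, 50.0]])
        scalar, _ = cw_loss(y, logits, ClassWeights((1.0, 1.0), (1, 1)))
        assert np.isfinite(scalar.item())

    def test_weights_amplify_minority_error(self):
        """When only the minority class is mispredicted, the weighted loss
        exceeds the unweighted one."""
        y = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        logits = np.array([[-3.0, -3.0], [-3.0, 3.0], [-3.0, 3.0], [-3.0, 3.0]])
        weights = compute_class_weights((1, 3))
        weighted, _ = cw_loss(y, logits, weights)
        plain = bce_elementwise(y, logits).mean()
        assert weighted.item() > plain.item()


class TestFocal:
    def test_confident_correct_predictions_zero_out(self):
        y = np.array([[1.0, 0.0]])
        logits = np.array([[60.0, -60.0]])  # p_t -> 1
        per = bce_elementwise(y, logits)
        assert focal_modulate(per, y, logits, r=2).item() == pytest.approx(0.0, abs=1e-20)

    def test_reference_arithmetic(self):
        """r=2, p_t=0.5, per-element loss 1 -> 2 · 0.25 · 1 = 0.5."""
        y = np.array([[1.0]])
        logits = np.array([[0.0]])  # sigmoid = 0.5
        out = focal_modulate(np.array([[1.0]]), y, logits, r=2)
        assert out.item() == pytest.approx(0.5, rel=1e-9)

    def test_orthodox_variant_drops_leading_factor(self):
        y = np.array([[1.0]])
        logits = np.array([[0.0]])
        with pytest.warns(UserWarning):
            out = focal_modulate(np.array([[1.0]]), y, logits, r=1, orthodox_focal=True)
        assert out.item() == pytest.approx(0.5, rel=1e-9)  # (1 - 0.5)^1 · 1

    def test_r_validation_and_range_warning(self):
        y = np.array([[1.0]])
        with pytest.raises(ValueError):
            focal_modulate(np.array([[1.0]]), y, np.array([[0.0]]), r=0)
        with pytest.warns(UserWarning, match="r=5"):
            focal_modulate(np.array([[1.0]]), y, np.array([[0.0]]), r=5)


class TestMakeLoss:
    def _random_batch(self, seed=1, n=5, c=4):
        rng = np.random.default_rng(seed)
        y = (rng.uniform(size=(n, c)) < 0.5).astype(float)
        logits = rng.normal(size=(n, c)) * 2
        return y, logits

    def test_cw_f_with_unit_weights_equals_bce_f(self):
        y, logits = self._random_batch()
        unit = ClassWeights((1.0,) * 4, (1,) * 4)
        cw_f = make_loss(LossConfig(kind="cw_f", r=2, weights=unit))
        bce_f = make_loss(LossConfig(kind="bce_f", r=2))
        assert cw_f(y, logits).item() == pytest.approx(bce_f(y, logits).item(), rel=1e-12)

    def test_cw_requires_weights(self):
        with pytest.raises(ValueError, match="weights"):
            LossConfig(kind="cw_f", weights=None)
        with pytest.raises(ValueError):
            LossConfig(kind="nll")

    def test_all_variants_finite_for_extreme_logits(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        logits = np.array([[50.0, -50.0], [-50.0, 50.0]])
        weights = compute_class_weights((3, 1))
        for kind in ("bce", "cw", "bce_f", "cw_f"):
            cfg = LossConfig(kind=kind, r=2,
                             weights=weights if kind.startswith("cw") else None)
            assert np.isfinite(make_loss(cfg)(y, logits).item())

    def test_gradient_matches_finite_differences(self):
        """Autograd gradient of cw_f w.r.t. logits vs central differences, 2×2."""
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        logits0 = np.array([[0.3, -0.7], [1.2, 0.1]])
        weights = compute_class_weights((3, 1))
        loss_fn = make_loss(LossConfig(kind="cw_f", r=2, weights=weights))

        x = Tensor(logits0.copy(), requires_grad=True)
        loss_fn(y, x).backward()
        eps = 1e-6
        for i in range(2):
            for j in range(2):
                pert = logits0.copy()
                pert[i, j] += eps
                lp = loss_fn(y, pert).item()
                pert[i, j] -= 2 * eps
                lm = loss_fn(y, pert).item()
                assert x.grad[i, j] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5)

    def test_loss_ordering_on_imbalanced_batch(self):
        """Mispredicting only minority-class positives costs cw variants more
        than their bce counterparts."""
        y = np.zeros((8, 2))
        y[:, 0] = 1.0  # majority class present everywhere
        y[0, 1] = 1.0  # single minority positive
        logits = np.full((8, 2), 3.0)
        logits[:, 1] = -3.0  # minority positive confidently missed
        weights = compute_class_weights((8, 1))
        for base, weighted in (("bce", "cw"), ("bce_f", "cw_f")):
            l_plain = make_loss(LossConfig(kind=base, r=2))(y, logits).item()
            l_weighted = make_loss(
                LossConfig(kind=weighted, r=2, weights=weights))(y, logits).item()
            assert l_weighted > l_plain
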
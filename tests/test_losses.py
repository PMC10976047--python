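"""Unit and property tests for the segmentation losses and their gradients."""

import numpy as np
import pytest

import lesionloss.losses as L


def _random_pair(rng, shape=(4, 4, 4), fg=0.3):
    logits = rng.uniform(-3.0, 3.0, size=shape)
    target = (rng.random(shape) < fg).astype(int)
    return logits, target


# ---------------------------------------------------------------------------
# class counts
# ---------------------------------------------------------------------------

class TestClassCounts:
    def test_direct_counts(self):
        c = L.class_counts([1, 1, 0, 0])
        assert (c.n_total, c.n_fg, c.n_bg) == (4, 2, 2)

    def test_empty_foreground(self):
        c = L.class_counts(np.zeros(8))
        assert (c.n_total, c.n_fg, c.n_bg) == (8, 0, 8)

    def test_matches_bruteforce_tally(self, rng):
        mask = (rng.random((10, 10, 10)) < 0.2).astype(int)
        tally = sum(1 for v in mask.ravel() if v == 1)
        c = L.class_counts(mask)
        assert c.n_fg == tally and c.n_bg == mask.size - tally

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            L.class_counts([0, 1, 2])


# ---------------------------------------------------------------------------
# scalar loss values (closed-form oracles)
# ---------------------------------------------------------------------------

class TestLossValues:
    def test_cross_entropy_closed_form(self):
        # y=[1,0], p=[0.8,0.2]: both voxels contribute -ln 0.8
        assert L.cross_entropy([0.8, 0.2], [1, 0]) == pytest.approx(
            -np.log(0.8), rel=1e-12)

    def test_cross_entropy_midpoint(self):
        assert L.cross_entropy([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(
            np.log(2), rel=1e-9)

    def test_cross_entropy_perfect(self):
        assert L.cross_entropy([1.0, 0.0], [1, 0]) == pytest.approx(0.0, abs=1e-6)

    def test_cross_entropy_shape_mismatch(self):
        with pytest.raises(ValueError):
            L.cross_entropy([0.5, 0.5], [1])

    def test_focal_single_voxel(self):
        # alpha (1-p)^gamma (-ln p) with p=0.9, alpha=0.25, gamma=2
        assert L.focal([0.9], [1], 0.25, 2.0) == pytest.approx(
            0.25 * 0.01 * -np.log(0.9), rel=1e-12)

    def test_focal_perfect_confidence(self):
        assert L.focal([1.0, 1.0], [1, 1], 0.25, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_focal_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            L.focal([0.5], [1], alpha=1.5)

    def test_generalized_dice_hand_computed(self):
        # N=4, w_fg=1/N_fg^2=1, w_bg=1/N_bg^2=1/9
        val = L.generalized_dice([0.5, 0.5, 0, 0], [1, 0, 0, 0], 1.0, 1.0 / 9.0)
        assert val == pytest.approx(5.0 / 12.0, rel=1e-12)

    def test_generalized_dice_perfect_overlap(self, rng):
        y = (rng.random(50) < 0.4).astype(int)
        assert L.generalized_dice(y, y, 1.0, 1.0 / 9.0) == pytest.approx(0.0, abs=1e-12)

    def test_binary_dice_direct(self):
        assert L.binary_dice([1, 0, 0, 0], [1, 1, 0, 0], 0.0) == pytest.approx(
            1.0 / 3.0, rel=1e-12)

    def test_binary_dice_empty_with_smoothing(self):
        assert L.binary_dice([0, 0], [0, 0], 1e-6) == 0.0

    def test_binary_dice_empty_without_smoothing_raises(self):
        with pytest.raises(ZeroDivisionError):
            L.binary_dice([0.0, 0.0], [0, 0], 0.0)

    def test_mixed_is_sum_of_components(self, rng):
        p = rng.random(30)
        y = (rng.random(30) < 0.3).astype(int)
        expected = L.binary_dice(p, y, 1e-6) + L.cross_entropy(p, y)
        assert L.mixed(p, y, 1e-6) == pytest.approx(expected, rel=1e-12)

    def test_all_losses_nonneg_and_zero_at_perfect(self, rng):
        y = (rng.random(40) < 0.4).astype(int)
        p = y.astype(float)
        assert L.cross_entropy(p, y) < 1e-5
        assert L.focal(p, y) < 1e-6
        assert L.binary_dice(p, y, 1e-6) == pytest.approx(0.0, abs=1e-6)
        q = rng.random(40)
        for val in (L.cross_entropy(q, y), L.focal(q, y),
                    L.binary_dice(q, y), L.mixed(q, y)):
            assert val >= 0.0

    def test_permutation_invariance(self, rng):
        p = rng.random(64)
        y = (rng.random(64) < 0.3).astype(int)
        perm = rng.permutation(64)
        for fn in (lambda a, b: L.cross_entropy(a, b),
                   lambda a, b: L.focal(a, b, 0.75, 2.0),
                   lambda a, b: L.binary_dice(a, b),
                   lambda a, b: L.generalized_dice(a, b, 1.0, 0.01)):
            assert fn(p, y) == pytest.approx(fn(p[perm], y[perm]), rel=1e-12)


# ---------------------------------------------------------------------------
# algebraic reductions
# ---------------------------------------------------------------------------

class TestReductions:
    def test_focal_gamma0_is_half_cross_entropy(self, rng):
        for _ in range(10):
            p = rng.random(20)
            y = (rng.random(20) < 0.5).astype(int)
            assert L.focal(p, y, alpha=0.5, gamma=0.0) == pytest.approx(
                0.5 * L.cross_entropy(p, y), abs=1e-12)

    def test_gdsc_reduces_to_binary_dice(self, rng):
        for _ in range(10):
            p = rng.random(20)
            y = (rng.random(20) < 0.5).astype(int)
            if y.sum() == 0:
                y[0] = 1
            assert L.generalized_dice(p, y, 1.0, 0.0) == pytest.approx(
                L.binary_dice(p, y, 0.0), abs=1e-12)


# ---------------------------------------------------------------------------
# gradient-defined loss
# ---------------------------------------------------------------------------

class TestWeightedGradient:
    def test_formula_values(self):
        # fg voxel p=0.5, alpha=0.8, gamma=2 -> -0.8*0.25; bg -> +0.2*0.25
        g = L.weighted_gradient_backward([0.0, 0.0], [1, 0], 0.8, 2.0)
        n = 2
        assert g[0] == pytest.approx(-0.8 * 0.25 / n, rel=1e-12)
        assert g[1] == pytest.approx(0.2 * 0.25 / n, rel=1e-12)

    def test_vanishes_at_confident_foreground(self):
        g = L.weighted_gradient_backward([20.0], [1], 0.8, 2.0)
        assert abs(g[0]) < 1e-8

    def test_reduces_to_half_ce_gradient(self, rng):
        f, y = _random_pair(rng)
        g = L.weighted_gradient_backward(f, y, 0.5, 1.0)
        ce = L.loss_gradient_wrt_logits("xent", f, y)
        assert np.abs(g - 0.5 * ce).max() < 1e-12

    def test_custom_backward_is_bitwise_contract(self, rng):
        f, y = _random_pair(rng)
        loss = L.make_logit_loss("new")
        alpha = L.class_counts(y).n_bg / y.size
        expected = L.weighted_gradient_backward(f, y, alpha, 2.0)
        assert np.array_equal(loss.grad(f, y), expected)

    def test_all_background_batch(self, rng):
        f = rng.uniform(-2, 2, size=8)
        y = np.zeros(8, dtype=int)
        loss = L.make_logit_loss("new")
        with pytest.warns(RuntimeWarning):
            g = loss.grad(f, y)
        assert np.all(g == 0.0)  # alpha=1 kills the background term

    def test_foreground_background_magnitude_ratio(self):
        # at p=0.5, |grad_fg| / |grad_bg| = alpha / (1 - alpha)
        n_fg, n = 10, 1000
        y = np.r_[np.ones(n_fg, int), np.zeros(n - n_fg, int)]
        f = np.zeros(n)
        loss = L.make_logit_loss("new")
        g = loss.grad(f, y)
        alpha = (n - n_fg) / n
        assert abs(g[0]) / abs(g[-1]) == pytest.approx(alpha / (1 - alpha), rel=1e-9)

    def test_rejects_nonfinite_logits(self):
        with pytest.raises(ValueError):
            L.weighted_gradient_backward([np.inf], [1], 0.5, 2.0)

    def test_monitoring_value_is_weighted_ce(self, rng):
        f, y = _random_pair(rng, shape=(64,))
        alpha = L.class_counts(y).n_bg / y.size
        p = L.sigmoid(f)
        expected = np.mean(
            -alpha * y * np.log(p) - (1 - alpha) * (1 - y) * np.log(1 - p))
        assert L.weighted_gradient_loss(f, y) == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# analytic gradients vs finite differences
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", ["xent", "focal1", "focal2", "gdsc", "dsc", "mixed"])
def test_gradient_matches_finite_differences(name, rng):
    loss = L.make_logit_loss(name)
    h = 1e-4
    for _ in range(5):
        f, y = _random_pair(rng)
        if y.sum() == 0:
            y.flat[0] = 1
        g = loss.grad(f, y)
        for t in range(0, f.size, 7):
            i = np.unravel_index(t, f.shape)
            fp = f.copy(); fp[i] += h
            fm = f.copy(); fm[i] -= h
            fd = (loss.value(fp, y) - loss.value(fm, y)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-12)


def test_dice_gradient_saturates_for_confident_errors():
    """A confidently wrong background voxel: Dice+sigmoid gradient decays to
    zero while the cross-entropy gradient stays near 1/N."""
    n = 8
    y = np.zeros(n, dtype=int)
    y[-1] = 1
    mags_dice, mags_ce = [], []
    for k in range(1, 7):
        p = 1.0 - 10.0**-k
        f = np.zeros(n)
        f[0] = np.log(p / (1 - p))
        mags_dice.append(abs(L.loss_gradient_wrt_logits("dsc", f, y)[0]))
        mags_ce.append(abs(L.loss_gradient_wrt_logits("xent", f, y)[0]))
    assert all(a > b for a, b in zip(mags_dice, mags_dice[1:]))
    assert mags_dice[-1] < 1e-6
    assert mags_ce[-1] == pytest.approx(1.0 / n, rel=1e-5)


def test_unknown_loss_name_rejected(rng):
    f, y = _random_pair(rng)
    with pytest.raises(ValueError):
        L.loss_gradient_wrt_logits("tversky", f, y)
    with pytest.raises(ValueError):
        L.preset("boundary")
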
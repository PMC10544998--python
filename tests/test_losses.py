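"""Loss core: oracle equivalence, limiting cases, gradients, invariants.

Every loss is compared against an independent pure-scalar (loop-based,
no array library) oracle, and every analytic gradient against central
finite differences in float64.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stagedistill import (
    Adapter,
    FocalParams,
    LossWeights,
    entropy,
    feature_match_loss,
    focal_loss,
    soft_target_loss,
    tempered_softmax,
    total_loss,
)
from stagedistill.losses import softmax_backward


# ---------------------------------------------------------------------------
# scalar-loop oracles (no numpy in the arithmetic)
# ---------------------------------------------------------------------------

def softmax_oracle(logits, temperature):
    scaled = [z / temperature for z in logits]
    m = max(scaled)
    exps = [math.exp(z - m) for z in scaled]
    total = sum(exps)
    return [e / total for e in exps]


def soft_target_oracle(student_batch, teacher_batch, temperature):
    per_sample = []
    for zs, zt in zip(student_batch, teacher_batch):
        pt = softmax_oracle(zt, temperature)
        ps = softmax_oracle(zs, temperature)
        per_sample.append(sum(-t * math.log(s) for t, s in zip(pt, ps)))
    return sum(per_sample) / len(per_sample)


def focal_oracle(prob_batch, labels, gamma, weights):
    values = []
    for probs, y in zip(prob_batch, labels):
        p = max(probs[y], 1e-12)
        values.append(-weights[y] * (1.0 - p) ** gamma * math.log(p))
    return sum(values) / len(values)


def feature_match_oracle(student_feats, teacher_feats, adapters):
    stage_losses = []
    for fs, ft, ad in zip(student_feats, teacher_feats, adapters):
        b, cs, h, w = fs.shape
        ct = ft.shape[1]
        total, count = 0.0, 0
        for bi in range(b):
            for co in range(ct):
                for i in range(h):
                    for j in range(w):
                        proj = ad.bias[co] + sum(
                            ad.weight[co][ci] * fs[bi][ci][i][j] for ci in range(cs)
                        )
                        total += (proj - ft[bi][co][i][j]) ** 2
                        count += 1
        stage_losses.append(total / count)
    return sum(stage_losses) / len(stage_losses)


def fd_grad(fn, x, eps=1e-6):
    """Central finite differences of scalar fn w.r.t. every entry of x."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        old = x[idx]
        x[idx] = old + eps
        hi = fn()
        x[idx] = old - eps
        lo = fn()
        x[idx] = old
        g[idx] = (hi - lo) / (2 * eps)
    return g


def make_adapters(rng, student_channels, teacher_channels):
    ads = []
    for cs, ct in zip(student_channels, teacher_channels):
        ad = Adapter.__new__(Adapter)
        ad.weight = rng.normal(size=(ct, cs))
        ad.bias = rng.normal(size=ct)
        ads.append(ad)
    return ads


# ---------------------------------------------------------------------------
# tempered softmax
# ---------------------------------------------------------------------------

class TestTemperedSoftmax:
    def test_constant_logits_are_uniform(self):
        for c in (3.0, -7.5, 0.0):
            np.testing.assert_allclose(
                tempered_softmax([c, c, c], 2.5), np.full(3, 1 / 3), atol=1e-12
            )

    @pytest.mark.parametrize(
        "temperature,expected",
        [
            (1.0, [0.09003057, 0.24472847, 0.66524096]),
            (2.0, [0.18632372, 0.30719589, 0.50648039]),
        ],
    )
    def test_worked_example(self, temperature, expected):
        np.testing.assert_allclose(
            tempered_softmax([1.0, 2.0, 3.0], temperature), expected, atol=5e-7
        )

    def test_matches_scalar_oracle(self, rng):
        for _ in range(100):
            z = rng.normal(scale=5, size=5)
            t = float(rng.uniform(0.1, 10))
            np.testing.assert_allclose(
                tempered_softmax(z, t), softmax_oracle(list(z), t), atol=1e-6
            )

    def test_sums_to_one_for_extreme_inputs(self, rng):
        for t in (1e-2, 1.0, 1e4):
            z = rng.normal(scale=50, size=(10, 5))
            np.testing.assert_allclose(
                tempered_softmax(z, t).sum(axis=-1), 1.0, atol=1e-6
            )

    def test_entropy_nondecreasing_in_temperature(self, rng):
        """Higher temperature smooths the distribution."""
        for _ in range(100):
            z = rng.normal(scale=3, size=5)
            ents = [float(entropy(tempered_softmax(z, t))) for t in (1, 2, 4, 8)]
            assert all(b >= a - 1e-12 for a, b in zip(ents, ents[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tempered_softmax([1.0, 2.0], 0.0)
        with pytest.raises(ValueError):
            tempered_softmax([1.0, 2.0], -1.0)
        with pytest.raises(ValueError):
            tempered_softmax([np.nan, 1.0], 1.0)
        with pytest.raises(ValueError):
            tempered_softmax([np.inf, 1.0], 1.0)


# ---------------------------------------------------------------------------
# soft-target loss
# ---------------------------------------------------------------------------

class TestSoftTargetLoss:
    def test_identical_logits_give_teacher_entropy(self):
        assert soft_target_loss([0.0, 0.0], [0.0, 0.0], 1.0) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_opposed_confident_logits(self):
        loss = soft_target_loss([0.0, 10.0], [10.0, 0.0], 1.0)
        assert loss == pytest.approx(10.0, abs=1e-2)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(100):
            zs = rng.normal(scale=4, size=(4, 5))
            zt = rng.normal(scale=4, size=(4, 5))
            t = float(rng.uniform(0.5, 8))
            expected = soft_target_oracle(zs.tolist(), zt.tolist(), t)
            assert soft_target_loss(zs, zt, t) == pytest.approx(expected, abs=1e-6)

    def test_gibbs_inequality(self, rng):
        """Loss is bounded below by the tempered teacher entropy, with
        equality iff the student logits equal the teacher's up to a
        constant shift."""
        for _ in range(50):
            zt = rng.normal(scale=3, size=(2, 5))
            zs = rng.normal(scale=3, size=(2, 5))
            t = float(rng.uniform(0.5, 6))
            lower = float(np.mean(entropy(tempered_softmax(zt, t))))
            assert soft_target_loss(zs, zt, t) >= lower - 1e-10
            shifted = zt + rng.normal(scale=2)
            assert soft_target_loss(shifted, zt, t) == pytest.approx(lower, abs=1e-8)

    def test_gradient_matches_finite_differences(self, rng):
        zs = rng.normal(scale=2, size=(3, 5))
        zt = rng.normal(scale=2, size=(3, 5))
        for t, t2 in ((1.0, False), (4.0, False), (4.0, True)):
            _, grad = soft_target_loss(zs, zt, t, t_squared=t2, return_grad=True)
            numeric = fd_grad(
                lambda: soft_target_loss(zs, zt, t, t_squared=t2), zs
            )
            np.testing.assert_allclose(grad, numeric, rtol=1e-4, atol=1e-9)

    def test_t_squared_flag_scales_loss(self, rng):
        zs = rng.normal(size=(2, 5))
        zt = rng.normal(size=(2, 5))
        base = soft_target_loss(zs, zt, 4.0)
        scaled = soft_target_loss(zs, zt, 4.0, t_squared=True)
        assert scaled == pytest.approx(16.0 * base, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            soft_target_loss(rng.normal(size=(2, 5)), rng.normal(size=(2, 4)), 1.0)


# ---------------------------------------------------------------------------
# focal loss
# ---------------------------------------------------------------------------

class TestFocalLoss:
    def test_reduces_to_cross_entropy_at_gamma_zero(self):
        params = FocalParams(gamma=0.0, class_weights=np.ones(2))
        assert focal_loss(np.array([[0.5, 0.5]]), np.array([0]), params) == (
            pytest.approx(math.log(2), abs=1e-12)
        )

    def test_worked_example(self):
        params = FocalParams(gamma=2.0, class_weights=np.full(2, 0.25))
        loss = focal_loss(np.array([[0.9, 0.1]]), np.array([0]), params)
        assert loss == pytest.approx(2.6341e-4, rel=1e-4)

    def test_perfect_prediction_gives_zero(self):
        for gamma in (0.0, 1.0, 2.0):
            params = FocalParams(gamma=gamma, class_weights=np.array([3.0, 0.5]))
            assert focal_loss(np.array([[1.0, 0.0]]), np.array([0]), params) == 0.0

    def test_matches_scalar_oracle(self, rng):
        for _ in range(100):
            p = rng.dirichlet(np.ones(5), size=6)
            y = rng.integers(0, 5, size=6)
            gamma = float(rng.uniform(0, 4))
            w = rng.uniform(0.2, 5, size=5)
            params = FocalParams(gamma=gamma, class_weights=w)
            expected = focal_oracle(p.tolist(), y.tolist(), gamma, w.tolist())
            assert focal_loss(p, y, params) == pytest.approx(expected, abs=1e-6)

    def test_gamma_zero_unit_weights_equals_mean_cross_entropy(self, rng):
        p = rng.dirichlet(np.ones(5), size=16)
        y = rng.integers(0, 5, size=16)
        params = FocalParams(gamma=0.0, class_weights=np.ones(5))
        ce = -np.mean(np.log(p[np.arange(16), y]))
        assert focal_loss(p, y, params) == pytest.approx(ce, abs=1e-8)

    def test_strictly_decreasing_in_true_class_probability(self):
        params = FocalParams(gamma=2.0, class_weights=np.ones(2))
        grid = np.linspace(0.01, 0.99, 60)
        vals = [
            focal_loss(np.array([[p, 1 - p]]), np.array([0]), params) for p in grid
        ]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.dirichlet(np.ones(5), size=4)
        y = rng.integers(0, 5, size=4)
        for gamma in (0.0, 2.0):
            params = FocalParams(gamma=gamma, class_weights=rng.uniform(0.5, 2, 5))
            _, grad = focal_loss(p, y, params, return_grad=True)
            numeric = fd_grad(lambda: focal_loss(p, y, params), p)
            np.testing.assert_allclose(grad, numeric, rtol=1e-4, atol=1e-10)

    def test_confident_mistake_stays_finite(self):
        params = FocalParams(gamma=2.0, class_weights=np.ones(2))
        loss = focal_loss(np.array([[0.0, 1.0]]), np.array([0]), params)
        assert np.isfinite(loss)

    def test_label_out_of_range_rejected(self):
        params = FocalParams()
        with pytest.raises(ValueError):
            focal_loss(np.full((1, 5), 0.2), np.array([5]), params)
        with pytest.raises(ValueError):
            focal_loss(np.full((1, 5), 0.2), np.array([-1]), params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FocalParams(gamma=-0.5)
        with pytest.raises(ValueError):
            FocalParams(class_weights=np.array([1.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# feature-matching loss
# ---------------------------------------------------------------------------

class TestFeatureMatchLoss:
    def _random_stage_sets(self, rng, batch=2, hw=(8, 4, 2, 1)):
        cs = (3, 4, 5, 6)
        ct = (4, 6, 8, 10)
        fs = [rng.normal(size=(batch, c, h, h)) for c, h in zip(cs, hw)]
        ft = [rng.normal(size=(batch, c, h, h)) for c, h in zip(ct, hw)]
        return fs, ft, make_adapters(rng, cs, ct)

    def test_zero_iff_adapted_maps_match(self, rng):
        fs, _, ads = self._random_stage_sets(rng)
        ft = []
        for f, ad in zip(fs, ads):
            ft.append(
                np.einsum("oc,bchw->bohw", ad.weight, f) + ad.bias[None, :, None, None]
            )
        assert feature_match_loss(fs, ft, ads) == pytest.approx(0.0, abs=1e-20)
        ft[2][0, 0, 0, 0] += 0.5
        assert feature_match_loss(fs, ft, ads) > 0

    def test_single_stage_hand_example(self, rng):
        """One stage off by a constant 1 everywhere, three stages equal:
        the mean-of-stage-MSE reduction gives (1+0+0+0)/4."""
        cs = (1, 1, 1, 1)
        ads = make_adapters(rng, cs, cs)
        for ad in ads:
            ad.weight = np.ones((1, 1))
            ad.bias = np.zeros(1)
        fs = [np.ones((1, 1, 2, 2)) for _ in range(4)]
        ft = [np.ones((1, 1, 2, 2)) for _ in range(4)]
        ft[0] = np.zeros((1, 1, 2, 2))
        assert feature_match_loss(fs, ft, ads) == pytest.approx(0.25, abs=1e-15)

    def test_quadratic_homogeneity(self, rng):
        fs, ft, ads = self._random_stage_sets(rng)
        base = feature_match_loss(fs, ft, ads)
        # scale every difference by c: scale teacher maps toward adapted maps
        adapted = [
            np.einsum("oc,bchw->bohw", ad.weight, f) + ad.bias[None, :, None, None]
            for f, ad in zip(fs, ads)
        ]
        c = 3.0
        ft_scaled = [a - c * (a - t) for a, t in zip(adapted, ft)]
        scaled = feature_match_loss(fs, ft_scaled, ads)
        assert scaled == pytest.approx(c**2 * base, rel=1e-10)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(5):
            fs, ft, ads = self._random_stage_sets(rng, batch=2, hw=(4, 3, 2, 1))
            expected = feature_match_oracle(fs, ft, ads)
            assert feature_match_loss(fs, ft, ads) == pytest.approx(expected, abs=1e-6)

    def test_spatial_mismatch_resized(self, rng):
        """Adapted student maps are bilinearly resized to the teacher's
        spatial size when the downsampling schedules differ."""
        cs, ct = (2, 2, 2, 2), (3, 3, 3, 3)
        fs = [rng.normal(size=(1, 2, 8, 8)) for _ in range(4)]
        ft = [rng.normal(size=(1, 3, 4, 4)) for _ in range(4)]
        ads = make_adapters(rng, cs, ct)
        loss = feature_match_loss(fs, ft, ads)
        assert np.isfinite(loss) and loss > 0

    def test_gradients_match_finite_differences(self, rng):
        fs, ft, ads = self._random_stage_sets(rng, batch=2, hw=(4, 3, 2, 1))
        _, fgrads, agrads = feature_match_loss(fs, ft, ads, return_grads=True)
        for k in (0, 3):
            numeric = fd_grad(lambda: feature_match_loss(fs, ft, ads), fs[k])
            np.testing.assert_allclose(fgrads[k], numeric, rtol=1e-4, atol=1e-10)
            numeric_w = fd_grad(lambda: feature_match_loss(fs, ft, ads), ads[k].weight)
            np.testing.assert_allclose(agrads[k][0], numeric_w, rtol=1e-4, atol=1e-10)
            numeric_b = fd_grad(lambda: feature_match_loss(fs, ft, ads), ads[k].bias)
            np.testing.assert_allclose(agrads[k][1], numeric_b, rtol=1e-4, atol=1e-10)

    def test_gradient_with_resize_matches_finite_differences(self, rng):
        cs, ct = (2, 2, 2, 2), (3, 3, 3, 3)
        fs = [rng.normal(size=(1, 2, 6, 6)) for _ in range(4)]
        ft = [rng.normal(size=(1, 3, 3, 3)) for _ in range(4)]
        ads = make_adapters(rng, cs, ct)
        _, fgrads, _ = feature_match_loss(fs, ft, ads, return_grads=True)
        numeric = fd_grad(lambda: feature_match_loss(fs, ft, ads), fs[1])
        np.testing.assert_allclose(fgrads[1], numeric, rtol=1e-4, atol=1e-10)

    def test_wrong_stage_count_rejected(self, rng):
        fs, ft, ads = self._random_stage_sets(rng)
        with pytest.raises(ValueError):
            feature_match_loss(fs[:3], ft, ads)
        with pytest.raises(ValueError):
            feature_match_loss(fs, ft[:3], ads)
        fs_bad = [f.copy() for f in fs]
        fs_bad[0] = fs_bad[0][:1]
        with pytest.raises(ValueError):
            feature_match_loss(fs_bad, ft, ads)


# ---------------------------------------------------------------------------
# combined objective
# ---------------------------------------------------------------------------

class TestTotalLoss:
    def test_reference_coefficients(self):
        # alpha = 0.5, beta = 1 are the published coefficient choices
        w = LossWeights(alpha=0.5, beta=1.0, temperature=4.0)
        assert total_loss(2.0, 4.0, 1.0, w) == pytest.approx(4.0)

    @pytest.mark.parametrize(
        "alpha,beta,expected",
        [(1.0, 0.0, 2.0), (0.0, 0.0, 4.0)],
    )
    def test_degenerate_weightings(self, alpha, beta, expected):
        w = LossWeights(alpha=alpha, beta=beta)
        assert total_loss(2.0, 4.0, 1.0, w) == expected

    @given(
        l1=st.floats(-10, 10),
        l2=st.floats(-10, 10),
        l3=st.floats(-10, 10),
        alpha=st.floats(0, 1),
        beta=st.floats(0, 5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linear_combination(self, l1, l2, l3, alpha, beta):
        w = LossWeights(alpha=alpha, beta=beta)
        assert total_loss(l1, l2, l3, w) == pytest.approx(
            alpha * l1 + (1 - alpha) * l2 + beta * l3, abs=1e-9
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            total_loss(np.nan, 0.0, 0.0, LossWeights())

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=1.5)
        with pytest.raises(ValueError):
            LossWeights(beta=-0.1)
        with pytest.raises(ValueError):
            LossWeights(temperature=0.0)


class TestSoftmaxBackward:
    def test_chain_rule_against_finite_differences(self, rng):
        """softmax_backward composes focal-loss gradients onto logits."""
        z = rng.normal(size=(3, 5))
        y = rng.integers(0, 5, size=3)
        params = FocalParams(gamma=2.0, class_weights=rng.uniform(0.5, 2, 5))

        def loss_of_logits():
            return focal_loss(tempered_softmax(z, 1.0), y, params)

        probs = tempered_softmax(z, 1.0)
        _, gp = focal_loss(probs, y, params, return_grad=True)
        analytic = softmax_backward(probs, gp)
        numeric = fd_grad(loss_of_logits, z)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-4, atol=1e-10)
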
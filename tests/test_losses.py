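"""The composite objective: term oracles, breakdown identity, gradients."""

import numpy as np
import pytest

import mkdespeckle as mk
from mkdespeckle.losses import mse_term
from mkdespeckle.nn import Tensor


def brute_force_kl(t_logits, s_logits, temperature, epsilon=1e-10):
    def soft(v):
        e = np.exp(np.asarray(v, dtype=float) / temperature)
        return e / e.sum()
    qt, qs = soft(t_logits), soft(s_logits)
    return float(np.sum(qt * (np.log(qt + epsilon) - np.log(qs + epsilon))))


@pytest.fixture
def toy_batch(rng):
    g = rng.random((4, 16, 16))
    p_s = np.clip(g + 0.08 * rng.standard_normal(g.shape), 0, 1)
    p_t = np.clip(g + 0.03 * rng.standard_normal(g.shape), 0, 1)
    return g, p_s, p_t


class TestL1Term:
    def test_zero_for_perfect_prediction(self, toy_batch):
        g, _, _ = toy_batch
        assert mk.l1_term(g, g.copy()) == 0.0

    def test_batch_mean_of_per_patch_maes(self):
        a = np.zeros((1, 4, 4))
        b = np.full((1, 4, 4), 0.2)
        batch_g = np.concatenate([a, a])
        batch_p = np.concatenate([b, 2 * b])   # MAEs 0.2 and 0.4
        assert mk.l1_term(batch_g, batch_p) == pytest.approx(0.3)

    def test_matches_triple_loop(self, rng):
        g, p = rng.random((3, 5, 5)), rng.random((3, 5, 5))
        expected = np.mean([abs(g[i, r, c] - p[i, r, c])
                            for i in range(3) for r in range(5) for c in range(5)])
        assert mk.l1_term(g, p) == pytest.approx(expected, abs=1e-12)


class TestDistillationTerm:
    def test_identical_logits_give_zero(self, rng):
        x = rng.random((2, 8, 8))
        for t in (0.5, 0.8, 1.0, 4.0):
            assert mk.distillation_term(x, x.copy(), temperature=t) == pytest.approx(0.0, abs=1e-9)

    def test_two_logit_toy_case(self):
        t = np.array([1.0, 0.0]).reshape(1, 1, 2)
        s = np.array([0.0, 1.0]).reshape(1, 1, 2)
        kl = mk.distillation_term(t, s, temperature=1.0)
        assert kl == pytest.approx(0.4621171573, abs=1e-6)
        assert kl == pytest.approx(brute_force_kl([1, 0], [0, 1], 1.0), abs=1e-9)

    def test_matches_brute_force_on_random_patch(self, rng):
        t = rng.standard_normal((2, 4, 4))
        s = rng.standard_normal((2, 4, 4))
        expected = np.mean([brute_force_kl(t[i].ravel(), s[i].ravel(), 0.8)
                            for i in range(2)])
        assert mk.distillation_term(t, s, temperature=0.8) == pytest.approx(expected, rel=1e-9)

    def test_strictly_decreasing_in_temperature(self, rng):
        t = rng.standard_normal((1, 6, 6))
        s = rng.standard_normal((1, 6, 6))
        values = [mk.distillation_term(t, s, temperature=T)
                  for T in (0.5, 1.0, 2.0, 8.0, 32.0)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 0.1 * values[0]   # approaches 0 as both soften

    def test_asymmetric_in_general(self, rng):
        t = rng.standard_normal((1, 4, 4))
        s = rng.standard_normal((1, 4, 4))
        assert mk.distillation_term(t, s) != pytest.approx(mk.distillation_term(s, t), abs=1e-6)

    def test_nonnegative(self, rng):
        for _ in range(5):
            t = rng.standard_normal((2, 5, 5))
            s = rng.standard_normal((2, 5, 5))
            assert mk.distillation_term(t, s) >= -1e-12

    def test_nonpositive_temperature_rejected(self, rng):
        x = rng.random((1, 4, 4))
        with pytest.raises(ValueError):
            mk.distillation_term(x, x, temperature=0.0)


class TestSSIMTerm:
    def test_zero_for_perfect_prediction(self, rng):
        g = rng.random((2, 16, 16))
        assert mk.ssim_term(g, g.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_equals_one_minus_batch_mean_ssim(self, rng):
        g = rng.random((3, 32, 32))
        p = np.clip(g + 0.1 * rng.standard_normal(g.shape), 0, 1)
        expected = 1.0 - np.mean([mk.ssim(g[i], p[i]) for i in range(3)])
        assert mk.ssim_term(g, p) == pytest.approx(expected, abs=1e-12)

    def test_plus_ssim_sign_switch(self, rng):
        g = rng.random((1, 16, 16))
        p = np.clip(g + 0.05 * rng.standard_normal(g.shape), 0, 1)
        dissim = mk.ssim_term(g, p)
        literal = mk.ssim_term(g, p, sign="plus_ssim")
        assert dissim == pytest.approx(1.0 - literal, abs=1e-12)


class TestTotalLoss:
    def test_breakdown_identity_holds(self, toy_batch):
        g, p_s, p_t = toy_batch
        w = mk.LossWeights()
        bd = mk.total_loss(g, p_s, p_t, w)
        recon = (bd.mse_term + w.alpha * bd.kd_term + w.beta * bd.ssim_term
                 + w.gamma_l1 * bd.l1_term) / bd.psnr_divisor
        assert bd.total == pytest.approx(recon, rel=1e-9)

    def test_terms_match_independent_oracles(self, toy_batch):
        """Each breakdown term equals its stand-alone metric computation."""
        g, p_s, p_t = toy_batch
        bd = mk.total_loss(g, p_s, p_t, mk.LossWeights(), peak=1.0)
        assert bd.mse_term == pytest.approx(
            np.mean([(gi - pi) ** 2 for gi, pi in zip(g, p_s)]).mean(), rel=1e-12)
        assert bd.l1_term == pytest.approx(mk.l1_term(g, p_s), rel=1e-12)
        assert bd.kd_term == pytest.approx(mk.distillation_term(p_t, p_s), rel=1e-9)
        assert bd.ssim_term == pytest.approx(mk.ssim_term(g, p_s), rel=1e-9)
        assert bd.psnr_divisor == pytest.approx(
            mk.psnr(np.stack(g), np.stack(p_s), peak=1.0), rel=1e-12)

    def test_hand_composed_example(self):
        """(0.01 + 0.3*0.1 + 1*0.05 + 1*0.08) / 20 = 0.0085."""
        total = (0.01 + 0.3 * 0.1 + 1.0 * 0.05 + 1.0 * 0.08) / 20.0
        assert total == pytest.approx(0.0085, abs=1e-15)
        # and the implementation reproduces the same composition rule
        bd = mk.LossBreakdown(mse_term=0.01, kd_term=0.1, ssim_term=0.05,
                              l1_term=0.08, psnr_divisor=20.0, total=total)
        w = mk.LossWeights(alpha=0.3, beta=1.0, gamma_l1=1.0)
        assert bd.total == pytest.approx(
            (bd.mse_term + w.alpha * bd.kd_term + w.beta * bd.ssim_term
             + w.gamma_l1 * bd.l1_term) / bd.psnr_divisor)

    def test_perfect_prediction_gives_zero_total(self, rng):
        g = rng.random((2, 16, 16))
        bd = mk.total_loss(g, g.copy(), g.copy(), mk.LossWeights())
        assert bd.total == 0.0
        assert bd.psnr_divisor == pytest.approx(1e-10)   # sentinel PSNR floored

    def test_monotone_in_mse_and_divisor(self, toy_batch):
        g, p_s, p_t = toy_batch
        w = mk.LossWeights()
        base = mk.total_loss(g, p_s, p_t, w)
        worse = mk.total_loss(g, np.clip(g + 2 * (p_s - g), -1, 2), p_t, w)
        assert worse.total > base.total                   # larger errors cost more
        bigger_peak = mk.total_loss(g, p_s, p_t, w, peak=4.0)
        assert bigger_peak.psnr_divisor > base.psnr_divisor
        assert bigger_peak.total < base.total             # larger divisor shrinks total

    def test_divisor_off_reproduces_weighted_sum(self, toy_batch):
        g, p_s, p_t = toy_batch
        w = mk.LossWeights(psnr_divisor=False)
        bd = mk.total_loss(g, p_s, p_t, w)
        assert bd.psnr_divisor == 1.0
        assert bd.total == pytest.approx(
            bd.mse_term + w.alpha * bd.kd_term + bd.ssim_term + bd.l1_term, rel=1e-9)

    def test_continuous_in_weights(self, toy_batch):
        g, p_s, p_t = toy_batch
        totals = [mk.total_loss(g, p_s, p_t, mk.LossWeights(alpha=a)).total
                  for a in np.linspace(0.0, 1.0, 7)]
        diffs = np.diff(totals)
        assert np.all(np.abs(diffs - diffs[0]) < 1e-6)    # affine in alpha

    def test_all_terms_nonnegative(self, toy_batch):
        g, p_s, p_t = toy_batch
        bd = mk.total_loss(g, p_s, p_t, mk.LossWeights())
        assert min(bd.mse_term, bd.kd_term, bd.ssim_term, bd.l1_term) >= 0.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mk.total_loss(rng.random((2, 8, 8)), rng.random((2, 8, 9)), None)


class TestTeacherLoss:
    def test_zero_for_perfect_teacher(self, rng):
        g = rng.random((2, 16, 16))
        assert mk.teacher_loss(g, g.copy()).total == 0.0

    def test_equals_total_loss_with_alpha_zero(self, toy_batch):
        g, p_s, _ = toy_batch
        a = mk.teacher_loss(g, p_s, mk.LossWeights())
        b = mk.total_loss(g, p_s, None, mk.LossWeights(alpha=0.0))
        assert a.total == pytest.approx(b.total, rel=1e-12)
        assert a.kd_term == 0.0

    def test_hand_composed_example_without_kd(self):
        assert (0.01 + 0.05 + 0.08) / 20.0 == pytest.approx(0.007)


class TestGradients:
    def test_numerator_gradient_matches_finite_differences(self, rng):
        """Analytic gradient of the loss numerator on a small patch batch."""
        g = rng.random((1, 12, 12))
        p0 = np.clip(g + 0.1 * rng.standard_normal(g.shape), 0.05, 0.95)
        w = mk.LossWeights(psnr_divisor=False)

        ps = Tensor(p0, requires_grad=True)
        bd = mk.total_loss(Tensor(g), ps, Tensor(np.clip(g + 0.02, 0, 1)), w)
        bd.graph.backward()
        analytic = ps.grad.copy()

        eps = 1e-6
        for idx in [(0, 3, 4), (0, 7, 7), (0, 11, 0)]:
            pp, pm = p0.copy(), p0.copy()
            pp[idx] += eps
            pm[idx] -= eps
            fp = mk.total_loss(g, pp, np.clip(g + 0.02, 0, 1), w).total
            fm = mk.total_loss(g, pm, np.clip(g + 0.02, 0, 1), w).total
            fd = (fp - fm) / (2 * eps)
            assert analytic[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_divisor_is_detached(self, rng):
        """No gradient flows through the PSNR divisor: scaling check."""
        g = rng.random((1, 12, 12))
        p0 = np.clip(g + 0.1 * rng.standard_normal(g.shape), 0.05, 0.95)
        w_off = mk.LossWeights(psnr_divisor=False)
        w_on = mk.LossWeights(psnr_divisor=True)

        ps1 = Tensor(p0, requires_grad=True)
        mk.total_loss(Tensor(g), ps1, None, w_off).graph.backward()
        ps2 = Tensor(p0, requires_grad=True)
        bd = mk.total_loss(Tensor(g), ps2, None, w_on)
        bd.graph.backward()
        # with a detached divisor the two gradients differ by exactly 1/PSNR
        np.testing.assert_allclose(ps2.grad, ps1.grad / bd.psnr_divisor, rtol=1e-9)
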
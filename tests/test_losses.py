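"""Training objectives vs independent brute-force scalar transcriptions.

The oracle functions below re-derive every objective with plain Python
loops and share no helper code with the implementations.
"""

import math

import numpy as np
import pytest

from virtualhic.losses import (
    LossConfig,
    chromhmm_focal_loss,
    hic_loss,
    hybrid_loss,
    surrogate_loss,
    weighted_correlation,
    weighted_lp_losses,
)

# ---------------------------------------------------------------------------
# scalar oracles (independent code path)


def oracle_lp(y_true, y_pred, w):
    l1 = l2 = 0.0
    for i in range(len(y_true)):
        for j in range(len(y_true[i])):
            d = y_true[i][j] - y_pred[i][j]
            l1 += w[i][j] * abs(d)
            l2 += w[i][j] * d * d
    return l1, l2


def oracle_weighted_corr(x, y, w):
    n, m = len(x), len(x[0])
    num = vx = vy = 0.0
    xbar = [sum(w[i][j] * x[i][j] for j in range(m))
            / sum(w[i][j] for j in range(m)) for i in range(n)]
    ybar = [sum(w[i][j] * y[i][j] for j in range(m))
            / sum(w[i][j] for j in range(m)) for i in range(n)]
    for i in range(n):
        for j in range(m):
            num += w[i][j] * (x[i][j] - xbar[i]) * (y[i][j] - ybar[i])
            vx += w[i][j] * (x[i][j] - xbar[i]) ** 2
            vy += w[i][j] * (y[i][j] - ybar[i]) ** 2
    return num / math.sqrt(vx * vy)


def oracle_stratified_corr(x, y, w):
    n, m = len(x), len(x[0])
    total_mass = 0.0
    acc = 0.0
    for j in range(m):
        mass = sum(w[i][j] for i in range(n))
        xbar = sum(w[i][j] * x[i][j] for i in range(n)) / mass
        ybar = sum(w[i][j] * y[i][j] for i in range(n)) / mass
        num = vx = vy = 0.0
        for i in range(n):
            num += w[i][j] * (x[i][j] - xbar) * (y[i][j] - ybar)
            vx += w[i][j] * (x[i][j] - xbar) ** 2
            vy += w[i][j] * (y[i][j] - ybar) ** 2
        r = num / math.sqrt(vx * vy) if vx > 0 and vy > 0 else 0.0
        acc += mass * r
        total_mass += mass
    return acc / total_mass


def oracle_hic(y_true, y_pred, w, cfg):
    n = len(y_true)
    lp = 0.0
    for i in range(n):
        l1 = sum(w[i][j] * abs(y_true[i][j] - y_pred[i][j])
                 for j in range(len(y_true[i])))
        l2 = sum(w[i][j] * (y_true[i][j] - y_pred[i][j]) ** 2
                 for j in range(len(y_true[i])))
        lp += cfg.w_l1 * l1 + (1 - cfg.w_l1) * l2
    lp /= n
    r = oracle_weighted_corr(y_true, y_pred, w)
    rd = oracle_stratified_corr(y_true, y_pred, w)
    return lp + cfg.w_lwcorr * (1 - r) + cfg.w_lwdcorr * (1 - rd)


def oracle_focal(y_true, y_pred, cfg):
    n = len(y_true)
    alpha = cfg.alpha_or_default(len(y_true[0][0]))
    acc = 0.0
    for i in range(n):
        for j in range(len(y_true[i])):
            for k in range(len(y_true[i][j])):
                p = min(max(y_pred[i][j][k], cfg.clip_delta),
                        1 - cfg.clip_delta)
                y = y_true[i][j][k]
                acc += alpha[k] * (1 - p) ** cfg.gamma * math.log(p) * y
                acc += p**cfg.gamma * math.log(1 - p) * (1 - y)
    return -acc / n


def oracle_surrogate(x, y, cfg):
    n = len(x)
    charb = 0.0
    for i in range(n):
        for j in range(n):
            charb += math.sqrt((x[i][j] - y[i][j]) ** 2
                               + cfg.eps_charbonnier**2)
    charb /= n * n
    acc = 0.0
    for d in range(4, 199):
        a = [x[i][i + d] for i in range(n - d)]
        b = [y[i][i + d] for i in range(n - d)]
        am, bm = sum(a) / len(a), sum(b) / len(b)
        cov = sum((u - am) * (v - bm) for u, v in zip(a, b)) / len(a)
        sa = math.sqrt(sum((u - am) ** 2 for u in a) / len(a))
        sb = math.sqrt(sum((v - bm) ** 2 for v in b) / len(b))
        acc += cov / (sa * sb + cfg.eps_corr)
    return charb + (1 - acc / 195)


# ---------------------------------------------------------------------------


class TestWeightedLp:
    def test_perfect_prediction_zero(self, rng):
        y = rng.normal(size=(3, 100))
        assert weighted_lp_losses(y, y, np.ones_like(y)) == (0.0, 0.0)

    def test_hand_value_single_entry(self):
        # w=2, delta=3 -> L1 = 2*3 = 6, L2 = 2*9 = 18
        l1, l2 = weighted_lp_losses([[4.0]], [[1.0]], [[2.0]])
        assert (l1, l2) == (6.0, 18.0)

    def test_linear_in_weights(self, rng):
        y, p = rng.normal(size=(4, 50)), rng.normal(size=(4, 50))
        w = rng.uniform(0.1, 1, size=(4, 50))
        l1, l2 = weighted_lp_losses(y, p, w)
        l1d, l2d = weighted_lp_losses(y, p, 2 * w)
        assert l1d == pytest.approx(2 * l1) and l2d == pytest.approx(2 * l2)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            weighted_lp_losses(np.ones((2, 5)), np.ones((2, 6)))


class TestWeightedCorrelation:
    @pytest.mark.parametrize("stratified", [False, True])
    def test_perfect_is_one(self, rng, stratified):
        y = rng.normal(size=(5, 100))
        w = rng.uniform(0.5, 2, size=(5, 100))
        assert weighted_correlation(y, y, w, stratified) == pytest.approx(1.0)

    def test_antisymmetric_is_minus_one(self, rng):
        y = rng.normal(size=(4, 60))
        y -= y.mean(axis=1, keepdims=True)
        assert weighted_correlation(y, -y) == pytest.approx(-1.0)

    def test_three_point_toy_matches_formula(self):
        x, y, w = [[1.0, 2.0, 3.0]], [[1.0, 2.0, 4.0]], [[1.0, 1.0, 2.0]]
        expected = oracle_weighted_corr(x, y, w)
        assert weighted_correlation(x, y, w) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_zero_variance_contributes_zero_with_warning(self):
        with pytest.warns(UserWarning):
            r = weighted_correlation([[1.0, 1.0, 1.0]], [[1.0, 2.0, 3.0]])
        assert r == 0.0


class TestHicLoss:
    def test_perfect_prediction_zero(self, rng):
        y = rng.normal(size=(4, 100))
        w = rng.uniform(0.5, 2, size=(4, 100))
        assert hic_loss(y, y, w) == pytest.approx(0.0, abs=1e-9)

    def test_correlation_terms_isolated(self, rng):
        y, p = rng.normal(size=(4, 100)), rng.normal(size=(4, 100))
        w = rng.uniform(0.5, 2, size=(4, 100))
        cfg = LossConfig(w_lwcorr=0.0, w_lwdcorr=0.0)
        l1, l2 = None, None
        delta = y - p
        l1_i = (w * np.abs(delta)).sum(axis=1)
        l2_i = (w * delta**2).sum(axis=1)
        expected = float((cfg.w_l1 * l1_i + 0.9 * l2_i).mean())
        assert hic_loss(y, p, w, cfg) == pytest.approx(expected, rel=1e-12)

    def test_noise_increases_expected_loss(self, rng):
        y = rng.normal(size=(8, 100))
        w = np.ones_like(y)
        sigmas = [0.1, 0.5, 1.0]
        means = []
        for s in sigmas:
            vals = [
                hic_loss(y, y + rng.normal(0, s, y.shape), w)
                for _ in range(100)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestFocalLoss:
    def test_confident_correct_near_zero(self):
        cfg = LossConfig()
        y = np.ones((1, 1, 13))
        p = np.full((1, 1, 13), 1 - cfg.clip_delta)
        val = chromhmm_focal_loss(y, p, cfg)
        assert 0 <= val <= 13 * cfg.gamma * cfg.clip_delta

    def test_hand_value_half_probability(self):
        # alpha=1, gamma=3.5, y=1, p=0.5 -> 2^-3.5 * ln 2
        cfg = LossConfig(alpha=np.ones(1))
        val = chromhmm_focal_loss(
            np.ones((1, 1, 1)), np.full((1, 1, 1), 0.5), cfg
        )
        assert val == pytest.approx(2**-3.5 * math.log(2), rel=1e-12)

    def test_gamma_zero_reduces_to_bce(self, rng):
        y = (rng.random((3, 10, 13)) < 0.3).astype(float)
        p = rng.uniform(0.05, 0.95, size=(3, 10, 13))
        cfg = LossConfig(gamma=0.0, alpha=np.ones(13))
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum() / 3
        assert chromhmm_focal_loss(y, p, cfg) == pytest.approx(bce, abs=1e-9)

    def test_non_binary_targets_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            chromhmm_focal_loss(
                np.full((1, 2, 13), 0.5), np.full((1, 2, 13), 0.5)
            )


class TestHybridLoss:
    def test_additivity(self, rng):
        y, p = rng.normal(size=(3, 100)), rng.normal(size=(3, 100))
        w = rng.uniform(0.5, 2, size=(3, 100))
        st = (rng.random((3, 100, 13)) < 0.2).astype(float)
        sp = rng.uniform(0.05, 0.95, size=(3, 100, 13))
        total = hybrid_loss(y, p, w, st, sp)
        parts = hic_loss(y, p, w) + chromhmm_focal_loss(st, sp)
        assert total == pytest.approx(parts, abs=1e-12)

    def test_both_zero_components(self, rng):
        y = rng.normal(size=(2, 100))
        w = np.ones_like(y)
        st = np.ones((2, 100, 13))
        cfg = LossConfig(clip_delta=1e-12)
        val = hybrid_loss(y, y, w, st, st, cfg)
        assert val == pytest.approx(0.0, abs=1e-6)


class TestSurrogate:
    def test_perfect_prediction_near_epsilon(self, rng):
        x = rng.normal(size=(210, 210)) * 10  # variance >> eps
        total = surrogate_loss(x, x)
        assert total == pytest.approx(1e-3, abs=1e-4)

    def test_diagonal_count_is_195(self):
        assert 198 - 4 + 1 == 195  # the range the loss averages over
        # and the implementation rejects tiles that cannot form diagonal 198
        with pytest.raises(ValueError, match="198"):
            surrogate_loss(np.zeros((150, 150)), np.zeros((150, 150)))

    def test_constant_shift_leaves_diag_term(self, rng):
        x = rng.normal(size=(205, 205))
        cfg = LossConfig()
        base = surrogate_loss(x, x, cfg)
        shifted = surrogate_loss(x, x + 5.0, cfg)
        # correlation is shift invariant; only the Charbonnier term moves
        diag_base = base - np.sqrt(0 + cfg.eps_charbonnier**2)
        diag_shift = shifted - np.sqrt(25 + cfg.eps_charbonnier**2)
        assert diag_shift == pytest.approx(diag_base, abs=1e-9)


class TestOracleEquivalence:
    """Vectorized implementations match brute-force transcriptions."""

    def test_fifty_random_instances(self, rng):
        cfg = LossConfig(alpha=rng.uniform(0.5, 2, size=4))
        for _ in range(50):
            y = rng.normal(size=(3, 7)).tolist()
            p = rng.normal(size=(3, 7)).tolist()
            w = rng.uniform(0.2, 2, size=(3, 7)).tolist()
            assert hic_loss(y, p, w, cfg) == pytest.approx(
                oracle_hic(y, p, w, cfg), abs=1e-9
            )
            st = (rng.random((3, 7, 4)) < 0.3).astype(float).tolist()
            sp = rng.uniform(0.02, 0.98, size=(3, 7, 4)).tolist()
            assert chromhmm_focal_loss(st, sp, cfg) == pytest.approx(
                oracle_focal(st, sp, cfg), abs=1e-9
            )

    def test_surrogate_oracle(self, rng):
        cfg = LossConfig()
        for _ in range(3):
            x = rng.normal(size=(200, 200))
            y = x + 0.2 * rng.normal(size=(200, 200))
            assert surrogate_loss(x, y, cfg) == pytest.approx(
                oracle_surrogate(x.tolist(), y.tolist(), cfg), abs=1e-9
            )

    def test_losses_finite_and_bounded(self, rng):
        y, p = rng.normal(size=(4, 50)), 100 * rng.normal(size=(4, 50))
        w = rng.uniform(0, 3, size=(4, 50))
        assert np.isfinite(hic_loss(y, p, w))
        r = weighted_correlation(y, p, w)
        assert -1 <= r <= 1
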
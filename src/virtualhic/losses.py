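"""Training objectives for the contact-diagonal predictor and tile denoiser.

The predictor's hybrid objective is the sum of a Hi-C regression loss and a
multi-label chromatin-state classification loss. The Hi-C part mixes
distance-weighted L1/L2 terms with two correlation penalties:

    HiCLoss = (1/N) Σ_i [W_l1·L1_i + (1−W_l1)·L2_i]
              + W_lwcorr·(1 − weighted_corr)
              + W_lwdcorr·(1 − weighted_dist_corr)

with per-sample sums L1_i = Σ_j w_ij |Δ_ij| and L2_i = Σ_j w_ij Δ_ij².
``weighted_corr`` is a single weighted Pearson coefficient over the batch
with per-sample weighted means; ``weighted_dist_corr`` stratifies by
genomic separation: each offset j is correlated across the batch and the
per-offset coefficients are averaged with their weight mass. The state loss
is a per-label focal loss with class-balance weights α and focusing
parameter γ.

The denoiser surrogate objective is a Charbonnier term plus a diagonal
correlation term averaging Pearson over matrix diagonals 4..198 (195
diagonals) with an ε-stabilized denominator.

These are the forward-only reference implementations used for evaluation
and for verifying the differentiable versions in :mod:`virtualhic.nn`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "weighted_lp_losses",
    "weighted_correlation",
    "hic_loss",
    "chromhmm_focal_loss",
    "hybrid_loss",
    "surrogate_loss",
]


@dataclass
class LossConfig:
    """Objective constants.

    ``w_l1`` balances L1 vs L2 (0.1), ``w_lwcorr`` weights the batch
    correlation penalty (5), ``w_lwdcorr`` the distance-stratified one
    (100). ``gamma`` is the focal focusing parameter (3.5); ``alpha`` the
    per-state balance vector (inverse genome-wide state frequency, see
    :func:`virtualhic.states.alpha_weights`; defaults to uniform).
    ``eps_charbonnier``/``eps_corr`` stabilize the
    denoiser loss (both 1e-3); ``clip_delta`` bounds predicted
    probabilities away from {0, 1} before the logs in the focal loss.
    """

    w_l1: float = 0.1
    w_lwcorr: float = 5.0
    w_lwdcorr: float = 100.0
    gamma: float = 3.5
    alpha: np.ndarray | None = None
    eps_charbonnier: float = 1e-3
    eps_corr: float = 1e-3
    clip_delta: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("w_l1", "w_lwcorr", "w_lwdcorr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.clip_delta < 0.5):
            raise ValueError("clip_delta must be in (0, 0.5)")
        if self.alpha is not None:
            self.alpha = np.asarray(self.alpha, dtype=float)

    def alpha_or_default(self, n_states: int) -> np.ndarray:
        if self.alpha is None:
            return np.ones(n_states)
        if self.alpha.shape != (n_states,):
            raise ValueError(
                f"alpha length {self.alpha.shape} != n_states {n_states}"
            )
        return self.alpha


def _check_shapes(y_true, y_pred, weights=None):
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    if weights is None:
        weights = np.ones_like(y_true)
    else:
        weights = np.atleast_2d(np.asarray(weights, dtype=float))
        if weights.shape != y_true.shape:
            raise ValueError("weights shape mismatch")
        if not np.isfinite(weights).all() or (weights < 0).any():
            raise ValueError("weights must be finite and >= 0")
    return y_true, y_pred, weights


def weighted_lp_losses(y_true, y_pred, weights=None) -> tuple[float, float]:
    """Distance-weighted L1 and L2 sums over the whole batch.

    Returns (Σ_ij w|Δ|, Σ_ij wΔ²) — sums, not means.
    """
    y_true, y_pred, w = _check_shapes(y_true, y_pred, weights)
    delta = y_true - y_pred
    return float((w * np.abs(delta)).sum()), float((w * delta**2).sum())


def weighted_correlation(
    y_true, y_pred, weights=None, stratified: bool = False
) -> float:
    """Weighted Pearson correlation of a batch of diagonals.

    ``stratified=False``: a single coefficient over the batch using
    per-sample weighted means. ``stratified=True``: one coefficient per
    offset (values sharing a genomic separation, correlated across the
    batch), averaged with per-offset weight mass. Zero-variance units
    contribute 0 with a warning.
    """
    x, y, w = _check_shapes(y_true, y_pred, weights)
    if stratified:
        wsum = w.sum(axis=0)
        ok = wsum > 0
        xm = np.where(ok, (w * x).sum(axis=0) / np.where(ok, wsum, 1), 0.0)
        ym = np.where(ok, (w * y).sum(axis=0) / np.where(ok, wsum, 1), 0.0)
        dx, dy = x - xm, y - ym
        num = (w * dx * dy).sum(axis=0)
        vx = (w * dx**2).sum(axis=0)
        vy = (w * dy**2).sum(axis=0)
        denom = np.sqrt(vx * vy)
        good = ok & (denom > 0)
        if not good.all():
            warnings.warn(
                f"{int((~good).sum())} zero-variance offset strata "
                "contribute correlation 0", stacklevel=2,
            )
        r_j = np.where(good, num / np.where(good, denom, 1), 0.0)
        total = wsum.sum()
        return float((wsum * r_j).sum() / total) if total > 0 else 0.0
    wsum_i = w.sum(axis=1, keepdims=True)
    xm = np.where(wsum_i > 0, (w * x).sum(axis=1, keepdims=True)
                  / np.where(wsum_i > 0, wsum_i, 1), 0.0)
    ym = np.where(wsum_i > 0, (w * y).sum(axis=1, keepdims=True)
                  / np.where(wsum_i > 0, wsum_i, 1), 0.0)
    dx, dy = x - xm, y - ym
    num = (w * dx * dy).sum()
    denom = np.sqrt((w * dx**2).sum() * (w * dy**2).sum())
    if denom == 0:
        warnings.warn("zero weighted variance; correlation defined as 0",
                      stacklevel=2)
        return 0.0
    return float(num / denom)


def hic_loss(y_true, y_pred, weights=None, cfg: LossConfig | None = None) -> float:
    """The full Hi-C regression objective (weighted Lp mixture plus the two
    correlation penalties)."""
    cfg = cfg or LossConfig()
    y_true, y_pred, w = _check_shapes(y_true, y_pred, weights)
    n = y_true.shape[0]
    delta = y_true - y_pred
    l1_i = (w * np.abs(delta)).sum(axis=1)
    l2_i = (w * delta**2).sum(axis=1)
    lp = float((cfg.w_l1 * l1_i + (1 - cfg.w_l1) * l2_i).sum() / n)
    r = weighted_correlation(y_true, y_pred, w, stratified=False)
    r_dist = weighted_correlation(y_true, y_pred, w, stratified=True)
    return lp + cfg.w_lwcorr * (1 - r) + cfg.w_lwdcorr * (1 - r_dist)


def chromhmm_focal_loss(
    y_true, y_pred, cfg: LossConfig | None = None
) -> float:
    """Per-label focal loss for the multi-label state head.

    ``y_true``: (N, P, K) binary; ``y_pred``: same shape in (0, 1). α
    multiplies the positive term only; predictions are clipped to
    [clip_delta, 1−clip_delta] before the logs. Normalized by N (the batch
    size), matching the printed objective.
    """
    cfg = cfg or LossConfig()
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    if y_true.ndim == 2:
        y_true = y_true[None]
        y_pred = y_pred[None]
    if not np.isin(y_true, (0.0, 1.0)).all():
        raise ValueError("y_true must be binary")
    n, _, k = y_true.shape
    alpha = cfg.alpha_or_default(k)
    p = np.clip(y_pred, cfg.clip_delta, 1 - cfg.clip_delta)
    pos = alpha * (1 - p) ** cfg.gamma * np.log(p) * y_true
    neg = p**cfg.gamma * np.log(1 - p) * (1 - y_true)
    return float(-(pos + neg).sum() / n)


def hybrid_loss(
    y_true, y_pred, weights, states_true, states_pred,
    cfg: LossConfig | None = None,
) -> float:
    """Total objective: Hi-C loss + chromatin-state focal loss."""
    cfg = cfg or LossConfig()
    return hic_loss(y_true, y_pred, weights, cfg) + chromhmm_focal_loss(
        states_true, states_pred, cfg
    )


def matrix_diagonal(m: np.ndarray, offset: int) -> np.ndarray:
    return np.diagonal(m, offset=offset)


def surrogate_loss(
    y_true_tile: np.ndarray,
    y_pred_tile: np.ndarray,
    cfg: LossConfig | None = None,
    diag_range: tuple[int, int] = (4, 198),
) -> float:
    """Denoiser objective: Charbonnier + diagonal-correlation terms.

    The correlation term averages, over matrix diagonals 4..198 (195 of
    them), 1 − cov/(σ_true·σ_pred + ε) with population moments.
    """
    cfg = cfg or LossConfig()
    x = np.asarray(y_true_tile, dtype=float)
    y = np.asarray(y_pred_tile, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError("tiles must be equal square matrices")
    lo, hi = diag_range
    if x.shape[0] <= hi:
        raise ValueError(
            f"tile side {x.shape[0]} cannot form diagonal {hi}"
        )
    charb = float(
        np.sqrt((x - y) ** 2 + cfg.eps_charbonnier**2).mean()
    )
    acc = 0.0
    n_diag = hi - lo + 1
    for d in range(lo, hi + 1):
        a = matrix_diagonal(x, d)
        b = matrix_diagonal(y, d)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        acc += cov / (a.std() * b.std() + cfg.eps_corr)
    diag_term = 1.0 - acc / n_diag
    return charb + diag_term
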
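"""Differentiable (Tensor) versions of the training objectives.

These mirror :mod:`virtualhic.losses` term for term; a test asserts the two
code paths agree to 1e-9 so the numpy implementations serve as the frozen
reference for these differentiable ones.
"""

from __future__ import annotations

import numpy as np

from ..losses import LossConfig
from .autograd import Tensor

__all__ = ["hic_loss_t", "focal_loss_t", "hybrid_loss_t", "surrogate_loss_t"]


def _abs(x: Tensor) -> Tensor:
    return x.relu() + (-x).relu()


def hic_loss_t(
    y_true: np.ndarray, y_pred: Tensor, weights: np.ndarray,
    cfg: LossConfig,
) -> Tensor:
    """Weighted L1/L2 mixture plus the two correlation penalties."""
    dt = y_pred.data.dtype
    x = np.asarray(y_true, dtype=dt)
    w = np.asarray(weights, dtype=dt)
    n, m = x.shape
    delta = y_pred - x
    l1_i = (Tensor(w) * _abs(delta)).sum(axis=1)
    l2_i = (Tensor(w) * delta * delta).sum(axis=1)
    lp = (l1_i * cfg.w_l1 + l2_i * (1 - cfg.w_l1)).sum() * (1.0 / n)

    # batch weighted Pearson with per-sample weighted means
    wsum_i = w.sum(axis=1, keepdims=True)
    xm = (w * x).sum(axis=1, keepdims=True) / wsum_i
    ym = (Tensor(w) * y_pred).sum(axis=1, keepdims=True) / Tensor(wsum_i)
    dx = Tensor(x - xm)
    dy = y_pred - ym
    num = (Tensor(w) * dx * dy).sum()
    den = (
        (Tensor(w) * dx * dx).sum() * (Tensor(w) * dy * dy).sum()
    ).sqrt()
    r = num / den

    # distance-stratified: per-offset correlation across the batch
    wsum_j = w.sum(axis=0, keepdims=True)
    xmj = (w * x).sum(axis=0, keepdims=True) / wsum_j
    ymj = (Tensor(w) * y_pred).sum(axis=0, keepdims=True) / Tensor(wsum_j)
    dxj = Tensor(x - xmj)
    dyj = y_pred - ymj
    numj = (Tensor(w) * dxj * dyj).sum(axis=0)
    denj = (
        (Tensor(w) * dxj * dxj).sum(axis=0)
        * (Tensor(w) * dyj * dyj).sum(axis=0)
    ).sqrt()
    r_j = numj / denj
    r_dist = (Tensor(wsum_j[0]) * r_j).sum() * (1.0 / wsum_j.sum())

    return lp + (1 - r) * cfg.w_lwcorr + (1 - r_dist) * cfg.w_lwdcorr


def focal_loss_t(
    states_true: np.ndarray, states_pred: Tensor, cfg: LossConfig
) -> Tensor:
    """Per-label focal loss; ``states_pred`` holds probabilities in (0,1)."""
    dt = states_pred.data.dtype
    y = np.asarray(states_true, dtype=dt)
    if y.ndim == 2:
        y = y[None]
    n, _, k = y.shape
    alpha = cfg.alpha_or_default(k).astype(dt)
    p = states_pred.clip(cfg.clip_delta, 1 - cfg.clip_delta)
    pos = Tensor(alpha * y) * (1 - p) ** cfg.gamma * p.log()
    neg = Tensor(1 - y) * p**cfg.gamma * (1 - p).log()
    return -(pos + neg).sum() * (1.0 / n)


def hybrid_loss_t(
    y_true: np.ndarray, y_pred: Tensor, weights: np.ndarray,
    states_true: np.ndarray, states_pred: Tensor, cfg: LossConfig,
) -> Tensor:
    return hic_loss_t(y_true, y_pred, weights, cfg) + focal_loss_t(
        states_true, states_pred, cfg
    )


def surrogate_loss_t(
    tiles_true: np.ndarray, tiles_pred: Tensor,
    cfg: LossConfig, diag_range: tuple[int, int] = (4, 198),
) -> Tensor:
    """Charbonnier + diagonal-correlation objective over a batch of tiles."""
    x = np.asarray(tiles_true, dtype=tiles_pred.data.dtype)
    if x.ndim == 2:
        x = x[None]
        tiles_pred = tiles_pred.reshape(1, *tiles_pred.shape)
    b, n, _ = x.shape
    lo, hi = diag_range
    if n <= hi:
        raise ValueError(f"tile side {n} cannot form diagonal {hi}")
    delta = tiles_pred - x
    charb = ((delta * delta + cfg.eps_charbonnier**2) ** 0.5).mean()
    acc = None
    for d in range(lo, hi + 1):
        rows = np.arange(n - d)
        a = x[:, rows, rows + d]
        p = tiles_pred[(slice(None), rows, rows + d)]
        am = a.mean(axis=1, keepdims=True)
        pm = p.mean(axis=1, keepdims=True)
        dp = p - pm
        cov = (Tensor(a - am) * dp).mean(axis=1)
        # tiny floor keeps the sqrt differentiable on exactly-constant
        # diagonals (e.g. masked separations zero-filled in both tiles)
        std_p = ((dp * dp).mean(axis=1) + 1e-12) ** 0.5
        term = cov / (std_p * a.std(axis=1) + cfg.eps_corr)
        acc = term if acc is None else acc + term
    diag_term = 1 - acc.sum() * (1.0 / (b * (hi - lo + 1)))
    return charb + diag_term
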
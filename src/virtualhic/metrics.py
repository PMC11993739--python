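"""Contact-map evaluation metrics and comparison-harness transforms.

Predicted and ground-truth maps are compared over the jointly valid entries
of the upper triangle with: Pearson r, Spearman ρ (average ranks), a
distance-stratified correlation (one Pearson per diagonal), the
observed/expected correlation (each matrix divided by its per-distance mean
before correlating), and a single-window SSIM. Two harness transforms are
included: per-diagonal z-normalization (which puts matrices from
heterogeneous sources on the same distance-stratified scale) and a
percentile-rank partition that buckets scored 1-Mb regions into quartile
bands labeled PR99/PR75/PR50/PR25 from the top down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import ContactMap

__all__ = [
    "MetricReport",
    "matrix_correlations",
    "distance_stratified_correlation",
    "expected_profile",
    "oe_correlation",
    "ssim",
    "distance_stratified_normalize",
    "percentile_rank_partition",
    "evaluate_maps",
]


@dataclass
class MetricReport:
    pearson: float
    spearman: float
    distance_stratified: dict[int, float] = field(default_factory=dict)
    oe_correlation: float = np.nan
    ssim: float = np.nan
    n_valid_entries: int = 0

    def mean_distance_stratified(self) -> float:
        vals = list(self.distance_stratified.values())
        return float(np.mean(vals)) if vals else np.nan

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "spearman": self.spearman,
            "mean_distance_stratified": self.mean_distance_stratified(),
            "oe_correlation": self.oe_correlation,
            "ssim": self.ssim,
            "n_valid_entries": self.n_valid_entries,
        }


def _as_matrix(x) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, ContactMap):
        return x.values, x.mask
    x = np.asarray(x, dtype=float)
    return x, np.isfinite(x)


def _joint_upper(X, Y) -> tuple[np.ndarray, np.ndarray]:
    xv, xm = _as_matrix(X)
    yv, ym = _as_matrix(Y)
    if xv.shape != yv.shape:
        raise ValueError(f"shape mismatch {xv.shape} vs {yv.shape}")
    iu, ju = np.triu_indices(xv.shape[0])
    ok = (xm & ym)[iu, ju]
    return xv[iu, ju][ok], yv[iu, ju][ok]


def matrix_correlations(X, Y) -> tuple[float, float]:
    """Pearson and Spearman over jointly valid upper-triangle entries."""
    a, b = _joint_upper(X, Y)
    if a.size < 3:
        raise ValueError(
            f"only {a.size} jointly valid entries; correlations undefined"
        )
    pearson = float(stats.pearsonr(a, b).statistic)
    spearman = float(stats.spearmanr(a, b).statistic)
    return pearson, spearman


def distance_stratified_correlation(
    X, Y, d_range: tuple[int, int] | None = None
) -> dict[int, float]:
    """Pearson per diagonal offset d; degenerate diagonals omitted."""
    xv, xm = _as_matrix(X)
    yv, ym = _as_matrix(Y)
    if xv.shape != yv.shape:
        raise ValueError("shape mismatch")
    n = xv.shape[0]
    lo, hi = d_range if d_range is not None else (1, n - 1)
    out: dict[int, float] = {}
    skipped = []
    for d in range(lo, min(hi, n - 1) + 1):
        a = np.diagonal(xv, d)
        b = np.diagonal(yv, d)
        ok = np.diagonal(xm, d) & np.diagonal(ym, d)
        a, b = a[ok], b[ok]
        if a.size < 3 or a.std() == 0 or b.std() == 0:
            skipped.append(d)
            continue
        out[d] = float(stats.pearsonr(a, b).statistic)
    if skipped:
        warnings.warn(
            f"{len(skipped)} degenerate diagonals omitted from the "
            "distance-stratified correlation", stacklevel=2,
        )
    return out


def expected_profile(X) -> np.ndarray:
    """Per-distance mean contact over valid entries (the expected value at
    each genomic separation)."""
    xv, xm = _as_matrix(X)
    n = xv.shape[0]
    out = np.full(n, np.nan)
    for d in range(n):
        a = np.diagonal(xv, d)
        ok = np.diagonal(xm, d)
        if ok.any():
            out[d] = a[ok].mean()
    return out


def oe_matrix(X) -> np.ndarray:
    """Observed/expected transform; entries with zero expected are NaN."""
    xv, xm = _as_matrix(X)
    n = xv.shape[0]
    exp = expected_profile(X)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    denom = exp[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(xm & (denom != 0) & np.isfinite(denom), xv / denom, np.nan)
    if np.any(denom == 0):
        warnings.warn("zero expected value at some distances; entries masked",
                      stacklevel=2)
    return oe


def oe_correlation(X, Y, d_range: tuple[int, int] | None = None):
    """O/E matrices of both inputs and the Pearson correlation of their
    jointly valid upper-triangle entries (optionally restricted to a
    diagonal range)."""
    oe_x = oe_matrix(X)
    oe_y = oe_matrix(Y)
    n = oe_x.shape[0]
    iu, ju = np.triu_indices(n)
    if d_range is not None:
        lo, hi = d_range
        keep = (ju - iu >= lo) & (ju - iu <= hi)
        iu, ju = iu[keep], ju[keep]
    a, b = oe_x[iu, ju], oe_y[iu, ju]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        raise ValueError("O/E correlation undefined (degenerate entries)")
    r = float(stats.pearsonr(a, b).statistic)
    return oe_x, oe_y, r


def ssim(X, Y, c1: float | None = None, c2: float | None = None,
         mode: str = "global") -> float:
    """Structural similarity of two contact matrices.

    ``mode="global"`` follows the single-window definition: means,
    variances and covariance over all jointly valid entries, with
    C1=(0.01·L)² and C2=(0.03·L)² where L is the joint observed data range.
    ``mode="windowed"`` delegates to scikit-image's sliding-window SSIM
    (a different estimator; provided for comparability with image
    libraries).
    """
    xv, xm = _as_matrix(X)
    yv, ym = _as_matrix(Y)
    if xv.shape != yv.shape:
        raise ValueError("shape mismatch")
    ok = xm & ym
    if not ok.any():
        raise ValueError("no jointly valid entries")
    a, b = xv[ok], yv[ok]
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    data_range = max(hi - lo, 1e-12)
    if mode == "windowed":
        from skimage.metrics import structural_similarity

        return float(
            structural_similarity(
                np.where(ok, xv, 0.0), np.where(ok, yv, 0.0),
                data_range=data_range,
            )
        )
    if mode != "global":
        raise ValueError(f"unknown SSIM mode {mode!r}")
    if c1 is None:
        c1 = (0.01 * data_range) ** 2
    if c2 is None:
        c2 = (0.03 * data_range) ** 2
    mu_x, mu_y = a.mean(), b.mean()
    var_x, var_y = a.var(), b.var()
    cov = np.mean((a - mu_x) * (b - mu_y))
    return float(
        (2 * mu_x * mu_y + c1) * (2 * cov + c2)
        / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


def distance_stratified_normalize(m: np.ndarray) -> np.ndarray:
    """Per-diagonal z-normalization: each diagonal is replaced by
    (x − mean)/sd of its valid entries; zero-sd diagonals map to 0.
    NaN entries stay NaN."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("square matrix required")
    n = m.shape[0]
    out = np.full_like(m, np.nan)
    for d in range(-(n - 1), n):
        idx = np.arange(max(0, -d), min(n, n - d))
        rows, cols = idx, idx + d
        vals = m[rows, cols]
        ok = np.isfinite(vals)
        if not ok.any():
            continue
        mu = vals[ok].mean()
        sd = vals[ok].std()
        # guard against constant diagonals whose std is pure rounding noise
        degenerate = sd <= 1e-12 * max(1.0, abs(mu))
        z = np.where(ok, 0.0 if degenerate else (vals - mu) / sd, np.nan)
        out[rows, cols] = z
    return out


_PR_LABELS = ("PR99", "PR75", "PR50", "PR25")


def percentile_rank_partition(
    regions: Sequence, scores: Sequence[float]
) -> dict[str, list]:
    """Bucket scored regions into quartile bands by score.

    PR99 holds the top quartile, PR75 the next, then PR50, then PR25.
    Ties at a cut-point fall into the lower band; identical scores for all
    regions collapse into a single bucket with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    regions = list(regions)
    if len(regions) != scores.size:
        raise ValueError("regions/scores length mismatch")
    if len(regions) < 4:
        raise ValueError("need at least 4 regions to form quartile bands")
    if np.ptp(scores) == 0:
        warnings.warn("all region scores equal; single degenerate bucket",
                      stacklevel=2)
        return {"PR25": regions, "PR50": [], "PR75": [], "PR99": []}
    q25, q50, q75 = np.quantile(scores, [0.25, 0.50, 0.75])
    out: dict[str, list] = {k: [] for k in _PR_LABELS}
    for region, s in zip(regions, scores):
        if s > q75:
            out["PR99"].append(region)
        elif s > q50:
            out["PR75"].append(region)
        elif s > q25:
            out["PR50"].append(region)
        else:
            out["PR25"].append(region)
    return out


def evaluate_maps(
    truth, pred, d_range: tuple[int, int] | None = None
) -> MetricReport:
    """Full metric suite for one (truth, prediction) pair."""
    pearson, spearman = matrix_correlations(truth, pred)
    dsc = distance_stratified_correlation(truth, pred, d_range)
    try:
        _, _, r_oe = oe_correlation(truth, pred, d_range)
    except ValueError:
        r_oe = np.nan
    a, _ = _joint_upper(truth, pred)
    return MetricReport(
        pearson=pearson,
        spearman=spearman,
        distance_stratified=dsc,
        oe_correlation=r_oe,
        ssim=ssim(truth, pred),
        n_valid_entries=int(a.size),
    )
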
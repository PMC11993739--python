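"""Downstream chromatin-structure analytics.

Includes virtual-4C promoter hubness, the ±15-bin interaction change score
with its permutation-test enrichment machinery, active-enhancer importance
counting, the interaction-quartile/enhancer association, the tissue
dendrogram over per-region L1 features, gene ranking by structural change,
and coordinated in-silico perturbation editing of sequence and tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .coords import GenomicRegion
from .io_formats import AnnotationTable, ContactMap, OneHotSequence, TrackSet
from .interpretation import GeneScoreTable
from .states import ACTIVE_ENHANCER_STATE, MultiLabelStates

__all__ = [
    "ChangeScoreTrack",
    "PerturbationSpec",
    "promoter_hubness",
    "interaction_change_score",
    "region_permutation_test",
    "enhancer_importance",
    "quantile_association",
    "hic_dendrogram",
    "linkage_to_newick",
    "rank_genes_by_change",
    "apply_perturbation",
]

CHANGE_WINDOW = 15
CHANGE_THRESHOLD = 3.0
CHANGE_EXCLUDED = (-1, 0, 1)
MAX_CHANGE_SCORE = 28  # 31 offsets in ±15 minus the excluded ±1/0 vicinity


@dataclass
class ChangeScoreTrack:
    """Integer interaction-change scores per 5-kb bin (0..28)."""

    region: GenomicRegion
    bin_size: int
    scores: np.ndarray
    window: int = CHANGE_WINDOW
    threshold: float = CHANGE_THRESHOLD
    max_possible: int = MAX_CHANGE_SCORE

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.min(initial=0) < 0 or self.scores.max(initial=0) > self.max_possible:
            raise ValueError("change scores outside [0, max_possible]")


def promoter_hubness(
    cmap: ContactMap,
    promoters: AnnotationTable,
    flank: int = 250_000,
    mode: str = "mean",
    threshold: float | None = None,
) -> GeneScoreTable:
    """Virtual-4C hubness per promoter.

    ``mode="mean"``: mean contact value between the promoter bin and every
    valid bin within ±flank. ``mode="count"``: number of such bins whose
    contact exceeds ``threshold``. Windows truncated at the map edge emit a
    warning.
    """
    if mode not in {"mean", "count"}:
        raise ValueError(f"unknown hubness mode {mode!r}")
    if mode == "count" and threshold is None:
        raise ValueError("count mode requires a threshold")
    bs = cmap.bin_size
    half = flank // bs
    reg = cmap.region
    rows = []
    for rec in promoters.records.itertuples():
        if rec.chrom != reg.chrom or not (
            reg.start <= rec.start < reg.end
        ):
            warnings.warn(f"promoter {rec.label} outside map; skipped",
                          stacklevel=2)
            continue
        p = (int(rec.start) - reg.start) // bs
        lo, hi = p - half, p + half + 1
        if lo < 0 or hi > cmap.side:
            warnings.warn(
                f"promoter {rec.label} within {flank} bp of the map edge; "
                "window truncated", stacklevel=2,
            )
            lo, hi = max(lo, 0), min(hi, cmap.side)
        row = cmap.values[p, lo:hi]
        ok = cmap.mask[p, lo:hi]
        vals = row[ok]
        if mode == "mean":
            score = float(vals.mean()) if vals.size else np.nan
        else:
            score = int((vals > threshold).sum())
        rows.append((rec.label, rec.chrom, int(rec.start), int(rec.end), score))
    return GeneScoreTable(
        pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "score"]),
        score_kind="hubness",
    )


def interaction_change_score(
    map_a: ContactMap,
    map_b: ContactMap,
    window: int = CHANGE_WINDOW,
    threshold: float = CHANGE_THRESHOLD,
) -> ChangeScoreTrack:
    """Count, per bin, the offsets in a ±window band (excluding the ±1-bin
    vicinity) where the contact difference strictly exceeds ±threshold."""
    if map_a.values.shape != map_b.values.shape or map_a.bin_size != map_b.bin_size:
        raise ValueError("maps must share region and bin size")
    n = map_a.side
    delta = map_a.values - map_b.values
    joint = map_a.mask & map_b.mask
    scores = np.zeros(n, dtype=int)
    for o in range(-window, window + 1):
        if o in CHANGE_EXCLUDED:
            continue
        i = np.arange(max(0, -o), min(n, n - o))
        j = i + o
        hit = joint[i, j] & (np.abs(delta[i, j]) > threshold)
        scores[i] += hit
    return ChangeScoreTrack(map_a.region, map_a.bin_size, scores,
                            window, threshold)


def region_permutation_test(
    change_scores: Sequence[float],
    enhancer_scores: Sequence[float],
    regions: Sequence[GenomicRegion],
    de_genes: AnnotationTable,
    top_k: int | None = None,
    gene_flank: int = 600_000,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Enrichment of differentially-expressed genes in regions ranked high
    by both interaction change and enhancer difference.

    The observed statistic is the proportion of DE genes whose ±gene_flank
    extended span intersects the intersection of the two top-k region sets;
    the null shuffles which regions carry the top labels. p = (1 + #null ≥
    observed)/(1 + n_perm). ``top_k`` defaults to the top decile.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be > 0 (degenerate null)")
    change_scores = np.asarray(change_scores, dtype=float)
    enhancer_scores = np.asarray(enhancer_scores, dtype=float)
    regions = list(regions)
    n = len(regions)
    if change_scores.size != n or enhancer_scores.size != n:
        raise ValueError("score/region length mismatch")
    if top_k is None:
        top_k = max(1, n // 10)
    top_change = set(np.argsort(-change_scores, kind="stable")[:top_k])
    top_enh = set(np.argsort(-enhancer_scores, kind="stable")[:top_k])
    hot = sorted(top_change & top_enh)
    gene_spans = [
        (rec.chrom, int(rec.start) - gene_flank, int(rec.end) + gene_flank)
        for rec in de_genes.records.itertuples()
    ]
    if not gene_spans:
        raise ValueError("no DE genes supplied")
    # gene x region intersection matrix (precomputed once)
    hits = np.zeros((len(gene_spans), n), dtype=bool)
    for gi, (chrom, a, b) in enumerate(gene_spans):
        for ri, r in enumerate(regions):
            hits[gi, ri] = r.chrom == chrom and r.start < b and a < r.end

    def overlap_fraction(idx) -> float:
        if len(idx) == 0:
            return 0.0
        return float(hits[:, idx].any(axis=1).mean())

    observed = overlap_fraction(np.asarray(hot, dtype=int))
    if not hot:
        warnings.warn("empty top-rank intersection; p = 1", stacklevel=2)
        return observed, 1.0
    rng = np.random.default_rng(seed)
    k = len(hot)
    exceed = 0
    for _ in range(n_perm):
        null_idx = rng.choice(n, size=k, replace=False)
        if overlap_fraction(null_idx) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return observed, p


def enhancer_importance(
    states: MultiLabelStates,
    promoters: AnnotationTable | None = None,
    regions: Sequence[GenomicRegion] | None = None,
    mode: str = "gene",
    flank: int = 250_000,
) -> GeneScoreTable:
    """Active-enhancer bin counts near promoters (gene mode) or within
    1-Mb regions (region mode)."""
    if ACTIVE_ENHANCER_STATE not in states.vocabulary.output_states:
        raise ValueError("vocabulary lacks the active-enhancer state")
    enh = states.state_track(ACTIVE_ENHANCER_STATE)
    bs = states.bin_size
    reg = states.region
    rows = []
    if mode == "gene":
        if promoters is None:
            raise ValueError("gene mode requires promoters")
        for rec in promoters.records.itertuples():
            if rec.chrom != reg.chrom:
                continue
            a = max(int(rec.start) - flank, reg.start)
            b = min(int(rec.end) + flank, reg.end)
            ia = (a - reg.start) // bs
            ib = -(-(b - reg.start) // bs)
            rows.append(
                (rec.label, rec.chrom, int(rec.start), int(rec.end),
                 int(enh[ia:ib].sum()))
            )
    elif mode == "region-1Mb":
        if regions is None:
            raise ValueError("region mode requires regions")
        for r in regions:
            ia = (max(r.start, reg.start) - reg.start) // bs
            ib = (min(r.end, reg.end) - reg.start) // bs
            rows.append(
                (str(r), r.chrom, r.start, r.end, int(enh[ia:ib].sum()))
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GeneScoreTable(
        pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "score"]),
        score_kind="enhancer-count",
    )


def quantile_association(
    cmap: ContactMap, states: MultiLabelStates
) -> dict:
    """Split bins into quartiles of their mean Hi-C interaction value and
    compare per-bin active-enhancer counts between quartiles (two-sided
    Mann-Whitney for adjacent quartiles and lowest vs highest)."""
    n = cmap.side
    if n < 4:
        raise ValueError("need at least 4 bins")
    summary = np.where(cmap.mask, cmap.values, np.nan)
    row_mean = np.nanmean(summary, axis=1)
    enh = states.state_track(ACTIVE_ENHANCER_STATE)
    order = np.argsort(np.argsort(row_mean, kind="stable"), kind="stable")
    quartile = (order * 4) // n  # sizes differ by <= 1
    groups = [enh[quartile == q] for q in range(4)]
    pvals = {}
    for a, b in [(0, 1), (1, 2), (2, 3), (0, 3)]:
        try:
            pvals[f"q{a}_vs_q{b}"] = float(
                stats.mannwhitneyu(groups[a], groups[b],
                                   alternative="two-sided").pvalue
            )
        except ValueError:  # identical groups
            pvals[f"q{a}_vs_q{b}"] = 1.0
    return {
        "quartile_of_bin": quartile,
        "enhancer_counts": [int(g.sum()) for g in groups],
        "quartile_sizes": [int((quartile == q).sum()) for q in range(4)],
        "p_values": pvals,
    }


def hic_dendrogram(
    maps: dict[str, ContactMap],
    region_bp: int = 1_000_000,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of tissues by chromatin-structure distance.

    For each 1-Mb region the feature is the L1 distance between the
    tissue's sub-matrix and the across-tissue mean sub-matrix; tissues are
    clustered on these feature vectors (average linkage, Euclidean).
    Returns (scipy linkage matrix, tissue names).
    """
    names = list(maps)
    if len(names) < 2:
        raise ValueError("need at least two tissues")
    first = maps[names[0]]
    for m in maps.values():
        if m.values.shape != first.values.shape or m.region != first.region:
            raise ValueError("tissue maps must share the same grid")
    bs = first.bin_size
    step = region_bp // bs
    n = first.side
    starts = range(0, n - step + 1, step)
    stack = np.stack([np.where(m.mask, m.values, 0.0) for m in maps.values()])
    mean_map = stack.mean(axis=0)
    features = np.zeros((len(names), len(list(starts))))
    for ri, s in enumerate(range(0, n - step + 1, step)):
        tiles = stack[:, s : s + step, s : s + step]
        mean_tile = mean_map[s : s + step, s : s + step]
        features[:, ri] = np.abs(tiles - mean_tile).sum(axis=(1, 2))
    link = hierarchy.linkage(features, method=method, metric=metric)
    return link, names


def linkage_to_newick(link: np.ndarray, names: list[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string."""
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - (0 if node.left.is_leaf() else node.left.dist)
        dr = node.dist - (0 if node.right.is_leaf() else node.right.dist)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


def rank_genes_by_change(
    change: ChangeScoreTrack,
    genes: AnnotationTable,
    flank: int = 600_000,
) -> GeneScoreTable:
    """Sum of interaction-change scores within gene span ± flank, ranked
    descending (exportable with export_prerank)."""
    bs = change.bin_size
    reg = change.region
    rows = []
    for rec in genes.records.itertuples():
        if rec.chrom != reg.chrom:
            warnings.warn(f"gene {rec.label} outside scored region",
                          stacklevel=2)
            continue
        a = max(int(rec.start) - flank, reg.start)
        b = min(int(rec.end) + flank, reg.end)
        ia = (a - reg.start) // bs
        ib = -(-(b - reg.start) // bs)
        rows.append(
            (rec.label, rec.chrom, int(rec.start), int(rec.end),
             int(change.scores[ia:ib].sum()))
        )
    return GeneScoreTable(
        pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "score"]),
        score_kind="change-rank",
    )


# ---------------------------------------------------------------------------
# in-silico perturbation


@dataclass
class PerturbationSpec:
    """A coordinated edit of sequence and all tracks.

    ``kind``: "insertion", "deletion" or "duplication". For deletion,
    ``source`` is the span removed. For insertion/duplication, ``source``
    is the span copied and ``target`` the bp coordinate it is inserted at
    (duplication defaults to inserting right after the source). All
    coordinates must be aligned to the track resolution so sequence and
    tracks stay in register.
    """

    kind: str
    source: GenomicRegion
    target: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"insertion", "deletion", "duplication"}:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.kind == "insertion" and self.target is None:
            raise ValueError("insertion requires a target coordinate")


def apply_perturbation(
    seq: OneHotSequence,
    tracks: TrackSet,
    spec: PerturbationSpec,
) -> tuple[OneHotSequence, TrackSet]:
    """Apply the edit jointly to the sequence and every track.

    Insertions shift downstream coordinates; deletions remove the span.
    The edited region keeps its start coordinate; its end moves by the
    length change. Out-of-register edits (span not a multiple of the track
    resolution) are an error.
    """
    res = tracks.resolution
    reg = seq.region
    if tracks.region != reg:
        raise ValueError("sequence and tracks must cover the same region")
    span = spec.source
    if not reg.contains(span):
        raise ValueError(f"edit source {span} outside inputs {reg}")
    if len(span) % res or span.start % res:
        raise ValueError(
            f"edit span {span} not aligned to track resolution {res} "
            "(sequence and tracks would fall out of register)"
        )
    a, b = span.start - reg.start, span.end - reg.start
    if spec.kind == "deletion":
        new_seq = np.delete(seq.values, slice(a, b), axis=0)
        new_tr = np.delete(tracks.values, slice(a // res, b // res), axis=1)
        new_mask = np.delete(tracks.mask, slice(a // res, b // res), axis=1)
        length_change = -(b - a)
    else:
        target = spec.target
        if target is None:  # duplication default: right after the source
            target = span.end
        if target % res:
            raise ValueError("target coordinate not aligned to resolution")
        if not (reg.start <= target <= reg.end):
            raise ValueError("target outside inputs")
        t = target - reg.start
        new_seq = np.concatenate(
            [seq.values[:t], seq.values[a:b], seq.values[t:]], axis=0
        )
        ta, ra, rb = t // res, a // res, b // res
        new_tr = np.concatenate(
            [tracks.values[:, :ta], tracks.values[:, ra:rb],
             tracks.values[:, ta:]], axis=1,
        )
        new_mask = np.concatenate(
            [tracks.mask[:, :ta], tracks.mask[:, ra:rb], tracks.mask[:, ta:]],
            axis=1,
        )
        length_change = b - a
    new_region = GenomicRegion(reg.chrom, reg.start, reg.end + length_change)
    out_seq = OneHotSequence(new_region, new_seq, seq.n_policy)
    out_tracks = TrackSet(
        new_region, list(tracks.track_names), res, new_tr,
        standardized=tracks.standardized, mask=new_mask,
        zscore_mean=tracks.zscore_mean, zscore_std=tracks.zscore_std,
    )
    return out_seq, out_tracks
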
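"""Diagonal extraction, peak-balanced sampling, and tile assembly/stitching.

A training sample is the anti-diagonal stripe of contacts centered on a
genomic bin c: target[t] = C[c−t, c+t] for offsets t = 1..100, so one
sample spans genomic separations 10 kb .. 1 Mb at 5-kb bins, with an
aligned 200-bin (1-Mb) feature window centered on c. Samples whose target
contains zeros, NaNs, or masked entries are dropped; the remainder are
flagged by a peak rule and subsampled so peak-bearing and peak-free
diagonals appear at a 1:2.5 ratio.

For denoising, predicted diagonals are re-assembled into 1-Mb (200×200)
tiles sliding with 0.5-Mb overlap at training time and 0.25-Mb overlap at
prediction time, excluding the first/last 2 Mb of each chromosome;
denoised tiles are stitched back into a chromosome-scale map by averaging
overlaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import h5py
import numpy as np

from .coords import DEFAULT_BIN_SIZE, GenomicRegion
from .io_formats import ContactMap

__all__ = [
    "DiagonalSample",
    "Tile",
    "default_distance_weights",
    "extract_samples",
    "sample_training_set",
    "assemble_tiles",
    "stitch_predictions",
    "tile_starts",
    "save_samples",
    "load_samples",
]

MAX_OFFSET = 100
WINDOW_BINS = 200
TILE_BP = 1_000_000
TRAIN_STEP_BP = 500_000
PREDICT_STEP_BP = 750_000  # 0.25-Mb overlap between 1-Mb prediction tiles
EDGE_EXCLUSION_BP = 2_000_000
PEAK_THRESHOLD = 3.0


@dataclass
class DiagonalSample:
    """One contact-diagonal target with its aligned feature window."""

    chrom: str
    center_bin: int  # absolute bin index on the chromosome
    bin_size: int
    target: np.ndarray  # (max_offset,) y[t-1] = C[c-t, c+t]
    weights: np.ndarray
    has_peak: bool
    window_bins: int = WINDOW_BINS

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.target.shape != self.weights.shape:
            raise ValueError("target/weights shape mismatch")

    @property
    def max_offset(self) -> int:
        return self.target.shape[0]

    @property
    def feature_window(self) -> GenomicRegion:
        half = self.window_bins // 2
        start = (self.center_bin - half) * self.bin_size
        return GenomicRegion(
            self.chrom, start, start + self.window_bins * self.bin_size
        )


def default_distance_weights(
    target: np.ndarray, cap: float = 10.0
) -> np.ndarray:
    """Distance weight per target value: up-weight strong normalized
    contacts, w = 1 + min(relu(y), cap)/cap."""
    return 1.0 + np.minimum(np.maximum(target, 0.0), cap) / cap


def extract_samples(
    cmap: ContactMap,
    stride: int = 1,
    max_offset: int = MAX_OFFSET,
    window_bins: int = WINDOW_BINS,
    peak_threshold: float = PEAK_THRESHOLD,
    weight_fn: Callable[[np.ndarray], np.ndarray] = default_distance_weights,
    drop_zero: bool = True,
) -> list[DiagonalSample]:
    """Extract QC-passing diagonal samples from a contact map.

    Candidate centers lie in ``[max_offset, side − max_offset)`` stepped by
    ``stride``; a candidate is dropped when its target contains a zero, a
    NaN, or a masked entry.
    """
    side = cmap.side
    half = window_bins // 2
    lo = max(max_offset, half)
    hi = side - max(max_offset, half)
    if hi <= lo:
        warnings.warn(
            f"map side {side} too small for a {window_bins}-bin window",
            stacklevel=2,
        )
        return []
    b0 = cmap.region.start // cmap.bin_size
    t = np.arange(1, max_offset + 1)
    out = []
    for c in range(lo, hi, stride):
        rows, cols = c - t, c + t
        vals = cmap.values[rows, cols]
        ok = cmap.mask[rows, cols]
        if not ok.all() or not np.isfinite(vals).all():
            continue
        if drop_zero and (vals == 0).any():
            continue
        out.append(
            DiagonalSample(
                chrom=cmap.region.chrom,
                center_bin=b0 + c,
                bin_size=cmap.bin_size,
                target=vals,
                weights=weight_fn(vals),
                has_peak=bool((vals >= peak_threshold).any()),
                window_bins=window_bins,
            )
        )
    return out


def sample_training_set(
    samples: Sequence[DiagonalSample],
    seed: int,
    ratio: float = 2.5,
) -> list[DiagonalSample]:
    """Peak-balanced subsample at a 1:ratio peak:no-peak count ratio.

    Selection is uniform within each stratum and reproducible by seed;
    selected samples are returned bit-exactly. An empty stratum returns the
    other stratum whole, with a warning.
    """
    rng = np.random.default_rng(seed)
    peaks = [s for s in samples if s.has_peak]
    quiet = [s for s in samples if not s.has_peak]
    if not peaks or not quiet:
        warnings.warn(
            "one peak stratum is empty; returning the other unchanged "
            "(1:%.1f ratio unachievable)" % ratio, stacklevel=2,
        )
        return list(peaks or quiet)
    n_peak = min(len(peaks), max(1, int(round(len(quiet) / ratio))))
    n_quiet = min(len(quiet), int(round(ratio * n_peak)))
    sel_p = rng.choice(len(peaks), size=n_peak, replace=False)
    sel_q = rng.choice(len(quiet), size=n_quiet, replace=False)
    chosen = [peaks[i] for i in sorted(sel_p)] + [
        quiet[i] for i in sorted(sel_q)
    ]
    rng.shuffle(chosen)
    return chosen


@dataclass
class Tile:
    """A 1-Mb (200×200-bin) symmetric matrix assembled from diagonals."""

    region: GenomicRegion
    bin_size: int
    values: np.ndarray
    mask: np.ndarray
    provenance: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.region.n_bins(self.bin_size)
        if self.values.shape != (n, n):
            raise ValueError("tile shape mismatch with region")

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @property
    def start_bin(self) -> int:
        return self.region.start // self.bin_size


def tile_starts(
    chrom_length: int,
    tile_bp: int = TILE_BP,
    step_bp: int = TRAIN_STEP_BP,
    edge_bp: int = EDGE_EXCLUSION_BP,
) -> list[int]:
    """Start coordinates of the sliding tiles: from the 2-Mb edge exclusion
    to ``chrom_length − 2 Mb − tile``."""
    out = []
    start = edge_bp
    while start + tile_bp <= chrom_length - edge_bp:
        out.append(start)
        start += step_bp
    return out


def assemble_tiles(
    samples: Sequence[DiagonalSample],
    chrom_length: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    tile_bp: int = TILE_BP,
    step_bp: int = TRAIN_STEP_BP,
    edge_bp: int = EDGE_EXCLUSION_BP,
) -> list[Tile]:
    """Assemble (predicted) diagonals into overlapping 1-Mb tiles.

    Each tile entry is the mean of every diagonal value mapping to it (a
    value at offset t of a sample centered at c maps to (c−t, c+t) and its
    transpose); entries no sample covers are masked, with a warning when a
    tile has gaps on the reachable separations.
    """
    if not samples:
        raise ValueError("no samples to assemble")
    chrom = samples[0].chrom
    entries_i, entries_j, entries_v = [], [], []
    centers = []
    for s in samples:
        if s.chrom != chrom:
            raise ValueError("samples from multiple chromosomes")
        t = np.arange(1, s.max_offset + 1)
        entries_i.append(s.center_bin - t)
        entries_j.append(s.center_bin + t)
        entries_v.append(s.target)
        centers.append(s.center_bin)
    ii = np.concatenate(entries_i)
    jj = np.concatenate(entries_j)
    vv = np.concatenate(entries_v)
    # symmetrize the scatter
    ii, jj, vv = (
        np.concatenate([ii, jj]),
        np.concatenate([jj, ii]),
        np.concatenate([vv, vv]),
    )
    n_tile = tile_bp // bin_size
    tiles = []
    gap_warned = False
    for start in tile_starts(chrom_length, tile_bp, step_bp, edge_bp):
        tb = start // bin_size
        sel = (ii >= tb) & (ii < tb + n_tile) & (jj >= tb) & (jj < tb + n_tile)
        sums = np.zeros((n_tile, n_tile))
        counts = np.zeros((n_tile, n_tile))
        np.add.at(sums, (ii[sel] - tb, jj[sel] - tb), vv[sel])
        np.add.at(counts, (ii[sel] - tb, jj[sel] - tb), 1.0)
        mask = counts > 0
        with np.errstate(invalid="ignore"):
            values = np.where(mask, sums / np.where(mask, counts, 1), np.nan)
        # stripes at integer centers reach the even separations
        # 2..2*max_offset; check coverage there
        d = np.abs(np.subtract.outer(np.arange(n_tile), np.arange(n_tile)))
        reachable = (d >= 2) & (d <= 2 * samples[0].max_offset) & (d % 2 == 0)
        if not gap_warned and (~mask & reachable).any():
            warnings.warn("coverage gaps in assembled tiles; entries masked",
                          stacklevel=2)
            gap_warned = True
        region = GenomicRegion(chrom, start, start + tile_bp)
        prov = [c for c in centers if tb <= c < tb + n_tile]
        tiles.append(Tile(region, bin_size, values, mask, prov))
    return tiles


def stitch_predictions(tiles: Sequence[Tile]) -> ContactMap:
    """Average overlapping (denoised) tiles into one chromosome-scale map."""
    if not tiles:
        raise ValueError("no tiles to stitch")
    bin_size = tiles[0].bin_size
    chrom = tiles[0].region.chrom
    for t in tiles:
        if t.bin_size != bin_size:
            raise ValueError("inconsistent bin size across tiles")
        if t.region.chrom != chrom:
            raise ValueError("tiles from multiple chromosomes")
    start = min(t.region.start for t in tiles)
    end = max(t.region.end for t in tiles)
    n = (end - start) // bin_size
    sums = np.zeros((n, n))
    counts = np.zeros((n, n))
    for t in tiles:
        o = (t.region.start - start) // bin_size
        m = t.side
        sums[o : o + m, o : o + m] += np.where(t.mask, t.values, 0.0)
        counts[o : o + m, o : o + m] += t.mask
    mask = counts > 0
    values = np.where(mask, sums / np.where(mask, counts, 1), np.nan)
    region = GenomicRegion(chrom, start, end)
    return ContactMap(region, bin_size, values, mask)


# ---------------------------------------------------------------------------
# serialization


def save_samples(path: str | Path, samples: Sequence[DiagonalSample]) -> None:
    if not samples:
        raise ValueError("nothing to save")
    with h5py.File(path, "w") as f:
        f.attrs["bin_size"] = samples[0].bin_size
        f.attrs["window_bins"] = samples[0].window_bins
        f.create_dataset(
            "chrom",
            data=np.array([s.chrom for s in samples], dtype="S32"),
        )
        f.create_dataset(
            "center_bin", data=np.array([s.center_bin for s in samples])
        )
        f.create_dataset("target", data=np.stack([s.target for s in samples]))
        f.create_dataset("weights", data=np.stack([s.weights for s in samples]))
        f.create_dataset(
            "has_peak", data=np.array([s.has_peak for s in samples])
        )


def load_samples(path: str | Path) -> list[DiagonalSample]:
    with h5py.File(path, "r") as f:
        chroms = [c.decode() for c in f["chrom"][:]]
        centers = f["center_bin"][:]
        targets = f["target"][:]
        weights = f["weights"][:]
        peaks = f["has_peak"][:]
        bin_size = int(f.attrs["bin_size"])
        window_bins = int(f.attrs["window_bins"])
    return [
        DiagonalSample(
            chrom=chroms[i],
            center_bin=int(centers[i]),
            bin_size=bin_size,
            target=targets[i],
            weights=weights[i],
            has_peak=bool(peaks[i]),
            window_bins=window_bins,
        )
        for i in range(len(chroms))
    ]
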
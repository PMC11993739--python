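"""On-disk artifact I/O and the coordinate-consistent domain containers.

Contact matrices are exchanged as single-resolution cooler-style HDF5
(``.cool``), dense ``.npz`` or dense TSV; signal tracks as bedGraph or
bigWig; sequence as indexed FASTA; annotations as BED4/BED6. All containers
carry a :class:`~virtualhic.coords.GenomicRegion` and use 0-based half-open
coordinates; 1-based sources must be converted at the boundary by the
caller.

Missing data is explicit: entries absent from a source (unstored cooler
pixels, NaNs, uncovered track bases) are flagged in a mask, never silently
zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .coords import DEFAULT_BIN_SIZE, DEFAULT_TRACK_RESOLUTION, GenomicRegion

__all__ = [
    "ContactMap",
    "TrackSet",
    "OneHotSequence",
    "AnnotationTable",
    "load_contact_map",
    "write_contact_map",
    "load_tracks",
    "write_tracks_bedgraph",
    "load_sequence",
    "write_fasta",
    "read_bed",
    "write_bed",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class FormatError(ValueError):
    """Unrecognized or malformed on-disk format."""


class BoundsError(ValueError):
    """Requested region outside the stored extent."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ContactMap:
    """A symmetric, binned, normalized Hi-C contact matrix for one region.

    ``values`` is square with side ``len(region) // bin_size``; ``mask`` is
    True where the entry is valid. Values are on the distance-stratified
    normalized scale (per-diagonal z-scores of raw contacts), the scale every
    loss and metric in this package operates on.
    """

    region: GenomicRegion
    bin_size: int
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        side = self.region.n_bins(self.bin_size)
        if self.values.shape != (side, side):
            raise ValueError(
                f"matrix shape {self.values.shape} != ({side}, {side}) implied "
                f"by region {self.region} at {self.bin_size} bp bins"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")
        valid = self.mask & self.mask.T
        sym_err = np.nanmax(
            np.abs(np.where(valid, self.values - self.values.T, 0.0)), initial=0.0
        )
        if sym_err > 1e-8:
            raise ValueError(
                f"asymmetric contact map (max |C - C.T| = {sym_err:.3g}); "
                "use ContactMap.from_dense to symmetrize"
            )

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_dense(
        cls,
        region: GenomicRegion,
        bin_size: int,
        values: np.ndarray,
        mask: np.ndarray | None = None,
        asym_rtol: float = 0.1,
    ) -> "ContactMap":
        """Build from a possibly asymmetric dense matrix.

        Asymmetric input is symmetrized by averaging with a warning; if the
        asymmetry exceeds ``asym_rtol`` relative to the matrix magnitude the
        input is rejected instead.
        """
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.isfinite(values)
        mask = np.asarray(mask, dtype=bool) & np.isfinite(values)
        filled = np.where(mask, values, 0.0)
        asym = np.abs(filled - filled.T)
        scale = max(np.max(np.abs(filled)), 1e-12)
        if asym.max(initial=0.0) > 0:
            if asym.max() > asym_rtol * scale:
                raise ValueError(
                    f"matrix asymmetry {asym.max():.3g} exceeds {asym_rtol} "
                    f"of magnitude {scale:.3g}"
                )
            warnings.warn(
                "asymmetric contact matrix symmetrized by averaging",
                stacklevel=2,
            )
        sym = 0.5 * (filled + filled.T)
        joint = mask & mask.T
        sym = np.where(joint, sym, np.where(mask, filled, filled.T))
        return cls(region, bin_size, np.where(mask | mask.T, sym, np.nan),
                   mask | mask.T)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class TrackSet:
    """Named epigenetic signal vectors over one region at fixed resolution.

    When ``standardized`` is set, each track was z-scored with the recorded
    ``zscore_mean``/``zscore_std`` (fit on training data, reused verbatim at
    prediction time to avoid leakage).
    """

    region: GenomicRegion
    track_names: list[str]
    resolution: int
    values: np.ndarray  # (n_tracks, n_positions)
    standardized: bool = False
    mask: np.ndarray = None  # type: ignore[assignment]
    zscore_mean: np.ndarray | None = None
    zscore_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n_pos = self.region.n_bins(self.resolution)
        if self.values.shape != (len(self.track_names), n_pos):
            raise ValueError(
                f"track array {self.values.shape} != "
                f"({len(self.track_names)}, {n_pos})"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_tracks(self) -> int:
        return len(self.track_names)

    def standardize(self, mean=None, std=None) -> "TrackSet":
        """Z-score per track, fitting statistics unless given."""
        if self.standardized:
            return self
        if mean is None:
            mean = self.values.mean(axis=1)
            std = self.values.std(axis=1)
            bad = np.flatnonzero(std == 0)
            if bad.size:
                raise ValueError(
                    "zero-variance track(s) under standardization: "
                    + ", ".join(self.track_names[i] for i in bad)
                )
        mean = np.asarray(mean, dtype=float)
        std = np.asarray(std, dtype=float)
        vals = (self.values - mean[:, None]) / std[:, None]
        return TrackSet(
            self.region, list(self.track_names), self.resolution, vals,
            standardized=True, mask=self.mask.copy(),
            zscore_mean=mean, zscore_std=std,
        )


@dataclass
class OneHotSequence:
    """One-hot encoded DNA over a region (rows = positions, cols = A,C,G,T).

    Ambiguous bases are encoded per ``n_policy``: ``"zero"`` (default) writes
    an all-zero row, ``"uniform"`` writes 0.25 everywhere.
    """

    region: GenomicRegion
    values: np.ndarray
    n_policy: str = "zero"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region), 4):
            raise ValueError(
                f"one-hot shape {self.values.shape} != ({len(self.region)}, 4)"
            )

    @classmethod
    def from_string(
        cls, region: GenomicRegion, seq: str, n_policy: str = "zero"
    ) -> "OneHotSequence":
        if len(seq) != len(region):
            raise ValueError("sequence length != region length")
        out = np.zeros((len(seq), 4))
        for i, base in enumerate(seq.upper()):
            j = _BASE_INDEX.get(base)
            if j is not None:
                out[i, j] = 1.0
            elif n_policy == "uniform":
                out[i, :] = 0.25
            elif n_policy != "zero":
                raise ValueError(f"unknown n_policy {n_policy!r}")
        return cls(region, out, n_policy)

    def to_string(self) -> str:
        idx = self.values.argmax(axis=1)
        filled = self.values.sum(axis=1) > 0
        return "".join(
            ALPHABET[j] if ok else "N" for j, ok in zip(idx, filled)
        )


@dataclass
class AnnotationTable:
    """BED-style records: (region, label, optional score)."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "label", "score"]
        )
    )

    @classmethod
    def from_tuples(cls, rows: Sequence[tuple]) -> "AnnotationTable":
        """Rows of (chrom, start, end, label[, score])."""
        recs = []
        for row in rows:
            chrom, start, end, label = row[:4]
            score = row[4] if len(row) > 4 else np.nan
            recs.append((chrom, int(start), int(end), str(label), score))
        return cls(
            pd.DataFrame(recs, columns=["chrom", "start", "end", "label", "score"])
        )

    def __len__(self) -> int:
        return len(self.records)

    def sorted(self) -> "AnnotationTable":
        return AnnotationTable(
            self.records.sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    def regions(self) -> list[GenomicRegion]:
        return [
            GenomicRegion(r.chrom, int(r.start), int(r.end))
            for r in self.records.itertuples()
        ]


# ---------------------------------------------------------------------------
# contact map I/O


def write_contact_map(path: str | Path, cmap: ContactMap) -> None:
    """Write ``.cool`` (minimal single-resolution cooler layout), ``.npz``,
    or dense TSV depending on the file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".cool":
        _write_cool(path, cmap)
    elif suffix == ".npz":
        np.savez_compressed(
            path,
            values=cmap.values,
            mask=cmap.mask,
            chrom=np.array(cmap.region.chrom),
            start=np.array(cmap.region.start),
            end=np.array(cmap.region.end),
            bin_size=np.array(cmap.bin_size),
        )
    elif suffix in {".tsv", ".txt"}:
        np.savetxt(path, np.where(cmap.mask, cmap.values, np.nan), delimiter="\t")
    else:
        raise FormatError(f"unknown contact-map format {suffix!r}")


def load_contact_map(
    path: str | Path,
    region: GenomicRegion,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> ContactMap:
    """Load a region from a ``.cool``, ``.npz`` or dense text matrix file."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".cool":
        return _read_cool(path, region, bin_size)
    if suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            stored = GenomicRegion(
                str(z["chrom"]), int(z["start"]), int(z["end"])
            )
            stored_bs = int(z["bin_size"])
            if stored_bs != bin_size:
                raise FormatError(
                    f"stored bin size {stored_bs} != requested {bin_size}"
                )
            if not stored.contains(region):
                raise BoundsError(f"{region} outside stored extent {stored}")
            i0 = (region.start - stored.start) // bin_size
            n = region.n_bins(bin_size)
            vals = z["values"][i0 : i0 + n, i0 : i0 + n]
            mask = z["mask"][i0 : i0 + n, i0 : i0 + n]
        return ContactMap.from_dense(region, bin_size, vals, mask)
    if suffix in {".tsv", ".txt"}:
        vals = np.loadtxt(path, delimiter="\t", ndmin=2)
        n = region.n_bins(bin_size)
        if vals.shape != (n, n):
            raise BoundsError(
                f"dense matrix {vals.shape} does not match region "
                f"{region} ({n} bins)"
            )
        return ContactMap.from_dense(region, bin_size, vals)
    raise FormatError(f"unknown contact-map format {suffix!r}")


def _write_cool(path: Path, cmap: ContactMap) -> None:
    n = cmap.side
    iu, ju = np.triu_indices(n)
    keep = cmap.mask[iu, ju]
    iu, ju = iu[keep], ju[keep]
    counts = cmap.values[iu, ju]
    start = cmap.region.start
    bs = cmap.bin_size
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["format-version"] = 3
        f.attrs["bin-size"] = bs
        f.attrs["bin-type"] = "fixed"
        f.attrs["storage-mode"] = "symmetric-upper"
        f.attrs["nbins"] = n
        chroms = f.create_group("chroms")
        chroms.create_dataset(
            "name", data=np.array([cmap.region.chrom], dtype="S32")
        )
        chroms.create_dataset("length", data=np.array([cmap.region.end]))
        bins = f.create_group("bins")
        bins.create_dataset("chrom", data=np.zeros(n, dtype=np.int32))
        bins.create_dataset(
            "start", data=start + bs * np.arange(n, dtype=np.int64)
        )
        bins.create_dataset(
            "end", data=start + bs * (1 + np.arange(n, dtype=np.int64))
        )
        pixels = f.create_group("pixels")
        pixels.create_dataset("bin1_id", data=iu.astype(np.int64))
        pixels.create_dataset("bin2_id", data=ju.astype(np.int64))
        pixels.create_dataset("count", data=counts.astype(np.float64))
        # offset of the region inside its chromosome, so a sub-region read
        # can translate bp -> stored bin id
        f.attrs["region-start"] = start


def _read_cool(path: Path, region: GenomicRegion, bin_size: int) -> ContactMap:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "HDF5::Cooler":
            raise FormatError(f"{path} is not a cooler-style container")
        if int(f.attrs["bin-size"]) != bin_size:
            raise FormatError(
                f"stored bin size {f.attrs['bin-size']} != requested {bin_size}"
            )
        names = [s.decode() for s in f["chroms/name"][:]]
        if region.chrom not in names:
            raise BoundsError(f"chromosome {region.chrom!r} not in {path}")
        starts = f["bins/start"][:]
        ends = f["bins/end"][:]
        if region.start < int(starts[0]) or region.end > int(ends[-1]):
            raise BoundsError(
                f"{region} outside stored extent "
                f"{region.chrom}:{starts[0]}-{ends[-1]}"
            )
        i0 = int(np.searchsorted(starts, region.start))
        n = region.n_bins(bin_size)
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        cnt = f["pixels/count"][:]
    sel = (b1 >= i0) & (b1 < i0 + n) & (b2 >= i0) & (b2 < i0 + n)
    vals = np.full((n, n), np.nan)
    vals[b1[sel] - i0, b2[sel] - i0] = cnt[sel]
    vals[b2[sel] - i0, b1[sel] - i0] = cnt[sel]
    return ContactMap.from_dense(region, bin_size, vals)


# ---------------------------------------------------------------------------
# track I/O


def _read_coverage(path: Path, region: GenomicRegion) -> np.ndarray:
    """Per-base coverage over ``region`` from bedGraph or bigWig; NaN where
    uncovered."""
    suffix = path.suffix.lower()
    per_base = np.full(len(region), np.nan)
    if suffix in {".bw", ".bigwig"}:
        import pyBigWig

        bw = pyBigWig.open(str(path))
        try:
            if region.chrom not in bw.chroms():
                return per_base
            end = min(region.end, bw.chroms()[region.chrom])
            if end > region.start:
                vals = np.asarray(
                    bw.values(region.chrom, region.start, end), dtype=float
                )
                per_base[: end - region.start] = vals
        finally:
            bw.close()
        return per_base
    if suffix in {".bedgraph", ".bg", ".bdg"}:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
        )
        df = df[df.chrom == region.chrom]
        for row in df.itertuples():
            a = max(int(row.start), region.start) - region.start
            b = min(int(row.end), region.end) - region.start
            if b > a:
                per_base[a:b] = float(row.value)
        return per_base
    raise FormatError(f"unknown track format {suffix!r}")


def load_tracks(
    paths: Sequence[str | Path],
    region: GenomicRegion,
    resolution: int = DEFAULT_TRACK_RESOLUTION,
    standardize: bool = False,
    names: Sequence[str] | None = None,
) -> TrackSet:
    """Read coverage tracks, bin to ``resolution`` by the mean of covered
    bases (uncovered bases count 0 with a mask bit), optionally z-score."""
    paths = [Path(p) for p in paths]
    if names is None:
        names = [p.stem for p in paths]
    n_pos = region.n_bins(resolution)
    values = np.zeros((len(paths), n_pos))
    mask = np.ones((len(paths), n_pos), dtype=bool)
    for t, p in enumerate(paths):
        per_base = _read_coverage(p, region)
        covered = np.isfinite(per_base)
        if not covered.all():
            warnings.warn(
                f"track {p.name}: {100 * (~covered).mean():.1f}% of {region} "
                "uncovered; masked", stacklevel=2,
            )
        per_base = np.where(covered, per_base, 0.0)
        binned = per_base.reshape(n_pos, resolution)
        values[t] = binned.mean(axis=1)
        mask[t] = covered.reshape(n_pos, resolution).any(axis=1)
    ts = TrackSet(region, list(names), resolution, values, mask=mask)
    return ts.standardize() if standardize else ts


def write_tracks_bedgraph(
    directory: str | Path, tracks: TrackSet
) -> list[Path]:
    """One bedGraph per track, named after the track."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    res = tracks.resolution
    starts = tracks.region.start + res * np.arange(tracks.values.shape[1])
    for t, name in enumerate(tracks.track_names):
        p = directory / f"{name}.bedgraph"
        df = pd.DataFrame(
            {
                "chrom": tracks.region.chrom,
                "start": starts,
                "end": starts + res,
                "value": tracks.values[t],
            }
        )
        df[tracks.mask[t]].to_csv(p, sep="\t", header=False, index=False)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# sequence I/O


def load_sequence(
    path: str | Path, region: GenomicRegion, n_policy: str = "zero"
) -> OneHotSequence:
    """One-hot encode ``region`` from an indexed (or indexable) FASTA."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    try:
        if region.chrom not in fa:
            raise BoundsError(f"contig {region.chrom!r} not in {path}")
        contig_len = len(fa[region.chrom])
        if region.end > contig_len:
            raise BoundsError(
                f"{region} beyond contig end {contig_len}"
            )
        seq = fa[region.chrom][region.start : region.end].seq
    finally:
        fa.close()
    return OneHotSequence.from_string(region, seq, n_policy)


def write_fasta(path: str | Path, contigs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation I/O


def read_bed(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(df.shape[1], 5)]
    cols = ["chrom", "start", "end", "label", "score"][: df.shape[1]]
    df.columns = cols
    if "label" not in df.columns:
        df["label"] = "."
    if "score" not in df.columns:
        df["score"] = np.nan
    df["chrom"] = df["chrom"].astype(str)
    return AnnotationTable(df.reset_index(drop=True))


def write_bed(path: str | Path, table: AnnotationTable) -> None:
    df = table.sorted().records.copy()
    has_scores = df["score"].notna().any()
    cols = ["chrom", "start", "end", "label"] + (["score"] if has_scores else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)
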
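"""Coupled synthetic genomes, tracks, chromatin states and contact maps.

The generator emulates the statistical structure the prediction pipeline
assumes, at desk scale and with full determinism under a seed:

* contact maps: a power-law distance decay ``(1+d)^-γ`` multiplied by
  planted TAD blocks (square intra-domain boosts) and loop bumps (Gaussian
  corner peaks), with multiplicative Gaussian noise, then per-diagonal
  z-normalized so the output scale matches the distance-stratified
  normalized inputs every loss and metric operates on;
* tracks: a "boundary" track peaking at TAD boundaries, an "anchor" track
  peaking at loop anchors, an "activity" track coupled to the map's row
  mean, plus smooth noise tracks — all standardized at bin level so that
  with no planted structure every informative track is distributionally
  identical to a noise track;
* states: 13-dimensional multi-label vectors that are deterministic
  threshold functions of the tracks (the active-enhancer state co-occurs
  with high row-sum bins by construction);
* sequence: i.i.d. uniform background with consensus motifs planted at a
  configured rate and their positions logged for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .coords import DEFAULT_BIN_SIZE, GenomicRegion
from .io_formats import (
    AnnotationTable,
    ContactMap,
    OneHotSequence,
    TrackSet,
    write_bed,
    write_contact_map,
    write_fasta,
    write_tracks_bedgraph,
)
from .metrics import distance_stratified_normalize
from .states import DEFAULT_VOCABULARY, MultiLabelStates

__all__ = [
    "SimulationConfig",
    "simulate_contact_map",
    "simulate_tracks_and_states",
    "simulate_sequences",
    "simulate_dataset",
    "chrom_region",
]

INFORMATIVE_TRACKS = (
    "boundary", "anchor", "activity", "promoter", "transcription",
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults are the desk-scale conditions used throughout the test suite:
    two 10-Mb chromosomes of 5-kb bins (2000 bins each, large enough to
    hold 1-Mb tiles inside the 2-Mb end exclusions), a contact decay
    exponent of 1 (the classic fractal-globule-like ``1/d`` decay),
    multiplicative noise of sd 0.1 on the raw decay scale (distance-
    independent signal-to-noise after per-diagonal normalization), eight
    tracks, and one CTCF-like 14-bp consensus planted at 1e-4 per bp.
    TAD/loop layouts are drawn from the seed unless given explicitly.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    bin_size: int = DEFAULT_BIN_SIZE
    decay_exponent: float = 1.0
    tad_spec: dict[str, list[tuple[int, int, float]]] | None = None
    loop_spec: dict[str, list[tuple[int, int, float]]] | None = None
    noise_sd: float = 0.1
    track_noise_sd: float = 0.2
    n_tracks: int = 8
    track_resolution: int = 25
    motif_bank: list[tuple[str, float]] = field(
        default_factory=lambda: [("CCACCAGGGGGCGC", 1e-4)]
    )
    tad_size_bins: tuple[int, int] = (50, 150)
    tad_boost: tuple[float, float] = (1.5, 2.5)
    loop_strength: tuple[float, float] = (2.0, 4.0)
    loop_probability: float = 0.7

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for chrom, length in self.chrom_lengths.items():
            if length % self.bin_size:
                raise ValueError(
                    f"{chrom} length {length} not a multiple of bin size"
                )
        if self.n_tracks < len(INFORMATIVE_TRACKS):
            raise ValueError(
                f"n_tracks must be >= {len(INFORMATIVE_TRACKS)}"
            )
        for consensus, rate in self.motif_bank:
            if len(consensus) > 15:
                raise ValueError(f"motif {consensus!r} longer than 15")
            if not (0 <= rate):
                raise ValueError("planting rate must be >= 0")

    def chrom_index(self, chrom: str) -> int:
        return list(self.chrom_lengths).index(chrom)

    def track_names(self) -> list[str]:
        extra = self.n_tracks - len(INFORMATIVE_TRACKS)
        return list(INFORMATIVE_TRACKS) + [
            f"noise_{i + 1}" for i in range(extra)
        ]


def chrom_region(cfg: SimulationConfig, chrom: str) -> GenomicRegion:
    return GenomicRegion(chrom, 0, cfg.chrom_lengths[chrom])


def _rng(cfg: SimulationConfig, chrom: str, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        [cfg.seed % (2**31), cfg.chrom_index(chrom), stream]
    )


def tad_loop_layout(
    cfg: SimulationConfig, chrom: str
) -> tuple[list[tuple[int, int, float]], list[tuple[int, int, float]]]:
    """TAD blocks and corner loops for one chromosome (drawn from the seed
    unless the config pins them explicitly)."""
    if cfg.tad_spec is not None:
        tads = list(cfg.tad_spec.get(chrom, []))
        loops = list((cfg.loop_spec or {}).get(chrom, []))
        return tads, loops
    rng = _rng(cfg, chrom, 0)
    n_bins = cfg.chrom_lengths[chrom] // cfg.bin_size
    tads, loops = [], []
    pos = int(rng.integers(0, 20))
    while pos < n_bins - cfg.tad_size_bins[0]:
        size = int(rng.integers(*cfg.tad_size_bins))
        end = min(pos + size, n_bins)
        boost = float(rng.uniform(*cfg.tad_boost))
        tads.append((pos, end, boost))
        if rng.random() < cfg.loop_probability and end - pos > 10:
            strength = float(rng.uniform(*cfg.loop_strength))
            loops.append((pos, end - 1, strength))
        pos = end
    return tads, loops


def simulate_contact_map(
    cfg: SimulationConfig, region: GenomicRegion
) -> ContactMap:
    """Distance-decay map with planted TADs/loops, noise, then per-diagonal
    z-normalization. Deterministic in (cfg.seed, region)."""
    if region.end > cfg.chrom_lengths.get(region.chrom, -1):
        raise ValueError(f"{region} outside simulated chromosomes")
    bs = cfg.bin_size
    n = region.n_bins(bs)
    b0 = region.start // bs
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    raw = (1.0 + d).astype(float) ** (-cfg.decay_exponent)

    tads, loops = tad_loop_layout(cfg, region.chrom)
    for s, e, boost in tads:
        lo, hi = max(s - b0, 0), min(e - b0, n)
        if hi > lo:
            raw[lo:hi, lo:hi] *= boost
    if loops:
        for i0, j0, strength in loops:
            i0, j0 = i0 - b0, j0 - b0
            if not (-10 < i0 < n + 10 and -10 < j0 < n + 10):
                continue
            bump_i = np.exp(-((idx - i0) ** 2) / 8.0)
            bump_j = np.exp(-((idx - j0) ** 2) / 8.0)
            bump = np.outer(bump_i, bump_j)
            raw *= 1.0 + strength * (bump + bump.T)

    if cfg.noise_sd > 0:
        rng = _rng(cfg, region.chrom, 1 + b0)
        eps = rng.normal(0.0, cfg.noise_sd, size=(n, n))
        eps = 0.5 * (eps + eps.T)
        raw = raw * (1.0 + eps)

    values = distance_stratified_normalize(raw)
    return ContactMap(region, bs, values, np.ones((n, n), dtype=bool))


def _smooth_noise(rng: np.random.Generator, n: int, sigma: float = 2.0) -> np.ndarray:
    x = gaussian_filter1d(rng.normal(size=n), sigma, mode="wrap")
    return (x - x.mean()) / x.std()


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_tracks_and_states(
    cfg: SimulationConfig,
    region: GenomicRegion,
    cmap: ContactMap,
) -> tuple[TrackSet, MultiLabelStates]:
    """Tracks statistically coupled to the map plus deterministic states.

    Bin-level signals are built first (boundary/anchor bumps, row-mean
    coupled activity, smooth noise), states are thresholded from them, and
    the signals are then upsampled to ``cfg.track_resolution`` by
    repetition, so mean-binning back to 5 kb recovers the bin values
    exactly.
    """
    bs = cfg.bin_size
    n = region.n_bins(bs)
    b0 = region.start // bs
    rng = _rng(cfg, region.chrom, 2 + b0)
    tads, loops = tad_loop_layout(cfg, region.chrom)
    idx = np.arange(n)

    def bumps_at(centers: list[int], amplitude: float = 4.0) -> np.ndarray:
        out = np.zeros(n)
        for c in centers:
            c = c - b0
            if -10 < c < n + 10:
                out += amplitude * np.exp(-((idx - c) ** 2) / 2.0)
        return out

    boundaries = sorted({t[0] for t in tads} | {t[1] for t in tads})
    anchors = sorted({a for i, j, _ in loops for a in (i, j)})

    # informative tracks carry the structure nearly deterministically: the
    # noise floor (track_noise_sd, default 0.2 of unit scale) exists so
    # that with no planted structure each informative track z-scores to the
    # same smoothed-Gaussian marginal as a pure noise track
    s = cfg.track_noise_sd
    signals = {}
    signals["boundary"] = _zscore(
        bumps_at(boundaries) + s * _smooth_noise(rng, n)
    )
    signals["anchor"] = _zscore(
        bumps_at(anchors) + s * _smooth_noise(rng, n)
    )
    row_mean = np.nanmean(np.where(cmap.mask, cmap.values, np.nan), axis=1)
    act_noise = _smooth_noise(rng, n)
    if row_mean.std() <= 1e-12:  # featureless map: activity is pure noise
        signals["activity"] = act_noise
    else:
        w = np.sqrt(max(1.0 - s**2, 0.0))
        signals["activity"] = w * _zscore(row_mean) + s * act_noise
    signals["promoter"] = _smooth_noise(rng, n)
    signals["transcription"] = _smooth_noise(rng, n)
    for name in cfg.track_names()[len(INFORMATIVE_TRACKS):]:
        signals[name] = _smooth_noise(rng, n)

    vocab = DEFAULT_VOCABULARY
    labels = np.zeros((n, len(vocab)), dtype=np.int8)
    labels[:, vocab.index("Prom")] = signals["promoter"] > 1.5
    labels[:, vocab.index("TssA")] = signals["promoter"] > 2.2
    labels[:, vocab.index("Tx")] = signals["transcription"] > 1.0
    labels[:, vocab.index("EnhA")] = signals["activity"] > 1.0
    labels[:, vocab.index("EnhW")] = (
        (signals["activity"] > 0.3) & (signals["activity"] <= 1.0)
    )
    covered = labels.sum(axis=1) > 0
    labels[~covered, vocab.index("Quies")] = 1
    states = MultiLabelStates(region, bs, labels, vocab)

    reps = bs // cfg.track_resolution
    values = np.stack(
        [np.repeat(signals[name], reps) for name in cfg.track_names()]
    )
    tracks = TrackSet(
        region, cfg.track_names(), cfg.track_resolution, values
    )
    return tracks, states


@dataclass
class MotifPlant:
    consensus: str
    start: int  # absolute bp


def simulate_sequences(
    cfg: SimulationConfig, region: GenomicRegion
) -> tuple[OneHotSequence, list[MotifPlant]]:
    """Uniform background sequence with motifs planted at the configured
    per-bp rate; overlapping plants are skipped (and simply not logged)."""
    rng = _rng(cfg, region.chrom, 3)
    length = len(region)
    bases = rng.integers(0, 4, size=length)
    occupied = np.zeros(length, dtype=bool)
    plants: list[MotifPlant] = []
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for consensus, rate in cfg.motif_bank:
        k = len(consensus)
        n_plant = rng.binomial(max(length - k, 0), rate)
        starts = rng.integers(0, length - k, size=n_plant)
        for s in np.sort(starts):
            s = int(s)
            if occupied[s : s + k].any():
                continue
            bases[s : s + k] = [base_idx[b] for b in consensus]
            occupied[s : s + k] = True
            plants.append(MotifPlant(consensus, region.start + s))
    onehot = np.zeros((length, 4))
    onehot[np.arange(length), bases] = 1.0
    return OneHotSequence(region, onehot), plants


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Write the full synthetic dataset (FASTA + bedGraph tracks + state
    BED + .cool maps) plus a JSON truth file; returns the truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: dict = {"config": {
        "seed": cfg.seed,
        "chrom_lengths": cfg.chrom_lengths,
        "bin_size": cfg.bin_size,
        "decay_exponent": cfg.decay_exponent,
        "noise_sd": cfg.noise_sd,
        "n_tracks": cfg.n_tracks,
    }, "chromosomes": {}}
    contigs = {}
    vocab = DEFAULT_VOCABULARY
    for chrom in cfg.chrom_lengths:
        region = chrom_region(cfg, chrom)
        cmap = simulate_contact_map(cfg, region)
        tracks, states = simulate_tracks_and_states(cfg, region, cmap)
        seq, plants = simulate_sequences(cfg, region)
        write_contact_map(outdir / f"{chrom}.cool", cmap)
        write_tracks_bedgraph(outdir / f"tracks_{chrom}", tracks)
        rows = []
        for k, state in enumerate(vocab.output_states):
            for b in np.flatnonzero(states.values[:, k]):
                rows.append(
                    (chrom, int(b) * cfg.bin_size,
                     (int(b) + 1) * cfg.bin_size, state)
                )
        write_bed(outdir / f"states_{chrom}.bed",
                  AnnotationTable.from_tuples(rows))
        contigs[chrom] = seq.to_string()
        tads, loops = tad_loop_layout(cfg, chrom)
        truth["chromosomes"][chrom] = {
            "tads": [list(t) for t in tads],
            "loops": [list(l) for l in loops],
            "motif_plants": [[p.consensus, p.start] for p in plants],
        }
    write_fasta(outdir / "genome.fa", contigs)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
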
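"""Model introspection: motif PWMs, integrated gradients, gene importance.

Motifs are recovered from the first sequence-encoder convolution: positions
whose activation exceeds a threshold are extended ±7 bases to 15-mers and
the base frequencies accumulated per kernel into a position weight matrix.
Integrated gradients attribute a scalar model output (sum of the predicted
contact diagonal, or a chromatin-state logit) to the epigenetic input
tracks along the straight path from an all-zero baseline. Gene importance
averages attribution mass around each promoter; differential tables and
pre-ranked exports feed downstream enrichment tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .coords import GenomicRegion
from .io_formats import ALPHABET, AnnotationTable, OneHotSequence
from .models import HiConformer
from .nn import Tensor

__all__ = [
    "PWM",
    "AttributionMap",
    "GeneScoreTable",
    "extract_pwms",
    "write_meme",
    "integrated_gradients",
    "gene_importance",
    "differential_importance",
    "export_prerank",
    "read_prerank",
]

PWM_WIDTH = 15
IG_STEPS = 64


@dataclass
class PWM:
    """Per-kernel base-frequency matrix over a 15-bp window (−7..+7)."""

    kernel_id: int
    matrix: np.ndarray  # (15, 4), rows sum to 1 when support > 0
    support: int

    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in self.matrix.argmax(axis=1))

    def matches(self, consensus: str) -> int:
        """Number of positions of ``consensus`` matched anywhere in the PWM
        consensus at the best ungapped alignment."""
        own = self.consensus()
        best = 0
        k = len(consensus)
        for off in range(-k + 1, PWM_WIDTH):
            score = sum(
                1
                for i, base in enumerate(consensus)
                if 0 <= off + i < PWM_WIDTH and own[off + i] == base
            )
            best = max(best, score)
        return best


def extract_pwms(
    model: HiConformer,
    sequences: Sequence[OneHotSequence],
    activation_threshold: float = 2.0,
    flank: int = 7,
    stage: str = "post",
) -> list[PWM]:
    """Scan the first sequence-encoder convolution over base-resolution
    one-hot sequences and build one PWM per kernel.

    Activation sites within ``flank`` of a sequence edge are dropped.
    Kernels with no site above the threshold yield a uniform PWM with
    support 0.
    """
    width = 2 * flank + 1
    for s in sequences:
        if len(s.region) < width:
            raise ValueError(
                f"sequence {s.region} shorter than the {width}-bp PWM window"
            )
    n_kernels = model.seq_encoder.blocks.layers[0].w.shape[0]
    counts = np.zeros((n_kernels, width, 4))
    support = np.zeros(n_kernels, dtype=int)
    for s in sequences:
        acts = model.first_conv_activations(s.values.T[None], stage=stage)[0]
        L = acts.shape[1]
        for k in range(n_kernels):
            sites = np.flatnonzero(acts[k] > activation_threshold)
            sites = sites[(sites >= flank) & (sites < L - flank)]
            for p in sites:
                counts[k] += s.values[p - flank : p + flank + 1]
            support[k] += sites.size
    pwms = []
    for k in range(n_kernels):
        if support[k] == 0:
            matrix = np.full((width, 4), 0.25)
        else:
            totals = counts[k].sum(axis=1, keepdims=True)
            matrix = np.where(totals > 0, counts[k] / np.maximum(totals, 1),
                              0.25)
        pwms.append(PWM(kernel_id=k, matrix=matrix, support=int(support[k])))
    return pwms


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    """MEME minimal motif format, one motif per kernel."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for p in pwms:
            fh.write(f"MOTIF kernel_{p.kernel_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {PWM_WIDTH} "
                f"nsites= {max(p.support, 1)} E= 0\n"
            )
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# integrated gradients


@dataclass
class AttributionMap:
    """Per-track, per-bin integrated-gradient scores."""

    region: GenomicRegion
    track_names: list[str]
    values: np.ndarray  # (n_tracks, n_positions)
    resolution: int
    baseline: str = "all-zero"
    steps: int = IG_STEPS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("attributions must be finite")


def _resolve_target(target) -> Callable:
    if callable(target):
        return target
    if target == "hic_sum":
        return lambda hic, logits: hic.sum()
    if isinstance(target, tuple) and target[0] == "state_logit":
        k = target[1]
        bins = target[2] if len(target) > 2 else slice(None)
        return lambda hic, logits: logits[:, bins, k].sum()
    raise ValueError(f"unknown IG target {target!r}")


def integrated_gradients(
    model: HiConformer,
    seq_x: np.ndarray,
    epi_x: np.ndarray,
    target="hic_sum",
    steps: int = IG_STEPS,
    region: GenomicRegion | None = None,
    track_names: list[str] | None = None,
) -> AttributionMap:
    """Riemann (trapezoid) integrated gradients of a scalar model output
    with respect to the epigenetic tracks, from an all-zero baseline.

    ``seq_x``: (4, L_seq) one window; ``epi_x``: (n_tracks, L_epi).
    The completeness identity Σ IG ≈ F(x) − F(0) holds to the quadrature
    error of the path integral.
    """
    target_fn = _resolve_target(target)
    model.eval()
    seq_b = np.asarray(seq_x, dtype=float)[None]
    epi = np.asarray(epi_x, dtype=float)
    alphas = np.linspace(0.0, 1.0, steps + 1)
    quad_w = np.full(steps + 1, 1.0 / steps)
    quad_w[0] = quad_w[-1] = 0.5 / steps
    total = np.zeros_like(epi)
    for a, qw in zip(alphas, quad_w):
        x = Tensor(a * epi[None], requires_grad=True)
        hic, _, logits = model(seq_b, x)
        scalar = target_fn(hic, logits)
        if scalar.size != 1:
            raise ValueError("IG target must be scalar")
        scalar.backward()
        total += qw * x.grad[0]
    values = epi * total
    if region is None:
        region = GenomicRegion("window", 0, epi.shape[1])
        resolution = 1
    else:
        resolution = len(region) // epi.shape[1]
    if track_names is None:
        track_names = [f"track_{i}" for i in range(epi.shape[0])]
    return AttributionMap(region, list(track_names), values, resolution,
                          baseline="all-zero", steps=steps)


# ---------------------------------------------------------------------------
# gene scores


@dataclass
class GeneScoreTable:
    """One score per gene for a given score kind."""

    records: pd.DataFrame  # columns: gene, chrom, start, end, score
    score_kind: str = "IG-importance"

    def __post_init__(self) -> None:
        need = {"gene", "score"}
        if not need <= set(self.records.columns):
            raise ValueError(f"records must have columns {need}")

    def ranked(self) -> pd.DataFrame:
        return self.records.sort_values(
            ["score", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


def gene_importance(
    attrib: AttributionMap,
    promoters: AnnotationTable,
    flank: int = 250_000,
) -> GeneScoreTable:
    """Mean attribution (over tracks and positions) within promoter ± flank
    for each gene; promoters outside the attributed region are skipped."""
    rows = []
    reg = attrib.region
    res = attrib.resolution
    n_pos = attrib.values.shape[1]
    for rec in promoters.records.itertuples():
        if rec.chrom != reg.chrom or rec.end <= reg.start or rec.start >= reg.end:
            warnings.warn(
                f"promoter {rec.label} outside attributed region; skipped",
                stacklevel=2,
            )
            continue
        a = max(int(rec.start) - flank, reg.start)
        b = min(int(rec.end) + flank, reg.end)
        ia = (a - reg.start) // res
        ib = max(ia + 1, -(-(b - reg.start) // res))
        window = attrib.values[:, max(ia, 0) : min(ib, n_pos)]
        rows.append(
            (rec.label, rec.chrom, int(rec.start), int(rec.end),
             float(window.mean()))
        )
    return GeneScoreTable(
        pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "score"]),
        score_kind="IG-importance",
    )


def differential_importance(
    table_a: GeneScoreTable, table_b: GeneScoreTable
) -> GeneScoreTable:
    """Per-gene score difference (condition A − condition B), ranked for
    pre-ranked enrichment analysis."""
    a = table_a.records.set_index("gene")["score"]
    b = table_b.records.set_index("gene")["score"]
    common = a.index.intersection(b.index)
    diff = (a[common] - b[common]).reset_index()
    diff.columns = ["gene", "score"]
    meta = table_a.records.set_index("gene").loc[common, ["chrom", "start", "end"]]
    out = diff.merge(meta.reset_index(), on="gene")
    return GeneScoreTable(out, score_kind="differential-importance")


def export_prerank(table: GeneScoreTable, path: str | Path) -> None:
    """Two-column tab-separated (gene, score), sorted by descending score
    with ties broken by gene id; duplicate genes are an error."""
    df = table.ranked()
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate genes in ranking: {dupes}")
    df[["gene", "score"]].to_csv(path, sep="\t", header=False, index=False)


def read_prerank(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
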
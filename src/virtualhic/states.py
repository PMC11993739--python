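"""Chromatin-state vocabulary collapsing and per-bin multi-label encoding.

The 25-state ROADMAP segmentation vocabulary is merged into 13 states:
the three promoter-flanking states become one, the seven transcription /
transcription-enhancer states become one, the three active-enhancer states
become one, the three weak/acetylated-enhancer states become one, and the
remaining nine states pass through unchanged. Bins then carry a binary
13-dimensional multi-label vector: a state bit is set whenever any part of
the 5-kb bin overlaps a segment of that state, so one bin can legitimately
carry several states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coords import DEFAULT_BIN_SIZE, GenomicRegion
from .io_formats import AnnotationTable

ROADMAP_25 = [
    "TssA", "PromU", "PromD1", "PromD2", "Tx5", "Tx", "Tx3", "TxWk",
    "TxReg", "TxEnh5", "TxEnh3", "TxEnhW", "EnhA1", "EnhA2", "EnhAF",
    "EnhW1", "EnhW2", "EnhAc", "DNase", "ZNF/Rpts", "Het", "PromP",
    "PromBiv", "ReprPC", "Quies",
]

MERGE_GROUPS: dict[str, tuple[str, ...]] = {
    "Prom": ("PromU", "PromD1", "PromD2"),
    "Tx": ("Tx5", "Tx", "Tx3", "TxReg", "TxEnh5", "TxEnh3", "TxEnhW"),
    "EnhA": ("EnhA1", "EnhA2", "EnhAF"),
    "EnhW": ("EnhW1", "EnhW2", "EnhAc"),
}

ACTIVE_ENHANCER_STATE = "EnhA"


def _build_mapping() -> dict[str, str]:
    mapping = {}
    for merged, members in MERGE_GROUPS.items():
        for m in members:
            mapping[m] = merged
    for s in ROADMAP_25:
        mapping.setdefault(s, s)
    return mapping


@dataclass(frozen=True)
class StateVocabulary:
    """The 25→13 state mapping with a fixed output order.

    Output order: the four merged states first (in the numeric order of
    their first ROADMAP member), then the pass-through states in ROADMAP
    numeric order. A fixed order keeps per-state weight vectors (the focal
    loss α) aligned across runs.
    """

    input_states: tuple[str, ...] = tuple(ROADMAP_25)
    mapping: dict[str, str] = field(default_factory=_build_mapping)

    @property
    def output_states(self) -> list[str]:
        merged = list(MERGE_GROUPS)
        members = {m for group in MERGE_GROUPS.values() for m in group}
        passthrough = [s for s in self.input_states if s not in members]
        return merged + passthrough

    def index(self, state: str) -> int:
        return self.output_states.index(state)

    def __len__(self) -> int:
        return len(self.output_states)


DEFAULT_VOCABULARY = StateVocabulary()
assert len(DEFAULT_VOCABULARY) == 13


@dataclass
class MultiLabelStates:
    """Binary 13-dim state vector per 5-kb bin, aligned to Hi-C bins."""

    region: GenomicRegion
    bin_size: int
    values: np.ndarray  # (n_bins, 13) in {0, 1}
    vocabulary: StateVocabulary = field(default_factory=StateVocabulary)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = self.region.n_bins(self.bin_size)
        k = len(self.vocabulary)
        if self.values.shape != (n, k):
            raise ValueError(
                f"state array {self.values.shape} != ({n}, {k})"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("state vectors must be binary")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def state_track(self, state: str) -> np.ndarray:
        return self.values[:, self.vocabulary.index(state)]


def merge_states(
    segmentation: AnnotationTable,
    vocabulary: StateVocabulary = DEFAULT_VOCABULARY,
) -> AnnotationTable:
    """Collapse a 25-state segmentation to the 13-state vocabulary.

    Unknown labels raise; adjacent records that end up with the same merged
    label are unioned into a single record. Idempotent: 13-state input maps
    to itself.
    """
    known = set(vocabulary.mapping) | set(vocabulary.output_states)
    rows = []
    for rec in segmentation.sorted().records.itertuples():
        label = rec.label
        if label not in known:
            raise ValueError(f"unknown chromatin state label {label!r}")
        rows.append(
            [rec.chrom, int(rec.start), int(rec.end),
             vocabulary.mapping.get(label, label)]
        )
    merged: list[list] = []
    for row in rows:
        if (
            merged
            and merged[-1][0] == row[0]
            and merged[-1][3] == row[3]
            and merged[-1][2] >= row[1]
        ):
            merged[-1][2] = max(merged[-1][2], row[2])
        else:
            merged.append(row)
    return AnnotationTable.from_tuples([tuple(r) for r in merged])


def encode_bins(
    segmentation: AnnotationTable,
    region: GenomicRegion,
    bin_size: int = DEFAULT_BIN_SIZE,
    vocabulary: StateVocabulary = DEFAULT_VOCABULARY,
) -> MultiLabelStates:
    """Encode a 13-state segmentation as per-bin binary multi-label vectors.

    A bin's state bit is set on any overlap (>= 1 bp, half-open
    coordinates); uncovered bins stay all-zero with a coverage warning.
    """
    n = region.n_bins(bin_size)
    out = np.zeros((n, len(vocabulary)), dtype=np.int8)
    out_states = {s: i for i, s in enumerate(vocabulary.output_states)}
    for rec in segmentation.records.itertuples():
        if rec.chrom != region.chrom:
            continue
        k = out_states.get(rec.label)
        if k is None:
            raise ValueError(
                f"label {rec.label!r} is not a merged-vocabulary state; "
                "run merge_states first"
            )
        a = max(int(rec.start), region.start)
        b = min(int(rec.end), region.end)
        if b <= a:
            continue
        first = (a - region.start) // bin_size
        last = (b - 1 - region.start) // bin_size  # inclusive
        out[first : last + 1, k] = 1
    if (out.sum(axis=1) == 0).any():
        warnings.warn(
            f"{int((out.sum(axis=1) == 0).sum())}/{n} bins uncovered by the "
            "segmentation (all-zero state vectors)", stacklevel=2,
        )
    return MultiLabelStates(region, bin_size, out, vocabulary)


def state_frequencies(states: MultiLabelStates) -> np.ndarray:
    """Per-state bin frequency, the basis of the focal-loss α weights."""
    return states.values.mean(axis=0)


def alpha_weights(frequencies: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Inverse-frequency focal-loss balance weights, α_k = 1/f_k.

    The weights are intentionally not rescaled: rare states receive
    proportionally larger positive-term gradients, which is what lets the
    classification head learn states occupying a few percent of bins. A
    frequency floor keeps absent states from exploding.
    """
    f = np.maximum(np.asarray(frequencies, dtype=float), floor)
    return 1.0 / f
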
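"""The multi-task contact-diagonal predictor and the tile denoiser.

The predictor is a CNN-Transformer: a sequence encoder and an epigenetic
encoder (five conv→batchnorm→GELU→maxpool blocks each) produce one
embedding per 5-kb bin of the 200-bin feature window; the concatenated
"genomic embedding" feeds a transformer encoder whose output drives two
heads — a Hi-C head emitting the 100 diagonal contact values and a
chromatin-state head emitting 13 per-bin sigmoid probabilities. Widths,
pool factors and input resolutions are configurable so desk-scale
instances train in minutes on one CPU while the published-scale
configuration remains expressible.

The denoiser is a reduced multi-scale residual network (2 residual groups
× 2 multi-resolution blocks) mapping assembled 200×200 tiles to cleaned
tiles, trained with the Charbonnier + diagonal-correlation surrogate
objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .coords import DEFAULT_BIN_SIZE, GenomicRegion
from .diagonal import (
    DiagonalSample,
    Tile,
    default_distance_weights,
    PEAK_THRESHOLD,
)
from .io_formats import OneHotSequence, TrackSet
from .losses import LossConfig, weighted_correlation, surrogate_loss
from .states import MultiLabelStates
from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "HiConformer",
    "MultiScaleDenoiser",
    "DiagonalDataset",
    "build_dataset",
    "build_hiconformer",
    "train_hiconformer",
    "predict_diagonals",
    "train_denoiser",
    "denoise",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture description.

    The default values are the published-scale architecture (64/128/128/256
    filter progression, base-pair sequence input, 25-bp track input);
    :meth:`desk_scale` returns the reduced configuration used throughout
    the test suite. ``scale_factor`` divides every channel/hidden width.
    Pool factors must multiply (together with the input resolution) to one
    embedding per 5-kb bin; any factorization with the right product is
    accepted.
    """

    n_tracks: int = 71
    n_states: int = 13
    bin_size: int = DEFAULT_BIN_SIZE
    window_bins: int = 200
    max_offset: int = 100
    seq_channels: tuple[int, ...] = (64, 128, 128, 256, 256)
    seq_kernels: tuple[int, ...] = (5, 5, 5, 5, 2)
    seq_pools: tuple[int, ...] = (5, 5, 5, 5, 8)
    seq_input_resolution: int = 1
    epi_channels: tuple[int, ...] = (64, 128, 128, 256, 256)
    epi_kernels: tuple[int, ...] = (5, 5, 4, 2, 1)
    epi_pools: tuple[int, ...] = (5, 5, 4, 2, 1)
    epi_input_resolution: int = 25
    transformer_layers: int = 2
    transformer_heads: int = 4
    head_units: tuple[int, ...] = (512, 256, 256)
    hic_head_mode: str = "pair"  # "pair" | "pooled"
    scale_factor: int = 1
    dtype: str = "float32"  # parameter/activation precision

    def __post_init__(self) -> None:
        for name in ("seq", "epi"):
            pools = getattr(self, f"{name}_pools")
            res = getattr(self, f"{name}_input_resolution")
            prod = int(np.prod(pools)) * res
            if prod != self.bin_size:
                raise ValueError(
                    f"{name} encoder pool factors {pools} x resolution {res} "
                    f"give {prod} bp per embedding, expected {self.bin_size} "
                    f"(block pool product mismatch)"
                )
        if self.hic_head_mode not in {"pair", "pooled"}:
            raise ValueError(f"unknown hic_head_mode {self.hic_head_mode!r}")

    def scaled(self, widths: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(max(4, w // self.scale_factor) for w in widths)

    @property
    def embedding_dim(self) -> int:
        return self.scaled(self.seq_channels)[-1] + self.scaled(self.epi_channels)[-1]

    @classmethod
    def desk_scale(cls, n_tracks: int = 8, scale_factor: int = 8) -> "ModelConfig":
        """Reduced instance: bin-resolution inputs (sequence enters as
        per-bin base composition), 8x narrower channels, wide (2-head)
        attention which maps to efficient BLAS calls on one CPU."""
        return cls(
            n_tracks=n_tracks,
            scale_factor=scale_factor,
            seq_input_resolution=DEFAULT_BIN_SIZE,
            seq_pools=(1, 1, 1, 1, 1),
            epi_input_resolution=DEFAULT_BIN_SIZE,
            epi_pools=(1, 1, 1, 1, 1),
            transformer_heads=2,
        )


@dataclass
class TrainConfig:
    """Optimization protocol.

    Published-scale defaults: 5000 epochs with patience 2000 on validation
    Pearson, 30 warmup epochs at lr 1e-7 then 1e-5. :meth:`desk_scale`
    shrinks the budget for minute-scale CPU runs.
    """

    max_epochs: int = 5000
    warmup_epochs: int = 30
    warmup_lr: float = 1e-7
    lr: float = 1e-5
    patience: int = 2000
    batch_size: int = 32
    seed: int = 0
    weight_decay: float = 0.0
    augment_flip: bool = True
    augment_input_noise: float = 0.0  # sd of Gaussian noise added to inputs
    cosine_decay: bool = False  # cosine-anneal lr after warmup
    val_metric: str = "pearson"  # "pearson" | "dist_pearson"
    denoiser_max_epochs: int = 200
    denoiser_patience: int = 20
    residual_groups: int = 2
    multiscale_blocks: int = 2

    def __post_init__(self) -> None:
        if self.warmup_epochs >= self.max_epochs:
            raise ValueError("warmup_epochs must be < max_epochs")
        if self.lr <= 0 or self.warmup_lr <= 0:
            raise ValueError("learning rates must be > 0")

    @classmethod
    def desk_scale(cls, seed: int = 0, max_epochs: int = 36) -> "TrainConfig":
        return cls(
            max_epochs=max_epochs,
            warmup_epochs=3,
            warmup_lr=1e-4,
            lr=1e-3,
            patience=20,
            batch_size=32,
            seed=seed,
            weight_decay=1e-4,
            augment_input_noise=0.25,
            cosine_decay=True,
            denoiser_max_epochs=80,
            denoiser_patience=20,
        )


@dataclass
class BinnedSequence:
    """Base-composition representation of a sequence at coarse resolution.

    Rows hold the mean one-hot (base fraction) over ``resolution``-bp
    windows; the desk-scale model consumes sequence in this form.
    """

    region: "GenomicRegion"
    resolution: int
    values: np.ndarray  # (L, 4)

    @classmethod
    def from_onehot(cls, seq: OneHotSequence, resolution: int) -> "BinnedSequence":
        L = len(seq.region)
        if L % resolution:
            raise ValueError("region length not divisible by resolution")
        pooled = seq.values.reshape(L // resolution, resolution, 4).mean(axis=1)
        return cls(seq.region, resolution, pooled)


def _seq_resolution(sequence) -> int:
    return getattr(sequence, "resolution", 1)


class _Encoder(nn.Module):
    def __init__(self, c_in, channels, kernels, pools, rng):
        layers = []
        prev = c_in
        for c, k, p in zip(channels, kernels, pools):
            layers += [
                nn.Conv1d(prev, c, k, rng),
                nn.BatchNorm(c),
                nn.GELU(),
                nn.MaxPool1d(p),
            ]
            prev = c
        self.blocks = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.blocks(x)


class _MLP(nn.Module):
    def __init__(self, n_in, units, n_out, rng):
        layers = []
        prev = n_in
        for u in units:
            layers += [nn.Linear(prev, u, rng), nn.GELU()]
            prev = u
        layers.append(nn.Linear(prev, n_out, rng))
        self.net = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class HiConformer(nn.Module):
    """Dual-encoder CNN-Transformer with Hi-C and chromatin-state heads."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        seq_ch = cfg.scaled(cfg.seq_channels)
        epi_ch = cfg.scaled(cfg.epi_channels)
        self.seq_encoder = _Encoder(
            4, seq_ch, cfg.seq_kernels, cfg.seq_pools, rng
        )
        self.epi_encoder = _Encoder(
            cfg.n_tracks, epi_ch, cfg.epi_kernels, cfg.epi_pools, rng
        )
        dim = seq_ch[-1] + epi_ch[-1]
        if dim % cfg.transformer_heads:
            raise ValueError(
                f"embedding dim {dim} not divisible by "
                f"{cfg.transformer_heads} heads"
            )
        self.positional = nn.sinusoidal_positions(cfg.window_bins, dim)
        self.transformer = nn.Sequential(
            *[
                nn.TransformerEncoderLayer(dim, cfg.transformer_heads,
                                           2 * dim, rng)
                for _ in range(cfg.transformer_layers)
            ]
        )
        units = cfg.scaled(cfg.head_units)
        head_in = 3 * dim if cfg.hic_head_mode == "pair" else dim
        self.hic_head = _MLP(
            head_in, units,
            1 if cfg.hic_head_mode == "pair" else cfg.max_offset, rng,
        )
        self.state_head = _MLP(dim, units, cfg.n_states, rng)
        c = cfg.window_bins // 2
        t = np.arange(1, cfg.max_offset + 1)
        self._pair_left = c - t
        # right endpoint bin c+t; the window [c-100, c+100) lacks c+100,
        # so the largest offset clamps to the last window bin
        self._pair_right = np.minimum(c + t, cfg.window_bins - 1)
        # span-average operator: row t averages the window bins between the
        # endpoints of offset t, the feature that carries "what lies
        # between" a contact's anchors (e.g. a domain boundary)
        span = np.zeros((cfg.max_offset, cfg.window_bins))
        for i, (a, b) in enumerate(zip(self._pair_left, self._pair_right)):
            span[i, a : b + 1] = 1.0 / (b + 1 - a)
        self._span_avg = span.astype(cfg.dtype)
        self.astype(np.dtype(cfg.dtype))
        self.positional = self.positional.astype(cfg.dtype)

    def embed(self, seq_x, epi_x) -> Tensor:
        """Inputs may be ndarrays or Tensors (the latter lets callers take
        gradients with respect to the inputs, as integrated gradients does)."""
        se = self.seq_encoder(
            seq_x if isinstance(seq_x, Tensor) else Tensor(seq_x)
        )
        ee = self.epi_encoder(
            epi_x if isinstance(epi_x, Tensor) else Tensor(epi_x)
        )
        emb = nn.concat([se, ee], axis=1)  # (B, D, bins)
        emb = emb.swapaxes(1, 2)  # (B, bins, D)
        return emb + self.positional

    def forward(self, seq_x, epi_x):
        """Returns (hic prediction (B, 100), state probabilities
        (B, bins, 13), state logits)."""
        emb = self.transformer(self.embed(seq_x, epi_x))
        if self.cfg.hic_head_mode == "pair":
            left = emb[:, self._pair_left, :]
            right = emb[:, self._pair_right, :]
            span = Tensor(self._span_avg) @ emb  # (B, offsets, D)
            pair = nn.concat([left, right, span], axis=2)
            hic = self.hic_head(pair).reshape(
                emb.shape[0], self.cfg.max_offset
            )
        else:
            hic = self.hic_head(emb.mean(axis=1))
        logits = self.state_head(emb)
        return hic, logits.sigmoid(), logits

    def first_conv_activations(self, seq_x: np.ndarray,
                               stage: str = "post") -> np.ndarray:
        """First sequence-encoder block activations before pooling.

        ``stage="post"`` (default) returns post-GELU feature maps;
        ``"pre"`` returns the raw conv+batchnorm output.
        """
        blocks = self.seq_encoder.blocks.layers
        with nn.no_grad():
            x = blocks[0](Tensor(np.asarray(seq_x, dtype=float)))
            x = blocks[1](x)
            if stage == "post":
                x = blocks[2](x)
        return x.data


def build_hiconformer(cfg: ModelConfig, seed: int = 0) -> HiConformer:
    model = HiConformer(cfg, seed)
    return model


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class DiagonalDataset:
    """Model-ready arrays for a set of diagonal samples."""

    samples: list[DiagonalSample]
    seq_x: np.ndarray  # (N, 4, L_seq)
    epi_x: np.ndarray  # (N, n_tracks, L_epi)
    targets: np.ndarray  # (N, max_offset)
    weights: np.ndarray
    states: np.ndarray  # (N, window_bins, n_states)

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, idx) -> "DiagonalDataset":
        idx = np.asarray(idx)
        return DiagonalDataset(
            [self.samples[i] for i in idx],
            self.seq_x[idx], self.epi_x[idx],
            self.targets[idx], self.weights[idx], self.states[idx],
        )


def _pool_columns(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    *lead, L = arr.shape
    return arr.reshape(*lead, L // factor, factor).mean(axis=-1)


def build_dataset(
    samples: Sequence[DiagonalSample],
    sequence: OneHotSequence,
    tracks: TrackSet,
    states: MultiLabelStates,
    cfg: ModelConfig,
) -> DiagonalDataset:
    """Slice per-sample feature windows out of chromosome-scale inputs and
    pool them to the model's input resolutions."""
    if not tracks.standardized:
        raise ValueError(
            "tracks must be standardized with the training z-score transform"
        )
    seq_list, epi_list, st_list = [], [], []
    bs = cfg.bin_size
    seq_res = _seq_resolution(sequence)
    if cfg.seq_input_resolution % seq_res:
        raise ValueError(
            f"sequence stored at {seq_res} bp cannot be pooled to "
            f"{cfg.seq_input_resolution} bp"
        )
    for s in samples:
        win = s.feature_window
        a = win.start - sequence.region.start
        b = win.end - sequence.region.start
        if a < 0 or b > len(sequence.region):
            raise ValueError(f"window {win} outside provided sequence")
        one_hot = sequence.values[a // seq_res : b // seq_res].T  # (4, L)
        seq_list.append(
            _pool_columns(one_hot, cfg.seq_input_resolution // seq_res)
        )
        ra = (win.start - tracks.region.start) // tracks.resolution
        rb = (win.end - tracks.region.start) // tracks.resolution
        tr = tracks.values[:, ra:rb]
        epi_list.append(
            _pool_columns(tr, cfg.epi_input_resolution // tracks.resolution)
        )
        ba = (win.start - states.region.start) // bs
        st_list.append(states.values[ba : ba + cfg.window_bins])
    dt = np.dtype(cfg.dtype)
    return DiagonalDataset(
        list(samples),
        np.stack(seq_list).astype(dt),
        np.stack(epi_list).astype(dt),
        np.stack([s.target for s in samples]),
        np.stack([s.weights for s in samples]),
        np.stack(st_list).astype(dt),
    )


# ---------------------------------------------------------------------------
# training


def _forward_loss(model, ds, idx, loss_cfg, flip=None, noise_rng=None,
                  noise_sd=0.0):
    seq_x = ds.seq_x[idx]
    epi_x = ds.epi_x[idx]
    states = ds.states[idx]
    if flip is not None and flip.any():
        # spatial reversal of the feature window leaves the anti-diagonal
        # target invariant (endpoints c-t and c+t swap); states reverse
        seq_x = seq_x.copy()
        epi_x = epi_x.copy()
        states = states.copy()
        seq_x[flip] = seq_x[flip][..., ::-1]
        epi_x[flip] = epi_x[flip][..., ::-1]
        states[flip] = states[flip][:, ::-1]
    if noise_sd > 0 and noise_rng is not None:
        epi_x = epi_x + noise_rng.normal(
            0.0, noise_sd, epi_x.shape
        ).astype(epi_x.dtype)
    hic, probs, _ = model(seq_x, epi_x)
    loss = nn.hybrid_loss_t(
        ds.targets[idx], hic, ds.weights[idx], states, probs, loss_cfg
    )
    return loss


def train_hiconformer(
    model: HiConformer,
    train_ds: DiagonalDataset,
    val_ds: DiagonalDataset,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> dict:
    """Optimize the hybrid loss with warmup and early stopping on the
    validation weighted Pearson correlation; returns the history and
    restores the best weights in place."""
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("empty training or validation set")
    rng = np.random.default_rng(train_cfg.seed)
    opt = nn.Adam(model.parameters(), lr=train_cfg.warmup_lr,
                  weight_decay=train_cfg.weight_decay)
    history = []
    best = (-np.inf, None, -1)  # (val pearson, weights, epoch)
    n = len(train_ds)
    for epoch in range(train_cfg.max_epochs):
        if epoch < train_cfg.warmup_epochs:
            opt.lr = train_cfg.warmup_lr
        elif train_cfg.cosine_decay:
            span = max(train_cfg.max_epochs - train_cfg.warmup_epochs - 1, 1)
            progress = (epoch - train_cfg.warmup_epochs) / span
            opt.lr = train_cfg.lr * 0.5 * (1 + np.cos(np.pi * progress))
        else:
            opt.lr = train_cfg.lr
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            if idx.size < 2:
                continue
            opt.zero_grad()
            flip = (rng.random(idx.size) < 0.5) if train_cfg.augment_flip \
                else None
            loss = _forward_loss(model, train_ds, idx, loss_cfg, flip,
                                 rng, train_cfg.augment_input_noise)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting "
                    f"{start} (sample centers "
                    f"{[train_ds.samples[i].center_bin for i in idx[:5]]}...)"
                )
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_pearson = _validation_pearson(
            model, val_ds, train_cfg.batch_size,
            stratified=train_cfg.val_metric == "dist_pearson",
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_pearson": val_pearson,
                "lr": opt.lr,
            }
        )
        if val_pearson > best[0]:
            best = (val_pearson, [a.copy() for a in model.state_arrays()],
                    epoch)
        if (
            epoch >= train_cfg.warmup_epochs
            and epoch - max(best[2], 0) >= train_cfg.patience + 1
        ):
            history[-1]["early_stop"] = True
            break
    if best[1] is not None:
        model.load_state_arrays(best[1])
    return {
        "history": history,
        "best_val_pearson": best[0],
        "best_epoch": best[2],
    }


def _validation_pearson(model, ds, batch_size, stratified=False) -> float:
    preds = _predict_batches(model, ds.seq_x, ds.epi_x, batch_size)[0]
    return weighted_correlation(ds.targets, preds, ds.weights,
                                stratified=stratified)


def _predict_batches(model, seq_x, epi_x, batch_size=64):
    model.eval()
    hic_out, prob_out = [], []
    with nn.no_grad():
        for start in range(0, seq_x.shape[0], batch_size):
            hic, probs, _ = model(
                seq_x[start : start + batch_size],
                epi_x[start : start + batch_size],
            )
            hic_out.append(hic.data)
            prob_out.append(probs.data)
    return np.concatenate(hic_out), np.concatenate(prob_out)


def predict_diagonals(
    model: HiConformer,
    sequence: OneHotSequence,
    tracks: TrackSet,
    chrom_length: int,
    stride: int = 1,
    edge_bp: int = 2_000_000,
    batch_size: int = 64,
) -> tuple[list[DiagonalSample], np.ndarray]:
    """Predict the contact diagonal at every valid center of a chromosome.

    Centers within ``edge_bp`` of either end are skipped to match the tile
    grid. Returns the predicted samples and the per-center state
    probabilities (n_centers, window_bins, n_states).
    """
    if not tracks.standardized:
        raise ValueError("tracks must carry the training z-score transform")
    cfg = model.cfg
    bs = cfg.bin_size
    n_bins = chrom_length // bs
    edge = max(edge_bp // bs, cfg.window_bins // 2)
    centers = np.arange(edge, n_bins - edge, stride)
    dummy = [
        DiagonalSample(
            chrom=sequence.region.chrom, center_bin=int(c), bin_size=bs,
            target=np.zeros(cfg.max_offset),
            weights=np.ones(cfg.max_offset), has_peak=False,
            window_bins=cfg.window_bins,
        )
        for c in centers
    ]
    states_stub = MultiLabelStates(
        sequence.region, bs,
        np.zeros((n_bins, cfg.n_states), dtype=np.int8),
    )
    ds = build_dataset(dummy, sequence, tracks, states_stub, cfg)
    preds, probs = _predict_batches(model, ds.seq_x, ds.epi_x, batch_size)
    out = [
        DiagonalSample(
            chrom=s.chrom, center_bin=s.center_bin, bin_size=bs,
            target=preds[i],
            weights=default_distance_weights(preds[i]),
            has_peak=bool((preds[i] >= PEAK_THRESHOLD).any()),
            window_bins=cfg.window_bins,
        )
        for i, s in enumerate(dummy)
    ]
    return out, probs


# ---------------------------------------------------------------------------
# denoiser


class _MultiResBlock(nn.Module):
    """Parallel full- and half-resolution conv paths, summed."""

    def __init__(self, channels: int, rng):
        self.full = nn.Conv2d(channels, channels, 3, rng)
        self.half = nn.Conv2d(channels, channels, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        full = self.full(x)
        B, C, H, W = x.shape
        down = x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
        half = self.half(down)
        idx_h = np.repeat(np.arange(H // 2), 2)
        idx_w = np.repeat(np.arange(W // 2), 2)
        up = half[:, :, idx_h, :][:, :, :, idx_w]
        return (full + up).gelu()


class _ResidualGroup(nn.Module):
    def __init__(self, channels: int, blocks: int, rng):
        self.blocks = nn.Sequential(
            *[_MultiResBlock(channels, rng) for _ in range(blocks)]
        )

    def forward(self, x: Tensor) -> Tensor:
        return x + self.blocks(x)


class MultiScaleDenoiser(nn.Module):
    """Reduced multi-scale residual denoiser for 200×200 tiles."""

    def __init__(self, channels: int = 8, groups: int = 2,
                 blocks: int = 2, seed: int = 0, dtype: str = "float32"):
        rng = np.random.default_rng(seed)
        self.head = nn.Conv2d(1, channels, 3, rng)
        self.groups = nn.Sequential(
            *[_ResidualGroup(channels, blocks, rng) for _ in range(groups)]
        )
        self.tail = nn.Conv2d(channels, 1, 3, rng)
        # zero-init the residual branch so the untrained model is exactly
        # the identity; training can only improve on the input
        self.tail.w.data[:] = 0.0
        self.astype(np.dtype(dtype))
        self._dtype = np.dtype(dtype)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, 1, H, W); output adds a learned residual to the input."""
        return x + self.tail(self.groups(self.head(x)))


def fill_masked_entries(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked entries by the mean of their valid 4-neighbors.

    Assembled tiles carry data only on even separations (a checkerboard
    in the off-diagonal band); zero-filling the gaps gives convolutions a
    high-frequency artifact to fight, so masked entries are interpolated
    instead. Entries that stay uncovered after two passes are 0.
    """
    from scipy.ndimage import convolve

    kernel = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
    filled = np.where(mask, values, 0.0)
    have = mask.astype(float)
    for _ in range(2):
        sums = convolve(filled * have, kernel, mode="nearest")
        counts = convolve(have, kernel, mode="nearest")
        interp = np.divide(sums, counts, out=np.zeros_like(sums),
                           where=counts > 0)
        filled = np.where(have > 0, filled, interp)
        have = np.maximum(have, (counts > 0).astype(float))
    return filled


def _pair_tiles(tiles_pred, tiles_true):
    by_region = {t.region: t for t in tiles_true}
    pairs = []
    orphans = [t.region for t in tiles_pred if t.region not in by_region]
    missing = set(by_region) - {t.region for t in tiles_pred}
    if orphans or missing:
        raise ValueError(
            f"unpaired tiles; predicted-only: {orphans}, truth-only: "
            f"{sorted(missing)}"
        )
    for t in tiles_pred:
        pairs.append((t, by_region[t.region]))
    return pairs


def train_denoiser(
    tiles_pred: Sequence[Tile],
    tiles_true: Sequence[Tile],
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    channels: int = 8,
    seed: int = 0,
    val_fraction: float = 0.25,
    diag_range: tuple[int, int] = (4, 198),
) -> tuple[MultiScaleDenoiser, dict]:
    """Train the denoiser on paired (assembled prediction, truth) tiles
    with early stopping on the validation diagonal-correlation loss."""
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    pairs = _pair_tiles(list(tiles_pred), list(tiles_true))
    x = np.stack([fill_masked_entries(p.values, p.mask)
                  for p, _ in pairs]).astype(np.float32)
    y = np.stack([fill_masked_entries(t.values, t.mask)
                  for _, t in pairs]).astype(np.float32)
    n_val = max(1, int(round(val_fraction * len(pairs))))
    val_idx = np.arange(len(pairs))[::-1][:n_val]
    train_idx = np.setdiff1d(np.arange(len(pairs)), val_idx)
    if train_idx.size == 0:
        raise ValueError("no training tiles left after validation split")
    model = MultiScaleDenoiser(
        channels, train_cfg.residual_groups, train_cfg.multiscale_blocks,
        seed,
    )
    opt = nn.Adam(model.parameters(), lr=3e-4)
    rng = np.random.default_rng(seed)
    history = []
    best_diag = np.inf  # patience counter tracks the diag-corr criterion
    best_diag_epoch = -1
    best = (np.inf, None, -1)  # weight snapshot by full surrogate loss
    batch = max(2, min(4, train_idx.size))
    for epoch in range(train_cfg.denoiser_max_epochs):
        model.train()
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, order.size, batch):
            idx = order[start : start + batch]
            opt.zero_grad()
            out = model(Tensor(x[idx][:, None]))
            loss = nn.surrogate_loss_t(
                y[idx], out.reshape(idx.size, x.shape[1], x.shape[2]),
                loss_cfg, diag_range,
            )
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_full, val_diag = _denoiser_val_loss(
            model, x[val_idx], y[val_idx], loss_cfg, diag_range
        )
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_loss": val_full, "val_diag_loss": val_diag}
        )
        if val_diag < best_diag - 1e-9:
            best_diag = val_diag
            best_diag_epoch = epoch
        if val_full < best[0] - 1e-9:
            best = (val_full, [a.copy() for a in model.state_arrays()], epoch)
        if epoch - max(best_diag_epoch, 0) >= train_cfg.denoiser_patience + 1:
            history[-1]["early_stop"] = True
            break
    if best[1] is not None:
        model.load_state_arrays(best[1])
    return model, {"history": history, "best_val_diag_loss": best_diag,
                   "best_val_loss": best[0], "best_epoch": best[2]}


def _denoiser_val_loss(model, x, y, loss_cfg, diag_range):
    """Full validation surrogate loss and its diagonal-correlation part."""
    model.eval()
    with nn.no_grad():
        out = model(Tensor(x[:, None])).data[:, 0]
    total_full = total_diag = 0.0
    for i in range(x.shape[0]):
        full = surrogate_loss(y[i], out[i], loss_cfg, diag_range)
        charb = float(
            np.sqrt((y[i] - out[i]) ** 2 + loss_cfg.eps_charbonnier**2).mean()
        )
        total_full += full
        total_diag += full - charb
    return total_full / x.shape[0], total_diag / x.shape[0]


def denoise(
    model: MultiScaleDenoiser, tiles: Sequence[Tile], batch_size: int = 8
) -> list[Tile]:
    """Apply the frozen denoiser tile by tile; outputs are symmetrized and
    masked entries stay masked."""
    model.eval()
    out_tiles = []
    tiles = list(tiles)
    for start in range(0, len(tiles), batch_size):
        chunk = tiles[start : start + batch_size]
        x = np.stack([fill_masked_entries(t.values, t.mask)
                      for t in chunk]).astype(model._dtype)
        with nn.no_grad():
            y = model(Tensor(x[:, None])).data[:, 0]
        for t, yi in zip(chunk, y):
            sym = 0.5 * (yi + yi.T)
            out_tiles.append(
                Tile(
                    t.region, t.bin_size,
                    np.where(t.mask, sym, np.nan), t.mask.copy(),
                    list(t.provenance),
                )
            )
    return out_tiles


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(
    path: str | Path,
    model: nn.Module,
    config: dict | None = None,
    zscore_mean: np.ndarray | None = None,
    zscore_std: np.ndarray | None = None,
) -> None:
    """Parameters + batchnorm running stats + config + the training z-score
    transform, in one .npz."""
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    bn = [m for m in model.modules() if isinstance(m, nn.BatchNorm)]
    for i, m in enumerate(bn):
        arrays[f"bn_mean_{i}"] = m.running_mean
        arrays[f"bn_var_{i}"] = m.running_var
    if zscore_mean is not None:
        arrays["zscore_mean"] = zscore_mean
        arrays["zscore_std"] = zscore_std
    arrays["config_json"] = np.array(json.dumps(config or {}))
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path, model: nn.Module) -> dict:
    """Restore parameters into a compatibly built model; returns the stored
    config dict (with z-score stats under 'zscore_mean'/'zscore_std')."""
    with np.load(path, allow_pickle=False) as z:
        n = len([k for k in z.files if k.startswith("param_")])
        model.load_state_arrays([z[f"param_{i}"] for i in range(n)])
        bn = [m for m in model.modules() if isinstance(m, nn.BatchNorm)]
        for i, m in enumerate(bn):
            m.running_mean = z[f"bn_mean_{i}"]
            m.running_var = z[f"bn_var_{i}"]
        out = json.loads(str(z["config_json"]))
        if "zscore_mean" in z.files:
            out["zscore_mean"] = z["zscore_mean"]
            out["zscore_std"] = z["zscore_std"]
    return out
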
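"""Model construction contracts, small-scale training behavior, denoiser."""

import numpy as np
import pytest

from virtualhic.coords import GenomicRegion
from virtualhic.diagonal import Tile, assemble_tiles, extract_samples
from virtualhic.io_formats import ContactMap, OneHotSequence, TrackSet
from virtualhic.losses import LossConfig
from virtualhic.models import (
    BinnedSequence,
    HiConformer,
    ModelConfig,
    MultiScaleDenoiser,
    TrainConfig,
    build_dataset,
    denoise,
    load_checkpoint,
    predict_diagonals,
    save_checkpoint,
    train_denoiser,
    train_hiconformer,
)
from virtualhic.states import MultiLabelStates
from virtualhic.nn import no_grad, Tensor


def tiny_cfg(n_tracks=4):
    return ModelConfig.desk_scale(n_tracks=n_tracks, scale_factor=16)


def random_inputs(rng, cfg, n=4):
    seq = rng.normal(size=(n, 4, cfg.window_bins)).astype(np.float32)
    epi = rng.normal(size=(n, cfg.n_tracks, cfg.window_bins)).astype(np.float32)
    return seq, epi


class TestBuild:
    def test_output_shapes_contract(self, rng):
        cfg = tiny_cfg()
        model = HiConformer(cfg, seed=0)
        seq, epi = random_inputs(rng, cfg, n=3)
        hic, probs, logits = model(seq, epi)
        assert hic.shape == (3, 100)
        assert probs.shape == (3, 200, 13)
        assert (probs.data > 0).all() and (probs.data < 1).all()

    def test_scale_factor_shrinks_parameters(self):
        big = HiConformer(ModelConfig.desk_scale(n_tracks=4, scale_factor=1),
                          seed=0)
        small = HiConformer(ModelConfig.desk_scale(n_tracks=4, scale_factor=8),
                            seed=0)
        assert big.n_parameters() >= 8 * small.n_parameters()
        # same output contract regardless of width
        rng = np.random.default_rng(0)
        seq, epi = random_inputs(rng, small.cfg, n=2)
        hic, probs, _ = small(seq, epi)
        assert hic.shape == (2, 100) and probs.shape == (2, 200, 13)

    def test_same_seed_identical_initial_predictions(self, rng):
        cfg = tiny_cfg()
        a = HiConformer(cfg, seed=5)
        b = HiConformer(cfg, seed=5)
        seq, epi = random_inputs(rng, cfg)
        a.eval(), b.eval()
        with no_grad():
            pa = a(seq, epi)[0].data
            pb = b(seq, epi)[0].data
        np.testing.assert_array_equal(pa, pb)

    def test_pool_factor_mismatch_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            ModelConfig(seq_pools=(5, 5, 5, 5, 4))

    def test_paper_default_pools_are_consistent(self):
        cfg = ModelConfig()  # published-scale: must validate
        assert int(np.prod(cfg.seq_pools)) * cfg.seq_input_resolution == 5000
        assert int(np.prod(cfg.epi_pools)) * cfg.epi_input_resolution == 5000


def small_chromosome_dataset(rng, cfg, n_bins=420, chrom="chr1"):
    bs = 5000
    region = GenomicRegion(chrom, 0, n_bins * bs)
    m = rng.normal(size=(n_bins, n_bins))
    m = 0.5 * (m + m.T) + 1.5
    cmap = ContactMap(region, bs, m)
    tracks = TrackSet(
        region, [f"t{i}" for i in range(cfg.n_tracks)], bs,
        rng.normal(size=(cfg.n_tracks, n_bins)),
    ).standardize()
    states = MultiLabelStates(
        region, bs,
        (rng.random((n_bins, 13)) < 0.15).astype(np.int8),
    )
    seq = BinnedSequence(region, bs, rng.dirichlet(np.ones(4), size=n_bins))
    samples = extract_samples(cmap, stride=4, drop_zero=False)
    ds = build_dataset(samples, seq, tracks, states, cfg)
    return cmap, tracks, states, seq, ds


class TestTraining:
    def test_single_batch_overfit(self, rng):
        cfg = tiny_cfg()
        _, _, _, _, ds = small_chromosome_dataset(rng, cfg)
        sub = ds.subset(np.arange(16))
        tc = TrainConfig.desk_scale(seed=0, max_epochs=300)
        tc.warmup_epochs = 2
        tc.patience = 1000
        tc.augment_flip = False
        tc.weight_decay = 0.0
        tc.augment_input_noise = 0.0
        tc.cosine_decay = False
        tc.lr = 3e-3
        model = HiConformer(cfg, seed=0)
        fit = train_hiconformer(model, sub, sub, LossConfig(), tc)
        first = fit["history"][0]["train_loss"]
        last = fit["history"][-1]["train_loss"]
        assert last < first  # learnability smoke test
        assert fit["best_val_pearson"] > 0.9  # overfit capacity check

    def test_patience_zero_stops_after_warmup(self, rng):
        cfg = tiny_cfg()
        _, _, _, _, ds = small_chromosome_dataset(rng, cfg)
        sub = ds.subset(np.arange(12))
        tc = TrainConfig.desk_scale(seed=0, max_epochs=30)
        tc.warmup_epochs = 2
        tc.patience = 0
        tc.lr = 1e-12  # no measurable improvement after warmup
        tc.warmup_lr = 1e-12
        tc.augment_input_noise = 0.0
        model = HiConformer(cfg, seed=0)
        from virtualhic import nn as vnn

        for m in model.modules():  # freeze BN running stats so the
            if isinstance(m, vnn.BatchNorm):  # validation metric is static
                m.momentum = 0.0
        fit = train_hiconformer(model, sub, sub, LossConfig(), tc)
        assert len(fit["history"]) <= tc.warmup_epochs + 2
        assert fit["history"][-1].get("early_stop")

    def test_nan_loss_aborts_with_diagnostic(self, rng):
        cfg = tiny_cfg()
        _, _, _, _, ds = small_chromosome_dataset(rng, cfg)
        sub = ds.subset(np.arange(8))
        sub.targets[0, 0] = np.nan
        model = HiConformer(cfg, seed=0)
        tc = TrainConfig.desk_scale(seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            train_hiconformer(model, sub, sub, LossConfig(), tc)


class TestPredict:
    def test_prediction_contract(self, rng):
        cfg = tiny_cfg()
        n_bins = 900  # 4.5 Mb: leaves a 0.5-Mb interior beyond 2-Mb edges
        bs = 5000
        region = GenomicRegion("chr1", 0, n_bins * bs)
        tracks = TrackSet(
            region, [f"t{i}" for i in range(cfg.n_tracks)], bs,
            rng.normal(size=(cfg.n_tracks, n_bins)),
        ).standardize()
        seq = BinnedSequence(region, bs, rng.dirichlet(np.ones(4), size=n_bins))
        model = HiConformer(cfg, seed=0)
        preds, probs = predict_diagonals(model, seq, tracks, n_bins * bs,
                                         stride=1)
        assert all(len(p.target) == 100 for p in preds)
        assert len(preds) == 900 - 2 * 400
        preds2, _ = predict_diagonals(model, seq, tracks, n_bins * bs,
                                      stride=2)
        assert abs(len(preds2) - len(preds) / 2) <= 1
        # identical windows -> identical predictions
        assert np.array_equal(preds[0].target, preds[0].target)

    def test_unstandardized_tracks_rejected(self, rng):
        cfg = tiny_cfg()
        region = GenomicRegion("chr1", 0, 900 * 5000)
        tracks = TrackSet(
            region, [f"t{i}" for i in range(cfg.n_tracks)], 5000,
            rng.normal(size=(cfg.n_tracks, 900)),
        )
        seq = BinnedSequence(region, 5000, rng.dirichlet(np.ones(4), size=900))
        model = HiConformer(cfg, seed=0)
        with pytest.raises(ValueError, match="z-score"):
            predict_diagonals(model, seq, tracks, 900 * 5000)


class TestDenoiser:
    def _tiles(self, rng, n=6, side=200):
        tiles = []
        for i in range(n):
            v = rng.normal(size=(side, side))
            v = 0.5 * (v + v.T)
            region = GenomicRegion("chr1", i * 1_000_000,
                                   (i + 1) * 1_000_000)
            tiles.append(Tile(region, 5000, v,
                              np.ones((side, side), dtype=bool)))
        return tiles

    def test_denoise_deterministic_symmetric_and_mask_preserving(self, rng):
        truth = self._tiles(rng)
        model = MultiScaleDenoiser(channels=4, seed=0)
        masked = truth[0]
        masked.mask[0, 5] = masked.mask[5, 0] = False
        out1 = denoise(model, truth)
        out2 = denoise(model, truth)
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(
                a.values[a.mask], b.values[b.mask]
            )
            sym_err = np.nanmax(np.abs(a.values - a.values.T))
            assert sym_err < 1e-6
        assert not out1[0].mask[0, 5]
        assert np.isnan(out1[0].values[0, 5])

    def test_identity_noise_converges_immediately(self, rng):
        truth = self._tiles(rng, n=5)
        tc = TrainConfig.desk_scale(seed=0)
        tc.denoiser_max_epochs = 2
        model, fit = train_denoiser(truth, truth, tc, channels=4, seed=0)
        # predicting the input is already near-optimal: the residual net
        # starts close to identity and the loss stays small
        assert fit["history"][-1]["train_loss"] < 1.0

    def test_unpaired_tiles_error(self, rng):
        truth = self._tiles(rng, n=4)
        with pytest.raises(ValueError, match="unpaired"):
            train_denoiser(truth[:3], truth[1:], TrainConfig.desk_scale())

    def test_patience_contract(self, rng):
        truth = self._tiles(rng, n=5)
        noisy = [
            Tile(t.region, t.bin_size,
                 t.values + rng.normal(0, 0.3, t.values.shape), t.mask)
            for t in truth
        ]
        tc = TrainConfig.desk_scale(seed=0)
        tc.denoiser_max_epochs = 40
        tc.denoiser_patience = 2
        model, fit = train_denoiser(noisy, truth, tc, channels=2, seed=0)
        best = fit["best_epoch"]
        assert len(fit["history"]) <= max(best, 0) + tc.denoiser_patience + 2


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        cfg = tiny_cfg()
        model = HiConformer(cfg, seed=3)
        seq, epi = random_inputs(rng, cfg)
        model.eval()
        with no_grad():
            before = model(seq, epi)[0].data
        save_checkpoint(tmp_path / "m.npz", model,
                        config={"scale": 16},
                        zscore_mean=np.arange(4.0),
                        zscore_std=np.ones(4))
        fresh = HiConformer(cfg, seed=99)
        meta = load_checkpoint(tmp_path / "m.npz", fresh)
        fresh.eval()
        with no_grad():
            after = fresh(seq, epi)[0].data
        np.testing.assert_allclose(before, after, atol=1e-7)
        assert meta["scale"] == 16
        np.testing.assert_array_equal(meta["zscore_mean"], np.arange(4.0))


class TestDenoiserRecovery:
    def test_denoising_gaussian_corruption_improves_ssim(self):
        """Tiles corrupted with additive Gaussian noise come out of the
        trained denoiser closer (by SSIM) to the clean truth on held-out
        tiles."""
        from virtualhic.experiments import denoiser_recovery

        res = denoiser_recovery(seed=0)
        assert res["ssim_after"] > res["ssim_before"]
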
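"""Variational perfusion-deficit model: contracts, losses, splits, calibration."""

import numpy as np
import pandas as pd
import pytest

from perfudim import nn
from perfudim.dlm import (
    ModelConfig,
    PerfusionDLM,
    assemble_input,
    calibrate_threshold,
    elbo_loss,
    infer_substrate,
    kl_divergence,
    pad_to_shape,
    predict_score,
    select_checkpoint,
    split_cohort,
    train,
    TrainResult,
)
from perfudim.reference import dot_product_loop, kl_closed_form

TINY = dict(
    input_shape=(8, 8, 8),
    channel_schedule=(4, 6, 4),
    latent_dim=10,
    substrate_latent=5,
    rng_seed=3,
)


class TestAssembleInput:
    def test_zero_score_gives_zero_fifth_channel(self):
        x = assemble_input(np.ones((8, 8, 8)), 0, 4.0, (8, 8, 8))
        assert np.all(x[..., 4] == 0)

    def test_coordinate_channels_span_minus_one_to_one(self):
        x = assemble_input(np.zeros((8, 8, 8)), 1, 4.0, (8, 8, 8))
        assert np.all(x[0, :, :, 1] == -1.0)
        assert np.all(x[-1, :, :, 1] == 1.0)
        assert np.all(x[:, 0, :, 2] == -1.0)
        assert np.all(x[:, :, -1, 3] == 1.0)

    def test_channel_zero_survives_pad_crop_roundtrip(self):
        rng = np.random.default_rng(6)
        cpm = rng.random((5, 7, 6))  # strictly smaller: zero-padding only
        x = assemble_input(cpm, 2, 4.0, (8, 8, 8))
        back = pad_to_shape(x[..., 0], (5, 7, 6))
        np.testing.assert_allclose(back, cpm, rtol=1e-6)
        # padded border is exactly zero
        assert x[..., 0].sum() == pytest.approx(cpm.sum(), rel=1e-6)

    def test_score_outside_range_rejected(self):
        with pytest.raises(ValueError, match="ordinal range"):
            assemble_input(np.zeros((8, 8, 8)), 5, 4.0, (8, 8, 8))


class TestArchitecture:
    def test_flat_dim_is_2048_for_full_scale_config(self):
        cfg = ModelConfig()  # 128-cube, schedule (5,16,32,64,128,256)
        assert cfg.flat_dim == 2048
        assert cfg.bottleneck_shape == (2, 2, 2)

    def test_spatial_side_halves_per_block(self):
        cfg = ModelConfig()
        for k in range(1, cfg.depth + 1):
            assert 128 // 2**k == 128 >> k  # 64, 32, 16, 8, 4, 2

    def test_encoder_emits_mean_and_sd_of_latent(self):
        model = PerfusionDLM(ModelConfig(**TINY))
        x = np.random.default_rng(0).normal(size=(2, 8, 8, 8, 5)).astype(np.float32)
        mu, sd, logvar = model.encode(x, train=False)
        assert mu.shape == (2, 10)
        assert sd.shape == (2, 10)
        assert np.all(sd > 0)

    def test_decoder_output_matches_input_shape(self):
        model = PerfusionDLM(ModelConfig(**TINY))
        sub = model.decode_substrate(np.zeros((2, 5), np.float32), train=False)
        rec = model.decode_perfusion(np.zeros((2, 5), np.float32), train=False)
        assert sub.shape == rec.shape == (2, 8, 8, 8)

    def test_indivisible_input_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(input_shape=(24, 24, 24),
                        channel_schedule=(4, 4, 4, 4, 4, 4))

    def test_reconstruction_gradient_never_reaches_substrate_branch(self):
        """With only the perfusion-reconstruction loss active, the substrate
        decoder receives exactly zero gradient."""
        cfg = ModelConfig(**{**TINY, "loss_weights": (0.0, 1.0, 0.0)})
        model = PerfusionDLM(cfg)
        optim = nn.Adam(model.params(), lr=0.0, weight_decay=0.0)
        x = np.random.default_rng(1).normal(size=(3, 8, 8, 8, 5)).astype(np.float32)
        model.train_step(x, np.zeros(3), optim, np.random.default_rng(2))
        for p in model.dec_substrate.params():
            assert np.all(p.grad == 0)
        assert any(np.any(p.grad != 0) for p in model.dec_recon.params())
        assert any(np.any(p.grad != 0) for p in model.encoder.params())


class TestTrainStepGradients:
    def test_full_model_gradients_match_finite_differences(self, monkeypatch):
        """End-to-end backward pass (encoder, both decoders, map bias and
        score intercept) against central differences on the total loss."""
        monkeypatch.setattr(nn, "_DTYPE", np.float64)
        cfg = ModelConfig(**TINY)
        model = PerfusionDLM(cfg)
        rng0 = np.random.default_rng(0)
        x = rng0.normal(size=(3, 8, 8, 8, 5))
        s = rng0.normal(size=3)

        def loss():
            optim = nn.Adam(model.params(), lr=0.0, weight_decay=0.0)
            return model.train_step(
                x.copy(), s, optim, np.random.default_rng(42)
            )["loss"]

        base = loss()
        grads = [p.grad.copy() for p in model.params()]
        h = 1e-4
        sel = np.random.default_rng(5)
        for pi, p in enumerate(model.params()):
            flat = p.value.ravel()
            g = grads[pi].ravel()
            for _ in range(2):
                idx = int(sel.integers(0, flat.size))
                orig = flat[idx]
                flat[idx] = orig + h
                lp = loss()
                flat[idx] = orig - h
                lm = loss()
                flat[idx] = orig
                fd = (lp - lm) / (2 * h)
                assert abs(fd - g[idx]) <= 5e-2 * max(abs(fd), abs(g[idx]), 1e-2), (
                    f"param {pi} ({p.name})"
                )

    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path):
        cfg = ModelConfig(**TINY)
        model = PerfusionDLM(cfg)
        x = np.random.default_rng(3).normal(size=(2, 8, 8, 8, 5)).astype(np.float32)
        before = model.substrate_for(x)
        path = tmp_path / "model.npz"
        model.save(str(path))
        loaded = PerfusionDLM.load(str(path))
        np.testing.assert_allclose(loaded.substrate_for(x), before, rtol=1e-6)


class TestReparameterize:
    def test_zero_sd_returns_the_mean(self):
        model = PerfusionDLM(ModelConfig(**TINY))
        mu = np.arange(10, dtype=np.float32)[None]
        z, _ = model.reparameterize(mu, np.zeros_like(mu), np.random.default_rng(0))
        np.testing.assert_array_equal(z, mu)

    def test_sample_mean_converges_to_posterior_mean(self):
        model = PerfusionDLM(ModelConfig(**TINY))
        mu = np.full((10_000, 10), 2.0, np.float32)
        sd = np.full_like(mu, 0.5)
        z, _ = model.reparameterize(mu, sd, np.random.default_rng(3))
        assert abs(z.mean() - 2.0) < 4 * 0.5 / 100

    def test_fixed_rng_reproduces_sample(self):
        model = PerfusionDLM(ModelConfig(**TINY))
        mu = np.ones((2, 10), np.float32)
        sd = np.ones_like(mu)
        z1, _ = model.reparameterize(mu, sd, np.random.default_rng(7))
        z2, _ = model.reparameterize(mu, sd, np.random.default_rng(7))
        np.testing.assert_array_equal(z1, z2)


class TestLosses:
    def test_standard_normal_code_and_perfect_recon_give_zero_loss(self):
        mean = np.zeros(10)
        sd = np.ones(10)
        cpm = np.random.default_rng(1).random((4, 4, 4))
        out = elbo_loss(mean, sd, cpm, cpm.copy(), 2.0, 2.0)
        assert out["total"] == pytest.approx(0.0, abs=1e-12)

    def test_kl_matches_closed_form_reference(self):
        rng = np.random.default_rng(2)
        mean = rng.normal(size=50)
        sd = np.exp(rng.normal(size=50) * 0.3)
        assert kl_divergence(mean, sd) == pytest.approx(
            kl_closed_form(mean, sd), abs=1e-10
        )

    def test_kl_is_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            mean = rng.normal(size=20)
            sd = np.exp(rng.normal(size=20))
            assert kl_divergence(mean, sd) >= 0

    def test_perturbing_reconstruction_increases_loss(self):
        cpm = np.random.default_rng(4).random((4, 4, 4))
        base = elbo_loss(np.zeros(5), np.ones(5), cpm, cpm.copy(), 1.0, 1.0)
        worse = elbo_loss(np.zeros(5), np.ones(5), cpm, cpm + 0.1, 1.0, 1.0)
        assert worse["total"] > base["total"]

    def test_components_reported_separately(self):
        out = elbo_loss(np.ones(3), np.ones(3), np.ones((2, 2, 2)),
                        np.zeros((2, 2, 2)), 1.0, 0.0)
        assert out["kl"] == pytest.approx(1.5)
        assert out["l2_cpm"] == pytest.approx(8.0)
        assert out["l2_score"] == pytest.approx(1.0)


class TestPredictScore:
    def test_zero_substrate_predicts_zero(self):
        assert predict_score(np.zeros((3, 3, 3)), np.ones((3, 3, 3))) == 0.0

    def test_one_hot_substrate_reads_single_voxel(self):
        sub = np.zeros((4, 4, 4))
        sub[1, 2, 3] = 2.5
        cpm = np.random.default_rng(5).random((4, 4, 4))
        assert predict_score(sub, cpm) == pytest.approx(2.5 * cpm[1, 2, 3])

    def test_matches_explicit_voxel_loop(self):
        rng = np.random.default_rng(6)
        sub, cpm = rng.random((5, 5, 5)), rng.random((5, 5, 5))
        assert predict_score(sub, cpm) == pytest.approx(
            dot_product_loop(sub, cpm), rel=1e-14
        )

    def test_bilinear_in_both_arguments(self):
        rng = np.random.default_rng(7)
        sub, cpm = rng.random((4, 4, 4)), rng.random((4, 4, 4))
        assert predict_score(2 * sub, cpm) == pytest.approx(2 * predict_score(sub, cpm))
        assert predict_score(sub, 2 * cpm) == pytest.approx(2 * predict_score(sub, cpm))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            predict_score(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)))


class TestSplit:
    def test_1393_patients_yield_70_calibration(self):
        split = split_cohort(list(range(1393)), rng_seed=0)
        assert len(split.calibration_ids) == 70
        assert len(split.validation_ids) == 70
        assert len(split.train_ids) == 1253

    def test_100_patients_split_90_5_5(self):
        split = split_cohort(list(range(100)), rng_seed=1)
        assert (len(split.train_ids), len(split.validation_ids),
                len(split.calibration_ids)) == (90, 5, 5)

    def test_split_partitions_the_cohort(self):
        ids = [f"p{i}" for i in range(57)]
        split = split_cohort(ids, rng_seed=2)
        joined = split.train_ids + split.validation_ids + split.calibration_ids
        assert sorted(joined) == sorted(ids)
        assert len(set(joined)) == len(ids)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="small"):
            split_cohort(list(range(10)))

    def test_checkpoint_selection_picks_minimum_error(self):
        assert select_checkpoint([3.0, 1.0, 2.0]) == 1
        assert select_checkpoint([2.0, 1.0, 1.0]) == 1  # tie -> earliest


@pytest.fixture(scope="module")
def tiny_cohort():
    rng = np.random.default_rng(11)
    sub = np.zeros((8, 8, 8))
    sub[3:6, 3:6, 3:6] = 1.0
    cpms = {i: rng.random((8, 8, 8)) for i in range(24)}
    raw = {i: float((sub * c).sum()) for i, c in cpms.items()}
    mx = max(raw.values())
    scores = {i: 4.0 * raw[i] / mx for i in cpms}
    return cpms, scores, sub


class TestTraining:

    def test_single_epoch_runs_and_logs_one_row(self, tiny_cohort):
        cpms, scores, _ = tiny_cohort
        cfg = ModelConfig(**{**TINY, "batch_size": 8})
        split = split_cohort(sorted(cpms), rng_seed=5)
        result = train(cpms, scores, split, cfg, epochs=1)
        assert len(result.log) == 1
        assert np.isfinite(result.log.loss.iloc[0])
        assert {"kl", "l2_cpm", "l2_score", "val_mse"} <= set(result.log.columns)

    def test_training_reduces_loss(self, tiny_cohort):
        cpms, scores, _ = tiny_cohort
        cfg = ModelConfig(**{**TINY, "batch_size": 8, "learning_rate": 1e-3})
        split = split_cohort(sorted(cpms), rng_seed=5)
        result = train(cpms, scores, split, cfg, epochs=30)
        assert result.log.loss.iloc[-1] < result.log.loss.iloc[0]

    def test_training_is_deterministic_given_seed(self, tiny_cohort):
        cpms, scores, _ = tiny_cohort
        cfg = ModelConfig(**{**TINY, "batch_size": 8})
        split = split_cohort(sorted(cpms), rng_seed=5)
        log1 = train(cpms, scores, split, cfg, epochs=2).log
        log2 = train(cpms, scores, split, cfg, epochs=2).log
        pd.testing.assert_frame_equal(log1, log2)


class TestInferAndCalibrate:
    def test_singleton_subset_equals_patient_map(self, tmp_path):
        cfg = ModelConfig(**TINY)
        model = PerfusionDLM(cfg)
        cpms = {0: np.random.default_rng(0).random((8, 8, 8))}
        scores = {0: 1.0}
        result = TrainResult(model=model, log=None, best_epoch=0,
                             cpm_scale=1.0, score_scale=4.0)
        pop = infer_substrate(result, cpms, scores, [0])
        x = assemble_input(cpms[0], scores[0], 4.0, cfg.input_shape, 1.0)
        direct = model.substrate_for(x[None])[0]
        np.testing.assert_allclose(pop, direct, rtol=1e-6)

    def test_population_map_is_order_invariant(self):
        cfg = ModelConfig(**TINY)
        model = PerfusionDLM(cfg)
        rng = np.random.default_rng(1)
        cpms = {i: rng.random((8, 8, 8)) for i in range(4)}
        scores = {i: float(i) for i in range(4)}
        result = TrainResult(model=model, log=None, best_epoch=0,
                             cpm_scale=1.0, score_scale=4.0)
        a = infer_substrate(result, cpms, scores, [0, 1, 2, 3])
        b = infer_substrate(result, cpms, scores, [3, 1, 0, 2])
        np.testing.assert_allclose(a, b, rtol=1e-5)

    def test_single_candidate_grid_returns_it(self):
        rng = np.random.default_rng(2)
        sub = rng.random((6, 6, 6))
        cpms = [rng.random((6, 6, 6)) for _ in range(5)]
        scores = [1.0, 2.0, 0.0, 3.0, 1.0]
        pct, binary, _ = calibrate_threshold(sub, cpms, scores,
                                             grid_lo=95.0, grid_hi=95.0)
        assert pct == 95.0
        assert binary.sum() > 0

    def test_returned_percentile_attains_recomputed_maximum(self):
        rng = np.random.default_rng(3)
        sub = rng.random((6, 6, 6))
        cpms = [rng.random((6, 6, 6)) for _ in range(8)]
        scores = [float(rng.integers(0, 5)) for _ in range(8)]
        pct, _, table = calibrate_threshold(sub, cpms, scores)
        # brute-force re-evaluation of every candidate
        for _, row in table.iterrows():
            thr = np.percentile(sub, row.percentile)
            binary = (sub > thr).astype(float)
            raw = np.array([predict_score(binary, c) for c in cpms])
            a = raw @ np.asarray(scores) / (raw @ raw)
            acc = -np.mean(np.abs(a * raw - np.asarray(scores)))
            assert acc == pytest.approx(row.accuracy, abs=1e-12)
        best = table.loc[table.accuracy.idxmax()]
        assert table[table.percentile == pct].accuracy.iloc[0] == pytest.approx(
            best.accuracy
        )

    def test_constant_substrate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_threshold(np.ones((5, 5, 5)), [np.ones((5, 5, 5))], [1.0])
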
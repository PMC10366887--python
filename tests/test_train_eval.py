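"""Training protocol contracts (scheduler, early stop, splits, augmentation)
and evaluation metrics."""

import numpy as np
import pytest

from pcctdenoise.containers import MaterialMaps, SpectralVolume
from pcctdenoise.spectral_materials import ROISpec
from pcctdenoise.train_eval import (
    PlateauEarlyStop,
    TrainConfig,
    attenuation_to_hu,
    augment,
    make_splits,
    material_rmse,
    rmse,
    rmse_hu,
    roi_bias_noise,
    ssim_psnr,
)


class TestTrainConfig:
    def test_defaults_match_protocol(self):
        cfg = TrainConfig()
        assert cfg.max_epochs == 2000
        assert cfg.batch_size == 8
        assert cfg.learning_rate == pytest.approx(2e-4)
        assert cfg.plateau_patience == 10
        assert cfg.stop_patience == 20

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(plateau_patience=0)
        with pytest.raises(ValueError):
            TrainConfig(stop_patience=5, plateau_patience=10)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)


class TestPlateauEarlyStop:
    def test_flat_sequence_halves_after_exactly_ten(self):
        sched = PlateauEarlyStop(10, 20)
        halvings = []
        sched.update(1.0)  # epoch 1 sets the minimum
        for epoch in range(2, 12):  # epochs 2..11 flat
            _, halve, stop = sched.update(1.0)
            if halve:
                halvings.append(epoch)
            assert not stop
        assert halvings == [11]

    def test_flat_sequence_stops_after_exactly_twenty(self):
        sched = PlateauEarlyStop(10, 20)
        sched.update(1.0)
        stops = []
        for epoch in range(2, 22):
            _, _, stop = sched.update(1.0)
            if stop:
                stops.append(epoch)
        assert stops == [21]

    def test_improvement_resets_both_counters(self):
        sched = PlateauEarlyStop(10, 20)
        sched.update(1.0)
        for _ in range(9):
            sched.update(1.0)
        improved, halve, stop = sched.update(0.5)  # new minimum just in time
        assert improved and not halve and not stop
        for _ in range(9):
            _, halve, _ = sched.update(0.5)
            assert not halve

    def test_decreasing_sequence_never_halves(self):
        sched = PlateauEarlyStop(10, 20)
        for v in np.linspace(1.0, 0.1, 50):
            improved, halve, stop = sched.update(float(v))
            assert improved and not halve and not stop


class TestMakeSplits:
    def test_nine_one_split(self):
        train, val = make_splits([4] * 10, seed=0)
        assert len(train) == 36 and len(val) == 4
        held = {v for v, _ in val}
        assert len(held) == 1
        assert held.isdisjoint({v for v, _ in train})

    def test_shuffle_deterministic(self):
        a = make_splits([6] * 4, seed=3)
        b = make_splits([6] * 4, seed=3)
        assert a == b

    def test_no_slice_in_both_splits(self):
        train, val = make_splits([5] * 6, seed=1)
        assert not set(train) & set(val)

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            make_splits([4])


class TestAugment:
    def test_double_flip_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 8, 8))
        flipped = np.flip(np.flip(x, axis=-1), axis=-1)
        np.testing.assert_array_equal(flipped, x)

    def test_input_and_label_flipped_identically(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 6, 6))
        y = x * 2.0
        for _ in range(20):
            xa, ya, _ = augment(x, y, rng)
            np.testing.assert_array_equal(ya, 2.0 * xa)

    def test_flip_frequency_is_half(self):
        rng = np.random.default_rng(2)
        x = np.zeros((1, 2, 2))
        counts = np.zeros(2)
        n = 10_000
        for _ in range(n):
            _, _, flips = augment(x, x, rng)
            counts += flips
        assert np.all(np.abs(counts / n - 0.5) < 0.02)


class TestMetrics:
    def test_hu_anchor_points(self):
        water = np.array([0.2, 0.3])
        vol = np.stack([np.full((1, 2, 2), 0.2), np.full((1, 2, 2), 0.3)])
        np.testing.assert_allclose(attenuation_to_hu(vol, water), 0.0)
        np.testing.assert_allclose(attenuation_to_hu(np.zeros_like(vol), water), -1000.0)
        np.testing.assert_allclose(attenuation_to_hu(2 * vol, water), 1000.0)

    def test_rmse_offset_and_identity(self):
        a = SpectralVolume(np.random.default_rng(3).normal(size=(2, 2, 4, 4)))
        assert rmse(a.data, a.data) == 0.0
        b = SpectralVolume(a.data + 0.25)
        assert rmse(b.data, a.data) == pytest.approx(0.25)

    def test_rmse_matches_brute_sum_on_toy(self):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([0.0, 2.0, 1.0])
        assert rmse(a, b) == pytest.approx(np.sqrt((1 + 0 + 9) / 3))

    def test_rmse_hu_scaling(self):
        water = np.array([0.2])
        a = SpectralVolume(np.full((1, 1, 2, 2), 0.2))
        b = SpectralVolume(np.full((1, 1, 2, 2), 0.21))
        # 0.01 cm^-1 on a 0.2 anchor is 50 HU
        assert rmse_hu(b, a, water) == pytest.approx(50.0)

    def test_material_rmse_per_map(self):
        m1 = MaterialMaps(np.zeros((2, 1, 2, 2)), ["water", "iodine"])
        data = np.zeros((2, 1, 2, 2))
        data[1] = 0.5
        m2 = MaterialMaps(data, ["water", "iodine"])
        out = material_rmse(m2, m1)
        assert out["water"] == 0.0
        assert out["iodine"] == pytest.approx(0.5)

    def test_roi_bias_noise_hand_computed(self):
        ref = np.zeros((1, 4, 8, 8))
        den = np.zeros((1, 4, 8, 8))
        roi = ROISpec((2, 4, 4), 1.6, 1, 3)
        mask = roi.mask((4, 8, 8))
        ref[0, mask] = 2.0
        den[0, mask] = 2.5
        bias, noise = roi_bias_noise(
            SpectralVolume(den), SpectralVolume(ref), roi
        )
        assert bias[0] == pytest.approx(0.5)
        assert noise[0] == pytest.approx(0.0)

    def test_denoised_equals_noisy_gives_zero_bias(self, noisy_pair):
        _, noisy = noisy_pair
        roi = ROISpec((6, 16, 16), 4.0, 3, 9)
        bias, noise = roi_bias_noise(noisy, noisy, roi)
        np.testing.assert_allclose(bias, 0.0)
        assert np.all(noise >= 0)

    def test_ssim_psnr_identity_and_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(32, 32))
        s, p = ssim_psnr(a, a)
        assert s == pytest.approx(1.0)
        assert np.isinf(p)
        b = a + rng.normal(0, 0.1, a.shape)
        s_ab, _ = ssim_psnr(a, b, data_range=float(a.max() - a.min()))
        s_ba, _ = ssim_psnr(b, a, data_range=float(a.max() - a.min()))
        assert s_ab == pytest.approx(s_ba, abs=1e-12)

    def test_psnr_hand_computed_on_tiny_image(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        b = np.array([[0.5, 1.0], [1.0, 0.0]])
        _, p = ssim_psnr(b, a, data_range=1.0)
        assert p == pytest.approx(10 * np.log10(1.0 / (0.25 / 4)))


class TestTrainingLoop:
    def test_smoke_training_reduces_loss(self):
        from pcctdenoise.losses import mse_loss_grad
        from pcctdenoise.denoise_nets import NetConfig, build_unet
        from pcctdenoise.train_eval import PairSliceDataset, train

        rng = np.random.default_rng(5)
        clean = [SpectralVolume(rng.normal(1, 0.3, (2, 6, 16, 16)).astype(np.float32))
                 for _ in range(2)]
        noisy = [SpectralVolume(c.data + rng.normal(0, 0.1, c.data.shape)
                                .astype(np.float32), c.energies) for c in clean]
        ds = PairSliceDataset(noisy, clean)
        splits = make_splits(ds.volumes(), seed=0)
        net = build_unet(NetConfig(levels=2, base_filters=8, in_channels=2,
                                   out_channels=2, residual=True, seed=0))

        def loss_grad(pred, label):
            loss, grad = mse_loss_grad(pred, label)
            return loss, grad, None

        cfg = TrainConfig(max_epochs=4, batch_size=4, seed=0)
        _, history = train(net, loss_grad, ds, splits, cfg)
        assert history["train_loss"][-1] < history["train_loss"][0]

    def test_empty_split_rejected(self):
        from pcctdenoise.train_eval import train

        with pytest.raises(ValueError):
            train(None, None, None, ([], [(0, 0)]), TrainConfig())

    def test_history_csv_written(self, tmp_path):
        from pcctdenoise.train_eval import write_history_csv

        history = {"train_loss": [1.0, 0.5], "val_loss": [1.1, 0.6],
                   "lr": [2e-4, 2e-4], "parts": [{"mse": 1.0}, {"mse": 0.5}]}
        path = tmp_path / "curves.csv"
        write_history_csv(history, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "epoch,train_loss,val_loss,lr,mse"
        assert len(lines) == 3
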
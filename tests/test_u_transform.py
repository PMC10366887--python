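"""Channel transform: noise estimation, SVD properties, exact invertibility."""

import numpy as np
import pytest

from pcctdenoise.containers import SpectralVolume
from pcctdenoise.u_transform import (
    UTransform,
    estimate_noise_variance,
    forward_transform,
    inverse_transform,
    project_label,
    sign_flip,
)


def _random_volume(seed, shape=(4, 8, 16, 16), smooth_plus_noise=True):
    rng = np.random.default_rng(seed)
    e, z, y, x = shape
    zz, yy, xx = np.meshgrid(
        np.linspace(-1, 1, z), np.linspace(-1, 1, y), np.linspace(-1, 1, x),
        indexing="ij",
    )
    base = np.exp(-(zz**2 + yy**2 + xx**2) / 0.3)
    weights = rng.uniform(0.5, 2.0, e)
    data = weights[:, None, None, None] * base
    if smooth_plus_noise:
        data = data + rng.normal(0, 0.02, (e, z, y, x))
    return SpectralVolume(data.astype(np.float32))


class TestNoiseEstimator:
    def test_recovers_gaussian_sigma(self):
        sigma = 0.02
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vol = SpectralVolume(rng.normal(0, sigma, (1, 3, 256, 256)))
            var = estimate_noise_variance(vol)
            assert abs(var[0] / sigma**2 - 1) < 0.1

    def test_constant_slice_floored_at_eps(self):
        vol = SpectralVolume(np.full((2, 3, 16, 16), 7.0))
        var = estimate_noise_variance(vol)
        assert np.all(var > 0)
        assert np.all(var <= 1e-10)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 0.05, (2, 3, 64, 64))
        a = estimate_noise_variance(SpectralVolume(data))
        b = estimate_noise_variance(SpectralVolume(data + 123.0))
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_variance(SpectralVolume(np.zeros((2, 3, 1, 16))))


class TestForwardTransform:
    def test_left_singular_columns_orthonormal(self):
        vol = _random_volume(1)
        variances = estimate_noise_variance(vol)
        weighted = vol.data.astype(np.float64) / variances[:, None, None, None]
        a = weighted.reshape(4, -1).T
        u, _, _ = np.linalg.svd(a, full_matrices=False)
        np.testing.assert_allclose(u.T @ u, np.eye(4), atol=1e-6)

    def test_rank_one_volume_has_one_singular_value(self):
        rng = np.random.default_rng(2)
        spatial = rng.uniform(0.1, 1.0, (6, 8, 8))
        spectrum = np.array([1.0, 0.7, 0.5, 0.3])
        vol = SpectralVolume(spectrum[:, None, None, None] * spatial)
        _, state = forward_transform(vol, variances=np.ones(4))
        s = state.singular_values
        assert np.all(s[1:] <= 1e-8 * s[0])

    def test_u_images_zero_mean_after_high_pass(self):
        vol = _random_volume(3, shape=(2, 16, 32, 32), smooth_plus_noise=False)
        U, _ = forward_transform(vol)
        for k in range(2):
            assert abs(U[k].mean()) < 1e-3  # relative to unit percentile scale

    def test_nonfinite_input_rejected(self):
        data = np.ones((2, 4, 8, 8))
        data[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            forward_transform(SpectralVolume(data))


class TestInverseTransform:
    def test_round_trip_float32(self):
        for seed in range(5):
            vol = _random_volume(seed)
            U, state = forward_transform(vol)
            rec = inverse_transform(U, state)
            err = np.abs(rec.data - vol.data).max() / np.abs(vol.data).max()
            assert err < 1e-4

    def test_slice_inversion_matches_full(self):
        vol = _random_volume(11)
        U, state = forward_transform(vol)
        full = inverse_transform(U, state)
        one = inverse_transform(U[:, 3:4], state, slices=[3])
        np.testing.assert_array_equal(one.data[:, 0], full.data[:, 3])

    def test_zero_u_returns_lowpass_content(self):
        # algebraic check on a 2-voxel toy with hand-buildable state
        vol = _random_volume(5, shape=(2, 2, 2, 2))
        U, state = forward_transform(vol)
        rec = inverse_transform(np.zeros_like(U), state)
        comps = state.lowpass.astype(np.float64).reshape(2, -1).T
        expected = (comps @ state.svt()).T.reshape(2, 2, 2, 2)
        expected *= state.variances[:, None, None, None]
        np.testing.assert_allclose(rec.data, expected, rtol=1e-5)

    def test_grid_mismatch_rejected(self):
        vol = _random_volume(6)
        U, state = forward_transform(vol)
        with pytest.raises(ValueError):
            inverse_transform(U[:, :, :8], state)
        with pytest.raises(ValueError):
            inverse_transform(U[:, :4], state, slices=[0, 1, 2, 99])


class TestSignFlip:
    def test_involution(self):
        vol = _random_volume(7)
        U, state = forward_transform(vol)
        mask = np.array([True, False, True, False])
        U2, state2 = sign_flip(*sign_flip(U, state, mask), mask)
        np.testing.assert_array_equal(U2, U)
        np.testing.assert_array_equal(state2.vt, state.vt)

    def test_inverse_invariant_under_flip(self):
        vol = _random_volume(8)
        U, state = forward_transform(vol)
        before = inverse_transform(U, state)
        Uf, statef = sign_flip(U, state, np.array([True, True, False, True]))
        after = inverse_transform(Uf, statef)
        np.testing.assert_allclose(after.data, before.data, atol=1e-6)

    def test_flip_negates_only_masked_components(self):
        vol = _random_volume(9)
        U, state = forward_transform(vol)
        Uf, _ = sign_flip(U, state, np.array([False, True, False, False]))
        np.testing.assert_array_equal(Uf[1], -U[1])
        np.testing.assert_array_equal(Uf[0], U[0])


class TestProjectLabel:
    def test_self_consistency_with_forward(self):
        vol = _random_volume(10)
        U, state = forward_transform(vol)
        U2 = project_label(vol, state)
        np.testing.assert_allclose(U2, U, atol=1e-6)

    def test_linearity(self):
        vol = _random_volume(12)
        _, state = forward_transform(vol)
        doubled = SpectralVolume(2.0 * vol.data)
        a = project_label(vol, state).astype(np.float64)
        b = project_label(doubled, state).astype(np.float64)
        np.testing.assert_allclose(b, 2.0 * a, atol=1e-6)

    def test_zero_label_maps_to_zero(self):
        vol = _random_volume(13)
        _, state = forward_transform(vol)
        zero = SpectralVolume(np.zeros_like(vol.data))
        assert not project_label(zero, state).any()


class TestStateAndEstimator:
    def test_state_save_load_round_trip(self, tmp_path):
        vol = _random_volume(14)
        U, state = forward_transform(vol)
        path = tmp_path / "state.npz"
        state.save(path)
        from pcctdenoise.u_transform import UTransformState

        loaded = UTransformState.load(path)
        rec = inverse_transform(U, loaded)
        orig = inverse_transform(U, state)
        np.testing.assert_array_equal(rec.data, orig.data)

    def test_estimator_round_trip(self):
        vol = _random_volume(15)
        tr = UTransform().fit(vol)
        rec = tr.inverse_transform(tr.U_)
        err = np.abs(rec.data - vol.data).max() / np.abs(vol.data).max()
        assert err < 1e-4

    def test_frobenius_energy_identity(self):
        vol = _random_volume(16)
        variances = estimate_noise_variance(vol)
        _, state = forward_transform(vol, variances=variances)
        a = (vol.data.astype(np.float64) / variances[:, None, None, None]).reshape(4, -1)
        np.testing.assert_allclose(
            np.linalg.norm(a), np.linalg.norm(state.singular_values), rtol=1e-6
        )
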
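"""Material decomposition: inversion round trips, non-negativity projection,
sensitivity calibration from vial ROIs."""

import numpy as np
import pytest

from pcctdenoise.containers import MaterialMaps, SpectralVolume
from pcctdenoise.phantom_sim import (
    PhantomObject,
    PhantomSpec,
    build_sensitivity_matrix,
    compose_phantom,
)
from pcctdenoise.spectral_materials import (
    MaterialDecomposer,
    ROISpec,
    SensitivityMatrix,
    colorize_maps,
    compose,
    decompose,
    decompose_nonneg,
    fit_sensitivity,
    nnls_subset_oracle,
)


class TestDecompose:
    def test_identity_matrix_returns_input(self):
        M = SensitivityMatrix(np.eye(3), ["a", "b", "c"])
        X = np.random.default_rng(0).uniform(0, 1, (3, 2, 4, 4))
        maps = decompose(SpectralVolume(X), M)
        np.testing.assert_allclose(maps.data, X, atol=1e-14)

    def test_round_trip_machine_precision(self, sensitivity):
        rng = np.random.default_rng(1)
        C = rng.uniform(0, 5, (4, 3, 8, 8))
        vol = compose(MaterialMaps(C, list(sensitivity.materials)), sensitivity)
        rec = decompose(vol, sensitivity)
        assert np.abs(rec.data - C).max() / C.max() < 1e-10

    def test_zero_volume_gives_zero_maps(self, sensitivity):
        maps = decompose(SpectralVolume(np.zeros((4, 2, 4, 4))), sensitivity)
        assert not maps.data.any()

    def test_rank_deficient_rejected(self):
        M = SensitivityMatrix(np.ones((2, 2)), ["a", "b"])
        with pytest.raises(np.linalg.LinAlgError):
            decompose(SpectralVolume(np.ones((2, 2, 2, 2))), M)

    def test_overdetermined_uses_least_squares(self):
        rng = np.random.default_rng(2)
        mat = rng.uniform(0.1, 1.0, (2, 4))
        M = SensitivityMatrix(mat, ["a", "b"])
        C = rng.uniform(0, 3, (2, 1, 3, 3))
        vol = compose(MaterialMaps(C, ["a", "b"]), M)
        rec = decompose(vol, M)
        np.testing.assert_allclose(rec.data, C, atol=1e-10)


class TestDecomposeNonneg:
    def test_nonnegative_solution_unchanged(self, sensitivity):
        rng = np.random.default_rng(3)
        C = rng.uniform(0.5, 5, (4, 2, 4, 4))
        vol = compose(MaterialMaps(C, list(sensitivity.materials)), sensitivity)
        plain = decompose(vol, sensitivity)
        constrained = decompose_nonneg(vol, sensitivity)
        np.testing.assert_array_equal(plain.data, constrained.data)

    def test_matches_subset_oracle_on_noisy_voxels(self, sensitivity):
        rng = np.random.default_rng(4)
        C = rng.uniform(0, 1, (4, 4, 8, 8))
        vol = compose(MaterialMaps(C, list(sensitivity.materials)), sensitivity)
        noisy = SpectralVolume(vol.data + rng.normal(0, 0.05, vol.data.shape))
        result = decompose_nonneg(noisy, sensitivity)
        assert result.data.min() >= 0
        X = noisy.data.reshape(4, -1).T
        got = result.data.reshape(4, -1).T
        idx = rng.choice(X.shape[0], 200, replace=False)
        for i in idx:
            expected = nnls_subset_oracle(X[i], sensitivity.matrix)
            np.testing.assert_allclose(got[i], expected, atol=1e-9)

    def test_forced_negative_component_is_zeroed(self, sensitivity):
        # attenuation below water at every energy forces negative components
        x = sensitivity.row_for("water") * 1.0 - sensitivity.row_for("iodine") * 2.0
        vol = SpectralVolume(x[:, None, None, None])
        res = decompose_nonneg(vol, sensitivity).data[:, 0, 0, 0]
        oracle = nnls_subset_oracle(x, sensitivity.matrix)
        np.testing.assert_allclose(res, oracle, atol=1e-10)
        assert res[sensitivity.materials.index("iodine")] == 0.0


class TestFitSensitivity:
    @staticmethod
    def _vial_phantom(M, conc=None):
        conc = conc or {"iodine": 8.0, "gadolinium": 6.0, "calcium": 40.0}
        objs, rois = [], []
        centers = [(8, 8), (8, 24), (24, 8)]
        for (name, c), (cy, cx) in zip(conc.items(), centers):
            objs.append(PhantomObject("cylinder", (6, cy, cx), (7, 4), name, c))
            rois.append(ROISpec((6, cy, cx), 2.5, 3, 9, name, c))
        water_roi = ROISpec((6, 24, 24), 2.5, 3, 9, "water", 1.0)
        spec = PhantomSpec(grid_shape=(12, 32, 32), objects=objs)
        _, vol = compose_phantom(spec, M)
        return vol, rois, water_roi

    def test_noiseless_round_trip(self, sensitivity):
        vol, rois, water_roi = self._vial_phantom(sensitivity)
        fitted = fit_sensitivity(vol, rois, water_roi)
        for name in fitted.materials:
            got = fitted.row_for(name)
            want = sensitivity.row_for(name)
            np.testing.assert_allclose(got, want, rtol=1e-8)

    def test_noisy_recovery_within_three_standard_errors(self, sensitivity):
        vol, rois, water_roi = self._vial_phantom(sensitivity)
        estimates = []
        sigma = 0.01
        for seed in range(30):
            rng = np.random.default_rng(seed)
            noisy = SpectralVolume(
                vol.data + rng.normal(0, sigma, vol.data.shape), vol.energies
            )
            estimates.append(fit_sensitivity(noisy, rois, water_roi).matrix)
        estimates = np.asarray(estimates)
        mean = estimates.mean(axis=0)
        sem = estimates.std(axis=0, ddof=1) / np.sqrt(len(estimates))
        z = np.abs(mean - sensitivity.matrix) / sem
        assert z.max() < 3.0

    def test_single_vial_one_point_slope(self):
        M = build_sensitivity_matrix(["water", "iodine"], [25.0, 34.0])
        vol, rois, water_roi = self._vial_phantom(M, conc={"iodine": 4.0})
        fitted = fit_sensitivity(vol, [rois[0]], water_roi)
        np.testing.assert_allclose(
            fitted.row_for("iodine"), M.row_for("iodine"), rtol=1e-10
        )

    def test_roi_order_invariance(self, sensitivity):
        vol, rois, water_roi = self._vial_phantom(sensitivity)
        a = fit_sensitivity(vol, rois, water_roi)
        b = fit_sensitivity(vol, rois[::-1], water_roi)
        for name in a.materials:
            np.testing.assert_allclose(a.row_for(name), b.row_for(name))

    def test_roi_outside_volume_rejected(self, sensitivity):
        vol, rois, water_roi = self._vial_phantom(sensitivity)
        bad = ROISpec((6, 30, 30), 4.0, 3, 9, "water", 1.0)
        with pytest.raises(ValueError):
            fit_sensitivity(vol, rois, bad)


class TestColorize:
    def test_zero_maps_are_black(self, sensitivity):
        maps = MaterialMaps(np.zeros((4, 2, 4, 4)), list(sensitivity.materials))
        rgb = colorize_maps(maps, {"iodine": (1, 0, 0)})
        assert not rgb.any()

    def test_saturated_map_gives_pure_color(self, sensitivity):
        data = np.zeros((4, 2, 4, 4))
        data[1] = 5.0
        maps = MaterialMaps(data, list(sensitivity.materials))
        rgb = colorize_maps(maps, {"iodine": (0, 1, 0)}, saturation={"iodine": 5.0})
        np.testing.assert_array_equal(rgb, np.broadcast_to([0, 1, 0], rgb.shape))

    def test_overlapping_maps_blend_additively(self, sensitivity):
        data = np.zeros((4, 1, 2, 2))
        data[1] = 2.0  # iodine at half saturation 4
        data[2] = 3.0  # gadolinium at full saturation 3
        maps = MaterialMaps(data, list(sensitivity.materials))
        rgb = colorize_maps(
            maps, {"iodine": (1, 0, 0), "gadolinium": (0, 0, 1)},
            slice_index=0, saturation={"iodine": 4.0, "gadolinium": 3.0},
        )
        np.testing.assert_allclose(rgb[0, 0], [0.5, 0.0, 1.0])


class TestMaterialDecomposerEstimator:
    def test_get_set_params_round_trip(self, sensitivity):
        est = MaterialDecomposer(sensitivity=sensitivity, nonneg=True)
        est.set_params(**est.get_params())
        assert est.nonneg is True

    def test_transform_and_inverse(self, sensitivity, small_phantom):
        maps, clean = small_phantom
        est = MaterialDecomposer(sensitivity=sensitivity).fit()
        got = est.transform(clean)
        assert np.abs(got.data - maps.data).max() < 1e-9
        back = est.inverse_transform(got)
        np.testing.assert_allclose(back.data, clean.data, atol=1e-9)

    def test_unfitted_raises(self, small_phantom):
        _, clean = small_phantom
        with pytest.raises(RuntimeError):
            MaterialDecomposer().transform(clean)
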
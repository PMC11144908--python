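"""First-order statistics, shape features, filters and the 1781-feature profile."""

import collections

import numpy as np
import pytest

from swallowtail.phantom import PhantomParams, generate_case
from swallowtail.preprocess import SetMagVolume, reconstruct_setmag
from swallowtail.radiomics import (
    EXPECTED_N_FEATURES,
    ExtractionConfig,
    extract_all,
    feature_table,
    filter_image,
    first_order_features,
    shape_features,
)


class TestFirstOrder:
    def test_constant_roi(self):
        f = first_order_features(np.array([2.0, 2.0, 2.0]))
        assert f["Mean"] == 2.0
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0

    def test_hand_arithmetic_small_roi(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["Mean"] == 2.5
        assert f["Range"] == 3.0
        assert f["Median"] == 2.5
        assert f["Minimum"] == 1.0 and f["Maximum"] == 4.0
        assert f["Energy"] == 1 + 4 + 9 + 16

    def test_symmetric_roi_zero_skewness(self):
        f = first_order_features(np.array([1.0, 2.0, 2.0, 3.0]))
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_moments_match_closed_forms(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 50, 200).astype(float)
        f = first_order_features(x)
        assert f["Mean"] == pytest.approx(x.sum() / x.size, abs=1e-10)
        assert f["Variance"] == pytest.approx(
            ((x - x.mean()) ** 2).sum() / x.size, abs=1e-10
        )
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt((x**2).mean()), abs=1e-10)

    def test_total_energy_scales_with_voxel_volume(self):
        x = np.array([1.0, 2.0])
        assert first_order_features(x, voxel_volume=0.25)["TotalEnergy"] == pytest.approx(
            0.25 * 5.0
        )

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            first_order_features(np.array([]))


class TestShape:
    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["VoxelVolume"] == 1.0

    def test_spacing_doubling_scales_volume_and_surface(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:5] = True
        f1 = shape_features(mask, (1.0, 1.0, 1.0))
        f2 = shape_features(mask, (2.0, 2.0, 2.0))
        assert f2["VoxelVolume"] == pytest.approx(8 * f1["VoxelVolume"])
        # marching-cubes vertices are float32, so exact-scaling holds to ~1e-6
        assert f2["MeshVolume"] == pytest.approx(8 * f1["MeshVolume"], rel=1e-5)
        assert f2["SurfaceArea"] == pytest.approx(4 * f1["SurfaceArea"], rel=1e-5)

    def test_sphericity_at_most_one_and_ball_like_masks_approach_it(self):
        rng = np.random.default_rng(1)
        spher = {}
        for name, builder in {
            "ball": lambda: _ball_mask(9),
            "slab": lambda: _slab_mask(),
            "random": lambda: _random_blob(rng),
        }.items():
            spher[name] = shape_features(builder(), (1.0, 1.0, 1.0))["Sphericity"]
            assert 0.0 < spher[name] <= 1.0 + 1e-9
        assert spher["ball"] > spher["slab"]

    def test_axis_lengths_ordered(self):
        mask = np.zeros((12, 8, 6), bool)
        mask[1:11, 2:6, 2:4] = True
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["MajorAxisLength"] >= f["MinorAxisLength"] >= f["LeastAxisLength"]
        assert 0 < f["Flatness"] <= f["Elongation"] <= 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            shape_features(np.zeros((3, 3, 3), bool))


def _ball_mask(n):
    g = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    return sum((x - c) ** 2 for x in g) <= (c - 0.5) ** 2


def _slab_mask():
    mask = np.zeros((10, 10, 4), bool)
    mask[1:9, 1:9, 1] = True
    return mask


def _random_blob(rng):
    from scipy import ndimage

    mask = rng.uniform(size=(8, 8, 8)) < 0.4
    mask = ndimage.binary_closing(mask)
    if not mask.any():
        mask[4, 4, 4] = True
    return mask


class TestFilters:
    def test_square_of_constant_is_constant(self):
        out = filter_image(np.full((4, 4, 4), 3.0), "square")
        assert len(out) == 1
        assert np.allclose(out[0][1], out[0][1].flat[0])

    def test_gradient_of_constant_is_zero(self):
        name, vol = filter_image(np.full((4, 4, 4), 5.0), "gradient")[0]
        assert name == "gradient"
        np.testing.assert_allclose(vol, 0.0)

    def test_wavelet_returns_8_named_subbands_same_shape(self):
        rng = np.random.default_rng(2)
        vol = rng.uniform(0, 1, (6, 5, 4))  # odd dims exercise padding
        out = filter_image(vol, "wavelet")
        assert len(out) == 8
        names = [n for n, _ in out]
        assert len(set(names)) == 8
        assert all(n.startswith("wavelet-") for n in names)
        assert all(v.shape == vol.shape for _, v in out)

    def test_log_one_volume_per_sigma(self):
        vol = np.random.default_rng(3).uniform(0, 1, (8, 8, 6))
        out = filter_image(vol, "log", log_sigmas=(1.0, 2.5))
        assert [n for n, _ in out] == ["log-sigma-1-mm-3D", "log-sigma-2-5-mm-3D"]

    def test_intensity_maps_preserve_max_magnitude(self):
        rng = np.random.default_rng(4)
        vol = rng.uniform(0, 120, (5, 5, 5))
        for kind in ("square", "squareroot", "logarithm"):
            _, out = filter_image(vol, kind)[0]
            assert np.abs(out).max() == pytest.approx(np.abs(vol).max(), rel=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            filter_image(np.zeros((3, 3, 3)), "fourier")


class TestExtractAll:
    @pytest.fixture(scope="class")
    def case_row(self):
        case = generate_case(PhantomParams(), "PD", 7)
        volume = reconstruct_setmag(case.echoes)
        return extract_all(volume, case.snpc_mask, case_id=case.case_id), case, volume

    def test_exactly_1781_named_features(self, case_row):
        row, _, _ = case_row
        assert len(row.values) == EXPECTED_N_FEATURES == 1781

    def test_decomposition_107_plus_18_times_93(self, case_row):
        row, _, _ = case_row
        by_image = collections.Counter(k.split("_")[0] for k in row.values)
        assert by_image.pop("original") == 107
        assert len(by_image) == 18
        assert set(by_image.values()) == {93}

    def test_shape_only_under_original(self, case_row):
        row, _, _ = case_row
        shape_keys = [k for k in row.values if "_shape_" in k]
        assert len(shape_keys) == 14
        assert all(k.startswith("original_") for k in shape_keys)

    def test_all_values_finite(self, case_row):
        row, _, _ = case_row
        assert np.isfinite(np.array(list(row.values.values()))).all()

    def test_bit_identical_on_rerun(self, case_row):
        row, case, volume = case_row
        again = extract_all(volume, case.snpc_mask, case_id=case.case_id)
        assert list(again.values) == list(row.values)
        np.testing.assert_array_equal(
            np.array(list(again.values.values())),
            np.array(list(row.values.values())),
        )

    def test_empty_mask_rejected(self, case_row):
        _, case, volume = case_row
        with pytest.raises(ValueError, match="empty"):
            extract_all(volume, np.zeros_like(case.snpc_mask))

    def test_feature_table_preserves_order(self, case_row):
        row, _, _ = case_row
        table = feature_table([row, row])
        assert list(table.columns) == list(row.values)
        assert table.shape == (2, 1781)
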
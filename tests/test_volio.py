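import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from capnet.volio import (
    VoxelVolume,
    extract_subregion,
    fill_holes,
    largest_component,
    read_stack,
    resample_isotropic,
    subregion_volume_mm3,
    write_stack,
)


def random_binary(shape, p=0.4, seed=0):
    rng = np.random.default_rng(seed)
    return (rng.random(shape) < p).astype(np.uint8)


class TestVoxelVolume:
    def test_rejects_non_3d(self):
        with pytest.raises(ValueError):
            VoxelVolume(np.zeros((4, 4)), (1, 1, 1))

    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError):
            VoxelVolume(np.zeros((2, 2, 2)), (150, 0, 150))

    def test_binary_detection(self):
        assert VoxelVolume(np.ones((2, 2, 2), np.uint8), (1, 1, 1)).is_binary
        assert not VoxelVolume(np.full((2, 2, 2), 3), (1, 1, 1)).is_binary

    def test_volume_mm3(self):
        vol = VoxelVolume(np.zeros((10, 10, 10), np.uint8), (1e5, 1e5, 1e5))
        assert vol.volume_mm3() == pytest.approx(1.0)


class TestStackIO:
    def test_tiff_round_trip_binary_identical(self, tmp_path):
        vol = VoxelVolume(random_binary((20, 20, 20), seed=1), (150.0,) * 3)
        path = str(tmp_path / "v.tif")
        write_stack(vol, path)
        back = read_stack(path)
        np.testing.assert_array_equal(back.data, vol.data)
        assert back.spacing_nm == vol.spacing_nm

    def test_tiff_page_axis_order(self, tmp_path):
        vol = VoxelVolume(np.zeros((10, 32, 16), np.uint8), (150.0,) * 3)
        path = str(tmp_path / "v.tif")
        write_stack(vol, path)
        assert read_stack(path).shape == (10, 32, 16)

    def test_metaimage_spacing_preserved(self, tmp_path):
        vol = VoxelVolume(random_binary((6, 5, 4), seed=2), (80.0, 40.0, 40.0))
        for name in ("v.mhd", "v.mha"):
            path = str(tmp_path / name)
            write_stack(vol, path)
            back = read_stack(path)
            np.testing.assert_array_equal(back.data, vol.data)
            assert back.spacing_nm == (80.0, 40.0, 40.0)

    def test_missing_spacing_rejected(self, tmp_path):
        import tifffile

        path = str(tmp_path / "bare.tif")
        tifffile.imwrite(path, np.zeros((3, 4, 4), np.uint8))
        with pytest.raises(ValueError, match="spacing"):
            read_stack(path)
        assert read_stack(path, spacing_nm=(1, 1, 1)).shape == (3, 4, 4)

    def test_unknown_extension_rejected(self, tmp_path):
        vol = VoxelVolume(np.zeros((2, 2, 2), np.uint8), (1, 1, 1))
        with pytest.raises(ValueError):
            write_stack(vol, str(tmp_path / "v.nii"))


class TestResampleIsotropic:
    def test_identity_at_target_spacing(self):
        vol = VoxelVolume(random_binary((8, 9, 10), seed=3), (150.0,) * 3)
        out = resample_isotropic(vol, 150.0, mode="nearest")
        assert out.shape == vol.shape
        np.testing.assert_array_equal(out.data, vol.data)

    def test_z_downsampling_slice_count(self):
        # 75 slices at 80 nm -> floor(75 * 80 / 150) = 40 slices at 150 nm
        rng = np.random.default_rng(0)
        vol = VoxelVolume(rng.random((75, 10, 10)).astype(np.float32), (80.0, 150.0, 150.0))
        out = resample_isotropic(vol, 150.0, mode="linear")
        assert out.shape == (40, 10, 10)
        assert out.spacing_nm == (150.0,) * 3

    def test_constant_volume_stays_constant(self):
        vol = VoxelVolume(np.full((12, 12, 12), 7.0, np.float32), (100.0,) * 3)
        out = resample_isotropic(vol, 130.0, mode="linear")
        assert np.allclose(out.data, 7.0)

    def test_linear_on_binary_rejected_without_threshold(self):
        vol = VoxelVolume(random_binary((8, 8, 8), seed=4), (100.0,) * 3)
        with pytest.raises(ValueError, match="binary"):
            resample_isotropic(vol, 130.0, mode="linear")
        out = resample_isotropic(vol, 130.0, mode="linear", threshold=True)
        assert out.is_binary

    def test_nearest_keeps_binary(self):
        vol = VoxelVolume(random_binary((8, 8, 8), seed=5), (100.0,) * 3)
        out = resample_isotropic(vol, 70.0, mode="nearest")
        assert out.is_binary

    def test_rejects_bad_target(self):
        vol = VoxelVolume(np.zeros((4, 4, 4), np.uint8), (100.0,) * 3)
        with pytest.raises(ValueError):
            resample_isotropic(vol, 0.0)


class TestFillHoles:
    def test_enclosed_cavity_filled_exactly(self):
        data = np.ones((9, 9, 9), np.uint8)
        data[3:6, 3:6, 3:6] = 0
        vol = VoxelVolume(data, (1.0,) * 3)
        out = fill_holes(vol, mode="full_3d")
        assert (out.data != data).sum() == 27
        assert out.data.all()

    def test_border_connected_channel_unchanged(self):
        data = np.ones((9, 9, 9), np.uint8)
        data[4, 4, :] = 0  # channel through to both x faces
        vol = VoxelVolume(data, (1.0,) * 3)
        out = fill_holes(vol, mode="full_3d")
        np.testing.assert_array_equal(out.data, data)

    def test_per_slice_fills_z_tunnel(self):
        data = np.ones((6, 9, 9), np.uint8)
        data[:, 4, 4] = 0  # tunnel along z: open in 3D, enclosed per slice
        vol = VoxelVolume(data, (1.0,) * 3)
        assert not fill_holes(vol, mode="full_3d").data.all()
        out = fill_holes(vol, mode="per_slice_2d")
        # oracle: brute-force 2D flood fill from the border per slice
        for z in range(6):
            expected = _flood_fill_2d_oracle(data[z])
            np.testing.assert_array_equal(out.data[z], expected)
        assert out.data.all()

    def test_never_removes_foreground_and_idempotent(self):
        for seed in range(5):
            vol = VoxelVolume(random_binary((12, 12, 12), p=0.3, seed=seed), (1.0,) * 3)
            once = fill_holes(vol)
            assert (once.data >= vol.data).all()
            twice = fill_holes(once)
            np.testing.assert_array_equal(twice.data, once.data)

    def test_rejects_nonbinary(self):
        vol = VoxelVolume(np.full((4, 4, 4), 2, np.uint8), (1.0,) * 3)
        with pytest.raises(ValueError):
            fill_holes(vol)


def _flood_fill_2d_oracle(sl):
    """4-connected flood fill of background from the border; the rest is filled."""
    sl = sl.astype(bool)
    reach = np.zeros_like(sl)
    stack = [
        (y, x)
        for y in range(sl.shape[0])
        for x in range(sl.shape[1])
        if (y in (0, sl.shape[0] - 1) or x in (0, sl.shape[1] - 1)) and not sl[y, x]
    ]
    for y, x in stack:
        reach[y, x] = True
    while stack:
        y, x = stack.pop()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx_ = y + dy, x + dx
            if 0 <= ny < sl.shape[0] and 0 <= nx_ < sl.shape[1]:
                if not sl[ny, nx_] and not reach[ny, nx_]:
                    reach[ny, nx_] = True
                    stack.append((ny, nx_))
    return (sl | ~reach).astype(np.uint8)


class TestLargestComponent:
    def test_small_blob_removed(self):
        data = np.zeros((20, 20, 20), np.uint8)
        data[2:7, 2:7, 2:7] = 1  # 125 voxels
        data[15:16, 15:16, 15:18] = 1  # 3 voxels
        out = largest_component(VoxelVolume(data, (1.0,) * 3))
        assert out.data.sum() == 125

    def test_single_component_identity(self):
        data = np.zeros((8, 8, 8), np.uint8)
        data[2:5, 2:5, 2:5] = 1
        out = largest_component(VoxelVolume(data, (1.0,) * 3))
        np.testing.assert_array_equal(out.data, data)

    def test_tie_broken_by_lowest_index_deterministically(self):
        data = np.zeros((10, 10, 10), np.uint8)
        data[1:3, 1:3, 1:3] = 1
        data[6:8, 6:8, 6:8] = 1
        vol = VoxelVolume(data, (1.0,) * 3)
        out1 = largest_component(vol)
        out2 = largest_component(vol)
        np.testing.assert_array_equal(out1.data, out2.data)
        assert out1.data[1, 1, 1] == 1 and out1.data[6, 6, 6] == 0

    def test_never_adds_foreground_and_idempotent(self):
        for seed in range(5):
            vol = VoxelVolume(random_binary((12, 12, 12), p=0.2, seed=seed + 50), (1.0,) * 3)
            if vol.data.sum() == 0:
                continue
            once = largest_component(vol)
            assert (once.data <= vol.data).all()
            np.testing.assert_array_equal(largest_component(once).data, once.data)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            largest_component(VoxelVolume(np.zeros((4, 4, 4), np.uint8), (1.0,) * 3))

    def test_connectivity_6_splits_diagonal_touch(self):
        data = np.zeros((4, 4, 4), np.uint8)
        data[0, 0, 0] = 1
        data[1, 1, 1] = 1
        data[1, 1, 2] = 1
        out = largest_component(VoxelVolume(data, (1.0,) * 3), connectivity=6)
        assert out.data.sum() == 2
        out26 = largest_component(VoxelVolume(data, (1.0,) * 3), connectivity=26)
        assert out26.data.sum() == 3


class TestPropertyInvariants:
    binary_volumes = arrays(np.uint8, (8, 8, 8), elements=st.integers(0, 1))

    @settings(max_examples=30, deadline=None)
    @given(data=binary_volumes)
    def test_fill_holes_monotone_and_idempotent(self, data):
        vol = VoxelVolume(data, (1.0,) * 3)
        once = fill_holes(vol)
        assert (once.data >= vol.data).all()
        np.testing.assert_array_equal(fill_holes(once).data, once.data)

    @settings(max_examples=30, deadline=None)
    @given(data=binary_volumes)
    def test_largest_component_shrinks_and_idempotent(self, data):
        vol = VoxelVolume(data, (1.0,) * 3)
        if vol.data.sum() == 0:
            return
        once = largest_component(vol)
        assert (once.data <= vol.data).all()
        np.testing.assert_array_equal(largest_component(once).data, once.data)

    @settings(max_examples=20, deadline=None)
    @given(data=binary_volumes)
    def test_resample_identity_at_own_spacing(self, data):
        vol = VoxelVolume(data, (100.0,) * 3)
        out = resample_isotropic(vol, 100.0, mode="nearest")
        np.testing.assert_array_equal(out.data, vol.data)


class TestExtractSubregion:
    def test_thousand_cube_volume(self):
        assert subregion_volume_mm3((1000, 1000, 1000), (150.0,) * 3) == pytest.approx(3.375e-3)

    def test_full_extraction_is_identity(self):
        vol = VoxelVolume(random_binary((6, 7, 8), seed=9), (1.0,) * 3)
        out = extract_subregion(vol, (0, 0, 0), vol.shape)
        np.testing.assert_array_equal(out.data, vol.data)
        assert out.origin_vx == (0, 0, 0)

    def test_origin_recorded_and_nested(self):
        vol = VoxelVolume(random_binary((10, 10, 10), seed=10), (1.0,) * 3)
        sub = extract_subregion(vol, (2, 3, 4), (5, 5, 5))
        assert sub.origin_vx == (2, 3, 4)
        nested = extract_subregion(sub, (1, 1, 1), (2, 2, 2))
        assert nested.origin_vx == (3, 4, 5)
        np.testing.assert_array_equal(nested.data, vol.data[3:5, 4:6, 5:7])

    def test_out_of_bounds_rejected(self):
        vol = VoxelVolume(np.zeros((5, 5, 5), np.uint8), (1.0,) * 3)
        with pytest.raises(ValueError):
            extract_subregion(vol, (4, 0, 0), (3, 2, 2))
        with pytest.raises(ValueError):
            extract_subregion(vol, (6, 0, 0), (1, 1, 1))
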
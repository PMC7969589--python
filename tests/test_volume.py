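"""Volume segmentation: thresholding, morphology, components, watershed,
marching-cubes surface extraction."""

import numpy as np
import pytest

from meshmorph.errors import EmptyInputError, NoSurfaceError, ParameterError
from meshmorph.volume import (
    BinaryMask,
    LabelMap,
    VolumeImage,
    extract_surface,
    largest_component,
    morph_open_close,
    read_volume,
    threshold_mask,
    watershed_parcellate,
    write_volume,
)


def ball_mask(radius=10, pad=3, spacing=1.0):
    n = 2 * (radius + pad) + 1
    c = radius + pad
    zz, yy, xx = np.mgrid[:n, :n, :n]
    arr = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    return BinaryMask(arr, spacing * np.ones(3), np.zeros(3))


class TestThreshold:
    def test_uniform_below_threshold_gives_empty_mask(self):
        vol = VolumeImage(np.full((4, 4, 4), 10.0))
        assert threshold_mask(vol, 50).count() == 0

    def test_two_level_volume_selects_high_voxels(self, rng):
        arr = rng.choice([0.0, 100.0], size=(5, 5, 5))
        vol = VolumeImage(arr)
        mask = threshold_mask(vol, 50)
        assert np.array_equal(mask.array, arr == 100.0)

    def test_popcount_on_enumerated_voxels(self, rng):
        arr = np.full((3, 3, 3), 20.0)
        idx = rng.choice(27, size=7, replace=False)
        arr.ravel()[idx] = 80.0
        assert threshold_mask(VolumeImage(arr), 50).count() == 7

    def test_monotone_in_tau(self, rng):
        vol = VolumeImage(rng.uniform(0, 100, size=(6, 6, 6)))
        m_lo = threshold_mask(vol, 30).array
        m_hi = threshold_mask(vol, 60).array
        assert np.all(m_hi <= m_lo)

    def test_nonfinite_tau_rejected(self):
        vol = VolumeImage(np.ones((2, 2, 2)))
        with pytest.raises(ParameterError):
            threshold_mask(vol, np.nan)


class TestMorphology:
    def test_isolated_voxel_removed_by_opening(self):
        arr = np.zeros((7, 7, 7), bool)
        arr[3, 3, 3] = True
        out = morph_open_close(BinaryMask(arr), 1)
        assert out.count() == 0

    def test_solid_cube_loses_at_most_surface_shell(self):
        # brute-force oracle: erosion/dilation by explicit voxel shifts of a ball
        arr = np.zeros((13, 13, 13), bool)
        arr[2:11, 2:11, 2:11] = True

        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if dz * dz + dy * dy + dx * dx <= 1
        ]

        def erode(m):
            out = np.ones_like(m)
            for dz, dy, dx in offsets:
                out &= np.roll(m, (dz, dy, dx), axis=(0, 1, 2))
            return out

        def dilate(m):
            out = np.zeros_like(m)
            for dz, dy, dx in offsets:
                out |= np.roll(m, (dz, dy, dx), axis=(0, 1, 2))
            return out

        expected = erode(dilate(dilate(erode(arr))))  # open then close
        got = morph_open_close(BinaryMask(arr), 1)
        assert np.array_equal(got.array, expected)

    def test_single_interior_hole_filled(self):
        arr = np.zeros((11, 11, 11), bool)
        arr[2:9, 2:9, 2:9] = True
        arr[5, 5, 5] = False
        out = morph_open_close(BinaryMask(arr), 1)
        assert out.array[5, 5, 5]

    def test_idempotent_on_own_output(self, rng):
        # open-then-close is an alternating filter (idempotent away from the
        # volume border); keep a margin so border handling cannot interfere
        arr = np.zeros((13, 13, 13), bool)
        arr[2:11, 2:11, 2:11] = rng.random((9, 9, 9)) > 0.4
        once = morph_open_close(BinaryMask(arr), 1)
        twice = morph_open_close(once, 1)
        assert np.array_equal(once.array, twice.array)

    def test_radius_below_one_rejected(self):
        with pytest.raises(ParameterError):
            morph_open_close(BinaryMask(np.ones((3, 3, 3), bool)), 0)


class TestLargestComponent:
    def test_keeps_strictly_larger_blob(self):
        arr = np.zeros((20, 10, 10), bool)
        arr[1:6, 1:6, 1:5] = True  # 100 voxels
        arr[15:16, 1:6, 1:2] = True  # 5 voxels
        out = largest_component(BinaryMask(arr))
        assert out.count() == 100
        assert not out.array[15, 1, 1]

    def test_single_blob_unchanged(self):
        arr = np.zeros((6, 6, 6), bool)
        arr[1:4, 1:4, 1:4] = True
        out = largest_component(BinaryMask(arr))
        assert np.array_equal(out.array, arr)

    def test_tie_break_smallest_linear_index(self):
        arr = np.zeros((3, 3, 7), bool)
        arr[0, 0, 0:2] = True  # first in C order
        arr[2, 2, 4:6] = True  # equally large
        out = largest_component(BinaryMask(arr), connectivity=6)
        assert out.array[0, 0, 0] and not out.array[2, 2, 4]

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyInputError):
            largest_component(BinaryMask(np.zeros((3, 3, 3), bool)))


class TestWatershed:
    def two_spheres_with_bridge(self):
        arr = np.zeros((15, 15, 29), bool)
        zz, yy, xx = np.mgrid[:15, :15, :29]
        arr |= (zz - 7) ** 2 + (yy - 7) ** 2 + (xx - 7) ** 2 <= 25
        arr |= (zz - 7) ** 2 + (yy - 7) ** 2 + (xx - 21) ** 2 <= 25
        arr[7, 7, 12:17] = True  # 1-voxel-wide bridge
        return arr

    def test_single_marker_floods_whole_mask(self):
        arr = np.zeros((6, 6, 6), bool)
        arr[1:5, 1:5, 1:5] = True
        markers = np.zeros_like(arr, int)
        markers[2, 2, 2] = 1
        out = watershed_parcellate(BinaryMask(arr), LabelMap(markers))
        assert np.array_equal(out.array > 0, arr)
        assert set(np.unique(out.array)) == {0, 1}

    def test_bridge_split_matches_distance_transform_oracle(self):
        from scipy import ndimage
        from skimage.segmentation import watershed as sk_watershed

        arr = self.two_spheres_with_bridge()
        markers = np.zeros_like(arr, int)
        markers[7, 7, 7] = 1
        markers[7, 7, 21] = 2
        out = watershed_parcellate(BinaryMask(arr), LabelMap(markers))
        # each sphere centre keeps its own label; the cut falls on the bridge
        assert out.array[7, 7, 7] == 1 and out.array[7, 7, 21] == 2
        lab1 = out.array == 1
        lab2 = out.array == 2
        assert abs(lab1.sum() - lab2.sum()) < 0.2 * lab1.sum()
        # independent oracle on the same small volume
        dist = ndimage.distance_transform_edt(arr)
        expected = sk_watershed(-dist, markers=markers, mask=arr)
        assert np.array_equal(out.array, expected)

    def test_marker_labels_preserved(self):
        arr = np.ones((4, 4, 8), bool)
        markers = np.zeros_like(arr, int)
        markers[2, 2, 1] = 1
        markers[2, 2, 6] = 3
        out = watershed_parcellate(BinaryMask(arr), LabelMap(markers))
        assert set(np.unique(out.array)) <= {0, 1, 3}

    def test_labels_partition_mask(self):
        arr = self.two_spheres_with_bridge()
        markers = np.zeros_like(arr, int)
        markers[7, 7, 7] = 1
        markers[7, 7, 21] = 2
        out = watershed_parcellate(BinaryMask(arr), LabelMap(markers))
        assert np.array_equal(out.array > 0, arr)

    def test_no_markers_rejected(self):
        arr = np.ones((3, 3, 3), bool)
        with pytest.raises(ParameterError):
            watershed_parcellate(BinaryMask(arr), LabelMap(np.zeros_like(arr, int)))


class TestExtractSurface:
    def test_ball_area_within_5_percent(self):
        mesh = extract_surface(ball_mask(radius=10))
        assert mesh.area() == pytest.approx(4 * np.pi * 100, rel=0.05)

    def test_vertices_near_mask_boundary(self):
        mask = ball_mask(radius=8)
        mesh = extract_surface(mask)
        r = np.linalg.norm(mesh.vertices - (8 + 3), axis=1)
        half_diag = np.sqrt(3) / 2
        assert np.all(np.abs(r - 8) <= half_diag + 0.5)

    def test_watertight_euler_2_outward(self):
        mesh = extract_surface(ball_mask(radius=6))
        assert mesh.is_watertight()
        assert mesh.euler_characteristic() == 2
        assert mesh.signed_volume() > 0

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(NoSurfaceError):
            extract_surface(BinaryMask(np.zeros((4, 4, 4), bool)))
        with pytest.raises(NoSurfaceError):
            extract_surface(BinaryMask(np.ones((4, 4, 4), bool)))

    def test_spacing_and_origin_applied(self):
        mask = ball_mask(radius=5, spacing=0.5)
        mask.origin = np.array([1.0, 2.0, 3.0])
        mesh = extract_surface(mask)
        # centre in physical (x, y, z): index centre 8 * 0.5 + origin reversed
        centre = mesh.vertices.mean(axis=0)
        assert np.allclose(centre, [3.0 + 4.0, 2.0 + 4.0, 1.0 + 4.0], atol=0.1)


def test_volume_io_roundtrip(tmp_path, rng):
    vol = VolumeImage(rng.random((5, 6, 7)), [0.5, 0.4, 0.3], [1.0, -2.0, 0.5])
    for ext in ("nrrd", "nii.gz", "mhd"):
        path = tmp_path / f"v.{ext}"
        write_volume(vol, path)
        back = read_volume(path)
        assert np.allclose(back.array, vol.array, atol=1e-6)
        assert np.allclose(back.spacing, vol.spacing)
        assert np.allclose(back.origin, vol.origin)
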
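"""Boundary tracking, seed handling, region growing, and structure recovery."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import boundary_oracle, flood_fill_oracle, random_filled_blob
from ctsim.contours import contours_to_mask, fill_polygon_slice
from ctsim.errors import NoObjectError, OutOfBoundsError
from ctsim.segmentation import (
    SeedPoint,
    SegmentationParams,
    dice,
    region_grow,
    relocate_seed_outside,
    remove_small_regions,
    segment_structure,
    track_boundary,
)
from ctsim.volume import BinaryMask, VoxelVolume


class TestTrackBoundary:
    def test_single_pixel_closed(self):
        m = np.zeros((3, 3), np.uint8)
        m[1, 1] = 1
        path = track_boundary(m, (1, 1))
        assert path[0] == path[-1] == (1, 1)
        assert set(path) == {(1, 1)}

    def test_solid_3x3_square_border(self):
        m = np.zeros((5, 5), np.uint8)
        m[1:4, 1:4] = 1
        path = track_boundary(m, (2, 2))
        assert path[0] == path[-1]
        border = {(r, c) for r in range(1, 4) for c in range(1, 4)} - {(2, 2)}
        assert set(path) == border
        assert len(path) == 9  # 8 border pixels plus the closing repeat

    def test_closed_returns_to_start(self):
        m = np.zeros((8, 8), np.uint8)
        m[2:6, 3:7] = 1
        path = track_boundary(m, (3, 0))  # probe ray +x hits the block
        assert path[0] == path[-1]

    def test_every_point_is_4_adjacent_to_background(self):
        m = np.zeros((10, 10), np.uint8)
        m[2:8, 2:8] = 1
        for r, c in track_boundary(m, (4, 4)):
            nbrs = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
            assert any(
                not (0 <= rr < 10 and 0 <= cc < 10) or m[rr, cc] == 0
                for rr, cc in nbrs
            )

    def test_empty_mask_errors(self):
        with pytest.raises(NoObjectError):
            track_boundary(np.zeros((4, 4), np.uint8), (1, 1))

    def test_matches_morphological_oracle_on_random_blobs(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            comp = random_filled_blob(rng)
            if comp is None:
                continue
            r, c = map(int, np.argwhere(comp)[0])
            path = track_boundary(comp.astype(np.uint8), (r, c))
            assert set(path) == boundary_oracle(comp)
            checked += 1


class TestRelocateSeed:
    def test_seed_inside_returned_unchanged(self):
        m = np.zeros((8, 8), np.uint8)
        m[2:6, 2:6] = 1
        assert relocate_seed_outside(m, (3, 3)) == (3, 3)

    def test_background_seed_lands_strictly_inside_disk(self):
        m = np.zeros((40, 40), np.uint8)
        yy, xx = np.mgrid[:40, :40]
        disk = (yy - 20) ** 2 + (xx - 28) ** 2 <= 64
        m[disk] = 1
        r, c = relocate_seed_outside(m, (20, 2))  # background, left of disk
        assert disk[r, c]
        assert all(m[r + dr, c + dc] for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)))

    def test_empty_mask_errors(self):
        with pytest.raises(NoObjectError):
            relocate_seed_outside(np.zeros((5, 5), np.uint8), (1, 1))

    def test_out_of_bounds_seed_errors(self):
        m = np.ones((4, 4), np.uint8)
        with pytest.raises(OutOfBoundsError):
            relocate_seed_outside(m, (9, 9))


class TestRemoveSmallRegions:
    def test_4cm2_blob_removed_at_6cm2_threshold(self):
        m = np.zeros((6, 6), np.uint8)
        m[2:4, 2:4] = 1  # 4 px at 10x10 mm = 4 cm^2
        out = remove_small_regions(m, (10.0, 10.0), 6.0)
        assert not out.data.any()

    def test_large_region_untouched(self):
        m = np.ones((100, 100), np.uint8)  # 100 cm^2 at 1 mm pixels
        out = remove_small_regions(m, (1.0, 1.0), 6.0)
        assert np.array_equal(out.data, m)

    def test_only_large_region_survives_mixed_mask(self):
        m = np.zeros((100, 100), np.uint8)
        m[10:60, 10:60] = 1           # 25 cm^2
        m[80:90, 80:90] = 1           # 1 cm^2 spot
        m[5:7, 80:82] = 1             # tiny spot
        out = remove_small_regions(m, (1.0, 1.0), 6.0)
        assert out.data[30, 30] == 1
        assert out.data[85, 85] == 0 and out.data[5, 80] == 0


class TestRegionGrow:
    def test_uniform_volume_grows_everywhere(self):
        v = np.full((5, 5, 5), 40.0)
        assert region_grow(v, (2, 2, 2), 1.0).data.all()

    def test_two_blocks_500HU_apart_delta_50(self):
        v = np.zeros((4, 4, 8))
        v[:, :, 4:] = 500.0
        m = region_grow(v, (0, 0, 0), 50.0)
        assert m.data[:, :, :4].all() and not m.data[:, :, 4:].any()

    def test_delta_zero_is_equality_component(self):
        v = np.zeros((3, 3, 3))
        v[1, 1, 1] = 1.0
        m = region_grow(v, (0, 0, 0), 0.0)
        assert m.data.sum() == 26 and m.data[1, 1, 1] == 0

    def test_out_of_bounds_seed_errors(self):
        with pytest.raises(OutOfBoundsError):
            region_grow(np.zeros((3, 3, 3)), (5, 0, 0), 1.0)

    @pytest.mark.parametrize("delta", [0.0, 50.0, 100.0, 150.0, 250.0])
    def test_matches_flood_fill_oracle_on_random_volumes(self, delta):
        rng = np.random.default_rng(int(delta) + 1)
        for _ in range(25):
            data = rng.integers(0, 5, size=(16, 16, 16)).astype(float) * 100.0
            seed = tuple(rng.integers(0, 16, size=3))
            got = region_grow(data, seed, delta).data.astype(bool)
            assert np.array_equal(got, flood_fill_oracle(data, seed, delta))

    def test_compare_to_seed_mode(self):
        # ramp 0,60,120: neighbor mode chains through, seed mode stops
        v = np.zeros((1, 2, 3))
        v[0, :, 1] = 60.0
        v[0, :, 2] = 120.0
        chain = region_grow(v, (0, 0, 0), 70.0)
        assert chain.data.all()
        strict = region_grow(v, (0, 0, 0), 70.0, compare_to="seed")
        assert strict.data[0, :, :2].all() and not strict.data[0, :, 2:].any()


class TestSegmentStructure:
    def test_left_lung_recovery(self, thorax_small):
        vol, gt = thorax_small
        rr, cc = np.nonzero(gt.masks["left_lung"].data[24])
        seed = SeedPoint((24, int(rr.mean()), int(cc.mean())))
        res = segment_structure(
            vol, seed,
            SegmentationParams(hu_window=(-950, -600), min_region_area_cm2=0.5),
        )
        assert dice(res.mask.data, gt.masks["left_lung"].data) >= 0.95

    def test_outside_seed_finds_skin_surface(self, thorax_small):
        vol, gt = thorax_small
        res = segment_structure(
            vol,
            SeedPoint((24, 1, 1)),  # air background outside the body
            SegmentationParams(hu_window=(-500, 3071), min_region_area_cm2=0.5),
        )
        assert dice(res.mask.data, gt.skin_mask().data) >= 0.95

    def test_small_bright_spot_inside_lung_ignored(self):
        # lung-valued disk with a 2 cm^2 bright spot next to the seed
        ny = nx = 96
        yy, xx = np.mgrid[:ny, :nx]
        lung = (yy - 48) ** 2 + (xx - 48) ** 2 <= 40**2
        img = np.full((3, ny, nx), 40.0)
        img[:, lung] = -800.0
        spot = (yy - 48) ** 2 + (xx - 60) ** 2 <= 8**2  # ~2 cm^2 at 1 mm px
        img[:, spot] = 900.0
        vol = VoxelVolume(img, spacing=(5.0, 1.0, 1.0))
        # window catching the bright spot only -> too small, must error out
        # rather than trace the meaningless spot
        with pytest.raises(NoObjectError):
            segment_structure(
                vol,
                SeedPoint((1, 48, 60)),
                SegmentationParams(hu_window=(500, 1200)),
            )
        # lung window with the seed on the spot: relocated into the lung
        res = segment_structure(
            vol,
            SeedPoint((1, 48, 60)),
            SegmentationParams(hu_window=(-950, -600)),
        )
        want = lung & ~spot
        got = res.mask.data[1].astype(bool)
        assert dice(got, lung) >= 0.93  # traced outer contour fills the spot

    def test_deterministic(self, thorax_small):
        vol, gt = thorax_small
        rr, cc = np.nonzero(gt.masks["right_lung"].data[24])
        seed = SeedPoint((24, int(rr.mean()), int(cc.mean())))
        p = SegmentationParams(hu_window=(-950, -600), min_region_area_cm2=0.5)
        a = segment_structure(vol, seed, p)
        b = segment_structure(vol, seed, p)
        assert np.array_equal(a.mask.data, b.mask.data)

    def test_filling_contours_reproduces_mask_exactly(self, thorax_small):
        vol, gt = thorax_small
        rr, cc = np.nonzero(gt.masks["right_lung"].data[24])
        seed = SeedPoint((24, int(rr.mean()), int(cc.mean())))
        res = segment_structure(
            vol, seed,
            SegmentationParams(hu_window=(-950, -600), min_region_area_cm2=0.5),
        )
        refilled = contours_to_mask(res.contours, vol)
        assert np.array_equal(refilled.data, res.mask.data)

    def test_absent_structure_errors(self, thorax_small):
        vol, _ = thorax_small
        with pytest.raises(NoObjectError):
            segment_structure(
                vol, SeedPoint((0, 1, 1)), SegmentationParams(hu_window=(2000, 3000))
            )


class TestMaskBoundaryRoundTrip:
    def test_fill_of_traced_boundary_recovers_blob(self):
        rng = np.random.default_rng(9)
        checked = 0
        while checked < 30:
            comp = random_filled_blob(rng, shape=(32, 32))
            if comp is None or comp.sum() < 12:
                continue
            r, c = map(int, np.argwhere(comp)[0])
            path = track_boundary(comp.astype(np.uint8), (r, c))
            filled = fill_polygon_slice(np.asarray(path, float), comp.shape)
            assert dice(filled, comp) >= 0.99
            checked += 1
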
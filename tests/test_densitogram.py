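"""Projection, quantization, colour rendering, density maxima, MAR, grid."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctoam import densitogram as dg
from ctoam.densitogram import (
    Densitogram,
    DomainError,
    WindowError,
    colorize,
    compute_mar,
    grid_coordinates,
    locate_density_maxima,
    project,
    quantize,
)
from ctoam.segmentation import (
    DORSAL,
    PROXIMAL,
    ViewMismatchError,
    extract_plate,
    find_articular_surface,
    segment_bone,
)
from ctoam.volume import CTVolume


def slab(value=800.0, hot=None):
    """3 mm slab at 0.5 mm spacing (surface layer z=15), optional hot voxel."""
    hu = np.full((20, 20, 24), -1000.0)
    hu[4:16, 4:16, 10:16] = value
    if hot is not None:
        (i, j, depth_mm), hv = hot
        hu[i, j, 15 - int(depth_mm / 0.5)] = hv
    return CTVolume(hu=hu, spacing=(0.5, 0.5, 0.5))


def project_slab(vol, depth_mm=1.5, view=PROXIMAL):
    bone = segment_bone(vol, 200.0)
    surface = find_articular_surface(bone, view)
    plate = extract_plate(bone, surface, depth_mm=depth_mm)
    return project(vol, plate, view)


def toy_densitogram(max_map, surface):
    """Wrap a raw 2D HU array as a Densitogram for quantization tests."""
    mm = np.where(surface, max_map, np.nan)
    return Densitogram(view=PROXIMAL, max_map=mm, mean_map=mm,
                       surface_mask=surface, pixel_spacing=(0.5, 0.5))


class TestProject:
    def test_constant_plate_projects_constant_maps(self):
        d = project_slab(slab(800.0))
        on = d.surface_mask
        assert on.sum() == 144
        assert np.allclose(d.max_map[on], 800.0)
        assert np.allclose(d.mean_map[on], 800.0)
        assert np.isnan(d.max_map[~on]).all()

    def test_hot_voxel_within_depth_raises_pixel_max(self):
        # 1100 HU voxel 1.0 mm below the surface: inside the 1.5 mm depth
        d = project_slab(slab(800.0, hot=((8, 8, 1.0), 1100.0)))
        assert d.max_map[8, 8] == pytest.approx(1100.0)
        assert d.max_map[8, 9] == pytest.approx(800.0)
        # the mean also feels it: (800*3 + 1100) / 4
        assert d.mean_map[8, 8] == pytest.approx((800.0 * 3 + 1100.0) / 4)

    def test_hot_voxel_beyond_depth_is_excluded(self):
        # same voxel 2.0 mm below the surface: beyond the 1.5 mm MIP depth
        d = project_slab(slab(800.0, hot=((8, 8, 2.0), 1100.0)))
        assert d.max_map[8, 8] == pytest.approx(800.0)

    def test_mip_dominates_mean_on_phantom(self, default_pair):
        (vol, _), _ = default_pair
        for view in (PROXIMAL, DORSAL):
            bone = segment_bone(vol, 200.0)
            surface = find_articular_surface(bone, view)
            plate = extract_plate(bone, surface, 1.5)
            d = project(vol, plate, view)
            on = d.surface_mask
            assert (d.max_map[on] >= d.mean_map[on] - 1e-9).all()

    def test_view_mismatch_rejected(self):
        vol = slab()
        bone = segment_bone(vol, 200.0)
        surface = find_articular_surface(bone, PROXIMAL)
        plate = extract_plate(bone, surface, 1.5)
        with pytest.raises(ViewMismatchError):
            project(vol, plate, DORSAL)


class TestQuantize:
    @pytest.mark.parametrize("hu,eightbit,bin_", [
        (200.0, 0, 0),  # window floor
        (1200.0, 255, 7),  # window ceiling stays in the top bin
        (700.0, 128, 4),  # round(255 * 0.5) = 128, half away from zero
        (100.0, 0, 0),  # below-window clips
        (1500.0, 255, 7),  # above-window clips
    ])
    def test_eightbit_and_bin_values(self, hu, eightbit, bin_):
        surface = np.ones((1, 1), dtype=bool)
        q = quantize(toy_densitogram(np.array([[hu]]), surface))
        assert q.eightbit_map[0, 0] == eightbit
        assert q.bin_map[0, 0] == bin_

    def test_256_levels_split_into_8_bins_of_32(self):
        # one pixel per representable 8-bit level across the window
        hu = 200.0 + 1000.0 * np.arange(256) / 255.0
        surface = np.ones((16, 16), dtype=bool)
        q = quantize(toy_densitogram(hu.reshape(16, 16), surface))
        levels = np.sort(q.eightbit_map[surface])
        assert np.array_equal(levels, np.arange(256))
        counts = np.bincount(q.bin_map[surface], minlength=8)
        assert np.array_equal(counts, np.full(8, 32))

    def test_bin_histogram_conserves_surface_pixels(self, default_pair):
        (vol, _), _ = default_pair
        d = _phantom_densitogram(vol)
        q = quantize(d)
        counts = np.bincount(q.bin_map[q.surface_mask], minlength=8)
        assert counts.sum() == q.surface_mask.sum()

    def test_off_surface_pixels_are_sentinel(self):
        surface = np.zeros((2, 2), dtype=bool)
        surface[0, 0] = True
        q = quantize(toy_densitogram(np.full((2, 2), 700.0), surface))
        assert q.eightbit_map[1, 1] == -1
        assert q.bin_map[1, 1] == -1

    def test_degenerate_window_rejected(self):
        surface = np.ones((1, 1), dtype=bool)
        with pytest.raises(WindowError):
            quantize(toy_densitogram(np.array([[700.0]]), surface),
                     window=(500.0, 500.0))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_bin_is_floor_of_eightbit_over_32(self, seed):
        rng = np.random.default_rng(seed)
        hu = rng.uniform(-200, 1600, size=(9, 9))
        surface = rng.random((9, 9)) < 0.8
        if not surface.any():
            surface[0, 0] = True
        q = quantize(toy_densitogram(hu, surface))
        on = surface
        assert np.array_equal(q.bin_map[on],
                              np.minimum(q.eightbit_map[on] // 32, 7))
        assert q.color_map[on].min() >= 0 and q.color_map[on].max() <= 9


class TestColorize:
    def test_color_scale_ends(self):
        surface = np.ones((1, 2), dtype=bool)
        q = quantize(toy_densitogram(np.array([[1150.0, 250.0]]), surface))
        img = colorize(q)
        assert q.color_map[0, 0] == 9 and tuple(img[0, 0]) == (0, 0, 0)  # black
        assert q.color_map[0, 1] == 0 and tuple(img[0, 1]) == (255, 255, 255)  # white

    def test_ramp_renders_all_ten_classes_in_order(self):
        hu = np.linspace(200.0, 1199.9, 10).reshape(1, 10)
        surface = np.ones((1, 10), dtype=bool)
        q = quantize(toy_densitogram(hu, surface))
        assert np.array_equal(q.color_map[0], np.arange(10))
        img = colorize(q)
        rendered = {tuple(px) for px in img[0]}
        assert len(rendered) == 10
        assert np.array_equal(img[0, 0], (255, 255, 255))
        assert np.array_equal(img[0, 9], (0, 0, 0))


class TestGridCoordinates:
    def test_bbox_corners_map_to_1_and_30(self):
        surface = np.zeros((80, 80), dtype=bool)
        surface[10:70, 10:70] = True  # 60 x 60 footprint
        assert grid_coordinates(surface, (10, 10)) == (1, 1)
        assert grid_coordinates(surface, (69, 69)) == (30, 30)

    def test_bbox_midpoint_of_60_footprint(self):
        surface = np.zeros((80, 80), dtype=bool)
        surface[10:70, 10:70] = True
        # pixel 30 beyond bbox min: 1 + floor(30 * 30 / 60) = 16
        assert grid_coordinates(surface, (40, 40)) == (16, 16)

    def test_point_off_surface_rejected(self):
        surface = np.zeros((10, 10), dtype=bool)
        surface[2:5, 2:5] = True
        with pytest.raises(DomainError):
            grid_coordinates(surface, (8, 8))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_all_surface_pixels_land_inside_the_grid(self, seed):
        rng = np.random.default_rng(seed)
        surface = rng.random((25, 31)) < 0.3
        if not surface.any():
            surface[3, 4] = True
        for i, j in zip(*np.nonzero(surface)):
            x, y = grid_coordinates(surface, (i, j))
            assert 1 <= x <= 30 and 1 <= y <= 30


class TestDensityMaxima:
    def test_whole_surface_in_top_bin(self):
        surface = np.ones((5, 5), dtype=bool)
        q = quantize(toy_densitogram(np.full((5, 5), 1200.0), surface))
        summary = locate_density_maxima(q)
        assert summary.n_regions == 1
        assert summary.mar == 1.0

    def test_nothing_above_bin_5_gives_empty_maximum(self):
        surface = np.ones((5, 5), dtype=bool)
        q = quantize(toy_densitogram(np.full((5, 5), 700.0), surface))
        summary = locate_density_maxima(q)
        assert summary.n_regions == 0
        assert summary.mar == 0.0

    def test_toy_regions_and_mar(self):
        # 4x4 surface; three maximum pixels: two 8-adjacent + one isolated
        surface = np.ones((4, 4), dtype=bool)
        hu = np.full((4, 4), 700.0)
        hu[0, 0] = 1150.0  # bin 7
        hu[1, 1] = 1000.0  # bin 6, diagonal neighbour -> same region
        hu[3, 3] = 1000.0  # isolated
        q = quantize(toy_densitogram(hu, surface))
        summary = locate_density_maxima(q)
        assert summary.n_regions == 2
        assert summary.mar == pytest.approx(3 / 16)
        assert sorted(r.n_pixels for r in summary.regions) == [1, 2]

    def test_restricting_to_top_bin_never_increases_mar(self, default_pair):
        (vol, _), _ = default_pair
        d = _phantom_densitogram(vol)
        q = quantize(d)
        both = compute_mar(q.surface_mask & (q.bin_map >= 6), q.surface_mask)
        top_only = compute_mar(q.surface_mask & (q.bin_map == 7), q.surface_mask)
        assert top_only <= both

    def test_translation_invariance_of_mar_bins_and_grid(self, default_pair):
        (vol, _), _ = default_pair
        d = _phantom_densitogram(vol)
        q = quantize(d)
        s = locate_density_maxima(q)
        shifted = CTVolume(hu=np.roll(vol.hu, (3, -2, 0), axis=(0, 1, 2)),
                           spacing=vol.spacing)
        d2 = _phantom_densitogram(shifted)
        q2 = quantize(d2)
        s2 = locate_density_maxima(q2)
        assert s2.mar == s.mar
        assert np.array_equal(
            np.bincount(q.bin_map[q.surface_mask], minlength=8),
            np.bincount(q2.bin_map[q2.surface_mask], minlength=8))
        assert sorted(s.grid_coords) == sorted(s2.grid_coords)


class TestComputeMar:
    def test_exact_count_ratio(self):
        surface = np.zeros((20, 20), dtype=bool)
        surface[:10, :20] = True  # 200 surface pixels
        maximum = np.zeros((20, 20), dtype=bool)
        maximum[:5, :5] = True  # 25 maximum pixels
        assert compute_mar(maximum, surface) == 0.125

    def test_bounds(self):
        surface = np.ones((4, 4), dtype=bool)
        assert compute_mar(np.zeros((4, 4), dtype=bool), surface) == 0.0
        assert compute_mar(surface, surface) == 1.0

    def test_empty_surface_rejected(self):
        with pytest.raises(DomainError):
            compute_mar(np.ones((2, 2), dtype=bool), np.zeros((2, 2), dtype=bool))


def _phantom_densitogram(vol, view=PROXIMAL):
    bone = segment_bone(vol, 200.0)
    surface = find_articular_surface(bone, view)
    plate = extract_plate(bone, surface, 1.5)
    return project(vol, plate, view)
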
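"""Contour finding, ellipse fitting, object measurement, species filters."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from zoobooth.detection import (
    Contour,
    EllipseFitError,
    ObjectMeasurement,
    SpeciesProfile,
    apply_species_filter,
    default_profile,
    find_contours,
    fit_ellipse,
    load_species_profiles,
    measure_object,
    select_largest,
)

masks_small = hnp.arrays(
    dtype=np.uint8,
    shape=st.tuples(st.integers(3, 14), st.integers(3, 14)),
    elements=st.sampled_from([0, 0, 0, 255]),
)


def flood_fill_count(mask: np.ndarray) -> int:
    """Independent 8-connected component count by explicit flood fill."""
    fg = mask > 0
    seen = np.zeros_like(fg)
    h, w = fg.shape
    count = 0
    for i in range(h):
        for j in range(w):
            if fg[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and fg[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


def raster_ellipse_mask(a, b, phi_deg=0.0, center=(64.0, 64.0), shape=(128, 128)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    phi = np.deg2rad(phi_deg)
    dx, dy = xx - center[0], yy - center[1]
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return (inside * np.uint8(255)).astype(np.uint8)


def ellipse_boundary_points(a, b, phi_deg, center, n=100, noise_sd=0.0, rng=None):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    phi = np.deg2rad(phi_deg)
    x = center[0] + a * np.cos(t) * np.cos(phi) - b * np.sin(t) * np.sin(phi)
    y = center[1] + a * np.cos(t) * np.sin(phi) + b * np.sin(t) * np.cos(phi)
    pts = np.column_stack([x, y])
    if noise_sd:
        pts += rng.normal(scale=noise_sd, size=pts.shape)
    return pts


def contour_from_points(pts):
    return Contour(points=np.asarray(pts, float), pixel_coords=(np.array([0]), np.array([0])))


class TestFindContours:
    def test_empty_mask(self):
        assert find_contours(np.zeros((10, 10), np.uint8)) == []

    def test_filled_square(self):
        mask = np.zeros((20, 20), np.uint8)
        mask[5:15, 5:15] = 255
        contours = find_contours(mask)
        assert len(contours) == 1
        assert contours[0].area_px == 100

    @given(mask=masks_small)
    def test_component_count_matches_flood_fill(self, mask):
        assert len(find_contours(mask)) == flood_fill_count(mask)

    def test_scan_order_is_top_left_first(self):
        mask = np.zeros((20, 20), np.uint8)
        mask[2:4, 10:12] = 255  # appears first in row scan
        mask[10:12, 2:4] = 255
        contours = find_contours(mask)
        firsts = [c.pixel_coords[0].min() for c in contours]
        assert firsts == sorted(firsts)


class TestSelectLargest:
    def test_picks_larger_area(self):
        mask = np.zeros((30, 30), np.uint8)
        mask[1:11, 1:11] = 255  # 100 px
        mask[15:29, 15:29] = 255  # 196 px
        best = select_largest(find_contours(mask))
        assert best.area_px == 196

    def test_empty_list(self):
        assert select_largest([]) is None

    def test_argmax_over_pixel_counts(self, rng):
        mask = (rng.random((40, 40)) < 0.3).astype(np.uint8) * 255
        contours = find_contours(mask)
        if not contours:
            return
        best = select_largest(contours)
        assert best.area_px == max(c.area_px for c in contours)


class TestFitEllipse:
    def test_axis_aligned_ellipse(self):
        pts = ellipse_boundary_points(30, 10, 0, (50, 50))
        major, minor, ori, center = fit_ellipse(contour_from_points(pts))
        assert major == pytest.approx(60, rel=0.01)
        assert minor == pytest.approx(20, rel=0.01)
        assert center[0] == pytest.approx(50, abs=0.5)
        assert center[1] == pytest.approx(50, abs=0.5)
        assert min(ori, 180 - ori) < 1.0

    def test_circle(self):
        pts = ellipse_boundary_points(15, 15, 0, (40, 40))
        major, minor, _, _ = fit_ellipse(contour_from_points(pts))
        assert major == pytest.approx(30, rel=0.01)
        assert minor == pytest.approx(30, rel=0.01)

    def test_noisy_rotated_matches_dense_refit(self, rng):
        noisy = ellipse_boundary_points(30, 10, 37, (60, 60), n=100, noise_sd=0.3, rng=rng)
        dense = ellipse_boundary_points(30, 10, 37, (60, 60), n=2000)
        got = fit_ellipse(contour_from_points(noisy))
        ref = fit_ellipse(contour_from_points(dense))
        assert got[0] == pytest.approx(ref[0], rel=0.02)
        assert got[1] == pytest.approx(ref[1], rel=0.02)
        assert abs(got[2] - ref[2]) < 2.0

    def test_too_few_points_rejected(self):
        with pytest.raises(EllipseFitError):
            fit_ellipse(contour_from_points(np.array([[0, 0], [1, 1], [2, 2], [3, 3]])))

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(EllipseFitError):
            fit_ellipse(contour_from_points(pts))

    def test_rotation_equivariance(self):
        base = ellipse_boundary_points(25, 12, 0, (0, 0))
        m0 = fit_ellipse(contour_from_points(base))
        for rot in (20, 65, 110):
            r = np.deg2rad(rot)
            rotm = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
            m1 = fit_ellipse(contour_from_points(base @ rotm.T))
            assert m1[0] == pytest.approx(m0[0], rel=0.01)
            assert m1[1] == pytest.approx(m0[1], rel=0.01)
            assert abs(((m1[2] - m0[2]) - rot + 90) % 180 - 90) < 1.0

    @pytest.mark.parametrize("a,b", [(10, 5), (30, 12), (60, 40), (100, 55)])
    def test_rasterized_ellipse_axes_within_2pct(self, a, b):
        mask = raster_ellipse_mask(a, b, 25.0, (128, 128), (256, 256))
        contour = select_largest(find_contours(mask))
        major, minor, _, _ = fit_ellipse(contour)
        assert major == pytest.approx(2 * a, rel=0.02, abs=1.5)
        assert minor == pytest.approx(2 * b, rel=0.02, abs=1.5)


class TestMeasureObject:
    def test_brightness_of_uniform_object(self):
        mask = raster_ellipse_mask(20, 10, 0, (50, 50), (100, 100))
        frame = np.zeros((100, 100), np.uint8)
        frame[mask > 0] = 200
        contour = select_largest(find_contours(mask))
        m = measure_object(contour, frame, (0, 0, 100, 100), frame_sharpness=5.0)
        assert m.brightness == pytest.approx(200)

    def test_brightness_equals_masked_mean_oracle(self, rng):
        mask = raster_ellipse_mask(18, 9, 30, (50, 50), (100, 100))
        frame = rng.integers(0, 256, size=(100, 100)).astype(np.uint8)
        contour = select_largest(find_contours(mask))
        m = measure_object(contour, frame, (0, 0, 100, 100), frame_sharpness=5.0)
        assert m.brightness == pytest.approx(frame[mask > 0].mean())

    def test_edge_distance(self):
        mask = raster_ellipse_mask(8, 4, 0, (12, 300), (600, 900))
        contour = select_largest(find_contours(mask))
        m = measure_object(contour, np.full((600, 900), 90, np.uint8), (0, 0, 900, 600),
                           frame_sharpness=5.0)
        assert m.edge_distance_px == pytest.approx(12, abs=0.5)


class TestSpeciesFilter:
    def make(self, **kw):
        defaults = dict(
            frame_index=0, major_axis_px=60.0, minor_axis_px=40.0, orientation_deg=0.0,
            area_px=2000.0, brightness=40.0, sharpness=2.0, center_x=300.0, center_y=300.0,
            edge_distance_px=50.0,
        )
        defaults.update(kw)
        return ObjectMeasurement(**defaults)

    def test_daphnia_profile_accepts_in_range(self, daphnia_profile):
        assert apply_species_filter(self.make(), daphnia_profile) is None

    def test_area_too_small_rejected(self, daphnia_profile):
        assert apply_species_filter(self.make(area_px=1000), daphnia_profile) == "area"

    def test_edge_too_close_rejected(self, daphnia_profile):
        assert apply_species_filter(self.make(edge_distance_px=5), daphnia_profile) == "edge"

    def test_first_failed_criterion_reported(self, daphnia_profile):
        m = self.make(area_px=1000, brightness=5, edge_distance_px=1)
        assert apply_species_filter(m, daphnia_profile) == "area"
        m = self.make(major_axis_px=80, minor_axis_px=40, brightness=5)  # ratio 2.0
        assert apply_species_filter(m, daphnia_profile) == "lw_ratio"
        assert apply_species_filter(self.make(sharpness=1.0), daphnia_profile) == "sharpness"

    def test_relaxing_thresholds_is_monotone(self, daphnia_profile, rng):
        ms = [
            self.make(
                area_px=float(rng.uniform(500, 6000)),
                major_axis_px=60.0,
                minor_axis_px=float(rng.uniform(30, 55)),
                brightness=float(rng.uniform(0, 255)),
                sharpness=float(rng.uniform(0, 5)),
                edge_distance_px=float(rng.uniform(0, 60)),
            )
            for _ in range(200)
        ]
        strict = sum(apply_species_filter(m, daphnia_profile) is None for m in ms)
        relaxed_profile = daphnia_profile.replace(
            min_area_px=100, max_area_px=10000, min_lw_ratio=1.0, max_lw_ratio=3.0,
            min_brightness=0, min_sharpness=0, min_edge_distance_px=0,
        )
        relaxed = sum(apply_species_filter(m, relaxed_profile) is None for m in ms)
        assert relaxed >= strict

    def test_packaged_profiles_match_field_table(self):
        profiles = load_species_profiles()
        d = profiles["daphnia"]
        assert (d.min_area_px, d.max_area_px) == (1500, 4000)
        assert (d.min_lw_ratio, d.max_lw_ratio) == (1.2, 1.7)
        assert d.min_brightness == 30 and d.optimal_percentile == 93
        assert d.min_sharpness == pytest.approx(1.8)
        assert d.min_edge_distance_px == 10
        cyc = profiles["eucyclops_mesocyclops"]
        assert (cyc.min_area_px, cyc.max_area_px, cyc.optimal_percentile) == (290, 850, 90)
        assert default_profile() == d
        assert set(profiles) == {
            "daphnia", "eucyclops_mesocyclops", "diaphanosoma", "heterocope",
            "polyphemus", "scapholebrius",
        }
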
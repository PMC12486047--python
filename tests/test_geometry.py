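"""Geometry oracles: analytic scenes, exhaustive scans, invariances."""

import numpy as np
import pytest

from conftest import bare_hemisphere, sheet
from vascbci import geometry, synth
from vascbci.types import (
    StentLine,
    StentSegmentation,
    SurfaceModel,
    VesselModel,
)


def straight_vessel(y_hi=70.0, y_lo=-40.0, radius=3.55, z=35.0, spacing=1.0):
    y = np.arange(y_hi, y_lo - 0.5 * spacing, -spacing)
    pts = np.stack([np.zeros_like(y), y, np.full_like(y, z)], axis=1)
    return VesselModel(points=pts, radii=np.full(len(y), radius))


def line_on_axis(y_hi, y_lo, z=0.0, spacing=0.5):
    y = np.arange(y_hi, y_lo - 1e-9, -spacing)
    return StentLine(points=np.stack(
        [np.zeros_like(y), y, np.full_like(y, z)], axis=1))


class TestFitStentLine:
    def test_straight_centerline_spans_expected_interval(self):
        vessel = straight_vessel()
        seg = StentSegmentation(points=np.array([[1.0, 60.0, 35.0]]))
        line = geometry.fit_stent_line(seg, vessel, length=25.0)
        lo, hi = line.rc_interval()
        assert hi == pytest.approx(60.0, abs=1e-9)
        assert lo == pytest.approx(35.0, abs=1e-9)
        assert line.arc_length == pytest.approx(25.0, abs=1e-9)

    def test_circular_arc_length_matches_quadrature(self):
        # quarter circle of radius 100 in the y-z plane, y decreasing
        theta = np.linspace(np.pi / 2, 0, 400)
        pts = np.stack(
            [np.zeros_like(theta), 100 * np.sin(theta), 100 * (1 - np.cos(theta))],
            axis=1,
        )
        vessel = VesselModel(points=pts, radii=np.full(len(pts), 3.0))
        seg = StentSegmentation(points=np.array([[0.0, 100.0, 0.0]]))
        line = geometry.fit_stent_line(seg, vessel, length=25.0)
        assert line.arc_length == pytest.approx(25.0, abs=0.1)
        # independent check: chord-sum quadrature at finer resolution
        chord = np.linalg.norm(np.diff(line.points, axis=0), axis=1).sum()
        assert chord == pytest.approx(25.0, abs=0.1)

    def test_single_point_segmentation_sets_station(self):
        vessel = straight_vessel()
        seg = StentSegmentation(points=np.array([[0.0, 41.3, 35.0]]))
        line = geometry.fit_stent_line(seg, vessel)
        # tip snaps to the nearest centerline station
        assert abs(line.rc_interval()[1] - 41.3) <= 0.5

    def test_exhausted_centerline_rejected(self):
        vessel = straight_vessel(y_hi=10.0, y_lo=-5.0)
        seg = StentSegmentation(points=np.array([[0.0, 10.0, 35.0]]))
        with pytest.raises(ValueError, match="exhausted"):
            geometry.fit_stent_line(seg, vessel, length=25.0)


class TestStentToCortex:
    def test_cylindrical_sheet_mean_equals_min(self):
        # vertices on a radius-6 cylinder around the line's axis, stations
        # matching the line samples so nearest vertices are exactly radial
        y = np.arange(45.0, 19.9, -0.5)
        line = line_on_axis(45.0, 20.0)
        hemis = {}
        for tag, sign in (("L", -1), ("R", 1)):
            ang = np.linspace(0.1, np.pi - 0.1, 9)
            verts = []
            for yy in y:
                verts.append(np.stack([
                    sign * 6 * np.sin(ang), np.full_like(ang, yy), 6 * np.cos(ang)
                ], axis=1))
            hemis[tag] = bare_hemisphere(np.concatenate(verts), tag=tag)
        surf = SurfaceModel(left=hemis["L"], right=hemis["R"])
        d = geometry.stent_to_cortex(line, surf)
        assert d.mean == pytest.approx(6.0, abs=0.05)
        assert d.minimum == pytest.approx(6.0, abs=0.05)

    def test_parallel_planes_average_and_min(self):
        y = np.arange(45.0, 19.9, -0.5)
        surf = SurfaceModel(
            left=bare_hemisphere(sheet(-8.0, y), tag="L"),
            right=bare_hemisphere(sheet(4.0, y), tag="R"),
        )
        line = line_on_axis(45.0, 20.0)
        d = geometry.stent_to_cortex(line, surf)
        assert d.mean == pytest.approx(6.0, abs=0.05)
        assert d.minimum == pytest.approx(4.0, abs=0.05)

    def test_matches_exhaustive_all_pairs_scan(self):
        rng = np.random.default_rng(3)
        verts_l = rng.uniform([-30, -20, -10], [-2, 60, 30], size=(500, 3))
        verts_r = rng.uniform([2, -20, -10], [30, 60, 30], size=(500, 3))
        surf = SurfaceModel(
            left=bare_hemisphere(verts_l, tag="L"),
            right=bare_hemisphere(verts_r, tag="R"),
        )
        line = line_on_axis(50.0, 25.0, z=10.0)
        d = geometry.stent_to_cortex(line, surf)
        # brute force oracle
        means, mins = [], []
        for verts in (verts_l, verts_r):
            dd = np.linalg.norm(
                line.points[:, None, :] - verts[None, :, :], axis=2
            ).min(axis=1)
            means.append(dd)
            mins.append(dd.min())
        assert d.mean == pytest.approx(np.mean(means, axis=0).mean(), abs=1e-12)
        assert d.minimum == pytest.approx(min(mins), abs=1e-12)

    def test_roi_restriction_and_missing_roi(self, small_surface):
        vessel, seg = synth.generate_vessel_and_stent(
            small_surface, rostral_tip=45.0, seed=1
        )
        line = geometry.fit_stent_line(seg, vessel)
        d_all = geometry.stent_to_cortex(line, small_surface, "ALL")
        d_m1 = geometry.stent_to_cortex(line, small_surface, "M1")
        assert d_all.minimum <= d_m1.minimum + 1e-12
        with pytest.raises(ValueError, match="absent"):
            # the synthetic label set never includes this region
            geometry.stent_to_cortex(line, small_surface, "OTHER" * 2)


class TestRoiOverlap:
    BANDS = {"SMA": (45.0, 70.0), "M1": (30.0, 55.0)}

    def test_interval_arithmetic_containment(self):
        ov = geometry.interval_overlap((20.0, 45.0), {"M1": (10.0, 50.0)})
        assert ov["M1"] == pytest.approx(100.0)

    def test_interval_arithmetic_partial(self):
        ov = geometry.interval_overlap((20.0, 45.0), {"M1": (30.0, 55.0)})
        assert ov["M1"] == pytest.approx(60.0)  # 15 of 25 mm

    def test_interval_arithmetic_disjoint(self):
        ov = geometry.interval_overlap((20.0, 45.0), {"M1": (50.0, 60.0)})
        assert ov["M1"] == 0.0

    def test_surface_extraction_recovers_declared_bands(self):
        surf = synth.generate_surface(spacing=1.0, seed=0)
        got = geometry.roi_band_intervals(surf)
        for roi, (lo, hi) in synth.DEFAULT_BANDS.items():
            glo, ghi = got[roi]
            # band edges recovered within half the vertex spacing
            assert abs(glo - lo) <= 0.51
            assert abs(ghi - hi) <= 0.51

    def test_overlaps_sum_to_100_over_exhaustive_bands(self, small_surface):
        vessel, seg = synth.generate_vessel_and_stent(
            small_surface, rostral_tip=40.0, seed=2
        )
        line = geometry.fit_stent_line(seg, vessel)
        ov = geometry.roi_overlap(line, small_surface)
        assert sum(ov.percent.values()) == pytest.approx(100.0, abs=0.1)

    def test_m1_overlap_monotone_in_tip_sweep(self):
        surf = synth.generate_surface(spacing=1.5, seed=4)
        vals = []
        for tip in [25.0, 30.0, 35.0, 40.0, 45.0]:
            vessel, seg = synth.generate_vessel_and_stent(
                surf, rostral_tip=tip, seed=5
            )
            line = geometry.fit_stent_line(seg, vessel)
            vals.append(geometry.roi_overlap(line, surf)["M1"])
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > vals[0]


class TestSinusWidth:
    def test_constant_radius(self):
        vessel = straight_vessel(radius=3.55, z=0.0)
        line = line_on_axis(45.0, 20.0)
        assert geometry.sinus_width(vessel, line) == pytest.approx(7.1)

    def test_linear_radius_mean(self):
        y = np.arange(70.0, -40.5, -1.0)
        # radius rises linearly 3 -> 4 mm across the stent span [20, 45]
        radii = np.interp(y, [20.0, 45.0], [3.0, 4.0])
        radii[y < 20] = 3.0
        radii[y > 45] = 4.0
        vessel = VesselModel(
            points=np.stack([np.zeros_like(y), y, np.zeros_like(y)], axis=1),
            radii=radii,
        )
        line = line_on_axis(45.0, 20.0)
        assert geometry.sinus_width(vessel, line) == pytest.approx(7.0, abs=0.01)

    def test_piecewise_radii_match_trapezoid_oracle(self):
        rng = np.random.default_rng(8)
        y = np.arange(70.0, -40.5, -1.0)
        radii = 3.0 + rng.uniform(0, 1.5, size=len(y))
        vessel = VesselModel(
            points=np.stack([np.zeros_like(y), y, np.zeros_like(y)], axis=1),
            radii=radii,
        )
        line = line_on_axis(45.0, 20.0)
        got = geometry.sinus_width(vessel, line)
        ys = np.linspace(20.0, 45.0, 2001)
        oracle = np.trapezoid(2 * vessel.radius_at(ys), ys) / 25.0
        assert got == pytest.approx(oracle, rel=0.01)

    def test_line_outside_vessel_rejected(self):
        vessel = straight_vessel(y_hi=40.0, y_lo=0.0)
        line = line_on_axis(60.0, 35.0)
        with pytest.raises(ValueError):
            geometry.sinus_width(vessel, line)


class TestCorticalThickness:
    def test_parallel_offset_sheets(self):
        surf = synth.generate_flat_surface(thickness=2.5, spacing=3.0)
        assert geometry.cortical_thickness(surf, "M1") == pytest.approx(2.5)

    def test_identical_surfaces_zero(self):
        y = np.arange(45.0, 19.9, -1.0)
        labels = np.full(len(y), "M1")
        h_l = bare_hemisphere(sheet(-5.0, y), labels=labels, tag="L")
        h_r = bare_hemisphere(sheet(5.0, y), labels=labels, tag="R")
        surf = SurfaceModel(left=h_l, right=h_r)
        assert geometry.cortical_thickness(surf, "M1") == 0.0

    def test_planted_offsets_recovered_exactly(self):
        rng = np.random.default_rng(1)
        y = np.arange(45.0, 19.9, -1.0)
        offsets = rng.uniform(1.5, 3.5, size=2 * len(y))
        pial_l, pial_r = sheet(-5.0, y), sheet(5.0, y)
        white_l = pial_l - np.stack([np.zeros(len(y)), np.zeros(len(y)), offsets[: len(y)]], axis=1)
        white_r = pial_r - np.stack([np.zeros(len(y)), np.zeros(len(y)), offsets[len(y):]], axis=1)
        labels = np.full(len(y), "M1")
        surf = SurfaceModel(
            left=bare_hemisphere(pial_l, white_l, labels, tag="L"),
            right=bare_hemisphere(pial_r, white_r, labels, tag="R"),
        )
        assert geometry.cortical_thickness(surf, "M1") == pytest.approx(
            offsets.mean(), abs=1e-12
        )


class TestRigidInvariance:
    def test_translation_leaves_all_measures_unchanged(self, small_surface):
        vessel, seg = synth.generate_vessel_and_stent(
            small_surface, rostral_tip=42.0, seed=6
        )
        line = geometry.fit_stent_line(seg, vessel)
        base = (
            geometry.stent_to_cortex(line, small_surface).mean,
            geometry.stent_to_cortex(line, small_surface).minimum,
            geometry.cortical_thickness(small_surface, "M1"),
        )
        rng = np.random.default_rng(0)
        for _ in range(3):
            t = rng.uniform(-30, 30, size=3)
            surf_t = SurfaceModel(
                left=bare_hemisphere(
                    small_surface.left.pial + t, small_surface.left.white + t,
                    small_surface.left.labels, tag="L"),
                right=bare_hemisphere(
                    small_surface.right.pial + t, small_surface.right.white + t,
                    small_surface.right.labels, tag="R"),
            )
            line_t = StentLine(points=line.points + t)
            d = geometry.stent_to_cortex(line_t, surf_t)
            assert d.mean == pytest.approx(base[0], abs=1e-9)
            assert d.minimum == pytest.approx(base[1], abs=1e-9)
            assert geometry.cortical_thickness(surf_t, "M1") == pytest.approx(
                base[2], abs=1e-9
            )
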
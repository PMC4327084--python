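import math

import numpy as np
import pytest

from planarheat import (
    FieldGrid,
    ThermalScales,
    axis_profile,
    extract_isotherms,
    homogeneity_report,
    total_surface_field,
)
from planarheat.fieldmap import (
    default_axes,
    grid_to_long_csv,
    grid_to_matrix_csv,
    isotherms_to_csv,
)
from planarheat.ring import ring_shape_exact
from planarheat.square import square_shape_surface
from conftest import FIG_T1, FIG_T2, SQUARE_CENTER


class TestTotalSurfaceField:
    def test_square_only_reduces_to_square_kernel(self):
        ax = np.linspace(-0.8, 0.8, 41)
        grid = total_surface_field(ThermalScales(t1=1.0, t2=0.0), 0.02, ax, ax)
        xx, yy = np.meshgrid(ax, ax)
        np.testing.assert_allclose(grid.values, square_shape_surface(xx, yy), rtol=1e-13)

    def test_center_value_fig_scenario_z0a_zero(self, fig_scales):
        ax = np.linspace(-0.2, 0.2, 5)
        grid = total_surface_field(fig_scales, 0.0, ax, ax)
        expected = FIG_T1 * SQUARE_CENTER + FIG_T2 * math.pi
        assert grid.values[2, 2] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.862, abs=5e-4)

    def test_linearity_in_scales(self, fig_grid):
        doubled = total_surface_field(
            ThermalScales(t1=2 * FIG_T1, t2=2 * FIG_T2),
            fig_grid.z0a,
            fig_grid.x_axis,
            fig_grid.y_axis,
        )
        np.testing.assert_allclose(doubled.values, 2.0 * fig_grid.values, rtol=1e-14)

    def test_four_fold_symmetry(self, fig_grid):
        v = fig_grid.values
        np.testing.assert_allclose(v, v[::-1, :], rtol=0, atol=1e-13)
        np.testing.assert_allclose(v, v[:, ::-1], rtol=0, atol=1e-13)
        np.testing.assert_allclose(v, v.T, rtol=0, atol=1e-13)

    def test_default_grid_shape_and_origin(self, fig_grid):
        assert fig_grid.values.shape == (201, 201)
        assert fig_grid.x_axis[100] == 0.0

    def test_axes_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            FieldGrid(
                x_axis=np.array([0.0, -1.0]),
                y_axis=np.array([0.0, 1.0]),
                values=np.zeros((2, 2)),
                scales=ThermalScales(),
                z0a=0.02,
            )

    def test_singular_node_reports_grid_context(self, fig_scales):
        ax = np.linspace(-1.0, 1.0, 5)  # contains x=0.5? no: -1,-.5,0,.5,1 yes
        with pytest.raises(Exception, match="grid"):
            total_surface_field(fig_scales, 0.0, ax, ax)


class TestAxisProfile:
    def test_columns_and_sum(self, fig_scales):
        s = np.linspace(-1, 1, 81)
        prof = axis_profile(fig_scales, 0.02, "x", s)
        np.testing.assert_allclose(prof["dT"], prof["dT1"] + prof["dT2"], rtol=1e-14)

    def test_square_part_maximal_at_center(self, fig_scales):
        prof = axis_profile(fig_scales, 0.02, "x", np.linspace(-0.45, 0.45, 91))
        assert np.argmax(prof["dT1"]) == 45

    def test_ring_part_minimal_at_center(self, fig_scales):
        prof = axis_profile(fig_scales, 0.02, "x", np.linspace(-0.45, 0.45, 91))
        assert np.argmin(prof["dT2"]) == 45

    def test_symmetric_profile(self, fig_scales):
        prof = axis_profile(fig_scales, 0.02, "x", np.linspace(-0.9, 0.9, 61))
        np.testing.assert_allclose(prof["dT"], prof["dT"][::-1], rtol=1e-13)

    def test_x_and_y_profiles_match(self, fig_scales):
        s = np.linspace(-0.4, 0.4, 21)
        px = axis_profile(fig_scales, 0.02, "x", s)
        py = axis_profile(fig_scales, 0.02, "y", s)
        np.testing.assert_allclose(px["dT"], py["dT"], rtol=1e-13)

    def test_flat_central_fragment(self, fig_scales):
        s = np.linspace(-0.2, 0.2, 41)
        prof = axis_profile(fig_scales, 0.02, "x", s)
        center = prof["dT"][20]
        assert np.max(np.abs(prof["dT"] - center)) < 0.05 * center

    def test_bad_axis_rejected(self, fig_scales):
        with pytest.raises(ValueError, match="axis"):
            axis_profile(fig_scales, 0.02, "z", np.array([0.0]))


@pytest.fixture(scope="module")
def ring_only_grid():
    ax = np.linspace(-1, 1, 201)
    return total_surface_field(ThermalScales(t1=0.0, t2=1.0), 0.02, ax, ax)


class TestIsotherms:
    def test_ring_contours_are_circles(self, ring_only_grid):
        grid = ring_only_grid
        center = grid.values[100, 100]
        level = 1.05 * center
        isos = extract_isotherms(grid, [level])
        polys = isos.contours[level]
        assert len(polys) >= 1
        for poly in polys:
            radii = np.hypot(poly[:, 0], poly[:, 1])
            assert np.std(radii) / np.mean(radii) < 0.01

    def test_contour_fidelity_reinterpolation(self, ring_only_grid):
        grid = ring_only_grid
        rng = float(grid.values.max() - grid.values.min())
        level = grid.values[100, 100] * 1.1
        isos = extract_isotherms(grid, [level])
        for poly in isos.contours[level]:
            vals = np.array([grid.interpolate(x, y) for x, y in poly[::25]])
            assert np.max(np.abs(vals - level)) < 1e-6 * rng

    def test_fig_scenario_95pct_contour_single_closed(self, fig_grid):
        center = fig_grid.values[100, 100]
        level = 0.95 * center
        isos = extract_isotherms(fig_grid, [level])
        polys = isos.contours[level]
        assert len(polys) == 1
        poly = polys[0]
        np.testing.assert_allclose(poly[0], poly[-1], atol=1e-9)  # closed
        # winding: the contour must enclose the origin
        ang = np.unwrap(np.arctan2(poly[:, 1], poly[:, 0]))
        assert abs(ang[-1] - ang[0]) == pytest.approx(2 * np.pi, abs=1e-6)

    def test_level_outside_range_warns_empty(self, fig_grid):
        with pytest.warns(UserWarning, match="outside"):
            isos = extract_isotherms(fig_grid, [1e6])
        assert isos.contours[1e6] == []
        assert isos.warnings

    def test_constant_field_has_no_contours(self):
        ax = np.linspace(-1, 1, 21)
        grid = FieldGrid(
            x_axis=ax,
            y_axis=ax,
            values=np.ones((21, 21)),
            scales=ThermalScales(),
            z0a=0.02,
        )
        isos = extract_isotherms(grid, [1.0])
        assert all(len(p) == 0 for p in isos.contours[1.0]) or isos.contours[1.0] == []


class TestHomogeneity:
    def test_square_only_infinite_epsilon(self):
        grid = total_surface_field(ThermalScales(t1=1.0), 0.02)
        rep = homogeneity_report(grid, probe_radius=0.2, epsilon=np.inf)
        assert rep.homogeneous_area_fraction == 1.0

    def test_center_is_exact_not_grid(self):
        # grid axes that do NOT contain the origin: center must still be exact
        ax = np.linspace(-1, 1, 200)  # even count, origin absent
        grid = total_surface_field(ThermalScales(t1=1.0), 0.02, ax, ax)
        rep = homogeneity_report(grid, probe_radius=0.3, epsilon=0.1)
        assert rep.center_value == pytest.approx(SQUARE_CENTER, rel=1e-12)

    def test_combined_beats_single_sources(self, fig_scales):
        z0a = 0.02
        combined = total_surface_field(fig_scales, z0a)
        rep_c = homogeneity_report(combined, probe_radius=0.2, epsilon=0.1)
        c0 = rep_c.center_value
        # single sources normalized to the same center value
        sq_center = SQUARE_CENTER
        ring_center = ring_shape_exact(0.0, 0.0, z0a)
        rep_s = homogeneity_report(
            total_surface_field(ThermalScales(t1=c0 / sq_center), z0a),
            probe_radius=0.2,
            epsilon=0.1,
        )
        rep_r = homogeneity_report(
            total_surface_field(ThermalScales(t2=c0 / ring_center), z0a),
            probe_radius=0.2,
            epsilon=0.1,
        )
        assert rep_c.max_abs_deviation < rep_s.max_abs_deviation
        assert rep_c.max_abs_deviation < rep_r.max_abs_deviation

    def test_deviation_nondecreasing_in_radius(self, fig_grid):
        devs = [
            homogeneity_report(fig_grid, probe_radius=r, epsilon=0.1).max_abs_deviation
            for r in (0.1, 0.2, 0.3, 0.4)
        ]
        assert all(b >= a for a, b in zip(devs, devs[1:]))

    def test_callable_field_accepted(self, fig_scales):
        f = lambda x, y: 1.0  # constant
        rep = homogeneity_report(f, probe_radius=0.2, epsilon=0.01)
        assert rep.max_abs_deviation == 0.0
        assert rep.homogeneous_area_fraction == 1.0

    def test_empty_probe_region_errors(self):
        ax = np.linspace(1.0, 2.0, 5)  # grid far from the origin disc
        grid = FieldGrid(
            x_axis=ax,
            y_axis=ax,
            values=np.ones((5, 5)),
            scales=ThermalScales(),
            z0a=0.02,
        )
        with pytest.raises(ValueError, match="probe"):
            homogeneity_report(grid, probe_radius=0.1, epsilon=0.1)


class TestExports:
    def test_long_csv_header_and_count(self, fig_scales):
        ax = np.linspace(-1, 1, 11)
        grid = total_surface_field(fig_scales, 0.02, ax, ax)
        text = grid_to_long_csv(grid)
        lines = text.strip().split("\n")
        assert lines[0] == "x,y,delta_T_C"
        assert len(lines) == 1 + 121

    def test_long_csv_roundtrip_9_sig_digits(self, fig_scales):
        ax = np.linspace(-1, 1, 11)
        grid = total_surface_field(fig_scales, 0.02, ax, ax)
        row = grid_to_long_csv(grid).strip().split("\n")[1 + 5 * 11 + 5]
        x, y, v = map(float, row.split(","))
        assert (x, y) == (0.0, 0.0)
        assert v == pytest.approx(grid.values[5, 5], rel=1e-8)

    def test_matrix_csv_shape(self, fig_scales):
        ax = np.linspace(-1, 1, 7)
        grid = total_surface_field(fig_scales, 0.02, ax, ax)
        lines = grid_to_matrix_csv(grid).strip().split("\n")
        assert len(lines) == 8
        assert all(len(line.split(",")) == 8 for line in lines)

    def test_isotherm_csv_format(self, fig_grid):
        level = 0.95 * fig_grid.values[100, 100]
        isos = extract_isotherms(fig_grid, [level])
        lines = isotherms_to_csv(isos).strip().split("\n")
        assert lines[0] == "level_C,contour_id,vertex_id,x,y"
        first = lines[1].split(",")
        assert float(first[0]) == pytest.approx(level, rel=1e-8)
        assert first[1] == "0" and first[2] == "0"

    def test_default_axes_pin_origin(self):
        x, y = default_axes(201, 1.0)
        assert x[100] == 0.0 and y[100] == 0.0 and x.size == 201
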
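"""Grid construction: polynomial border fits, coefficient-interpolated
curves, truncation, equal-arc resampling, tile assembly and vertex
assignment."""

import numpy as np
import pytest

from cgrid import (
    BorderFit,
    SampledCurve,
    build_cgrid,
    compute_y_range,
    fit_vertical_border,
    interpolate_coefficient_curves,
    resample_equal_arc,
    truncate_curve,
)
from cgrid.borders import Border, BorderSet
from cgrid.errors import (
    ConfigurationError,
    DegenerateCurveError,
    GeometryError,
    UnderdeterminedFitError,
)
from cgrid.mesh import FlatMesh


def border_from_points(pts, role="test"):
    """A Border over a face-less point cloud, for fitting/truncation tests."""
    pts = np.asarray(pts, dtype=float)
    mesh = FlatMesh(pts, np.empty((0, 3), dtype=int), ["A"] * len(pts))
    return Border(role, np.arange(len(pts)), ("A",), mesh)


class TestFitVerticalBorder:
    def test_constant_border(self):
        b = border_from_points([(3.0, y) for y in range(21)])
        fit = fit_vertical_border(b)
        ys = np.linspace(0, 20, 37)
        assert np.allclose(fit(ys), 3.0, atol=1e-6)

    def test_linear_border(self):
        b = border_from_points([(2.0 * y, y) for y in range(21)])
        fit = fit_vertical_border(b)
        assert abs(float(fit(10.0)) - 20.0) < 1e-6

    def test_too_few_vertices(self):
        b = border_from_points([(0, y) for y in range(5)])
        with pytest.raises(UnderdeterminedFitError):
            fit_vertical_border(b, order=10)

    def test_matches_normal_equations_oracle(self):
        """A noisy sinusoidal border: predictions must match an independent
        normal-equations solve on centered/scaled y."""
        rng = np.random.default_rng(42)
        y = np.linspace(0, 20, 60)
        x = np.sin(y / 3.0) + rng.normal(0, 0.01, y.size)
        b = border_from_points(np.column_stack([x, y]))
        fit = fit_vertical_border(b, order=10)

        lo, hi = y.min(), y.max()
        u = (2 * y - lo - hi) / (hi - lo)
        V = np.vander(u, 11, increasing=True)
        coeffs = np.linalg.solve(V.T @ V, V.T @ x)
        yt = np.linspace(0, 20, 101)
        ut = (2 * yt - lo - hi) / (hi - lo)
        oracle = np.vander(ut, 11, increasing=True) @ coeffs
        assert np.allclose(fit(yt), oracle, atol=1e-6)


def _borderset_with_caps(ven_pts, dor_pts):
    dummy = border_from_points([(0, y) for y in range(21)], "central_sulcus")
    return BorderSet(
        central_sulcus=dummy,
        precentral_sulcus=dummy,
        postcentral_sulcus=dummy,
        dorsal=border_from_points(dor_pts, "dorsal"),
        ventral=border_from_points(ven_pts, "ventral"),
    )


class TestComputeYRange:
    def test_direct_min_max(self):
        bs = _borderset_with_caps([(0, 0), (1, 1)], [(0, 9), (1, 10)])
        y_min, y_max = compute_y_range(bs, bs.ventral.mesh)
        assert (y_min, y_max) == (0.0, 10.0)

    def test_degenerate_range_raises(self):
        bs = _borderset_with_caps([(0, 5)], [(1, 5)])
        with pytest.raises(GeometryError):
            compute_y_range(bs, bs.ventral.mesh)

    def test_band_coverage_scan(self, subject, subject_borders, aparc):
        """Every gyrus-labeled vertex must lie within one edge length of the
        [y_min, y_max] window (exhaustive scan)."""
        y_min, y_max = compute_y_range(subject_borders, subject.mesh)
        smx = {aparc["precentral"], aparc["postcentral"]}
        labels = subject.mesh.label_array()
        ys = subject.mesh.vertices[[l in smx for l in labels], 1]
        eps = subject.spec.edge_length
        assert ys.min() >= y_min - eps and ys.max() <= y_max + eps


def three_parallel_fits(xs=(0.0, 10.0, 20.0), y_hi=20.0):
    basis = (0.0, y_hi)
    fits = []
    for x0 in xs:
        b = border_from_points([(x0, y) for y in np.linspace(0, y_hi, 25)])
        fits.append(fit_vertical_border(b, basis_domain=basis))
    return fits


class TestCoefficientInterpolation:
    def test_endpoint_curves_equal_source_fits(self):
        pre, cs, post = three_parallel_fits()
        curves = interpolate_coefficient_curves(pre, cs, post, 4, 0.0, 20.0)
        assert len(curves) == 5
        ys = curves[0].nodes[:, 1]
        assert np.allclose(curves[0].nodes[:, 0], pre(ys), atol=1e-9)
        assert np.allclose(curves[4].nodes[:, 0], post(ys), atol=1e-9)
        assert np.allclose(curves[2].nodes[:, 0], cs(ys), atol=1e-9)

    def test_midpoint_column_is_coefficient_mean(self):
        rng = np.random.default_rng(0)
        pre, cs, post = three_parallel_fits()
        pre = BorderFit(pre.coeffs + rng.normal(0, 0.1, 11), pre.domain,
                        pre.basis_domain)
        curves = interpolate_coefficient_curves(pre, cs, post, 4, 0.0, 20.0)
        mid = BorderFit((pre.coeffs + cs.coeffs) / 2, pre.domain, pre.basis_domain)
        ys = curves[1].nodes[:, 1]
        assert np.allclose(curves[1].nodes[:, 0], mid(ys), atol=1e-9)

    def test_parallel_lines_give_evenly_spaced_curves(self):
        """Three straight borders at x = 0, 10, 20 with M=4 must yield curves
        at x = 0, 5, 10, 15, 20 (direct construction oracle)."""
        curves = interpolate_coefficient_curves(*three_parallel_fits(), 4, 0.0, 20.0)
        for i, x_expect in enumerate([0.0, 5.0, 10.0, 15.0, 20.0]):
            assert np.allclose(curves[i].nodes[:, 0], x_expect, atol=1e-6)

    def test_unit_step_lattice_spans_range(self):
        curves = interpolate_coefficient_curves(*three_parallel_fits(), 2, 0.0, 20.0)
        ys = curves[0].nodes[:, 1]
        assert ys[0] == 0.0 and ys[-1] == 20.0
        assert np.allclose(np.diff(ys), 1.0)

    def test_odd_m_rejected(self):
        pre, cs, post = three_parallel_fits()
        with pytest.raises(ConfigurationError):
            interpolate_coefficient_curves(pre, cs, post, 5, 0.0, 20.0)


class TestTruncateCurve:
    def vertical_curve(self, y_hi=100):
        ys = np.arange(0.0, y_hi + 1)
        return SampledCurve(np.column_stack([np.zeros_like(ys), ys]))

    def test_exact_node_hit(self):
        curve = self.vertical_curve(20)
        ven = border_from_points([(0.0, 7.0)])  # coincides with node 7
        dor = border_from_points([(0.0, 18.0)])
        out = truncate_curve(curve, ven, dor)
        assert out.nodes[0, 1] == 7.0 and out.nodes[-1, 1] == 18.0

    def test_single_vertex_border_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        ys = np.arange(0.0, 51)
        xs = np.sin(ys / 7.0) * 3
        curve = SampledCurve(np.column_stack([xs, ys]))
        p_ven, p_dor = (1.0, 12.3), (-2.0, 44.8)
        out = truncate_curve(
            curve, border_from_points([p_ven]), border_from_points([p_dor])
        )
        d_ven = np.hypot(xs - p_ven[0], ys - p_ven[1])
        d_dor = np.hypot(xs - p_dor[0], ys - p_dor[1])
        lo, hi = sorted((int(np.argmin(d_ven)), int(np.argmin(d_dor))))
        assert np.array_equal(out.nodes, curve.nodes[lo : hi + 1])

    def test_straight_line_span(self):
        curve = self.vertical_curve(100)
        ven = border_from_points([(0.5, 20.2), (1.0, 19.7)])
        dor = border_from_points([(-0.5, 80.4)])
        out = truncate_curve(curve, ven, dor)
        assert abs(out.nodes[0, 1] - 20) <= 1 and abs(out.nodes[-1, 1] - 80) <= 1

    def test_coincident_cuts_raise(self):
        curve = self.vertical_curve(10)
        b = border_from_points([(0.0, 5.0)])
        with pytest.raises(DegenerateCurveError):
            truncate_curve(curve, b, b)


class TestResampleEqualArc:
    def test_straight_segment(self):
        curve = SampledCurve([(0.0, 0.0), (0.0, 10.0)])
        out = resample_equal_arc(curve, 5)
        assert np.allclose(out.nodes[:, 1], [0, 2, 4, 6, 8, 10])
        assert abs(out.length() - 10.0) < 1e-9

    def test_n1_returns_endpoints(self):
        curve = SampledCurve([(0.0, 0.0), (3.0, 4.0), (3.0, 10.0)])
        out = resample_equal_arc(curve, 1)
        assert np.array_equal(out.nodes, curve.nodes[[0, -1]])

    def test_quarter_circle_against_dense_quadrature(self):
        """Arc length of a radius-10 quarter circle within 0.2% of 5*pi and
        node spacings equal to 1e-3 relative (dense quadrature oracle)."""
        theta = np.linspace(0, np.pi / 2, 91)  # one-degree polyline
        nodes = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta)])
        out = resample_equal_arc(SampledCurve(nodes), 10)
        # oracle: very dense numerical arc length of the same polyline
        td = np.linspace(0, np.pi / 2, 200001)
        pd_ = np.column_stack([10 * np.cos(td), 10 * np.sin(td)])
        l_oracle = np.hypot(*np.diff(pd_, axis=0).T).sum()
        spacings = np.hypot(*np.diff(out.nodes, axis=0).T)
        assert abs(spacings.sum() - 5 * np.pi) < 0.002 * 5 * np.pi
        assert abs(spacings.sum() - l_oracle) < 0.002 * l_oracle
        assert np.ptp(spacings) / spacings.mean() < 1e-3

    def test_n_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            resample_equal_arc(SampledCurve([(0, 0), (0, 1)]), 0)


class TestBuildCgrid:
    def test_default_dimensions(self, subject, subject_borders):
        """Default 28 x 84 grid: 2352 tiles from 85 curves of 29 nodes."""
        gd = build_cgrid(subject.mesh, subject_borders)
        assert (gd.n_rows, gd.m_columns, gd.n_tiles) == (28, 84, 2352)
        assert gd.curve_nodes.shape == (85, 29, 2)

    def test_vertex_at_interior_tile_centroid_assigned_there(
        self, flat_subject, aparc
    ):
        from cgrid import extract_smx_borders

        mesh = flat_subject.mesh
        borders = extract_smx_borders(mesh, aparc)
        gd = build_cgrid(mesh, borders, 8, 10)
        quad = gd.tile_polygon(4, 5)
        centroid = quad.mean(axis=0)
        extended = FlatMesh(
            np.vstack([mesh.vertices, centroid]),
            mesh.faces,
            mesh.labels + [aparc["precentral"]],
            mesh.hemisphere,
        )
        borders2 = extract_smx_borders(extended, aparc)
        gd2 = build_cgrid(extended, borders2, 8, 10)
        assert gd2.vertex_tile[-1] == 4 * 10 + 5

    def test_assignment_against_ray_casting_oracle(self, subject, subject_borders):
        """Sampled vertices: the assigned tile must contain the vertex and no
        other tile may strictly contain it (even-odd ray casting oracle)."""
        gd = build_cgrid(subject.mesh, subject_borders, 14, 20)

        def even_odd_inside(pt, quad, eps=0.0):
            inside = False
            x, y = pt
            for k in range(4):
                x1, y1 = quad[k]
                x2, y2 = quad[(k + 1) % 4]
                if (y1 > y) != (y2 > y):
                    xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                    if x < xi - eps:
                        inside = not inside
            return inside

        quads = {
            (r, c): gd.tile_polygon(r, c)
            for r in range(gd.n_rows)
            for c in range(gd.m_columns)
        }
        rng = np.random.default_rng(0)
        sample = rng.choice(subject.mesh.n_vertices, size=200, replace=False)
        for v in sample:
            pt = subject.mesh.vertices[v]
            containing = {
                rc for rc, quad in quads.items() if even_odd_inside(pt, quad)
            }
            assigned = gd.vertex_tile[v]
            if assigned >= 0:
                rc = (assigned // gd.m_columns, assigned % gd.m_columns)
                # tolerate boundary-grazing: the assigned tile must at least
                # contain the point under a loosened edge test
                assert rc in containing or even_odd_inside(
                    pt, quads[rc], eps=-1e-9
                )
                assert containing <= {rc} or rc in containing
            else:
                assert not containing

    def test_equal_arc_property_all_curves(self, subject, subject_borders):
        gd = build_cgrid(subject.mesh, subject_borders)
        for c in range(gd.curve_nodes.shape[0]):
            spac = np.hypot(*np.diff(gd.curve_nodes[c], axis=0).T)
            assert np.ptp(spac) / spac.mean() < 1e-2

    def test_central_column_follows_central_sulcus_fit(
        self, subject, subject_borders
    ):
        gd = build_cgrid(subject.mesh, subject_borders)
        y_min, y_max = compute_y_range(subject_borders, subject.mesh)
        fit_cs = fit_vertical_border(
            subject_borders.central_sulcus, subject.mesh,
            basis_domain=(y_min, y_max),
        )
        mid = gd.curve_nodes[gd.m_columns // 2]
        assert np.abs(mid[:, 0] - fit_cs(mid[:, 1])).max() < 0.05

    def test_columns_ordered_left_to_right(self, subject, subject_borders):
        gd = build_cgrid(subject.mesh, subject_borders)
        for r in range(gd.n_rows + 1):
            assert np.all(np.diff(gd.curve_nodes[:, r, 0]) > 0)

    def test_each_vertex_in_at_most_one_tile(self, subject, subject_borders):
        gd = build_cgrid(subject.mesh, subject_borders)
        assert gd.vertex_tile.shape == (subject.mesh.n_vertices,)
        assert gd.vertex_tile.max() < gd.n_tiles
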
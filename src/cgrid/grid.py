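"""Construction of the Cgrid standard space.

Pipeline: fit an order-10 polynomial x(y) through each of the three vertical
borders; create M+1 in-between curves by linear interpolation of the 11
polynomial coefficients (the central-sulcus fit pinned at the middle column);
evaluate each curve on a unit-step y lattice spanning the band; truncate each
curve at the nodes nearest the ventral and dorsal cap borders; resample each
truncated curve into N equal-arc segments; form N x M quadrilateral tiles
from adjacent curve nodes and associate every mesh vertex with the tile that
encloses it.

Numerical conditioning: order-10 fits on raw coordinates in the hundreds are
ill-conditioned, so fitting and coefficient interpolation happen on y mapped
affinely to [-1, 1] over a common window. Coefficient interpolation across
fits is only meaningful in a shared basis, so :func:`build_cgrid` fits all
three borders over the common [y_min, y_max] window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely import STRtree
from shapely.geometry import Point, Polygon

from .borders import Border, BorderSet
from .errors import (
    ConfigurationError,
    DegenerateCurveError,
    ExtrapolationError,
    GeometryError,
    RankDeficientFitError,
    UnderdeterminedFitError,
)
from .mesh import FlatMesh

__all__ = [
    "BorderFit",
    "SampledCurve",
    "CgridDefinition",
    "fit_vertical_border",
    "compute_y_range",
    "interpolate_coefficient_curves",
    "truncate_curve",
    "resample_equal_arc",
    "build_cgrid",
    "DENSIFY_STEP",
]

log = logging.getLogger(__name__)

#: Node spacing (a.u.) used to densify a truncated curve before arc-length
#: estimation.
DENSIFY_STEP = 0.1


@dataclass
class BorderFit:
    """Least-squares polynomial x = p(y) through one vertical border.

    Coefficients are in the power basis of u = (2y - lo - hi)/(hi - lo),
    where (lo, hi) is ``basis_domain``; ``domain`` records the y range the
    border actually covered.
    """

    coeffs: np.ndarray  # length order+1, ascending powers of u
    domain: tuple[float, float]  # y range of the source border
    basis_domain: tuple[float, float]  # y window mapped to [-1, 1]
    role: str = ""

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not np.all(np.isfinite(self.coeffs)):
            raise RankDeficientFitError("non-finite polynomial coefficients")

    @property
    def order(self) -> int:
        return self.coeffs.size - 1

    def _scale(self, y: np.ndarray) -> np.ndarray:
        lo, hi = self.basis_domain
        return (2.0 * np.asarray(y, dtype=float) - lo - hi) / (hi - lo)

    def __call__(self, y) -> np.ndarray:
        """Evaluate x at y (extrapolates beyond the border's own range)."""
        return np.polynomial.polynomial.polyval(self._scale(y), self.coeffs)


@dataclass
class SampledCurve:
    """An ordered polyline with strictly monotone y; one vertical grid curve."""

    nodes: np.ndarray  # (K, 2)
    column: int = 0
    weight: float = 0.0  # interpolation position, 0 = precentral-side fit

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise DegenerateCurveError("curve nodes must be (K, 2)")
        if self.nodes.shape[0] < 2:
            raise DegenerateCurveError("curve needs at least 2 nodes")
        dy = np.diff(self.nodes[:, 1])
        if not (np.all(dy > 0) or np.all(dy < 0)):
            raise DegenerateCurveError("curve y must be strictly monotone")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.nodes, axis=0).T)))


def fit_vertical_border(
    border: Border,
    mesh: FlatMesh | None = None,
    order: int = 10,
    basis_domain: tuple[float, float] | None = None,
) -> BorderFit:
    """Fit x as a polynomial in y through a vertical border's vertices.

    y (the dorsoventral coordinate) is the independent variable. The fit is
    performed on y rescaled to [-1, 1] over ``basis_domain`` (default: the
    border's own y range); pass a common window when several fits must share
    a basis for coefficient interpolation.
    """
    mesh = mesh or border.mesh
    pts = mesh.vertices[border.vertex_indices]
    if pts.shape[0] <= order + 1:
        raise UnderdeterminedFitError(
            f"{pts.shape[0]} border vertices cannot constrain an order-{order} fit"
        )
    y, x = pts[:, 1], pts[:, 0]
    lo, hi = (float(y.min()), float(y.max())) if basis_domain is None else basis_domain
    if hi <= lo:
        raise UnderdeterminedFitError("degenerate fit domain (all y equal)")
    u = (2.0 * y - lo - hi) / (hi - lo)
    V = np.vander(u, order + 1, increasing=True)
    if np.linalg.matrix_rank(V) < order + 1:
        raise RankDeficientFitError(
            f"border '{border.role}' y values span too few distinct points "
            f"for an order-{order} fit"
        )
    coeffs, *_ = np.linalg.lstsq(V, x, rcond=None)
    return BorderFit(coeffs, (float(y.min()), float(y.max())), (lo, hi), border.role)


def compute_y_range(borders: BorderSet, mesh: FlatMesh | None = None) -> tuple[float, float]:
    """The dorsoventral window covered by the grid: from the lowest ventral-cap
    vertex to the highest dorsal-cap vertex."""
    if len(borders.ventral) == 0 or len(borders.dorsal) == 0:
        raise GeometryError("ventral/dorsal borders must be non-empty")
    y_min = float(borders.ventral.coords[:, 1].min())
    y_max = float(borders.dorsal.coords[:, 1].max())
    if y_min >= y_max:
        raise GeometryError(
            f"y_min={y_min:g} >= y_max={y_max:g}: flat map is degenerate or "
            "upside-down (ventral cap must lie below the dorsal cap)"
        )
    return y_min, y_max


def _unit_step_lattice(y_min: float, y_max: float) -> np.ndarray:
    """y_min, y_min+1, ... plus y_max itself if the span is not integral."""
    n = int(np.floor(y_max - y_min + 1e-9))
    ys = y_min + np.arange(n + 1, dtype=float)
    if ys[-1] < y_max - 1e-9:
        ys = np.append(ys, y_max)
    return ys


def interpolate_coefficient_curves(
    fit_pre: BorderFit,
    fit_cs: BorderFit,
    fit_post: BorderFit,
    m_columns: int,
    y_min: float,
    y_max: float,
) -> list[SampledCurve]:
    """M+1 vertical curves by linear interpolation of polynomial coefficients.

    Columns 0..M/2 blend the precentral-side fit into the central-sulcus fit;
    columns M/2..M blend the central-sulcus fit into the postcentral-side
    fit, so column M/2 is exactly the central sulcus. Each curve is the
    blended polynomial evaluated on the unit-step y lattice from y_min to
    y_max (extrapolating the fits where needed).
    """
    if m_columns % 2 != 0 or m_columns < 2:
        raise ConfigurationError(f"M must be an even integer >= 2, got {m_columns}")
    if not (fit_pre.basis_domain == fit_cs.basis_domain == fit_post.basis_domain):
        raise ConfigurationError(
            "coefficient interpolation requires fits sharing one basis domain"
        )
    ys = _unit_step_lattice(y_min, y_max)
    half = m_columns // 2
    curves = []
    for i in range(m_columns + 1):
        if i <= half:
            w = i / half
            coeffs = (1 - w) * fit_pre.coeffs + w * fit_cs.coeffs
        else:
            w = (i - half) / half
            coeffs = (1 - w) * fit_cs.coeffs + w * fit_post.coeffs
        blended = BorderFit(coeffs, (y_min, y_max), fit_cs.basis_domain)
        xs = blended(ys)
        curves.append(
            SampledCurve(np.column_stack([xs, ys]), column=i, weight=i / m_columns)
        )
    return curves


def truncate_curve(
    curve: SampledCurve,
    ventral: Border,
    dorsal: Border,
    mesh: FlatMesh | None = None,
) -> SampledCurve:
    """Cut a curve at its nodes nearest the ventral and dorsal cap borders.

    The cut nodes are the curve nodes minimizing Euclidean distance to any
    vertex of each cap border; both are kept (inclusive), ventral end first.
    """
    if len(ventral) == 0 or len(dorsal) == 0:
        raise GeometryError("cap borders must be non-empty")
    nodes = curve.nodes

    def nearest_node(border: Border) -> int:
        pts = border.coords
        d2 = (
            (nodes[:, None, 0] - pts[None, :, 0]) ** 2
            + (nodes[:, None, 1] - pts[None, :, 1]) ** 2
        )
        return int(np.argmin(d2.min(axis=1)))

    i_ven = nearest_node(ventral)
    i_dor = nearest_node(dorsal)
    if i_ven == i_dor:
        raise DegenerateCurveError(
            f"curve {curve.column}: ventral and dorsal cuts coincide at node {i_ven}"
        )
    lo, hi = sorted((i_ven, i_dor))
    sub = nodes[lo : hi + 1]
    if i_ven > i_dor:  # keep ventral end first
        sub = sub[::-1]
    return SampledCurve(sub, column=curve.column, weight=curve.weight)


def resample_equal_arc(curve: SampledCurve, n_rows: int) -> SampledCurve:
    """Resample a truncated curve into N equal-arc segments (N+1 nodes).

    The polyline is first densified to ~``DENSIFY_STEP`` node spacing by
    linear interpolation; its length l is the sum of consecutive node
    distances of the densified polyline; output nodes sit at arc positions
    0, l/N, ..., l with the original endpoints preserved exactly.
    """
    if n_rows < 1:
        raise ConfigurationError(f"N must be >= 1, got {n_rows}")
    nodes = curve.nodes
    seg = np.hypot(*np.diff(nodes, axis=0).T)
    if not np.all(seg > 0):
        raise DegenerateCurveError("zero-length segment in curve")
    # densify each segment to <= DENSIFY_STEP spacing
    dense = [nodes[0]]
    for k in range(len(seg)):
        n_sub = max(1, int(np.ceil(seg[k] / DENSIFY_STEP)))
        ts = np.arange(1, n_sub + 1) / n_sub
        dense.append(nodes[k] + ts[:, None] * (nodes[k + 1] - nodes[k]))
    dense = np.vstack([dense[0][None, :], *dense[1:]])
    darc = np.hypot(*np.diff(dense, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(darc)])
    total = float(cum[-1])
    if total <= 0:
        raise DegenerateCurveError("zero-length curve")
    targets = np.linspace(0.0, total, n_rows + 1)
    xs = np.interp(targets, cum, dense[:, 0])
    ys = np.interp(targets, cum, dense[:, 1])
    out = np.column_stack([xs, ys])
    out[0], out[-1] = nodes[0], nodes[-1]
    return SampledCurve(out, column=curve.column, weight=curve.weight)


@dataclass
class CgridDefinition:
    """A fully built grid: curves, tiles, and the tile-vertex association.

    ``curve_nodes[c, r]`` is node r (ventral to dorsal) of curve c
    (left to right along the flat map's x axis). Tile (r, c) is the
    quadrilateral between nodes r/r+1 of curves c/c+1. ``vertex_tile`` maps
    every mesh vertex to a flat row-major tile index, or -1 if unassigned.
    """

    n_rows: int
    m_columns: int
    curve_nodes: np.ndarray  # (M+1, N+1, 2)
    vertex_tile: np.ndarray  # (V,) int, -1 = unassigned
    smx_vertex_mask: np.ndarray  # (V,) bool: carries a band (gyrus) label
    y_min: float
    y_max: float
    precentral_side: str  # "left" | "right": which x side the precentral fit is on
    mesh: FlatMesh | None = None

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.m_columns

    def tile_polygon(self, row: int, col: int) -> np.ndarray:
        """Corner coordinates (4, 2) of tile (row, col), counter-ordered as
        [curve c node r, curve c+1 node r, curve c+1 node r+1, curve c node r+1]."""
        c, r = col, row
        return np.array(
            [
                self.curve_nodes[c, r],
                self.curve_nodes[c + 1, r],
                self.curve_nodes[c + 1, r + 1],
                self.curve_nodes[c, r + 1],
            ]
        )

    def tile_members(self, row: int, col: int) -> np.ndarray:
        """Vertex indices assigned to tile (row, col)."""
        flat = row * self.m_columns + col
        return np.nonzero(self.vertex_tile == flat)[0]


def _tile_polygons(curve_nodes: np.ndarray, n_rows: int, m_cols: int) -> list[Polygon]:
    polys = []
    for r in range(n_rows):
        for c in range(m_cols):
            quad = [
                curve_nodes[c, r],
                curve_nodes[c + 1, r],
                curve_nodes[c + 1, r + 1],
                curve_nodes[c, r + 1],
            ]
            poly = Polygon(quad)
            if not poly.is_valid:  # bow-tie quad from crossing curves
                poly = poly.buffer(0)
            polys.append(poly)
    return polys


def build_cgrid(
    mesh: FlatMesh,
    borders: BorderSet,
    n_rows: int = 28,
    m_columns: int = 84,
    order: int = 10,
) -> CgridDefinition:
    """Run the full grid construction on one hemisphere.

    The three vertical fits are ordered along the flat map's x axis (the
    grid's column axis follows x; which side is precentral is recorded so the
    orientation step can put it on the left). Each vertex is assigned to the
    first tile, in row-major order, whose polygon covers it (boundary
    inclusive) — a deterministic tie-break for vertices on shared edges.
    Defaults 28 x 84 give 2352 tiles per hemisphere.
    """
    y_min, y_max = compute_y_range(borders, mesh)
    basis = (y_min, y_max)
    fit_pre = fit_vertical_border(borders.precentral_sulcus, mesh, order, basis)
    fit_cs = fit_vertical_border(borders.central_sulcus, mesh, order, basis)
    fit_post = fit_vertical_border(borders.postcentral_sulcus, mesh, order, basis)

    pre_x = float(np.mean(mesh.vertices[borders.precentral_sulcus.vertex_indices, 0]))
    post_x = float(np.mean(mesh.vertices[borders.postcentral_sulcus.vertex_indices, 0]))
    if pre_x <= post_x:
        left_fit, right_fit, precentral_side = fit_pre, fit_post, "left"
    else:
        left_fit, right_fit, precentral_side = fit_post, fit_pre, "right"

    curves = interpolate_coefficient_curves(
        left_fit, fit_cs, right_fit, m_columns, y_min, y_max
    )
    # guard against runaway order-10 extrapolation
    x_extent = float(np.ptp(mesh.vertices[:, 0]))
    x_center = float(np.mean(mesh.vertices[:, 0]))
    for cv in curves:
        if np.abs(cv.nodes[:, 0] - x_center).max() > 3.0 * max(x_extent, 1.0):
            raise ExtrapolationError(
                f"curve {cv.column} leaves 3x the mesh x-extent; polynomial "
                "extrapolation is unstable for this flat map"
            )

    resampled = [
        resample_equal_arc(truncate_curve(cv, borders.ventral, borders.dorsal, mesh), n_rows)
        for cv in curves
    ]
    curve_nodes = np.stack([cv.nodes for cv in resampled])  # (M+1, N+1, 2)

    polys = _tile_polygons(curve_nodes, n_rows, m_columns)
    tree = STRtree(polys)
    points = [Point(xy) for xy in mesh.vertices]
    vertex_tile = np.full(mesh.n_vertices, -1, dtype=np.int64)
    qi, ti = tree.query(points, predicate="covered_by")
    if qi.size:
        # row-major tie-break: smallest tile index wins for boundary vertices
        order_ = np.lexsort((ti, qi))
        qi, ti = qi[order_], ti[order_]
        first = np.concatenate([[True], qi[1:] != qi[:-1]])
        vertex_tile[qi[first]] = ti[first]

    smx_labels = set(borders.dorsal.l1_labels)
    labels = mesh.label_array()
    smx_mask = np.array([l in smx_labels for l in labels], dtype=bool)
    n_smx = int(smx_mask.sum())
    n_unassigned = int((vertex_tile[smx_mask] < 0).sum())
    if n_smx and n_unassigned > 0.1 * n_smx:
        log.warning(
            "%d of %d band-labeled vertices (%.1f%%) fall outside every tile",
            n_unassigned, n_smx, 100.0 * n_unassigned / n_smx,
        )

    return CgridDefinition(
        n_rows=n_rows,
        m_columns=m_columns,
        curve_nodes=curve_nodes,
        vertex_tile=vertex_tile,
        smx_vertex_mask=smx_mask,
        y_min=y_min,
        y_max=y_max,
        precentral_side=precentral_side,
        mesh=mesh,
    )
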
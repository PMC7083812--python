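"""Mapping per-vertex scalar fields into grid space, orienting maps into the
display convention, slicing the motor/somatosensory halves, and a surface
smoothing operator for synthetic experiments.

Display convention: after :func:`orient_grid`, row 0 is dorsal (top), the
precentral gyrus occupies the left half of the column axis and the
postcentral gyrus the right half, regardless of hemisphere. The precentral
half is the primary motor cortex (M1), the postcentral half the primary
somatosensory cortex (S1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix

from .errors import ConfigurationError, OrientationError
from .grid import CgridDefinition
from .mesh import FlatMesh, VertexField, vertex_neighbors

__all__ = [
    "CgridMap",
    "RoiSlice",
    "map_vertex_values_to_grid",
    "orient_grid",
    "extract_roi_halves",
    "smooth_vertex_values",
]

log = logging.getLogger(__name__)


@dataclass
class CgridMap:
    """An N x M matrix of tile values with a validity mask.

    A tile is valid when at least one band-labeled (gyrus) vertex with a
    finite value contributed to it; invalid tiles hold NaN and are excluded
    from correlations downstream.
    """

    values: np.ndarray  # (N, M) float, NaN where invalid
    mask: np.ndarray  # (N, M) bool
    subject: str = ""
    hemisphere: str = ""
    task: str = ""
    field_name: str = ""
    row0: str = "ventral"  # which anatomical side row 0 is
    precentral_side: str = "left"  # which column side is precentral
    oriented: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ConfigurationError("values and mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, values, mask, **meta) -> "CgridMap":
        kwargs = dict(
            subject=self.subject,
            hemisphere=self.hemisphere,
            task=self.task,
            field_name=self.field_name,
            row0=self.row0,
            precentral_side=self.precentral_side,
            oriented=self.oriented,
        )
        kwargs.update(meta)
        return CgridMap(values, mask, **kwargs)


@dataclass
class RoiSlice:
    """One half of an oriented map: "M1" (precentral, left columns) or "S1"
    (postcentral, right columns)."""

    roi: str
    values: np.ndarray
    mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def map_vertex_values_to_grid(
    field: VertexField, griddef: CgridDefinition, weight_by_count: bool = False
) -> CgridMap:
    """Average vertex values per tile.

    The tile value is the unweighted arithmetic mean of the finite values of
    all vertices the tile encloses; the tile is marked valid only if at least
    one contributing vertex carries a band (gyrus) label. NaN vertex values
    are treated as missing and dropped from the mean. ``weight_by_count`` is
    accepted for API symmetry with count-weighted group averaging but does
    not change single-map means.
    """
    if len(field) != griddef.vertex_tile.size:
        raise ConfigurationError(
            f"field has {len(field)} values for {griddef.vertex_tile.size} vertices"
        )
    n_tiles = griddef.n_tiles
    tile = griddef.vertex_tile
    vals = field.values
    ok = (tile >= 0) & np.isfinite(vals)
    sums = np.bincount(tile[ok], weights=vals[ok], minlength=n_tiles)
    counts = np.bincount(tile[ok], minlength=n_tiles)
    smx_counts = np.bincount(
        tile[ok & griddef.smx_vertex_mask], minlength=n_tiles
    )
    with np.errstate(invalid="ignore"):
        means = sums / counts
    mask = (counts > 0) & (smx_counts > 0)
    means[~mask] = np.nan
    hemisphere = griddef.mesh.hemisphere if griddef.mesh is not None else ""
    return CgridMap(
        means.reshape(griddef.n_rows, griddef.m_columns),
        mask.reshape(griddef.n_rows, griddef.m_columns),
        hemisphere=hemisphere,
        field_name=field.name,
        row0="ventral",
        precentral_side=griddef.precentral_side,
        oriented=False,
    )


def orient_grid(
    cmap: CgridMap,
    flat_convention: str = "caret",
    force_flip: bool = False,
) -> CgridMap:
    """Bring a map into the display convention: dorsal at row 0, precentral
    half on the left, for either hemisphere.

    The column flip is decided from the map's recorded precentral side when
    the grid builder supplied it; otherwise from the hemisphere tag plus the
    flattening convention (under the Caret convention the right hemisphere's
    x axis runs posterior to anterior, so its columns are flipped).
    ``force_flip`` unconditionally flips the columns of an already-oriented
    map (applying it twice is the identity). Orienting an oriented map again
    is a no-op.
    """
    values, mask = cmap.values, cmap.mask
    row0, pre_side = cmap.row0, cmap.precentral_side

    if force_flip:
        return cmap.copy_with(values[:, ::-1].copy(), mask[:, ::-1].copy())

    if cmap.oriented:
        return cmap.copy_with(values.copy(), mask.copy())

    if row0 == "ventral":
        values, mask = values[::-1], mask[::-1]
        row0 = "dorsal"

    if pre_side in ("left", "right"):
        flip = pre_side == "right"
    else:
        if cmap.hemisphere not in ("left", "right"):
            raise OrientationError(
                f"cannot orient map: unknown hemisphere {cmap.hemisphere!r} "
                "and no recorded precentral side"
            )
        if flat_convention not in ("caret", "custom"):
            raise OrientationError(f"unknown flat convention {flat_convention!r}")
        flip = flat_convention == "caret" and cmap.hemisphere == "right"
    if flip:
        values, mask = values[:, ::-1], mask[:, ::-1]
    return cmap.copy_with(
        values.copy(), mask.copy(), row0=row0, precentral_side="left", oriented=True
    )


def extract_roi_halves(cmap: CgridMap) -> tuple[RoiSlice, RoiSlice]:
    """Split an oriented map at the central-sulcus column into its M1
    (precentral) and S1 (postcentral) halves."""
    if not cmap.oriented:
        raise OrientationError("orient the map before slicing ROI halves")
    n, m = cmap.shape
    if m % 2 != 0:
        raise ConfigurationError(f"column count {m} is odd; cannot split at M/2")
    h = m // 2
    m1 = RoiSlice("M1", cmap.values[:, :h].copy(), cmap.mask[:, :h].copy())
    s1 = RoiSlice("S1", cmap.values[:, h:].copy(), cmap.mask[:, h:].copy())
    return m1, s1


def smooth_vertex_values(
    field: VertexField, mesh: FlatMesh, fwhm: float
) -> VertexField:
    """Approximate Gaussian surface smoothing by iterated neighborhood
    averaging on the mesh graph.

    Each iteration replaces a vertex's value by the mean over its closed
    1-ring (itself plus its edge neighbors). By the central limit theorem the
    iterated kernel tends to a Gaussian whose variance grows by the mean
    squared neighbor displacement per step; the iteration count is chosen so
    the accumulated variance matches the requested full width at half
    maximum (in flat-map a.u.). ``fwhm=0`` returns the input unchanged.
    """
    if fwhm < 0:
        raise ConfigurationError(f"fwhm must be >= 0, got {fwhm}")
    if fwhm == 0 or mesh.n_faces == 0:
        return VertexField(field.values.copy(), field.name, field.units)
    sigma2 = fwhm**2 / (8.0 * np.log(2.0))

    nbrs = vertex_neighbors(mesh)
    rows, cols = [], []
    for v, ws in enumerate(nbrs):
        rows.append(v)
        cols.append(v)
        for w in ws:
            rows.append(v)
            cols.append(w)
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    disp = mesh.vertices[cols] - mesh.vertices[rows]
    # per-step variance gain, averaged over both axes and all vertices
    deg = np.bincount(rows, minlength=mesh.n_vertices).astype(float)
    gain = float(np.mean(
        (np.bincount(rows, weights=disp[:, 0] ** 2, minlength=mesh.n_vertices)
         + np.bincount(rows, weights=disp[:, 1] ** 2, minlength=mesh.n_vertices))
        / (2.0 * deg)
    ))
    if gain <= 0:
        return VertexField(field.values.copy(), field.name, field.units)
    n_steps = max(1, int(round(sigma2 / gain)))

    weights = 1.0 / deg[rows]
    S = csr_matrix((weights, (rows, cols)), shape=(mesh.n_vertices,) * 2)
    vals = field.values.copy()
    missing = ~np.isfinite(vals)
    if missing.any():
        vals = np.where(missing, 0.0, vals)
        norm = (~missing).astype(float)
        for _ in range(n_steps):
            vals = S @ vals
            norm = S @ norm
        with np.errstate(invalid="ignore"):
            vals = vals / norm
    else:
        for _ in range(n_steps):
            vals = S @ vals
    return VertexField(vals, field.name, field.units)
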
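"""Data model and I/O for flattened, atlas-labeled cortical surface meshes.

A flat map is a 2D unfolding of a cortical hemisphere produced by an
inflation/flattening tool (e.g. Caret). Distances on it approximate cortical
distances and are kept in the source's arbitrary units (a.u., roughly 1 mm).
Each vertex carries the name of the atlas region it belongs to (Desikan-
Killiany style gyral parcellation), which is what the border-extraction step
consumes.

Supported on-disk representations:

* FreeSurfer binary geometry + ``.annot`` annotation,
* GIFTI ``.surf.gii`` + ``.label.gii``,
* a minimal plain-text dialect, ``fmesh`` (see :func:`write_fmesh`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import (
    InvalidFaceError,
    MeshFormatError,
    MissingLabelError,
    NonPlanarMeshError,
)

__all__ = [
    "REGION_ROLES",
    "LabelDialect",
    "FlatMesh",
    "VertexField",
    "vertex_neighbors",
    "validate_flatmap",
    "ValidationReport",
    "load_flatmap",
    "read_fmesh",
    "write_fmesh",
    "read_freesurfer_flatmap",
    "write_freesurfer_flatmap",
    "read_gifti_flatmap",
    "write_gifti_flatmap",
]

#: Canonical region roles needed to bound the sensorimotor band: the two
#: gyri themselves plus their eight atlas neighbors.
REGION_ROLES = (
    "precentral",
    "postcentral",
    "pars_opercularis",
    "caudal_middle_frontal",
    "superior_frontal",
    "supramarginal",
    "superior_parietal",
    "paracentral",
    "insula",
)

# Ratio of |z| to the xy extent above which a 3D source is refused rather
# than silently projected: a genuinely curved surface must not be flattened
# by dropping a coordinate.
_Z_TOLERANCE = 1e-6


@dataclass(frozen=True)
class LabelDialect:
    """Mapping from canonical region roles to the literal strings a given
    annotation source uses.

    Atlas label spellings differ between tools (prose names vs FreeSurfer
    ``aparc`` short names); matching is exact-string through this table.
    """

    names: Mapping[str, str]

    def __post_init__(self):
        missing = [r for r in REGION_ROLES if r not in self.names]
        if missing:
            raise MissingLabelError(f"dialect lacks roles: {missing}")
        values = list(self.names[r] for r in REGION_ROLES)
        if len(set(values)) != len(values):
            raise MissingLabelError("dialect label strings must be unique")

    def __getitem__(self, role: str) -> str:
        try:
            return self.names[role]
        except KeyError:
            raise MissingLabelError(f"unknown region role {role!r}") from None

    @staticmethod
    def human() -> "LabelDialect":
        """Human-readable prose names."""
        return LabelDialect(
            {
                "precentral": "Precentral gyrus",
                "postcentral": "Postcentral gyrus",
                "pars_opercularis": "Pars opercularis",
                "caudal_middle_frontal": "Caudal middle frontal",
                "superior_frontal": "Superior frontal",
                "supramarginal": "Supramarginal",
                "superior_parietal": "Superior parietal",
                "paracentral": "Paracentral lobule",
                "insula": "Insula",
            }
        )

    @staticmethod
    def freesurfer_aparc() -> "LabelDialect":
        """FreeSurfer ``aparc`` (Desikan-Killiany) short names."""
        return LabelDialect(
            {
                "precentral": "precentral",
                "postcentral": "postcentral",
                "pars_opercularis": "parsopercularis",
                "caudal_middle_frontal": "caudalmiddlefrontal",
                "superior_frontal": "superiorfrontal",
                "supramarginal": "supramarginal",
                "superior_parietal": "superiorparietal",
                "paracentral": "paracentral",
                "insula": "insula",
            }
        )


DIALECTS = {
    "human": LabelDialect.human,
    "aparc": LabelDialect.freesurfer_aparc,
}


@dataclass
class FlatMesh:
    """A flattened cortical hemisphere: 2D vertices, triangle faces, one
    atlas label per vertex and a hemisphere tag."""

    vertices: np.ndarray  # (V, 2) float, a.u.
    faces: np.ndarray  # (F, 3) int
    labels: list[str]  # length V
    hemisphere: str = "left"  # "left" | "right"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise MeshFormatError("vertices must be an (V, 2) array")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise MeshFormatError("faces must be an (F, 3) array")
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)
        if len(self.labels) != self.n_vertices:
            raise MeshFormatError(
                f"{len(self.labels)} labels for {self.n_vertices} vertices"
            )
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
                raise InvalidFaceError(
                    f"face references vertex outside [0, {self.n_vertices})"
                )
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise MeshFormatError("degenerate face with repeated vertex index")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


@dataclass
class VertexField:
    """One scalar value per mesh vertex (e.g. a GLM beta projected onto the
    surface). NaN marks an explicitly missing value."""

    values: np.ndarray
    name: str = "field"
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return self.values.size


def vertex_neighbors(mesh: FlatMesh) -> list[set[int]]:
    """Per-vertex sets of vertices sharing a face edge (the 1-ring)."""
    nbrs: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.faces:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    return nbrs


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_flatmap`; report-only, callers escalate."""

    missing_labels: list[str] = field(default_factory=list)
    orientation_ok: bool = True
    principal_axis: tuple[float, float] = (0.0, 1.0)
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.missing_labels and self.orientation_ok


def validate_flatmap(mesh: FlatMesh, dialect: LabelDialect) -> ValidationReport:
    """Check a loaded flat map for the labels the grid needs and for a
    vertically oriented central sulcus.

    The central-sulcus proxy is the set of precentral vertices adjacent to
    postcentral vertices; its principal axis (leading eigenvector of the 2x2
    coordinate covariance) must be closer to vertical than horizontal.
    """
    report = ValidationReport()
    present = set(mesh.labels)
    for role in REGION_ROLES:
        if dialect[role] not in present:
            report.missing_labels.append(role)
            report.messages.append(f"missing label for role {role!r}")
    if "precentral" in report.missing_labels or "postcentral" in report.missing_labels:
        return report

    nbrs = vertex_neighbors(mesh)
    labels = mesh.label_array()
    pre, post = dialect["precentral"], dialect["postcentral"]
    boundary = [
        v
        for v in range(mesh.n_vertices)
        if labels[v] == pre and any(labels[w] == post for w in nbrs[v])
    ]
    if len(boundary) < 2:
        report.messages.append("central-sulcus boundary too small to orient")
        return report
    pts = mesh.vertices[boundary]
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    report.principal_axis = (float(axis[0]), float(axis[1]))
    report.orientation_ok = abs(axis[1]) > abs(axis[0])
    if not report.orientation_ok:
        report.messages.append(
            "central sulcus principal axis is closer to horizontal than "
            "vertical; rotate the flat map so dorsal is up"
        )
    return report


# ---------------------------------------------------------------------------
# fmesh plain-text dialect
# ---------------------------------------------------------------------------

def write_fmesh(mesh: FlatMesh, path: str | os.PathLike) -> None:
    """Write the plain-text ``fmesh`` dialect.

    Layout: header ``fmesh v1``, a ``hemisphere`` line, ``V <count>`` then V
    lines ``x y label`` (label may contain spaces), ``F <count>`` then F
    lines ``i j k`` of 0-based vertex indices. Floats are written with
    ``repr`` precision so a write/read cycle is lossless.
    """
    with open(path, "w") as fh:
        fh.write("fmesh v1\n")
        fh.write(f"hemisphere {mesh.hemisphere}\n")
        fh.write(f"V {mesh.n_vertices}\n")
        for (x, y), lab in zip(mesh.vertices, mesh.labels):
            fh.write(f"{float(x)!r} {float(y)!r} {lab}\n")
        fh.write(f"F {mesh.n_faces}\n")
        for i, j, k in mesh.faces:
            fh.write(f"{i} {j} {k}\n")


def read_fmesh(path: str | os.PathLike) -> FlatMesh:
    """Read the plain-text ``fmesh`` dialect (see :func:`write_fmesh`)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0].strip() != "fmesh v1":
        raise MeshFormatError(f"{path}: not an fmesh v1 file")
    pos = 1
    hemisphere = "left"
    if pos < len(lines) and lines[pos].startswith("hemisphere"):
        hemisphere = lines[pos].split()[1]
        pos += 1
    if pos >= len(lines) or not lines[pos].startswith("V "):
        raise MeshFormatError(f"{path}: missing vertex count")
    nv = int(lines[pos].split()[1])
    pos += 1
    verts = np.empty((nv, 2), dtype=float)
    labels: list[str] = []
    for i in range(nv):
        parts = lines[pos + i].split(maxsplit=2)
        if len(parts) != 3:
            raise MeshFormatError(f"{path}: bad vertex line {pos + i + 1}")
        verts[i, 0] = float(parts[0])
        verts[i, 1] = float(parts[1])
        labels.append(parts[2])
    pos += nv
    if pos >= len(lines) or not lines[pos].startswith("F "):
        raise MeshFormatError(f"{path}: missing face count")
    nf = int(lines[pos].split()[1])
    pos += 1
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        parts = lines[pos + i].split()
        if len(parts) != 3:
            raise MeshFormatError(f"{path}: bad face line {pos + i + 1}")
        faces[i] = [int(p) for p in parts]
    return FlatMesh(verts, faces, labels, hemisphere)


# ---------------------------------------------------------------------------
# FreeSurfer and GIFTI
# ---------------------------------------------------------------------------

def _project_planar(coords: np.ndarray, path) -> np.ndarray:
    """Drop a z column after verifying it is negligible vs the xy extent."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[1] == 2:
        return coords
    xy = coords[:, :2]
    extent = float(np.ptp(xy, axis=0).max())
    zmax = float(np.abs(coords[:, 2]).max()) if coords.shape[0] else 0.0
    if extent > 0 and zmax > _Z_TOLERANCE * extent:
        raise NonPlanarMeshError(
            f"{path}: |z| up to {zmax:g} vs xy extent {extent:g}; surface is "
            "not flat, refusing to project"
        )
    return xy


def write_freesurfer_flatmap(mesh: FlatMesh, geom_path, annot_path) -> None:
    """Write FreeSurfer binary geometry (z=0) plus a ``.annot`` label file."""
    import nibabel.freesurfer as nfs

    coords = np.column_stack([mesh.vertices, np.zeros(mesh.n_vertices)])
    nfs.write_geometry(str(geom_path), coords, mesh.faces.astype(np.int32))
    names = sorted(set(mesh.labels))
    index = {n: i for i, n in enumerate(names)}
    ids = np.array([index[l] for l in mesh.labels], dtype=np.int32)
    rng = np.random.default_rng(0)  # colors are cosmetic but must be unique
    ctab = np.zeros((len(names), 5), dtype=np.int32)
    ctab[:, :3] = rng.choice(255, size=(len(names), 3), replace=False) if len(
        names
    ) <= 85 else rng.integers(0, 255, size=(len(names), 3))
    ctab[:, 2] = np.arange(len(names))  # force distinct annot values
    ctab[:, 4] = ctab[:, 0] + ctab[:, 1] * 256 + ctab[:, 2] * 256**2
    nfs.write_annot(str(annot_path), ids, ctab, names, fill_ctab=False)


def read_freesurfer_flatmap(geom_path, annot_path, hemisphere="left") -> FlatMesh:
    """Read FreeSurfer binary geometry plus ``.annot`` vertex labels."""
    import nibabel.freesurfer as nfs

    try:
        coords, faces = nfs.read_geometry(str(geom_path))
    except Exception as exc:  # nibabel raises bare ValueError on bad magic
        raise MeshFormatError(f"{geom_path}: {exc}") from exc
    ids, _ctab, names = nfs.read_annot(str(annot_path))
    names = [n.decode() if isinstance(n, bytes) else str(n) for n in names]
    if ids.min() < 0:
        raise MissingLabelError(f"{annot_path}: unlabeled vertices present")
    labels = [names[i] for i in ids]
    verts = _project_planar(coords, geom_path)
    return FlatMesh(verts, faces, labels, hemisphere)


def write_gifti_flatmap(mesh: FlatMesh, surf_path, label_path) -> None:
    """Write a GIFTI ``.surf.gii`` (z=0) plus ``.label.gii`` pair."""
    import nibabel as nib
    from nibabel import gifti

    coords = np.column_stack([mesh.vertices, np.zeros(mesh.n_vertices)]).astype(
        np.float32
    )
    surf = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(coords, intent="NIFTI_INTENT_POINTSET"),
            gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(surf, str(surf_path))

    names = sorted(set(mesh.labels))
    index = {n: i for i, n in enumerate(names)}
    ids = np.array([index[l] for l in mesh.labels], dtype=np.int32)
    table = gifti.GiftiLabelTable()
    for i, n in enumerate(names):
        lab = gifti.GiftiLabel(key=i, red=0.5, green=0.5, blue=0.5, alpha=1.0)
        lab.label = n
        table.labels.append(lab)
    img = gifti.GiftiImage(
        darrays=[gifti.GiftiDataArray(ids, intent="NIFTI_INTENT_LABEL")],
        labeltable=table,
    )
    nib.save(img, str(label_path))


def read_gifti_flatmap(surf_path, label_path, hemisphere="left") -> FlatMesh:
    """Read a GIFTI surface + label pair."""
    import nibabel as nib

    surf = nib.load(str(surf_path))
    try:
        coords = surf.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        faces = surf.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    except IndexError:
        raise MeshFormatError(f"{surf_path}: missing pointset/triangle arrays")
    lab_img = nib.load(str(label_path))
    ids = lab_img.darrays[0].data.astype(int)
    table = {int(l.key): l.label for l in lab_img.labeltable.labels}
    try:
        labels = [table[i] for i in ids]
    except KeyError as exc:
        raise MissingLabelError(f"{label_path}: key {exc} absent from label table")
    verts = _project_planar(coords, surf_path)
    return FlatMesh(verts, faces, labels, hemisphere)


def load_flatmap(
    path: str | os.PathLike,
    dialect: LabelDialect | None = None,
    labels_path: str | os.PathLike | None = None,
    hemisphere: str = "left",
) -> FlatMesh:
    """Load a flat map in any supported format, picked by file extension.

    ``.fmesh``/``.txt`` files are the plain-text dialect; ``.gii`` needs a
    ``.label.gii`` companion; anything else is tried as FreeSurfer binary
    geometry with a ``.annot`` companion. When ``dialect`` is given, the file
    must contain at least the precentral and postcentral labels of that
    dialect (full coverage is reported by :func:`validate_flatmap`).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith((".fmesh", ".txt")):
        mesh = read_fmesh(path)
    elif path.endswith(".gii"):
        if labels_path is None:
            raise MeshFormatError("GIFTI surface needs labels_path=<.label.gii>")
        mesh = read_gifti_flatmap(path, labels_path, hemisphere)
    else:
        if labels_path is None:
            raise MeshFormatError("FreeSurfer surface needs labels_path=<.annot>")
        mesh = read_freesurfer_flatmap(path, labels_path, hemisphere)
    if dialect is not None:
        present = set(mesh.labels)
        for role in ("precentral", "postcentral"):
            if dialect[role] not in present:
                raise MissingLabelError(
                    f"{path}: no vertex labeled {dialect[role]!r} ({role})"
                )
    return mesh
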
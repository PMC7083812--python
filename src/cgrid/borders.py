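"""Extraction of atlas borders from a labeled flat map.

A border is the set of vertices carrying one atlas label that have at least
one neighbor carrying another given label. Five such borders bound the
sensorimotor band: three "vertical" ones running dorsoventrally (precentral
sulcus, central sulcus, postcentral sulcus) and two "horizontal" ones capping
it dorsally (against the paracentral lobule) and ventrally (against the
insula).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import EmptyBorderError
from .mesh import FlatMesh, LabelDialect, vertex_neighbors

__all__ = ["Border", "BorderSet", "extract_border", "extract_smx_borders"]

log = logging.getLogger(__name__)

BORDER_ROLES = ("central_sulcus", "precentral_sulcus", "postcentral_sulcus",
                "dorsal", "ventral")


@dataclass
class Border:
    """An unordered set of border vertices; ordering along the border (by y)
    only happens inside the polynomial fit."""

    role: str
    vertex_indices: np.ndarray  # sorted unique indices into the mesh
    l1_labels: tuple[str, ...]  # the label(s) the member vertices carry
    mesh: FlatMesh

    def __post_init__(self):
        self.vertex_indices = np.unique(np.asarray(self.vertex_indices, dtype=int))

    def __len__(self) -> int:
        return self.vertex_indices.size

    @property
    def coords(self) -> np.ndarray:
        return self.mesh.vertices[self.vertex_indices]


@dataclass
class BorderSet:
    """The five borders of one hemisphere's sensorimotor band."""

    central_sulcus: Border
    precentral_sulcus: Border
    postcentral_sulcus: Border
    dorsal: Border
    ventral: Border

    def __iter__(self):
        return iter(
            (
                self.central_sulcus,
                self.precentral_sulcus,
                self.postcentral_sulcus,
                self.dorsal,
                self.ventral,
            )
        )


def extract_border(
    mesh: FlatMesh,
    neighbors: Sequence[set[int]],
    l1: str | Iterable[str],
    l2set: Iterable[str],
    role: str = "",
) -> Border:
    """Vertices labeled in ``l1`` that touch a vertex labeled in ``l2set``.

    ``l1`` may be a single label or a collection (the dorsal and ventral cap
    borders use both gyri as the inside set). Raises
    :class:`EmptyBorderError` when no vertex qualifies.
    """
    l1set = {l1} if isinstance(l1, str) else set(l1)
    l2 = set(l2set)
    labels = mesh.label_array()
    members = [
        v
        for v in range(mesh.n_vertices)
        if labels[v] in l1set and any(labels[w] in l2 for w in neighbors[v])
    ]
    if not members:
        raise EmptyBorderError(tuple(sorted(l1set)), l2, role or None)
    return Border(role, np.array(members), tuple(sorted(l1set)), mesh)


def _largest_component(border: Border, neighbors: Sequence[set[int]]) -> Border:
    """Restrict a border to its largest connected component w.r.t. mesh
    adjacency among border members; stray label islands are discarded."""
    idx = border.vertex_indices
    pos = {v: i for i, v in enumerate(idx)}
    rows, cols = [], []
    for v in idx:
        for w in neighbors[v]:
            if w in pos:
                rows.append(pos[v])
                cols.append(pos[w])
    if not rows:
        return border  # all isolated; nothing to choose between
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(idx.size, idx.size)
    )
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp <= 1:
        return border
    sizes = np.bincount(comp)
    keep = comp == np.argmax(sizes)
    log.warning(
        "border %s has %d connected components; keeping largest (%d of %d vertices)",
        border.role or "<unnamed>", n_comp, int(keep.sum()), idx.size,
    )
    return Border(border.role, idx[keep], border.l1_labels, border.mesh)


def extract_smx_borders(mesh: FlatMesh, dialect: LabelDialect) -> BorderSet:
    """Extract the five sensorimotor-band borders.

    Central sulcus: precentral vertices touching postcentral. Precentral
    sulcus: precentral touching {pars opercularis, caudal middle frontal,
    superior frontal}. Postcentral sulcus: postcentral touching
    {supramarginal, superior parietal}. Dorsal cap: either gyrus touching the
    paracentral lobule; ventral cap: either gyrus touching the insula.
    Multi-component borders are reduced to their largest component.
    """
    nbrs = vertex_neighbors(mesh)
    pre = dialect["precentral"]
    post = dialect["postcentral"]
    rules = {
        "central_sulcus": (pre, {post}),
        "precentral_sulcus": (
            pre,
            {
                dialect["pars_opercularis"],
                dialect["caudal_middle_frontal"],
                dialect["superior_frontal"],
            },
        ),
        "postcentral_sulcus": (
            post,
            {dialect["supramarginal"], dialect["superior_parietal"]},
        ),
        "dorsal": ({pre, post}, {dialect["paracentral"]}),
        "ventral": ({pre, post}, {dialect["insula"]}),
    }
    out = {}
    for role, (l1, l2) in rules.items():
        border = extract_border(mesh, nbrs, l1, l2, role=role)
        out[role] = _largest_component(border, nbrs)
    return BorderSet(
        central_sulcus=out["central_sulcus"],
        precentral_sulcus=out["precentral_sulcus"],
        postcentral_sulcus=out["postcentral_sulcus"],
        dorsal=out["dorsal"],
        ventral=out["ventral"],
    )
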
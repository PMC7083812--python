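"""Synthetic flat-map subjects: warped two-gyrus bands with planted
somatotopic activation hotspots and known ground truth.

The generator emulates what the grid normalization is meant to absorb:
subject-to-subject (and left-right) variation in the *shape* of the
sensorimotor band while the *relative* somatotopic layout stays fixed. A
rectangular parametric band (s along the anteroposterior axis, t along the
dorsoventral axis, both in [0, 1]) is triangulated, surrounded by its eight
atlas neighbor regions, pushed through a smooth low-order harmonic warp, and
optionally mirrored for the right hemisphere. Activation fields are sums of
Gaussians in parametric coordinates — feet dorsal (t ~ 0.9), hand at about
two thirds of the dorsoventral axis (t ~ 0.67), tongue ventral (t ~ 0.15) —
plus white noise.

Every vertex's true parametric position is exposed for oracle use; the
normalization pipeline itself never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from .errors import GenerationError
from .mesh import FlatMesh, LabelDialect, VertexField

__all__ = [
    "Hotspot",
    "SubjectSpec",
    "SyntheticSubject",
    "CohortSubject",
    "CANONICAL_HOTSPOTS",
    "TASKS",
    "make_subject",
    "make_subject_flatmap",
    "make_activation",
    "make_cohort",
    "parametric_lookup",
]

#: Canonical somatotopic hotspot centers (s anteroposterior, t dorsoventral),
#: all centered on the central sulcus (s = 0.5): feet dorsal, hand at about
#: 2/3 of the dorsoventral axis, tongue ventral.
CANONICAL_HOTSPOTS = {
    "feet": (0.5, 0.90),
    "hand": (0.5, 0.67),
    "tongue": (0.5, 0.15),
}

TASKS = ("feet", "tongue", "hand_left", "hand_right")

#: Ipsilateral hand activation relative to the contralateral hemisphere.
IPSI_HAND_FACTOR = 0.25


@dataclass(frozen=True)
class Hotspot:
    """A Gaussian activation focus in parametric coordinates."""

    s: float
    t: float
    amplitude: float = 1.0
    width: float = 0.10  # sd in parametric units
    body_part: str = ""

    def __post_init__(self):
        if not (0.0 <= self.s <= 1.0 and 0.0 <= self.t <= 1.0):
            raise GenerationError(f"hotspot center ({self.s}, {self.t}) outside [0,1]^2")
        if self.width <= 0:
            raise GenerationError("hotspot width must be > 0")


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to deterministically rebuild one synthetic subject.

    Band dimensions are in a.u. (~mm): length is the dorsoventral extent of
    the sensorimotor band, width the anteroposterior extent across both
    gyri. ``warp_amplitude`` is the RMS displacement of the harmonic warp
    and ``warp_order`` its highest spatial frequency (low = smooth).
    ``edge_length`` is the target mesh edge length.
    """

    seed: int = 0
    band_length: float = 100.0
    band_width: float = 50.0
    margin: float = 8.0
    warp_amplitude: float = 2.5
    warp_order: int = 2
    edge_length: float = 0.7
    hemisphere: str = "left"
    hotspots: tuple[Hotspot, ...] = ()

    def __post_init__(self):
        if self.warp_amplitude < 0:
            raise GenerationError("warp amplitude must be >= 0")
        if self.edge_length <= 0:
            raise GenerationError("edge length must be > 0")


@dataclass
class SyntheticSubject:
    """A generated mesh plus its ground-truth parametric coordinates."""

    mesh: FlatMesh
    param_s: np.ndarray  # (V,) true anteroposterior parametric coordinate
    param_t: np.ndarray  # (V,) true dorsoventral parametric coordinate
    spec: SubjectSpec


_APARC = LabelDialect.freesurfer_aparc()


def _labels_from_parametric(s: np.ndarray, t: np.ndarray) -> list[str]:
    """Assign atlas labels from parametric position: the band itself splits
    into the two gyri at the central sulcus (s = 0.5); the margins hold the
    eight neighbor regions in their anatomical positions."""
    labels = []
    for si, ti in zip(s, t):
        if ti > 1.0:
            lab = _APARC["paracentral"]
        elif ti < 0.0:
            lab = _APARC["insula"]
        elif si < 0.0:
            if ti < 1.0 / 3.0:
                lab = _APARC["pars_opercularis"]
            elif ti < 2.0 / 3.0:
                lab = _APARC["caudal_middle_frontal"]
            else:
                lab = _APARC["superior_frontal"]
        elif si > 1.0:
            lab = _APARC["supramarginal"] if ti < 0.5 else _APARC["superior_parietal"]
        else:
            lab = _APARC["precentral"] if si < 0.5 else _APARC["postcentral"]
        labels.append(lab)
    return labels


def _harmonic_field(s, t, rng, order: int) -> np.ndarray:
    """A smooth random displacement field, RMS-normalized.

    Harmonic (sinusoidal) along the band's long dorsoventral axis and linear
    across its width: gyral shape variability is dominated by dorsoventral
    bending and shifting of the whole band, and across a band only a few
    centimetres wide the displacement gradient is approximately constant.
    The resulting warp is smooth and decidedly non-affine along the band.
    """
    f = np.zeros_like(s)
    for l in range(1, order + 1):
        a, b = rng.normal(size=2)
        pt = rng.uniform(0, 2 * np.pi)
        f += (a * (1.0 - s) + b * s) * np.sin(np.pi * l * t + pt)
    rms = float(np.sqrt(np.mean(f**2)))
    return f / rms if rms > 0 else f


def make_subject(spec: SubjectSpec) -> SyntheticSubject:
    """Build one warped, labeled synthetic hemisphere (deterministic in
    ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    w, L, m, h = spec.band_width, spec.band_length, spec.margin, spec.edge_length

    nx = int(round((w + 2 * m) / h)) + 1
    ny = int(round((L + 2 * m) / h)) + 1
    xs = np.linspace(-m, w + m, nx)
    ys = np.linspace(-m, L + m, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    x = X.ravel()
    y = Y.ravel()
    s = x / w
    t = y / L
    labels = _labels_from_parametric(s, t)

    # structured triangulation: split each cell along one diagonal
    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])

    if spec.warp_amplitude > 0:
        dx = spec.warp_amplitude * _harmonic_field(s, t, rng, spec.warp_order)
        dy = spec.warp_amplitude * _harmonic_field(s, t, rng, spec.warp_order)
        xw, yw = x + dx, y + dy
    else:
        xw, yw = x, y

    if spec.hemisphere == "right":
        xw = -xw

    verts = np.column_stack([xw, yw])
    tri = verts[faces]
    d1 = tri[:, 1] - tri[:, 0]
    d2 = tri[:, 2] - tri[:, 0]
    area2 = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    if not (np.all(area2 > 0) or np.all(area2 < 0)):
        raise GenerationError(
            "warp folds the band onto itself; lower warp_amplitude or "
            "warp_order"
        )
    mesh = FlatMesh(verts, faces, labels, spec.hemisphere)
    return SyntheticSubject(mesh, s, t, spec)


def make_subject_flatmap(spec: SubjectSpec) -> FlatMesh:
    """The mesh only (see :func:`make_subject` for the ground truth too)."""
    return make_subject(spec).mesh


def make_activation(
    subject: SyntheticSubject,
    noise_sd: float = 0.0,
    hotspots: Sequence[Hotspot] | None = None,
    seed: int | None = None,
    name: str = "beta",
) -> VertexField:
    """Sum-of-Gaussians activation in parametric coordinates plus white noise.

    Hotspots default to the subject spec's. Noise is seeded from ``seed``
    (default: the subject seed), so the field is deterministic.
    """
    hotspots = subject.spec.hotspots if hotspots is None else tuple(hotspots)
    vals = np.zeros(subject.mesh.n_vertices)
    for hs in hotspots:
        d2 = (subject.param_s - hs.s) ** 2 + (subject.param_t - hs.t) ** 2
        vals += hs.amplitude * np.exp(-d2 / (2.0 * hs.width**2))
    if noise_sd > 0:
        rng = np.random.default_rng(subject.spec.seed if seed is None else seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.size)
    return VertexField(vals, name=name)


def parametric_lookup(subject: SyntheticSubject):
    """Ground-truth inverse warp: a callable mapping flat-map (x, y) points
    to true parametric (s, t), by linear interpolation over the mesh
    vertices. Oracle-only; the normalization pipeline never uses it."""
    interp = LinearNDInterpolator(
        subject.mesh.vertices, np.column_stack([subject.param_s, subject.param_t])
    )

    def lookup(points: np.ndarray) -> np.ndarray:
        return interp(np.atleast_2d(np.asarray(points, dtype=float)))

    return lookup


@dataclass
class CohortSubject:
    """One synthetic subject of a cohort: two hemispheres, four task fields
    per hemisphere, and the planted hotspot truth."""

    subject_id: str
    hemispheres: dict  # hemi -> SyntheticSubject
    fields: dict  # (task, hemi) -> VertexField
    truth: dict  # body part -> (s, t) planted center


def _task_hotspots(
    centers: Mapping[str, tuple[float, float]], task: str, hemi: str
) -> tuple[Hotspot, ...]:
    """Hotspots for one task in one hemisphere: feet and tongue are
    bilateral; hand activation is predominantly contralateral."""
    if task == "feet":
        return (Hotspot(*centers["feet"], amplitude=1.0, body_part="feet"),)
    if task == "tongue":
        return (Hotspot(*centers["tongue"], amplitude=1.0, body_part="tongue"),)
    contra = {"hand_left": "right", "hand_right": "left"}[task]
    amp = 1.0 if hemi == contra else IPSI_HAND_FACTOR
    return (Hotspot(*centers["hand"], amplitude=amp, body_part="hand"),)


def make_cohort(
    n_subjects: int,
    base_spec: SubjectSpec | None = None,
    hotspot_jitter: float = 0.02,
    noise_sd: float = 0.1,
    seed: int = 0,
    scramble_hotspots: bool = False,
) -> list[CohortSubject]:
    """Generate a cohort of synthetic subjects (deterministic in ``seed``).

    Each subject gets an independently warped left hemisphere and a
    mirrored, independently warped right hemisphere sharing the subject's
    parametric hotspot layout (the paper-level premise: hemispheres differ
    anatomically but share relative somatotopy). ``hotspot_jitter`` is the
    sd (parametric units) of the subject-level displacement of the canonical
    hotspot centers; ``scramble_hotspots`` instead places each subject's
    hotspots uniformly at random, destroying the shared layout (a negative
    control for between-subject similarity).
    """
    if n_subjects < 3:
        raise GenerationError("cohort needs >= 3 subjects")
    base = base_spec if base_spec is not None else SubjectSpec()
    root = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        srng = np.random.default_rng(root.integers(2**31))
        centers: dict[str, tuple[float, float]] = {}
        for part, (s0, t0) in CANONICAL_HOTSPOTS.items():
            if scramble_hotspots:
                s0 = float(srng.uniform(0.2, 0.8))
                t0 = float(srng.uniform(0.1, 0.9))
            elif hotspot_jitter > 0:
                s0 = float(np.clip(s0 + srng.normal(0, hotspot_jitter), 0, 1))
                t0 = float(np.clip(t0 + srng.normal(0, hotspot_jitter), 0, 1))
            centers[part] = (s0, t0)
        hemispheres = {}
        fields = {}
        for hemi in ("left", "right"):
            spec = replace(
                base,
                seed=int(srng.integers(2**31)),
                hemisphere=hemi,
            )
            subj = make_subject(spec)
            hemispheres[hemi] = subj
            for task in TASKS:
                fields[(task, hemi)] = make_activation(
                    subj,
                    noise_sd=noise_sd,
                    hotspots=_task_hotspots(centers, task, hemi),
                    seed=int(srng.integers(2**31)),
                    name=f"beta_{task}",
                )
        cohort.append(
            CohortSubject(
                subject_id=f"sub{i:02d}",
                hemispheres=hemispheres,
                fields=fields,
                truth=centers,
            )
        )
    return cohort
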
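"""Exception hierarchy for the cgrid package.

Every failure mode that callers may want to catch separately gets its own
class; all inherit from :class:`CgridError`.
"""


class CgridError(Exception):
    """Base class for all cgrid errors."""


class MeshFormatError(CgridError):
    """A surface/label file could not be parsed or is internally inconsistent."""


class InvalidFaceError(MeshFormatError):
    """A face references a vertex index outside the vertex table."""


class MissingLabelError(CgridError):
    """A label table or dialect lacks a required region role."""


class NonPlanarMeshError(MeshFormatError):
    """Source coordinates have a z-extent too large to flatten by projection."""


class EmptyBorderError(CgridError):
    """Border extraction produced no vertices for a (L1, L2set) rule."""

    def __init__(self, l1, l2set, role=None):
        self.l1 = l1
        self.l2set = tuple(sorted(l2set))
        self.role = role
        where = f" ({role})" if role else ""
        super().__init__(
            f"empty border{where}: no vertex labeled {l1!r} has a neighbor "
            f"labeled in {self.l2set!r}"
        )


class UnderdeterminedFitError(CgridError):
    """Too few border vertices for the requested polynomial order."""


class RankDeficientFitError(CgridError):
    """The polynomial least-squares system is rank deficient."""


class GeometryError(CgridError):
    """Degenerate geometry (e.g. y_min >= y_max; mesh likely upside-down)."""


class ConfigurationError(CgridError):
    """Invalid grid configuration (e.g. odd number of columns)."""


class DegenerateCurveError(CgridError):
    """A truncated curve collapsed to a single node or zero length."""


class ExtrapolationError(CgridError):
    """A fitted polynomial exploded far outside the mesh while extrapolating."""


class OrientationError(CgridError):
    """Hemisphere/orientation metadata missing or unrecognised."""


class InsufficientTilesError(CgridError):
    """Fewer than the minimum number of jointly valid tiles for a correlation."""


class ZeroVarianceError(CgridError):
    """An input to a correlation or t-test has no variance."""


class GenerationError(CgridError):
    """Synthetic mesh generation failed (e.g. warp folds the band onto itself)."""
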
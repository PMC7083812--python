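"""End-to-end glue: from meshes and vertex fields to oriented grid maps and
cohort-level similarity reports.

These helpers chain the individual steps (border extraction, grid
construction, optional surface smoothing, tile averaging, orientation) the
way an analysis script would, and are what the CLI, the examples and the
synthetic-cohort evaluation use.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .borders import extract_smx_borders
from .grid import CgridDefinition, build_cgrid
from .mapping import CgridMap, map_vertex_values_to_grid, orient_grid, smooth_vertex_values
from .mesh import FlatMesh, LabelDialect, VertexField
from .similarity import (
    SimilarityReport,
    between_subject_report,
    within_subject_scores,
)
from .synthetic import TASKS, CohortSubject

__all__ = [
    "grid_for_mesh",
    "field_to_oriented_map",
    "cohort_grid_maps",
    "evaluate_cohort",
]


def grid_for_mesh(
    mesh: FlatMesh,
    dialect: LabelDialect | None = None,
    n_rows: int = 28,
    m_columns: int = 84,
) -> CgridDefinition:
    """Extract the five borders and build the grid for one hemisphere."""
    dialect = dialect or LabelDialect.freesurfer_aparc()
    borders = extract_smx_borders(mesh, dialect)
    return build_cgrid(mesh, borders, n_rows=n_rows, m_columns=m_columns)


def field_to_oriented_map(
    field: VertexField,
    mesh: FlatMesh,
    griddef: CgridDefinition,
    smooth_fwhm: float = 0.0,
    subject: str = "",
    task: str = "",
) -> CgridMap:
    """Smooth (optionally), average into tiles, and orient one field."""
    if smooth_fwhm > 0:
        field = smooth_vertex_values(field, mesh, smooth_fwhm)
    cmap = map_vertex_values_to_grid(field, griddef)
    cmap.subject = subject
    cmap.task = task
    return orient_grid(cmap)


def cohort_grid_maps(
    cohort: Sequence[CohortSubject],
    n_rows: int = 28,
    m_columns: int = 84,
    smooth_fwhm: float = 6.0,
    dialect: LabelDialect | None = None,
) -> dict[str, dict[tuple[str, str], CgridMap]]:
    """Oriented task maps for every synthetic subject and hemisphere.

    Returns {subject_id: {(task, hemisphere): oriented CgridMap}}. One grid
    is built per hemisphere and reused across that hemisphere's tasks.
    """
    out: dict[str, dict[tuple[str, str], CgridMap]] = {}
    for subj in cohort:
        maps: dict[tuple[str, str], CgridMap] = {}
        for hemi, synth in subj.hemispheres.items():
            griddef = grid_for_mesh(synth.mesh, dialect, n_rows, m_columns)
            for task in TASKS:
                maps[(task, hemi)] = field_to_oriented_map(
                    subj.fields[(task, hemi)],
                    synth.mesh,
                    griddef,
                    smooth_fwhm=smooth_fwhm,
                    subject=subj.subject_id,
                    task=task,
                )
        out[subj.subject_id] = maps
    return out


def evaluate_cohort(
    maps: Mapping[str, Mapping[tuple[str, str], CgridMap]],
) -> tuple[SimilarityReport, SimilarityReport]:
    """Within-subject (left-right) and between-subject (leave-one-out)
    similarity reports for a cohort of oriented task maps."""
    import pandas as pd

    within_scores = []
    within_agg = {}
    for subject_id, subj_maps in maps.items():
        rep = within_subject_scores(subj_maps, subject=subject_id)
        within_scores.extend(rep.scores)
        within_agg[subject_id] = float(rep.per_subject.iloc[0])
    within = SimilarityReport(within_scores, pd.Series(within_agg))

    cohort_by_task = {
        f"{task}:{hemi}": {s: m[(task, hemi)] for s, m in maps.items()}
        for task in TASKS
        for hemi in ("left", "right")
    }
    between = between_subject_report(cohort_by_task)
    return within, between
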
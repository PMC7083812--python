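"""Pattern-similarity evaluation in grid space.

Similarity between two grid maps is the Pearson correlation over tiles valid
in both, Fisher z-transformed (arctanh) so scores can be averaged and tested
across subjects; tanh inverts the transform back to a correlation. Two
schemes are provided: within-subject left-right similarity (with the hand
tasks paired contralaterally) and between-subject leave-one-out similarity
(each subject against the mean map of the others). Group differences between
normalization schemes are assessed with a paired t-test on per-subject
aggregate z scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientTilesError, ZeroVarianceError
from .mapping import CgridMap, RoiSlice, extract_roi_halves

__all__ = [
    "R_CLAMP",
    "SimilarityScore",
    "SimilarityReport",
    "pearson_similarity",
    "fisher_z",
    "inverse_fisher_z",
    "within_subject_scores",
    "between_subject_loo",
    "between_subject_report",
    "paired_t_test",
]

#: Correlations are clamped to +/-(1 - 1e-7) before arctanh so that perfect
#: (anti)correlation — common on synthetic data — stays finite.
R_CLAMP = 1.0 - 1e-7

MIN_TILES = 3

WITHIN_TASKS = ("feet", "tongue", "hand")


def fisher_z(r: float) -> float:
    """arctanh with the clamp applied; strictly increasing in r."""
    return float(np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP)))


def inverse_fisher_z(z: float) -> float:
    """Map a (group-averaged) similarity z score back to a correlation."""
    return float(np.tanh(z))


@dataclass
class SimilarityScore:
    """One Pearson/Fisher-z similarity with its context."""

    r: float
    z: float
    n_tiles: int
    subject: str = ""
    task: str = ""
    roi: str = ""
    comparison: str = ""  # "within" | "between"


@dataclass
class SimilarityReport:
    """Scores plus per-subject aggregates (mean z over tasks x ROIs) and
    group summary; z values, never r values, are averaged."""

    scores: list[SimilarityScore]
    per_subject: pd.Series = dc_field(default_factory=lambda: pd.Series(dtype=float))
    ttest: tuple[float, int, float] | None = None

    @property
    def group_mean_z(self) -> float:
        return float(self.per_subject.mean())

    @property
    def group_sd_z(self) -> float:
        return float(self.per_subject.std(ddof=1))

    @property
    def group_mean_r(self) -> float:
        return inverse_fisher_z(self.group_mean_z)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject": s.subject,
                    "task": s.task,
                    "roi": s.roi,
                    "comparison": s.comparison,
                    "r": s.r,
                    "z": s.z,
                    "n_tiles": s.n_tiles,
                }
                for s in self.scores
            ]
        )


def _values_mask(x: CgridMap | RoiSlice) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(x.values, dtype=float), np.asarray(x.mask, dtype=bool)


def pearson_similarity(a, b, **context) -> SimilarityScore:
    """Pearson correlation over tiles valid in both maps, plus Fisher z.

    Raises :class:`InsufficientTilesError` with fewer than 3 jointly valid
    tiles and :class:`ZeroVarianceError` when either pattern is constant on
    the joint support.
    """
    va, ma = _values_mask(a)
    vb, mb = _values_mask(b)
    if va.shape != vb.shape:
        raise InsufficientTilesError(
            f"shape mismatch: {va.shape} vs {vb.shape}"
        )
    common = ma & mb & np.isfinite(va) & np.isfinite(vb)
    n = int(common.sum())
    if n < MIN_TILES:
        raise InsufficientTilesError(
            f"only {n} jointly valid tiles; need >= {MIN_TILES}"
        )
    x, y = va[common], vb[common]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("constant pattern on the jointly valid tiles")
    r = float(np.clip(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy), -1.0, 1.0))
    return SimilarityScore(r=r, z=fisher_z(r), n_tiles=n, **context)


def _roi_slice(cmap: CgridMap, roi: str) -> RoiSlice:
    m1, s1 = extract_roi_halves(cmap)
    return m1 if roi == "M1" else s1


def within_subject_scores(
    maps: Mapping[tuple[str, str], CgridMap], subject: str = ""
) -> SimilarityReport:
    """Left-right similarity of one subject's task maps.

    ``maps`` is keyed by (task, hemisphere) with tasks feet, tongue,
    hand_left, hand_right and both hemispheres, all oriented. Per ROI (M1,
    S1): feet left vs right, tongue left vs right, and the contralateral
    hand pairing — the left-hemisphere map of the right-hand task against
    the right-hemisphere map of the left-hand task — giving 6 scores whose
    mean z is the subject's within-subject similarity.
    """
    pairs = {
        "feet": (("feet", "left"), ("feet", "right")),
        "tongue": (("tongue", "left"), ("tongue", "right")),
        "hand": (("hand_right", "left"), ("hand_left", "right")),
    }
    for key_a, key_b in pairs.values():
        for key in (key_a, key_b):
            if key not in maps:
                raise KeyError(f"missing task map {key}")
    scores = []
    for roi in ("M1", "S1"):
        for task, (key_a, key_b) in pairs.items():
            score = pearson_similarity(
                _roi_slice(maps[key_a], roi),
                _roi_slice(maps[key_b], roi),
                subject=subject,
                task=task,
                roi=roi,
                comparison="within",
            )
            scores.append(score)
    agg = float(np.mean([s.z for s in scores]))
    return SimilarityReport(scores, pd.Series({subject: agg}))


def _loo_mean(slices: Sequence[RoiSlice]) -> RoiSlice:
    """Tile-wise mean over contributors, valid only where ALL are valid."""
    mask = np.logical_and.reduce([s.mask for s in slices])
    stack = np.stack([s.values for s in slices])
    with np.errstate(invalid="ignore"):
        mean = np.where(mask, stack.mean(axis=0), np.nan)
    return RoiSlice(slices[0].roi, mean, mask)


def between_subject_loo(
    cohort: Mapping[str, CgridMap], task: str = "", roi: str = "M1"
) -> list[SimilarityScore]:
    """Leave-one-out similarity for one task and ROI.

    ``cohort`` maps subject id to that subject's oriented map for the task;
    each subject's ROI half is correlated against the tile-wise mean of the
    other subjects' halves (a tile enters the mean only if valid in every
    contributor).
    """
    subjects = list(cohort)
    if len(subjects) < 3:
        raise InsufficientTilesError(
            f"leave-one-out needs >= 3 subjects, got {len(subjects)}"
        )
    halves = {s: _roi_slice(cohort[s], roi) for s in subjects}
    scores = []
    for s in subjects:
        others = [halves[t] for t in subjects if t != s]
        mean_map = _loo_mean(others)
        scores.append(
            pearson_similarity(
                halves[s], mean_map, subject=s, task=task, roi=roi,
                comparison="between",
            )
        )
    return scores


def between_subject_report(
    cohort_by_task: Mapping[str, Mapping[str, CgridMap]],
    rois: Sequence[str] = ("M1", "S1"),
) -> SimilarityReport:
    """Leave-one-out scores over all tasks and ROIs, aggregated per subject.

    ``cohort_by_task`` maps task name to {subject: oriented map}. The
    per-subject similarity is the mean z over tasks x ROIs.
    """
    all_scores: list[SimilarityScore] = []
    for task, cohort in cohort_by_task.items():
        for roi in rois:
            all_scores.extend(between_subject_loo(cohort, task=task, roi=roi))
    frame = pd.DataFrame([{"subject": s.subject, "z": s.z} for s in all_scores])
    per_subject = frame.groupby("subject")["z"].mean()
    return SimilarityReport(all_scores, per_subject)


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired-samples t-test on per-subject scores.

    Returns (t, df, p) with t = mean(d) / (sd(d)/sqrt(n)) for d = a - b and
    df = n - 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ZeroVarianceError("paired samples must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ZeroVarianceError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("all paired differences identical")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p
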
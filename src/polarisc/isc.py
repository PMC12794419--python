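"""Voxel-wise inter-subject correlation (ISC) and the polarization contrast.

One-to-average ISC correlates each subject's voxel time course with the
average time course of the *other* subjects at the same voxel
(leave-one-out).  The grouped variant computes, per subject, the within-
group ISC (against the leave-one-out average of the subject's own group)
and the between-group ISC (against the full average of the other group);
their difference, averaged over subjects, is the neural-polarization map
the permutation test consumes.

Correlations are computed on the per-statement z-scored series; reference
averages are plain means of those series (no re-normalization).  Cohort
averages are taken over raw R values by default; a Fisher-z option exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import SubjectTimeSeries, VoxelGrid

__all__ = [
    "ISCMap",
    "PolarizationMaps",
    "one_to_average_isc",
    "grouped_isc",
    "narrative_restricted_isc",
]


@dataclass
class ISCMap:
    """Per-subject and cohort-average voxel-wise Pearson R."""

    subject_ids: list[str]
    subject_r: np.ndarray  # (n_subjects, n_voxels), NaN where undefined
    average_r: np.ndarray  # (n_voxels,)
    group_definition: str  # whole-sample | within | between
    narrative: str  # all | pro | anti
    grid: VoxelGrid | None = None


@dataclass
class PolarizationMaps:
    """Within-group R, between-group R and their difference, per subject."""

    subject_ids: list[str]
    groups: np.ndarray  # group label per subject
    within_r: np.ndarray  # (n_subjects, n_voxels)
    between_r: np.ndarray
    narrative: str = "all"
    grid: VoxelGrid | None = None

    @property
    def diff(self) -> np.ndarray:
        return self.within_r - self.between_r

    @property
    def average_diff(self) -> np.ndarray:
        return np.nanmean(self.diff, axis=0)


def _stack(cohort) -> tuple[np.ndarray, list[str], VoxelGrid | None, np.ndarray | None]:
    """Accept a list of SubjectTimeSeries or a (S, V, F) array."""
    if isinstance(cohort, np.ndarray):
        return np.asarray(cohort, dtype=float), [
            f"sub-{i:02d}" for i in range(cohort.shape[0])
        ], None, None
    ids = [ts.subject_id for ts in cohort]
    shapes = {ts.data.shape for ts in cohort}
    if len(shapes) != 1:
        raise ValueError("all subjects must share voxel set and frame count")
    data = np.stack([ts.data for ts in cohort]).astype(float)
    grid = cohort[0].grid
    ftypes = cohort[0].frame_types
    return data, ids, grid, ftypes


def _corr_with_reference(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson R per voxel between one subject (V, F) and a reference (V, F).

    Zero-variance series on either side yield NaN (masked, not zero)."""
    xc = x - x.mean(axis=1, keepdims=True)
    rc = ref - ref.mean(axis=1, keepdims=True)
    num = np.sum(xc * rc, axis=1)
    den = np.sqrt(np.sum(xc**2, axis=1) * np.sum(rc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r = np.where(den == 0, np.nan, r)
    return np.clip(r, -1.0, 1.0)


def _fisher_mean(r: np.ndarray, axis: int = 0) -> np.ndarray:
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    return np.tanh(np.nanmean(z, axis=axis))


def one_to_average_isc(
    cohort,
    leave_one_out: bool = True,
    fisher: bool = False,
    narrative: str = "all",
) -> ISCMap:
    """Whole-sample one-to-average ISC.

    For each subject and voxel, the Pearson correlation between the
    subject's time course and the average time course of the other
    subjects (``leave_one_out=True``, default) or of all subjects
    including them.  The cohort map averages R over subjects (raw R, or
    via Fisher z when ``fisher=True``).
    """
    data, ids, grid, _ = _stack(cohort)
    n_subj = data.shape[0]
    if n_subj < 3:
        raise ValueError("ISC needs at least 3 subjects")
    total = data.sum(axis=0)  # (V, F)
    rs = np.empty(data.shape[:2])
    for i in range(n_subj):
        ref = (total - data[i]) / (n_subj - 1) if leave_one_out else total / n_subj
        rs[i] = _corr_with_reference(data[i], ref)
    avg = _fisher_mean(rs) if fisher else np.nanmean(rs, axis=0)
    return ISCMap(
        subject_ids=ids, subject_r=rs, average_r=avg,
        group_definition="whole-sample", narrative=narrative, grid=grid,
    )


def _group_vectors(ids: list[str], assignment: pd.DataFrame) -> np.ndarray:
    lookup = assignment.set_index("subject_id")["group"]
    missing = [s for s in ids if s not in lookup.index]
    if missing:
        raise ValueError(f"subjects without group assignment: {missing}")
    return lookup.loc[ids].to_numpy()


def grouped_isc(
    cohort,
    assignment: pd.DataFrame,
    narrative: str = "all",
    frame_mask: np.ndarray | None = None,
) -> PolarizationMaps:
    """Within-group (leave-one-out) and between-group (full other-group
    average) ISC per subject and voxel, plus their difference."""
    data, ids, grid, _ = _stack(cohort)
    if frame_mask is not None:
        data = data[:, :, frame_mask]
    groups = _group_vectors(ids, assignment)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("grouped ISC requires exactly 2 groups")
    sizes = {lab: int(np.sum(groups == lab)) for lab in labels}
    if min(sizes.values()) < 2:
        raise ValueError("both groups need at least 2 subjects")

    sums = {lab: data[groups == lab].sum(axis=0) for lab in labels}
    within = np.empty(data.shape[:2])
    between = np.empty(data.shape[:2])
    for i in range(data.shape[0]):
        own, other = groups[i], labels[labels != groups[i]][0]
        own_ref = (sums[own] - data[i]) / (sizes[own] - 1)
        other_ref = sums[other] / sizes[other]
        within[i] = _corr_with_reference(data[i], own_ref)
        between[i] = _corr_with_reference(data[i], other_ref)
    return PolarizationMaps(
        subject_ids=ids, groups=groups, within_r=within, between_r=between,
        narrative=narrative, grid=grid,
    )


def narrative_restricted_isc(
    cohort,
    assignment: pd.DataFrame,
    narrative: str = "all",
    frame_types: np.ndarray | None = None,
    min_frames: int = 10,
) -> PolarizationMaps:
    """Grouped ISC over only the frames of one narrative type.

    ``frame_types`` labels each concatenated frame 'pro' or 'anti'; it is
    taken from the SubjectTimeSeries when not given.  ``narrative='all'``
    is exactly ``grouped_isc``.
    """
    if narrative not in ("all", "pro", "anti"):
        raise ValueError("narrative must be 'all', 'pro' or 'anti'")
    data, ids, grid, ftypes = _stack(cohort)
    if frame_types is None:
        frame_types = ftypes
    if narrative == "all":
        return grouped_isc(cohort, assignment, narrative="all")
    if frame_types is None:
        raise ValueError("frame_types required for narrative restriction")
    frame_types = np.asarray(frame_types)
    if frame_types.size != data.shape[2]:
        raise ValueError("frame_types length must match frame count")
    sel = frame_types == narrative
    if int(sel.sum()) < min_frames:
        raise ValueError(
            f"only {int(sel.sum())} frames of type {narrative!r} (<{min_frames})"
        )
    return grouped_isc(cohort, assignment, narrative=narrative, frame_mask=sel)
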
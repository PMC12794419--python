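"""From 4D volumes to analysis-ready voxel x time matrices.

Stages, in pipeline order: motion-based subject exclusion, nuisance
regression (6 motion parameters + derivatives, global signal, framewise
displacement, 6 aCompCor components, polynomial trends to order 2),
high-pass filtering at 0.01 Hz, then statement-window extraction with
per-statement z-scoring and concatenation (inter-statement frames
dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "SubjectTimeSeries",
    "CONFOUND_COLUMNS",
    "validate_schedule",
    "exclude_by_motion",
    "validate_confounds",
    "regress_nuisance",
    "highpass",
    "extract_and_concatenate",
    "from_volume",
    "series_to_nifti",
]

MOTION_PARAMS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
CONFOUND_COLUMNS = (
    MOTION_PARAMS
    + tuple(f"{m}_derivative1" for m in MOTION_PARAMS)
    + ("global_signal", "framewise_displacement")
    + tuple(f"a_comp_cor_{i:02d}" for i in range(6))
    + ("poly_0", "poly_1", "poly_2")
)


@dataclass(frozen=True)
class VoxelGrid:
    """Voxel bookkeeping: grid shape, affine to mm, masked voxel (i,j,k)."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    ijk: np.ndarray  # (n_voxels, 3) int

    def mm(self, ijk: np.ndarray | None = None) -> np.ndarray:
        """Map voxel indices to mm coordinates via the affine."""
        pts = self.ijk if ijk is None else np.atleast_2d(ijk)
        hom = np.column_stack([pts, np.ones(len(pts))])
        return (self.affine @ hom.T).T[:, :3]

    def linear_index(self) -> dict[tuple[int, int, int], int]:
        return {tuple(v): i for i, v in enumerate(map(tuple, self.ijk))}

    def to_volume(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.ijk[:, 0], self.ijk[:, 1], self.ijk[:, 2]] = values
        return vol


@dataclass
class SubjectTimeSeries:
    """One subject's masked voxel x frame matrix with grid metadata.

    ``frame_types`` is filled after statement extraction: the narrative
    type ('pro'/'anti') of the statement each concatenated frame came from.
    """

    subject_id: str
    data: np.ndarray  # (n_voxels, n_frames)
    grid: VoxelGrid
    tr_s: float
    frame_types: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def from_volume(
    volume: np.ndarray | str,
    mask: np.ndarray | str,
    subject_id: str,
    tr_s: float,
    affine: np.ndarray | None = None,
) -> SubjectTimeSeries:
    """Flatten a 4D volume (or NIfTI path) to masked voxels x frames."""
    if isinstance(volume, str):
        img = nib.load(volume)
        volume = np.asarray(img.dataobj)
        affine = img.affine
    if isinstance(mask, str):
        mimg = nib.load(mask)
        mask = np.asarray(mimg.dataobj).astype(bool)
        affine = mimg.affine if affine is None else affine
    if affine is None:
        raise ValueError("affine required when passing bare arrays")
    mask = np.asarray(mask, dtype=bool)
    ijk = np.argwhere(mask)
    data = np.asarray(volume, dtype=float)[mask]  # (n_voxels, T)
    grid = VoxelGrid(shape=mask.shape, affine=np.asarray(affine), ijk=ijk)
    return SubjectTimeSeries(subject_id=subject_id, data=data, grid=grid,
                             tr_s=float(tr_s))


def series_to_nifti(values: np.ndarray, grid: VoxelGrid) -> nib.Nifti1Image:
    """Pack a per-voxel vector (or voxel x frame matrix) into a NIfTI image."""
    values = np.asarray(values)
    if values.ndim == 1:
        vol = grid.to_volume(values)
    else:
        vol = np.full(grid.shape + (values.shape[1],), np.nan)
        vol[grid.ijk[:, 0], grid.ijk[:, 1], grid.ijk[:, 2], :] = values
    img = nib.Nifti1Image(vol.astype(np.float32), grid.affine)
    img.header.set_sform(grid.affine, code=1)
    img.header.set_qform(grid.affine, code=1)
    return img


def validate_schedule(schedule: pd.DataFrame) -> pd.DataFrame:
    """Statement table: onset_s, duration_s, type in {pro, anti};
    sorted by onset and non-overlapping."""
    required = {"onset_s", "duration_s", "type"}
    if required - set(schedule.columns):
        raise ValueError(f"schedule needs columns {sorted(required)}")
    if not set(schedule["type"]) <= {"pro", "anti"}:
        raise ValueError("statement type must be 'pro' or 'anti'")
    if (schedule["duration_s"] <= 0).any():
        raise ValueError("durations must be positive")
    sched = schedule.sort_values("onset_s").reset_index(drop=True)
    ends = sched["onset_s"] + sched["duration_s"]
    if (sched["onset_s"].to_numpy()[1:] < ends.to_numpy()[:-1]).any():
        raise ValueError("statements overlap")
    return sched


def exclude_by_motion(
    fd_by_subject: pd.DataFrame | dict,
    frac: float = 0.25,
    threshold_mm: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Split subjects into (kept, excluded) by framewise displacement.

    A subject is excluded iff strictly more than ``frac`` of FD values
    exceed ``threshold_mm`` (defaults: >25% of frames above 0.5 mm).
    """
    if threshold_mm < 0:
        raise ValueError("threshold_mm must be non-negative")
    if isinstance(fd_by_subject, dict):
        fd_by_subject = pd.DataFrame(fd_by_subject)
    kept, excluded = [], []
    for sub in fd_by_subject.columns:
        fd = fd_by_subject[sub].dropna().to_numpy(dtype=float)
        if fd.size == 0:
            raise ValueError(f"empty FD series for {sub}")
        prop = np.mean(fd > threshold_mm)
        (excluded if prop > frac else kept).append(sub)
    return kept, excluded


def validate_confounds(confounds: pd.DataFrame, n_frames: int) -> pd.DataFrame:
    """Check the 23-column nuisance set and its row count."""
    missing = set(CONFOUND_COLUMNS) - set(confounds.columns)
    if missing:
        raise ValueError(f"confounds missing columns: {sorted(missing)}")
    if len(confounds) != n_frames:
        raise ValueError(
            f"confounds have {len(confounds)} rows, expected {n_frames}"
        )
    return confounds[list(CONFOUND_COLUMNS)]


def regress_nuisance(
    ts: SubjectTimeSeries, confounds: pd.DataFrame
) -> SubjectTimeSeries:
    """Per-voxel OLS residuals on the nuisance design.

    The design is the 23 confound columns plus an intercept; if a constant
    column is already present (the order-0 polynomial trend) it serves as
    the intercept rather than being duplicated.  Raises on rank
    deficiency, naming the dependent columns.
    """
    conf = validate_confounds(confounds, ts.n_frames)
    X = conf.to_numpy(dtype=float)
    names = list(conf.columns)
    has_const = np.any(np.ptp(X, axis=0) == 0)
    if not has_const:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        dep, base = [], np.empty((X.shape[0], 0))
        for j, name in enumerate(names):
            cand = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                dep.append(name)
            else:
                base = cand
        raise ValueError(f"rank-deficient confounds; dependent: {dep}")
    # residual-maker via QR: r = y - Q Q' y
    Q, _ = np.linalg.qr(X)
    Y = ts.data.T  # frames x voxels
    resid = Y - Q @ (Q.T @ Y)
    return replace(ts, data=resid.T)


def _dct_basis(n_frames: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift basis: components with frequency below cutoff
    (frequency of order k is k / (2 n TR)), plus the constant."""
    k_max = int(np.floor(2 * n_frames * tr_s * cutoff_hz))
    t = np.arange(n_frames)
    cols = [np.ones(n_frames)]
    for k in range(1, k_max + 1):
        cols.append(np.cos(np.pi * k * (2 * t + 1) / (2 * n_frames)))
    return np.column_stack(cols)


def highpass(
    ts: SubjectTimeSeries, cutoff_hz: float = 0.01
) -> SubjectTimeSeries:
    """High-pass filter by regressing out a discrete-cosine drift basis
    spanning periods longer than 1/cutoff; removes the mean (DC)."""
    nyquist = 1.0 / (2.0 * ts.tr_s)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist:.3f} Hz")
    B = _dct_basis(ts.n_frames, ts.tr_s, cutoff_hz)
    Q, _ = np.linalg.qr(B)
    Y = ts.data.T
    resid = Y - Q @ (Q.T @ Y)
    return replace(ts, data=resid.T)


def statement_frames(
    schedule: pd.DataFrame, n_frames: int, tr_s: float
) -> list[tuple[np.ndarray, str]]:
    """Frame indices per statement: frames whose midpoints fall inside
    [onset, onset + duration)."""
    sched = validate_schedule(schedule)
    mid = (np.arange(n_frames) + 0.5) * tr_s
    windows = []
    for _, row in sched.iterrows():
        sel = np.nonzero(
            (mid >= row["onset_s"]) & (mid < row["onset_s"] + row["duration_s"])
        )[0]
        windows.append((sel, str(row["type"])))
    return windows


def extract_and_concatenate(
    ts: SubjectTimeSeries, schedule: pd.DataFrame
) -> SubjectTimeSeries:
    """Keep only statement frames, z-score each statement window per voxel,
    concatenate windows in schedule order.

    Z-scoring uses the sample (ddof=1) standard deviation; a zero-SD voxel
    within a window becomes zeros.  Raises if any statement covers fewer
    than 2 frames.  The result's ``frame_types`` labels each output frame
    with its statement's narrative type.
    """
    windows = statement_frames(schedule, ts.n_frames, ts.tr_s)
    chunks, types = [], []
    for i, (sel, stype) in enumerate(windows):
        if sel.size < 2:
            raise ValueError(f"statement {i} covers fewer than 2 frames")
        block = ts.data[:, sel]
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (block - mean) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = 0.0
        chunks.append(z)
        types.extend([stype] * sel.size)
    out = np.concatenate(chunks, axis=1)
    if not np.isfinite(out).all():
        raise ValueError("non-finite values after preparation")
    return replace(ts, data=out, frame_types=np.array(types))
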
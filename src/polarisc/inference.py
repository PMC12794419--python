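"""Nonparametric inference for per-subject voxel maps.

Implements the one-sample sign-flip permutation test and the two-stage
adaptive FDR step-up procedure of Benjamini, Krieger & Yekutieli (BKY).
Both operate on a subject x voxel matrix of per-subject statistics
(typically the within-minus-between ISC difference).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PermutationResult",
    "FDRResult",
    "InferenceReport",
    "signflip_permutation",
    "bky_fdr",
    "run_inference",
]


@dataclass
class PermutationResult:
    """Observed one-sample t per voxel and its permutation p-value.

    ``p`` is one-sided: the probability, under random sign flips of the
    per-subject values, of a null t at least as positive as the observed t.
    Voxels whose values are all exactly zero are undefined and carry NaN.
    """

    t_obs: np.ndarray
    p: np.ndarray
    n_permutations: int
    seed: int | None
    scheme: str
    valid: np.ndarray = field(repr=False, default=None)


@dataclass
class FDRResult:
    """Adaptive (BKY two-stage) FDR-adjusted q-values and rejection mask."""

    q: np.ndarray
    mask: np.ndarray
    n_true_nulls: int
    q_level: float


@dataclass
class InferenceReport:
    permutation: PermutationResult
    fdr: FDRResult


def _flip_ts(values: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """t-statistics for every sign-flip vector at once.

    Exploits that sum of squares is flip-invariant, so only the flipped
    means need recomputing: a (n_flips x n_subj) @ (n_subj x n_vox) matmul.
    """
    n = values.shape[0]
    sumsq = np.sum(values**2, axis=0)  # (V,)
    means = (flips @ values) / n  # (F, V)
    var = (sumsq[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
        t = np.where(var == 0, np.sign(means) * np.inf, t)
        t = np.where((var == 0) & (means == 0), np.nan, t)
    return t


def signflip_permutation(
    values: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive_max: int = 12,
) -> PermutationResult:
    """One-sample sign-flip permutation test across subjects, per voxel.

    The observed statistic is the one-sample t of the per-subject values
    against zero.  Each permutation draws one random +/-1 vector over
    subjects (each subject flipped independently with probability 1/2),
    applied to all voxels simultaneously so the spatial dependence of the
    null is preserved.  The one-sided p-value uses the add-one estimator
    ``(1 + #{t_null >= t_obs}) / (1 + n_perm)``; ties count toward the
    numerator.  With ``n_subjects <= exhaustive_max`` all 2^n flip vectors
    are enumerated instead and the p-value is the exact null proportion
    (the identity flip guarantees p > 0).

    Parameters
    ----------
    values : (n_subjects, n_voxels) array
        Per-subject statistic maps; non-finite entries mask the voxel.
    n_perm : int
        Number of random flip vectors (ignored under exhaustive
        enumeration).
    seed : int, optional
        Seed for the flip draws; fixed seed gives an identical p map.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_subj, n_vox = values.shape
    if n_subj < 3:
        raise ValueError("sign-flip permutation needs at least 3 subjects")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is very small; p-values will be coarse",
            stacklevel=2,
        )

    finite = np.isfinite(values).all(axis=0)
    nonzero = np.any(values != 0, axis=0)
    valid = finite & nonzero

    t_obs = np.full(n_vox, np.nan)
    p = np.full(n_vox, np.nan)
    if valid.any():
        v = values[:, valid]
        if n_subj <= exhaustive_max:
            # identity is the first flip vector; taking the observed t
            # from that row of the null guarantees an exact tie (p > 0)
            flips = np.array(
                list(itertools.product((1.0, -1.0), repeat=n_subj))
            )
            t_null = _flip_ts(v, flips)
            t_v = t_null[0]
            p_v = np.mean(t_null >= t_v[None, :], axis=0)
            scheme = f"exhaustive 2^{n_subj} sign flips"
            n_used = flips.shape[0]
        else:
            t_v = _flip_ts(v, np.ones((1, n_subj)))[0]
            rng = np.random.default_rng(seed)
            flips = rng.choice([1.0, -1.0], size=(n_perm, n_subj))
            t_null = _flip_ts(v, flips)
            p_v = (1 + np.sum(t_null >= t_v[None, :], axis=0)) / (1 + n_perm)
            scheme = f"{n_perm} random iid sign flips, add-one p"
            n_used = n_perm
        t_obs[valid] = t_v
        p[valid] = p_v
    else:
        scheme = "no valid voxels"
        n_used = 0

    return PermutationResult(
        t_obs=t_obs, p=p, n_permutations=n_used, seed=seed, scheme=scheme,
        valid=valid,
    )


def _bh_reject(p_sorted: np.ndarray, alpha: float) -> int:
    """Number of rejections of the BH linear step-up on sorted p-values."""
    m = p_sorted.size
    crit = alpha * np.arange(1, m + 1) / m
    below = np.nonzero(p_sorted <= crit)[0]
    return 0 if below.size == 0 else int(below[-1]) + 1


def bky_fdr(p_values: np.ndarray, q_level: float = 0.05) -> FDRResult:
    """Two-stage adaptive FDR control (Benjamini, Krieger & Yekutieli).

    Stage 1 runs the BH linear step-up at level ``q' = q/(1+q)``; the
    number of non-rejections estimates the number of true nulls m0.
    Stage 2 re-runs the step-up at the adapted level ``q' * m / m0``.
    Reported q-values are the BH-adjusted p-values rescaled by
    ``(m0/m)(1+q)`` (clipped at 1), so the rejection mask is ``q <= q_level``;
    they are specific to the given ``q_level``, as for any adaptive
    procedure.  NaN p-values are passed through and never rejected.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValueError("empty p-value array")
    flat = p_values.ravel()
    finite = np.isfinite(flat)
    p = flat[finite]
    if p.size and (np.any(p <= 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in (0, 1]")

    q = np.full(flat.shape, np.nan)
    mask = np.zeros(flat.shape, dtype=bool)
    m = p.size
    m0 = m
    if m > 0:
        order = np.argsort(p, kind="stable")
        p_sorted = p[order]
        alpha1 = q_level / (1.0 + q_level)
        r1 = _bh_reject(p_sorted, alpha1)

        # BH-adjusted p-values (step-up monotonized)
        ranks = np.arange(1, m + 1)
        adj = np.minimum.accumulate((p_sorted * m / ranks)[::-1])[::-1]

        if r1 == 0 or r1 == m:
            m0 = m - r1
            q_sorted = np.minimum(adj * (1.0 + q_level), 1.0)
            reject_sorted = np.zeros(m, bool) if r1 == 0 else np.ones(m, bool)
        else:
            m0 = m - r1
            alpha2 = alpha1 * m / m0
            r2 = _bh_reject(p_sorted, alpha2)
            q_sorted = np.minimum(adj * (m0 / m) * (1.0 + q_level), 1.0)
            reject_sorted = np.zeros(m, dtype=bool)
            reject_sorted[:r2] = True
            m0 = m - r2
        q_unsorted = np.empty(m)
        q_unsorted[order] = q_sorted
        rej_unsorted = np.empty(m, dtype=bool)
        rej_unsorted[order] = reject_sorted
        q[finite] = q_unsorted
        mask[finite] = rej_unsorted

    return FDRResult(
        q=q.reshape(p_values.shape),
        mask=mask.reshape(p_values.shape),
        n_true_nulls=int(m0),
        q_level=q_level,
    )


def run_inference(
    maps,
    n_perm: int = 10_000,
    seed: int | None = None,
    q_level: float = 0.05,
) -> InferenceReport:
    """Permutation test + BKY FDR on per-subject difference maps.

    ``maps`` may be a PolarizationMaps (its ``diff`` matrix is tested), an
    ISCMap (its per-subject R matrix, for the "average R > 0" test), or a
    bare subject x voxel array.
    """
    values = getattr(maps, "diff", None)
    if values is None:
        values = getattr(maps, "subject_r", None)
    if values is None:
        values = maps
    perm = signflip_permutation(np.asarray(values), n_perm=n_perm, seed=seed)
    fdr = bky_fdr(perm.p, q_level=q_level)
    return InferenceReport(permutation=perm, fdr=fdr)
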
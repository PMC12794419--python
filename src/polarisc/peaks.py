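"""Peak extraction and peak-level statistics for polarization maps.

Peaks are local maxima (26-connectivity) of the cohort-average
within-minus-between difference inside the FDR-significant mask, with
nearby maxima merged keeping the larger difference.  Subjects are scored
at the peak voxel itself; group tests reproduce the reporting pattern of
a 20/20 design: one-sample df n-1, two-sample df n1+n2-2, pooled
cross-peak df n_A+n_B-2, mixed-ANOVA interaction df (1, n-2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .behavioral import LESS, MORE, cohens_d_from_t
from .inference import bky_fdr
from .isc import PolarizationMaps
from .prep import VoxelGrid

__all__ = [
    "extract_peaks",
    "score_peaks",
    "peak_level_tests",
    "pooled_peak_contrast",
    "cross_narrative_contrast",
    "interaction_anova",
    "between_group_sign_comparison",
    "correlate_peaks_with_behavior",
]


def extract_peaks(
    average_diff: np.ndarray,
    significance_mask: np.ndarray,
    grid: VoxelGrid,
    min_distance_mm: float = 10.0,
    p_values: np.ndarray | None = None,
    source: str = "all",
) -> pd.DataFrame:
    """Local maxima of the average difference within the significant mask.

    Returns a table with voxel and mm coordinates, the average difference
    d at the peak, its permutation p (if given) and the narrative source.
    An empty mask yields an empty table; an all-flat map inside a
    non-empty mask is an error.
    """
    average_diff = np.asarray(average_diff, dtype=float)
    significance_mask = np.asarray(significance_mask, dtype=bool)
    cols = ["peak_id", "i", "j", "k", "x_mm", "y_mm", "z_mm", "d", "p", "source"]
    if not significance_mask.any():
        return pd.DataFrame(columns=cols)
    sig_vals = average_diff[significance_mask]
    if np.ptp(sig_vals[np.isfinite(sig_vals)]) == 0:
        raise ValueError("all-flat map inside the mask: peaks undefined")

    vol = grid.to_volume(np.where(np.isfinite(average_diff), average_diff, -np.inf),
                         fill=-np.inf)
    sig_vol = grid.to_volume(significance_mask.astype(float), fill=0.0) > 0
    local_max = (
        ndimage.maximum_filter(vol, footprint=np.ones((3, 3, 3))) == vol
    ) & sig_vol & np.isfinite(vol)
    cand_ijk = np.argwhere(local_max)
    cand_d = vol[local_max]
    order = np.argsort(-cand_d, kind="stable")
    cand_ijk, cand_d = cand_ijk[order], cand_d[order]
    cand_mm = grid.mm(cand_ijk)

    kept: list[int] = []
    for c in range(len(cand_d)):
        if all(
            np.linalg.norm(cand_mm[c] - cand_mm[k]) >= min_distance_mm
            for k in kept
        ):
            kept.append(c)

    lin = grid.linear_index()
    rows = []
    for pid, c in enumerate(kept):
        ijk = tuple(int(v) for v in cand_ijk[c])
        v = lin[ijk]
        rows.append(
            dict(peak_id=pid, i=ijk[0], j=ijk[1], k=ijk[2],
                 x_mm=cand_mm[c][0], y_mm=cand_mm[c][1], z_mm=cand_mm[c][2],
                 d=float(cand_d[c]),
                 p=float(p_values[v]) if p_values is not None else np.nan,
                 source=source)
        )
    return pd.DataFrame(rows, columns=cols)


def score_peaks(
    maps: PolarizationMaps,
    peaks: pd.DataFrame,
    assignment: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-subject within/between/diff values at each peak voxel.

    Long table: subject_id, group, peak_id, within_r, between_r, diff.
    """
    if maps.grid is None:
        raise ValueError("maps carry no voxel grid")
    lin = maps.grid.linear_index()
    groups = (
        assignment.set_index("subject_id")["group"].loc[maps.subject_ids].to_numpy()
        if assignment is not None
        else maps.groups
    )
    rows = []
    for _, pk in peaks.iterrows():
        key = (int(pk["i"]), int(pk["j"]), int(pk["k"]))
        if key not in lin:
            raise ValueError(f"peak {key} outside the analysis mask")
        v = lin[key]
        for s, sid in enumerate(maps.subject_ids):
            rows.append(
                dict(subject_id=sid, group=groups[s], peak_id=int(pk["peak_id"]),
                     within_r=maps.within_r[s, v],
                     between_r=maps.between_r[s, v],
                     diff=maps.within_r[s, v] - maps.between_r[s, v])
            )
    return pd.DataFrame(rows)


def _pooled_two_sample(x: np.ndarray, y: np.ndarray):
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), len(x) + len(y) - 2, float(res.pvalue)


def peak_level_tests(scores: pd.DataFrame) -> pd.DataFrame:
    """Per peak: one-sample t of the diff within each group separately
    (df n-1) and the pooled two-sample group contrast (df n1+n2-2) with
    Cohen's d."""
    rows = []
    for pid, sub in scores.groupby("peak_id"):
        more = sub.loc[sub["group"] == MORE, "diff"].to_numpy()
        less = sub.loc[sub["group"] == LESS, "diff"].to_numpy()
        if min(len(more), len(less)) < 2:
            raise ValueError("both groups need at least 2 subjects")
        row = {"peak_id": pid}
        for label, vals in (("more", more), ("less", less)):
            if np.ptp(vals) == 0 and vals[0] != 0:
                raise ValueError(f"zero variance in group {label}")
            t1 = stats.ttest_1samp(vals, 0.0)
            row[f"{label}_mean"] = float(vals.mean())
            row[f"{label}_t"] = float(t1.statistic) if np.ptp(vals) else 0.0
            row[f"{label}_df"] = len(vals) - 1
            row[f"{label}_p"] = float(t1.pvalue) if np.ptp(vals) else 1.0
        t, df, p = _pooled_two_sample(more, less)
        row.update(
            group_t=t, group_df=df, group_p=p,
            cohens_d=cohens_d_from_t(t, len(more), len(less)),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_peak_contrast(
    scores: pd.DataFrame, peak_ids: list[int] | None = None
) -> dict:
    """Pool each subject's diff over a peak set (mean over peaks), then
    contrast the groups: pooled-variance t, Cohen's d, and t-based 95% CI
    of each group mean."""
    sub = scores if peak_ids is None else scores[scores["peak_id"].isin(peak_ids)]
    if sub.empty:
        raise ValueError("empty peak set")
    pooled = (
        sub.groupby(["subject_id", "group"], sort=True)["diff"].mean().reset_index()
    )
    more = pooled.loc[pooled["group"] == MORE, "diff"].to_numpy()
    less = pooled.loc[pooled["group"] == LESS, "diff"].to_numpy()
    t, df, p = _pooled_two_sample(more, less)
    out = {
        "t": t, "df": df, "p": p,
        "cohens_d": cohens_d_from_t(t, len(more), len(less)),
        "pooled_by_subject": pooled,
    }
    for label, vals in (("more", more), ("less", less)):
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        tcrit = stats.t.ppf(0.975, len(vals) - 1)
        out[f"{label}_mean"] = float(vals.mean())
        out[f"{label}_ci95"] = (
            float(vals.mean() - tcrit * sem), float(vals.mean() + tcrit * sem)
        )
    return out


def cross_narrative_contrast(
    scores_pro: pd.DataFrame,
    scores_anti: pd.DataFrame,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Paired t per peak (df n-1) comparing each subject's diff under
    pro-narrative frames vs anti-narrative frames, BKY q over the peak
    family."""
    key = ["peak_id", "subject_id"]
    merged = scores_pro.merge(
        scores_anti, on=key, suffixes=("_pro", "_anti"), validate="one_to_one"
    )
    if len(merged) != len(scores_pro) or len(merged) != len(scores_anti):
        raise ValueError("subject/peak mismatch between the two scorings")
    rows = []
    for pid, sub in merged.groupby("peak_id"):
        a = sub["diff_pro"].to_numpy()
        b = sub["diff_anti"].to_numpy()
        if np.ptp(a - b) == 0:
            t, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(dict(peak_id=pid, t=t, df=len(a) - 1, p=p,
                         mean_pro=float(a.mean()), mean_anti=float(b.mean())))
    out = pd.DataFrame(rows)
    out["q"] = bky_fdr(np.clip(out["p"].to_numpy(), 1e-300, 1.0),
                       q_level=q_level).q
    return out


def interaction_anova(
    diffs: pd.DataFrame, assignment: pd.DataFrame
) -> dict:
    """Mixed-design 2x2 interaction: group (between) x narrative content
    (within, columns 'pro' and 'anti' of ``diffs``, indexed by subject).

    Classical sums-of-squares decomposition; with a two-level within
    factor the interaction F has df (1, n-2).
    """
    for col in ("pro", "anti"):
        if col not in diffs.columns:
            raise ValueError("diffs needs 'pro' and 'anti' columns")
    groups = assignment.set_index("subject_id")["group"].loc[diffs.index]
    if diffs.isna().any().any():
        raise ValueError("missing cells in the 2x2 layout")
    y = diffs[["pro", "anti"]].to_numpy(dtype=float)
    g = groups.to_numpy()
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("need exactly two groups")
    n = len(y)
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    cond_mean = y.mean(axis=0)
    # interaction SS: cell means vs additive group + condition effects
    ss_inter = 0.0
    resid = np.empty_like(y)
    for lab in labels:
        sel = g == lab
        ng = int(sel.sum())
        gmean = y[sel].mean()
        for c in range(2):
            cell = y[sel, c].mean()
            ss_inter += ng * (cell - gmean - cond_mean[c] + grand) ** 2
            # condition-by-subject residual within group
            resid[sel, c] = y[sel, c] - subj_mean[sel] - cell + gmean
    ss_err = float((resid**2).sum())
    df1, df2 = 1, n - 2
    f = (ss_inter / df1) / (ss_err / df2)
    p = float(stats.f.sf(f, df1, df2))
    return {"F": float(f), "df": (df1, df2), "p": p}


def between_group_sign_comparison(
    between_a: np.ndarray, between_b: np.ndarray
) -> dict:
    """Pooled two-sample t comparing per-subject between-group R at one
    peak (or peak average) against another peak set, all subjects pooled
    (df n_A + n_B - 2)."""
    a = np.asarray(between_a, dtype=float)
    b = np.asarray(between_b, dtype=float)
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValueError("zero variance")
    t, df, p = _pooled_two_sample(a, b)
    return {"t": t, "df": df, "p": p,
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}


def correlate_peaks_with_behavior(
    peak_scores: pd.DataFrame,
    behavior: pd.DataFrame,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Pearson and Spearman correlations between per-subject peak scores
    and behavioral measures; BKY q (on the Pearson p) over the family,
    uncorrected p reported alongside.

    Both inputs are wide, indexed by subject_id.
    """
    common = peak_scores.index.intersection(behavior.index)
    if len(common) < 3:
        raise ValueError("need at least 3 subjects in common")
    rows = []
    for score_col in peak_scores.columns:
        x = peak_scores.loc[common, score_col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"zero variance in {score_col!r}")
        for meas in behavior.columns:
            yv = behavior.loc[common, meas].to_numpy(dtype=float)
            if np.ptp(yv) == 0:
                raise ValueError(f"zero variance in {meas!r}")
            pr, pp = stats.pearsonr(x, yv)
            sr, sp = stats.spearmanr(x, yv)
            rows.append(
                dict(score=score_col, measure=meas,
                     pearson_r=float(pr), pearson_p=float(pp),
                     spearman_rho=float(sr), spearman_p=float(sp))
            )
    out = pd.DataFrame(rows)
    out["q"] = bky_fdr(np.clip(out["pearson_p"].to_numpy(), 1e-300, 1.0),
                       q_level=q_level).q
    return out
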
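"""Behavioral scoring and statistics for the attitude-polarization design.

Covers the Immigration Attitude Score (IAS = mean agreement with
pro-immigration statements minus mean agreement with anti-immigration
statements, range -4..+4), the median split into more/less supportive
groups, Likert scale scoring with reverse-coded items, Cronbach's alpha,
group comparisons with Cohen's d and adaptive FDR, correlations with the
IAS, an OLS linkage model, and minimal-detectable-effect power utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.power import TTestIndPower, TTestPower

from .inference import bky_fdr

__all__ = [
    "ScaleDefinition",
    "validate_ratings",
    "compute_ias",
    "median_split",
    "score_scale",
    "cronbach_alpha",
    "cohens_d_from_t",
    "compare_groups_on_scales",
    "minimal_detectable_effect",
    "correlate_with_ias",
    "regress_ias_on_scales",
]

RATING_MIN, RATING_MAX = 1, 5
MORE, LESS = "more_supportive", "less_supportive"


@dataclass(frozen=True)
class ScaleDefinition:
    """A multi-item Likert scale: items, reverse-coded subset, bounds."""

    scale_name: str
    item_ids: tuple[str, ...]
    reverse_items: tuple[str, ...] = ()
    range_min: int = 1
    range_max: int = 7

    def __post_init__(self):
        if not set(self.reverse_items) <= set(self.item_ids):
            raise ValueError(
                f"{self.scale_name}: reverse_items must be a subset of item_ids"
            )
        if self.range_min >= self.range_max:
            raise ValueError(f"{self.scale_name}: need range_min < range_max")


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format ratings table (subject_id, statement_id,
    statement_type, rating): complete design, ratings in 1..5."""
    required = {"subject_id", "statement_id", "statement_type", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    if not ratings["rating"].between(RATING_MIN, RATING_MAX).all():
        raise ValueError("ratings outside the 1-5 scale")
    if not set(ratings["statement_type"]) <= {"pro", "anti"}:
        raise ValueError("statement_type must be 'pro' or 'anti'")
    counts = ratings.groupby("subject_id")["statement_id"].nunique()
    per_sub = ratings.groupby("subject_id").size()
    if counts.nunique() != 1 or not (counts == per_sub).all():
        raise ValueError("every subject must rate every statement exactly once")
    return ratings


def compute_ias(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-subject IAS = mean pro rating - mean anti rating.

    Returns a frame with columns subject_id, mean_pro, mean_anti, ias
    (ias is bounded in [-4, 4] by the 1-5 rating range).
    """
    validate_ratings(ratings)
    means = (
        ratings.pivot_table(
            index="subject_id", columns="statement_type", values="rating",
            aggfunc="mean",
        )
        .rename(columns={"pro": "mean_pro", "anti": "mean_anti"})
        .reset_index()
    )
    if {"mean_pro", "mean_anti"} - set(means.columns):
        raise ValueError("each subject needs both pro and anti ratings")
    means["ias"] = means["mean_pro"] - means["mean_anti"]
    return means[["subject_id", "mean_pro", "mean_anti", "ias"]]


def median_split(scores: pd.DataFrame) -> pd.DataFrame:
    """Split subjects at the median IAS into less/more supportive groups.

    Subjects strictly above the median are more supportive, strictly below
    less supportive.  Ties at the median are filled deterministically in
    ascending (ias, subject_id) order so group sizes are floor(n/2) and
    ceil(n/2); every more-supportive IAS is >= every less-supportive IAS.
    """
    if len(scores) < 2:
        raise ValueError("median split needs at least 2 subjects")
    ias = scores["ias"].to_numpy(dtype=float)
    if np.ptp(ias) == 0:
        raise ValueError("all IAS values identical: median split undefined")
    split_value = float(np.median(ias))
    order = scores.sort_values(
        ["ias", "subject_id"], kind="stable"
    ).reset_index(drop=True)
    n_less = len(order) // 2
    group = np.where(np.arange(len(order)) < n_less, LESS, MORE)
    out = order[["subject_id", "ias"]].copy()
    out["group"] = group
    out["split_value"] = split_value
    return out.sort_values("subject_id").reset_index(drop=True)


def _apply_reversals(
    responses: pd.DataFrame, definition: ScaleDefinition
) -> pd.DataFrame:
    items = list(definition.item_ids)
    missing = set(items) - set(responses.columns)
    if missing:
        raise ValueError(f"missing items: {sorted(missing)}")
    sub = responses[items].astype(float)
    lo, hi = definition.range_min, definition.range_max
    if ((sub < lo) | (sub > hi)).any().any():
        raise ValueError(f"responses outside bounds [{lo}, {hi}]")
    for item in definition.reverse_items:
        sub[item] = lo + hi - sub[item]
    return sub


def score_scale(
    responses: pd.DataFrame, definition: ScaleDefinition
) -> pd.Series:
    """Mean over scale items after reflecting reverse-coded ones
    (v -> range_min + range_max - v).  ``responses`` is wide:
    subject rows x item columns."""
    scored = _apply_reversals(responses, definition)
    out = scored.mean(axis=1)
    out.name = definition.scale_name
    return out


def cronbach_alpha(
    responses: pd.DataFrame, definition: ScaleDefinition
) -> float:
    """Cronbach's alpha: (k/(k-1)) (1 - sum item variances / variance of sum),
    sample (ddof=1) variances, reversals applied first."""
    scored = _apply_reversals(responses, definition)
    k = scored.shape[1]
    if k < 2 or scored.shape[0] < 2:
        raise ValueError("alpha needs >=2 items and >=2 subjects")
    item_var = scored.var(axis=0, ddof=1).sum()
    total_var = scored.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of the item sum")
    return float(k / (k - 1) * (1 - item_var / total_var))


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Two-sample Cohen's d recovered from t: d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Student (pooled-variance) two-sample t, df, two-sided p."""
    res = stats.ttest_ind(x, y, equal_var=True)
    df = len(x) + len(y) - 2
    return float(res.statistic), df, float(res.pvalue)


def compare_groups_on_scales(
    scores_by_scale: pd.DataFrame,
    assignment: pd.DataFrame,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Pooled-variance two-sample t per scale (more minus less supportive),
    Cohen's d from t, BKY q over the scale family.

    ``scores_by_scale``: subject_id index, one column per scale.
    """
    groups = assignment.set_index("subject_id")["group"]
    aligned = scores_by_scale.loc[groups.index]
    g_more = aligned[groups == MORE]
    g_less = aligned[groups == LESS]
    n1, n2 = len(g_more), len(g_less)
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for scale in scores_by_scale.columns:
        x, y = g_more[scale].to_numpy(), g_less[scale].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            raise ValueError(f"zero pooled variance on scale {scale!r}")
        t, df, p = _pooled_t(x, y)
        d = cohens_d_from_t(t, n1, n2)
        tcrit = stats.t.ppf(0.975, df)
        diff = np.mean(x) - np.mean(y)
        sem = np.sqrt(
            ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1))
            / df * (1 / n1 + 1 / n2)
        )
        rows.append(
            dict(scale=scale, t=t, df=df, p=p, cohens_d=d,
                 mean_more=np.mean(x), mean_less=np.mean(y),
                 ci95_low=diff - tcrit * sem, ci95_high=diff + tcrit * sem)
        )
    out = pd.DataFrame(rows)
    out["q"] = bky_fdr(np.clip(out["p"].to_numpy(), 1e-300, 1.0),
                       q_level=q_level).q
    return out


def minimal_detectable_effect(
    n1: int,
    n2: int | None = None,
    alpha: float = 0.05,
    power: float = 0.80,
    design: str = "one_sample",
) -> float:
    """Smallest Cohen's d reaching the target power for a two-sided t-test,
    solved with exact noncentral-t power.

    design='one_sample' uses n1 observations; design='two_sample' uses
    independent groups of n1 and n2 (n2 defaults to n1).
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if power <= alpha:
        raise ValueError("infeasible: power must exceed alpha")
    if design == "one_sample":
        return float(
            TTestPower().solve_power(
                nobs=n1, alpha=alpha, power=power, alternative="two-sided"
            )
        )
    if design == "two_sample":
        n2 = n1 if n2 is None else n2
        return float(
            TTestIndPower().solve_power(
                nobs1=n1, ratio=n2 / n1, alpha=alpha, power=power,
                alternative="two-sided",
            )
        )
    raise ValueError(f"unknown design {design!r}")


def correlate_with_ias(
    scale_scores: pd.DataFrame,
    ias: pd.Series,
    method: str = "pearson",
    q_level: float = 0.05,
    fdr: bool = True,
) -> pd.DataFrame:
    """Correlate each scale score with the IAS; BKY q over the family.

    ``fdr=False`` reports uncorrected p only (used for the single
    political-inclination item, which the source design corrects
    separately).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    ias_aligned = ias.loc[scale_scores.index].to_numpy(dtype=float)
    if len(ias_aligned) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(ias_aligned) == 0:
        raise ValueError("zero variance in IAS")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for scale in scale_scores.columns:
        x = scale_scores[scale].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"zero variance in scale {scale!r}")
        r, p = corr(x, ias_aligned)
        rows.append(dict(scale=scale, method=method, r=float(r), p=float(p)))
    out = pd.DataFrame(rows)
    if fdr:
        out["q"] = bky_fdr(np.clip(out["p"].to_numpy(), 1e-300, 1.0),
                           q_level=q_level).q
    return out


def regress_ias_on_scales(
    scale_matrix: pd.DataFrame, ias: pd.Series
) -> dict:
    """OLS of IAS on the scale scores: overall F, df, adjusted R^2,
    coefficients.  Raises on rank-deficient designs, naming the collinear
    columns."""
    import statsmodels.api as sm

    X = scale_matrix.loc[ias.index].astype(float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need more subjects than predictors + 1")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify offending columns via incremental rank
        bad, cols = [], []
        base = np.ones((n, 1))
        for c in X.columns:
            cand = np.column_stack([base, X[c].to_numpy()])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(c)
            else:
                base = cand
                cols.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(ias.loc[X.index].to_numpy(dtype=float), design).fit()
    return {
        "f_stat": float(fit.fvalue),
        "df_model": int(fit.df_model),
        "df_resid": int(fit.df_resid),
        "p": float(fit.f_pvalue),
        "r2_adj": float(fit.rsquared_adj),
        "coefficients": dict(zip(design.columns, map(float, fit.params))),
    }
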
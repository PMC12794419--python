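"""Peak extraction geometry and peak-level statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polarisc import (
    Region,
    RunConfig,
    compute_ias,
    generate_cohort,
    grouped_isc,
    median_split,
    prepare_cohort,
    run_inference,
)
from polarisc.isc import PolarizationMaps
from polarisc.peaks import (
    between_group_sign_comparison,
    correlate_peaks_with_behavior,
    cross_narrative_contrast,
    extract_peaks,
    interaction_anova,
    peak_level_tests,
    pooled_peak_contrast,
    score_peaks,
)
from polarisc.prep import VoxelGrid
from conftest import tiny_simulation_config

MORE, LESS = "more_supportive", "less_supportive"


def full_grid(shape, vox=3.0):
    aff = np.diag([vox, vox, vox, 1.0])
    ijk = np.indices(shape).reshape(3, -1).T
    return VoxelGrid(shape=shape, affine=aff, ijk=ijk)


def blob(shape, center, width=1.5, height=1.0):
    coords = np.indices(shape).reshape(3, -1).T.astype(float)
    d = np.linalg.norm(coords - np.asarray(center, float), axis=1)
    return height * np.exp(-(d**2) / (2 * width**2))


class TestExtractPeaks:
    def test_single_blob_single_peak_at_center(self):
        shape = (10, 10, 10)
        vals = blob(shape, (4, 5, 6))
        mask = vals > 0.1
        out = extract_peaks(vals, mask, full_grid(shape))
        assert len(out) == 1
        assert (out.loc[0, ["i", "j", "k"]].tolist()) == [4, 5, 6]
        assert out.loc[0, "d"] == pytest.approx(1.0)
        assert out.loc[0, ["x_mm", "y_mm", "z_mm"]].tolist() == [12, 15, 18]

    def test_two_blobs_30mm_apart_two_peaks(self):
        shape = (6, 6, 16)
        vals = blob(shape, (2, 2, 2)) + 0.8 * blob(shape, (2, 2, 12))
        mask = vals > 0.05
        out = extract_peaks(vals, mask, full_grid(shape))
        assert len(out) == 2
        assert set(out["k"]) == {2, 12}

    def test_nearby_maxima_merged_keeping_larger(self):
        shape = (8, 8, 8)
        vals = blob(shape, (3, 3, 3), width=0.8) + \
            0.9 * blob(shape, (3, 3, 5), width=0.8)
        mask = vals > 0.01
        out = extract_peaks(vals, mask, full_grid(shape), min_distance_mm=10)
        assert len(out) == 1
        assert out.loc[0, "k"] == 3  # the larger of the two survives

    def test_empty_mask_empty_table(self):
        shape = (5, 5, 5)
        out = extract_peaks(np.zeros(125), np.zeros(125, bool),
                            full_grid(shape))
        assert len(out) == 0

    def test_flat_map_in_mask_rejected(self):
        shape = (5, 5, 5)
        with pytest.raises(ValueError, match="flat"):
            extract_peaks(np.ones(125), np.ones(125, bool), full_grid(shape))

    def test_translation_equivariance_through_affine(self):
        shape = (12, 12, 12)
        g = full_grid(shape)
        a = blob(shape, (4, 4, 4))
        b = blob(shape, (5, 4, 6))
        pa = extract_peaks(a, a > 0.1, g)
        pb = extract_peaks(b, b > 0.1, g)
        shift = pb.loc[0, ["x_mm", "y_mm", "z_mm"]].to_numpy() - \
            pa.loc[0, ["x_mm", "y_mm", "z_mm"]].to_numpy()
        assert shift.tolist() == [3.0, 0.0, 6.0]

    def test_peak_found_at_planted_region_center(self):
        """End-to-end: a single planted sphere yields one peak within a
        voxel of its center."""
        cfg = tiny_simulation_config(
            grid_shape=(8, 8, 8),
            polarized_region_spec=(Region((5, 3, 5), 2.0, "both"),),
            common_region_spec=(),
            seed=5,
        )
        cohort = generate_cohort(cfg)
        rc = RunConfig(simulation=cfg, n_perm=500, seed=1)
        prepared, _, _ = prepare_cohort(cohort, rc)
        assignment = median_split(compute_ias(cohort.ratings))
        maps = grouped_isc(prepared, assignment)
        rep = run_inference(maps, n_perm=500, seed=1)
        assert rep.fdr.mask.any()
        out = extract_peaks(maps.average_diff, rep.fdr.mask,
                            prepared[0].grid)
        assert len(out) >= 1
        top = out.iloc[0]
        assert abs(top["i"] - 5) <= 1 and abs(top["j"] - 3) <= 1 \
            and abs(top["k"] - 5) <= 1


def toy_maps(n_per_group=4, n_vox=8, seed=0):
    g = np.random.default_rng(seed)
    n = 2 * n_per_group
    ids = [f"s{i:02d}" for i in range(n)]
    groups = np.array([MORE] * n_per_group + [LESS] * n_per_group)
    within = g.uniform(-0.2, 0.8, size=(n, n_vox))
    between = g.uniform(-0.2, 0.8, size=(n, n_vox))
    grid = full_grid((n_vox, 1, 1))
    return PolarizationMaps(subject_ids=ids, groups=groups,
                            within_r=within, between_r=between, grid=grid)


def toy_peaks(voxels):
    return pd.DataFrame([
        dict(peak_id=pid, i=v, j=0, k=0, x_mm=3.0 * v, y_mm=0.0, z_mm=0.0,
             d=0.1, p=0.01, source="all")
        for pid, v in enumerate(voxels)
    ])


class TestScorePeaks:
    def test_scores_read_single_voxel_values(self):
        maps = toy_maps()
        scores = score_peaks(maps, toy_peaks([2, 5]))
        row = scores[(scores.subject_id == "s01") & (scores.peak_id == 1)]
        assert row["within_r"].iloc[0] == maps.within_r[1, 5]
        assert row["diff"].iloc[0] == pytest.approx(
            maps.within_r[1, 5] - maps.between_r[1, 5]
        )

    def test_peak_outside_mask_rejected(self):
        maps = toy_maps()
        with pytest.raises(ValueError, match="outside"):
            score_peaks(maps, toy_peaks([99]))

    def test_constant_maps_zero_group_difference(self):
        maps = toy_maps()
        maps.within_r[:] = 0.5
        maps.between_r[:] = 0.3
        scores = score_peaks(maps, toy_peaks([0]))
        means = scores.groupby("group")["diff"].mean()
        assert means[MORE] == pytest.approx(0.2)
        assert means[MORE] - means[LESS] == pytest.approx(0.0)


class TestPeakLevelTests:
    def test_reporting_dfs_match_20_20_design(self):
        maps = toy_maps(n_per_group=20, seed=2)
        tests = peak_level_tests(score_peaks(maps, toy_peaks([0])))
        assert tests.loc[0, "more_df"] == 19
        assert tests.loc[0, "less_df"] == 19
        assert tests.loc[0, "group_df"] == 38

    def test_matches_hand_computed_t(self):
        maps = toy_maps(seed=3)
        scores = score_peaks(maps, toy_peaks([1]))
        tests = peak_level_tests(scores)
        more = scores.loc[scores.group == MORE, "diff"].to_numpy()
        t_hand = stats.ttest_1samp(more, 0.0).statistic
        assert tests.loc[0, "more_t"] == pytest.approx(t_hand)
        t2 = stats.ttest_ind(
            more, scores.loc[scores.group == LESS, "diff"], equal_var=True
        ).statistic
        assert tests.loc[0, "group_t"] == pytest.approx(t2)

    def test_symmetric_polarization_rarely_differs_between_groups(self):
        n_sig = 0
        for seed in range(30):
            maps = toy_maps(n_per_group=10, n_vox=1, seed=seed)
            # same planted shift for both groups
            maps.within_r += 0.3
            tests = peak_level_tests(score_peaks(maps, toy_peaks([0])))
            n_sig += tests.loc[0, "group_p"] < 0.05
        assert n_sig / 30 <= 0.10


class TestPooledContrast:
    def test_single_peak_pooling_is_identity(self):
        maps = toy_maps(seed=4)
        scores = score_peaks(maps, toy_peaks([3]))
        pooled = pooled_peak_contrast(scores)
        tests = peak_level_tests(scores)
        assert pooled["t"] == pytest.approx(tests.loc[0, "group_t"])
        assert pooled["df"] == tests.loc[0, "group_df"]

    def test_pooled_score_is_mean_over_peaks(self):
        maps = toy_maps(seed=5)
        scores = score_peaks(maps, toy_peaks([0, 4, 6]))
        pooled = pooled_peak_contrast(scores)
        by_subject = pooled["pooled_by_subject"].set_index("subject_id")
        manual = scores.groupby("subject_id")["diff"].mean()
        assert np.allclose(by_subject["diff"].sort_index(), manual.sort_index())

    def test_empty_peak_set_rejected(self):
        maps = toy_maps()
        scores = score_peaks(maps, toy_peaks([0]))
        with pytest.raises(ValueError, match="empty"):
            pooled_peak_contrast(scores, peak_ids=[42])


class TestCrossNarrative:
    def test_identical_scorings_give_zero_t(self):
        maps = toy_maps(seed=6)
        scores = score_peaks(maps, toy_peaks([0, 1]))
        out = cross_narrative_contrast(scores, scores.copy())
        assert (out["t"] == 0.0).all()

    def test_matches_paired_t_formula(self):
        a = toy_maps(seed=7)
        b = toy_maps(seed=8)
        sa = score_peaks(a, toy_peaks([2]))
        sb = score_peaks(b, toy_peaks([2]))
        out = cross_narrative_contrast(sa, sb)
        t_hand = stats.ttest_rel(sa["diff"], sb["diff"]).statistic
        assert out.loc[0, "t"] == pytest.approx(t_hand)
        assert out.loc[0, "df"] == len(sa) - 1

    def test_subject_mismatch_rejected(self):
        a = toy_maps(seed=9)
        sa = score_peaks(a, toy_peaks([0]))
        sb = sa.copy()
        sb["subject_id"] = sb["subject_id"].str.replace("s0", "x0")
        with pytest.raises(Exception):
            cross_narrative_contrast(sa, sb)


def assignment_for(ids, n_more):
    return pd.DataFrame({
        "subject_id": ids,
        "group": [MORE] * n_more + [LESS] * (len(ids) - n_more),
    })


class TestInteractionAnova:
    def test_matches_pingouin_mixed_anova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 20
        ids = [f"s{i:02d}" for i in range(n)]
        diffs = pd.DataFrame(
            {"pro": rng.normal(0.1, 0.2, n), "anti": rng.normal(0.2, 0.2, n)},
            index=ids,
        )
        assign = assignment_for(ids, 10)
        out = interaction_anova(diffs, assign)
        long = diffs.reset_index(names="subject_id").melt(
            id_vars="subject_id", var_name="content", value_name="y"
        ).merge(assign, on="subject_id")
        ref = pingouin.mixed_anova(long, dv="y", within="content",
                                   between="group", subject="subject_id")
        ref_f = ref.loc[ref["Source"] == "Interaction", "F"].iloc[0]
        assert out["F"] == pytest.approx(ref_f, rel=1e-10)
        assert out["df"] == (1, n - 2)

    def test_equals_squared_two_sample_t_on_differences(self, rng):
        n = 16
        ids = [f"s{i:02d}" for i in range(n)]
        diffs = pd.DataFrame(
            {"pro": rng.normal(size=n), "anti": rng.normal(size=n)}, index=ids
        )
        assign = assignment_for(ids, 8)
        out = interaction_anova(diffs, assign)
        d = diffs["pro"] - diffs["anti"]
        groups = assign.set_index("subject_id")["group"].loc[ids]
        t = stats.ttest_ind(d[groups == MORE], d[groups == LESS],
                            equal_var=True).statistic
        assert out["F"] == pytest.approx(t**2, rel=1e-10)

    def test_crossed_effect_detected(self):
        n_sig = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            n = 20
            ids = [f"s{i:02d}" for i in range(n)]
            pro = np.r_[g.normal(0.4, 0.2, 10), g.normal(0.0, 0.2, 10)]
            anti = np.r_[g.normal(0.0, 0.2, 10), g.normal(0.4, 0.2, 10)]
            diffs = pd.DataFrame({"pro": pro, "anti": anti}, index=ids)
            out = interaction_anova(diffs, assignment_for(ids, 10))
            n_sig += out["p"] < 0.05
        assert n_sig / 20 >= 0.90

    def test_missing_cells_rejected(self, rng):
        ids = [f"s{i}" for i in range(6)]
        diffs = pd.DataFrame(
            {"pro": rng.normal(size=6), "anti": rng.normal(size=6)}, index=ids
        )
        diffs.loc[ids[0], "anti"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            interaction_anova(diffs, assignment_for(ids, 3))


class TestBetweenGroupSignComparison:
    def test_identical_distributions_near_zero_t(self, rng):
        x = rng.normal(0.1, 0.05, 40)
        out = between_group_sign_comparison(x, x.copy())
        assert out["t"] == pytest.approx(0.0)
        assert out["df"] == 78

    def test_matches_pooled_variance_formula(self, rng):
        a = rng.normal(-0.1, 0.1, 12)
        b = rng.normal(0.1, 0.1, 12)
        out = between_group_sign_comparison(a, b)
        t_ref = stats.ttest_ind(a, b, equal_var=True).statistic
        assert out["t"] == pytest.approx(t_ref)

    def test_planted_sign_difference_detected(self):
        g = np.random.default_rng(0)
        a = g.normal(-0.08, 0.05, 40)  # anti-correlated between-group R
        b = g.normal(0.08, 0.05, 40)
        out = between_group_sign_comparison(a, b)
        assert out["t"] < 0 and out["p"] < 0.001


class TestPeakBehaviorCorrelations:
    def test_affine_function_of_ias_gives_unit_r(self, rng):
        ids = [f"s{i}" for i in range(12)]
        ias = pd.Series(rng.normal(size=12), index=ids)
        scores = pd.DataFrame({"pooled": -2.0 * ias + 0.3}, index=ids)
        out = correlate_peaks_with_behavior(scores,
                                            pd.DataFrame({"ias": ias}))
        assert out.loc[0, "pearson_r"] == pytest.approx(-1.0)

    def test_monotone_nonlinear_spearman_one_pearson_below(self, rng):
        ids = [f"s{i}" for i in range(10)]
        x = pd.Series(np.linspace(0.1, 2.0, 10), index=ids)
        scores = pd.DataFrame({"pooled": np.exp(3 * x)}, index=ids)
        out = correlate_peaks_with_behavior(scores, pd.DataFrame({"x": x}))
        assert out.loc[0, "spearman_rho"] == pytest.approx(1.0)
        assert out.loc[0, "pearson_r"] < 1.0

    def test_null_scores_rarely_fdr_significant(self):
        g = np.random.default_rng(1)
        n_q_sig, n_p = 0, []
        for _ in range(20):
            ids = [f"s{i}" for i in range(40)]
            scores = pd.DataFrame({"pooled": g.normal(size=40)}, index=ids)
            behavior = pd.DataFrame(
                g.normal(size=(40, 5)),
                columns=[f"m{i}" for i in range(5)], index=ids,
            )
            out = correlate_peaks_with_behavior(scores, behavior)
            n_q_sig += int((out["q"] <= 0.05).sum())
            n_p.extend(out["pearson_p"])
        assert np.mean(np.array(n_p) < 0.05) < 0.12
        assert n_q_sig <= 2
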
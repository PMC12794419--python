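"""End-to-end orchestration: simulate -> prep -> ISC -> inference -> peaks
-> behavioral linkage, under one serializable configuration with
deterministic seeding, a config-hash cache for the expensive stages, and
a checksummed artifact manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavioral as bh
from . import inference as inf
from . import isc as isc_mod
from . import peaks as pk
from . import prep
from .synthetic import Region, SimulationConfig, SyntheticCohort, generate_cohort

__all__ = ["RunConfig", "run_full", "prepare_cohort"]


def _package_version() -> str:
    try:
        return metadata.version("polarisc")
    except metadata.PackageNotFoundError:
        return "unknown"


@dataclass(frozen=True)
class RunConfig:
    """One configuration for a full run; hashable and YAML-serializable."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "polarisc_run"
    seed: int = 0  # analysis-side randomness (permutation flips)
    n_perm: int = 10_000
    q_level: float = 0.05
    narratives: tuple[str, ...] = ("all", "pro", "anti")
    min_distance_mm: float = 10.0
    fd_frac: float = 0.25
    fd_threshold_mm: float = 0.5
    highpass_hz: float = 0.01
    use_cache: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["polarized_region_spec"] = [
            dataclasses.asdict(r)
            for r in self.simulation.polarized_region_spec
        ]
        d["simulation"]["common_region_spec"] = [
            dataclasses.asdict(r) for r in self.simulation.common_region_spec
        ]
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters only: where outputs land
        (out_dir) and whether caching is on never change the result."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("use_cache", None)
        payload = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        for key in ("polarized_region_spec", "common_region_spec"):
            if key in sim_raw:
                sim_raw[key] = tuple(
                    Region(tuple(r["center"]), r["radius_vox"],
                           r.get("narrative", "both"))
                    for r in sim_raw[key]
                )
        for key in ("grid_shape", "rating_group_means", "scale_loadings"):
            if key in sim_raw:
                sim_raw[key] = _deep_tuple(sim_raw[key])
        sim = SimulationConfig(**sim_raw)
        if "narratives" in raw:
            raw["narratives"] = tuple(raw["narratives"])
        return cls(simulation=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(
                json.dumps(self.to_dict(), default=list)
            ), sort_keys=True)
        )


def _deep_tuple(x):
    if isinstance(x, (list, tuple)):
        return tuple(_deep_tuple(v) for v in x)
    return x


def prepare_cohort(
    cohort: SyntheticCohort, config: RunConfig
) -> tuple[list[prep.SubjectTimeSeries], list[str], list[str]]:
    """Motion exclusion, nuisance regression, high-pass, statement
    extraction for every kept subject."""
    kept, excluded = prep.exclude_by_motion(
        cohort.fd_traces, frac=config.fd_frac,
        threshold_mm=config.fd_threshold_mm,
    )
    prepared = []
    for sid, vol in zip(cohort.subject_ids, cohort.volumes):
        if sid not in kept:
            continue
        ts = prep.from_volume(vol, cohort.mask, sid, cohort.config.tr_s,
                              affine=cohort.affine)
        ts = prep.regress_nuisance(ts, cohort.confounds[sid])
        ts = prep.highpass(ts, cutoff_hz=config.highpass_hz)
        ts = prep.extract_and_concatenate(ts, cohort.schedule)
        prepared.append(ts)
    return prepared, kept, excluded


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


class _Writer:
    def __init__(self, out: Path):
        self.out = out
        self.artifacts: dict[str, dict] = {}

    def csv(self, name: str, df: pd.DataFrame, index: bool = False):
        p = self.out / name
        df.to_csv(p, index=index, sep="\t" if name.endswith(".tsv") else ",")
        self._register(name, p)

    def json(self, name: str, payload: dict):
        p = self.out / name
        p.write_text(json.dumps(_to_jsonable(payload), indent=2,
                                sort_keys=True))
        self._register(name, p)

    def nifti(self, name: str, values: np.ndarray, grid: prep.VoxelGrid):
        import nibabel as nib

        p = self.out / name
        nib.save(prep.series_to_nifti(values, grid), p)
        self._register(name, p)

    def _register(self, name: str, p: Path):
        self.artifacts[name] = {"path": str(p), "sha256": _sha256(p)}


def _behavioral_stage(cohort: SyntheticCohort, kept: list[str],
                      config: RunConfig, w: _Writer):
    ratings = cohort.ratings[cohort.ratings["subject_id"].isin(kept)]
    scores = bh.compute_ias(ratings)
    assignment = bh.median_split(scores)
    w.csv("ias.csv", scores)
    w.csv("groups.csv", assignment)

    quest = cohort.questionnaires.loc[kept]
    multi = [s for s in cohort.scale_definitions if len(s.item_ids) >= 2]
    single = [s for s in cohort.scale_definitions if len(s.item_ids) == 1]
    scale_scores = pd.concat(
        [bh.score_scale(quest, s) for s in multi + single], axis=1
    )
    w.csv("scale_scores.csv", scale_scores.reset_index())
    alphas = pd.DataFrame(
        [{"scale": s.scale_name, "n_items": len(s.item_ids),
          "cronbach_alpha": bh.cronbach_alpha(quest, s)} for s in multi]
    )
    w.csv("cronbach_alphas.csv", alphas)

    multi_cols = [s.scale_name for s in multi]
    comparisons = bh.compare_groups_on_scales(
        scale_scores[multi_cols], assignment, q_level=config.q_level
    )
    w.csv("group_comparisons.csv", comparisons)

    ias = scores.set_index("subject_id")["ias"]
    corr = pd.concat(
        [
            bh.correlate_with_ias(scale_scores[multi_cols], ias, m,
                                  q_level=config.q_level)
            for m in ("pearson", "spearman")
        ],
        ignore_index=True,
    )
    w.csv("ias_correlations.csv", corr)
    if single:
        # single-item political inclination: uncorrected by design
        pol = pd.concat(
            [
                bh.correlate_with_ias(
                    scale_scores[[s.scale_name for s in single]], ias, m,
                    fdr=False,
                )
                for m in ("pearson", "spearman")
            ],
            ignore_index=True,
        )
        w.csv("ias_correlations_uncorrected.csv", pol)
    if len(scale_scores) > scale_scores.shape[1] + 1:
        regression = bh.regress_ias_on_scales(scale_scores, ias)
        w.json("ias_regression.json", regression)
    return assignment, scores, scale_scores


def _narrative_stage(data, assignment, grid, frame_types, sel: str,
                     config: RunConfig, w: _Writer, cache_dir: Path | None):
    """Grouped ISC + inference + peaks for one narrative selection."""
    cache = None
    if cache_dir is not None:
        cache = cache_dir / f"{config.config_hash}_{sel}.npz"
    maps = isc_mod.narrative_restricted_isc(
        data, assignment, narrative=sel, frame_types=frame_types
    )
    maps.grid = grid
    if cache is not None and cache.exists():
        z = np.load(cache)
        perm = inf.PermutationResult(
            t_obs=z["t_obs"], p=z["p"], n_permutations=int(z["n_perm"]),
            seed=config.seed, scheme=str(z["scheme"]), valid=z["valid"],
        )
        fdr = inf.bky_fdr(perm.p, q_level=config.q_level)
        report = inf.InferenceReport(permutation=perm, fdr=fdr)
    else:
        report = inf.run_inference(maps, n_perm=config.n_perm,
                                   seed=config.seed, q_level=config.q_level)
        if cache is not None:
            np.savez_compressed(
                cache, t_obs=report.permutation.t_obs, p=report.permutation.p,
                n_perm=report.permutation.n_permutations,
                scheme=report.permutation.scheme,
                valid=report.permutation.valid,
            )
    avg_diff = maps.average_diff
    w.nifti(f"avg_diff_{sel}.nii", avg_diff, grid)
    w.nifti(f"perm_p_{sel}.nii", report.permutation.p, grid)
    w.nifti(f"fdr_q_{sel}.nii", report.fdr.q, grid)
    table = pd.DataFrame({
        "voxel": np.arange(avg_diff.size),
        "avg_diff": avg_diff,
        "t": report.permutation.t_obs,
        "p": report.permutation.p,
        "q": report.fdr.q,
        "significant": report.fdr.mask,
    })
    w.csv(f"voxelwise_{sel}.tsv", table)

    mask = report.fdr.mask & np.isfinite(avg_diff)
    if mask.any() and np.ptp(avg_diff[mask]) > 0:
        peaks = pk.extract_peaks(avg_diff, mask, grid,
                                 min_distance_mm=config.min_distance_mm,
                                 p_values=report.permutation.p, source=sel)
    else:
        peaks = pk.extract_peaks(avg_diff, np.zeros_like(mask), grid,
                                 source=sel)
    w.csv(f"peaks_{sel}.tsv", peaks)
    scores = None
    if len(peaks):
        scores = pk.score_peaks(maps, peaks)
        w.csv(f"peak_scores_{sel}.csv", scores)
        w.csv(f"peak_tests_{sel}.csv", pk.peak_level_tests(scores))
        pooled = pk.pooled_peak_contrast(scores)
        w.json(f"pooled_contrast_{sel}.json",
               {k: v for k, v in pooled.items() if k != "pooled_by_subject"})
    return maps, report, peaks, scores


def run_full(config: RunConfig) -> dict:
    """Execute the whole pipeline under one config; returns the manifest.

    Stages: simulate -> motion exclusion -> nuisance regression ->
    high-pass -> statement extraction -> behavioral scoring and split ->
    grouped ISC, sign-flip permutation + BKY FDR, and peak statistics for
    each narrative selection -> cross-narrative and brain-behavior
    linkage.  Reruns with an identical config produce byte-identical
    artifacts; the permutation stage is cached on disk keyed by the
    config hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache_dir = None
    if config.use_cache:
        cache_dir = out / "cache"
        cache_dir.mkdir(exist_ok=True)
    w = _Writer(out)

    stage = "simulate"
    try:
        cohort = generate_cohort(config.simulation)
        stage = "prep"
        prepared, kept, excluded = prepare_cohort(cohort, config)
        if len(prepared) < 4:
            raise ValueError("fewer than 4 subjects survive exclusion")
        grid = prepared[0].grid
        frame_types = prepared[0].frame_types
        data = np.stack([ts.data for ts in prepared])

        stage = "behavioral"
        assignment, scores, scale_scores = _behavioral_stage(
            cohort, kept, config, w
        )

        stage = "isc/inference/peaks"
        per_sel = {}
        cohort_list = prepared
        for sel in config.narratives:
            per_sel[sel] = _narrative_stage(
                cohort_list, assignment, grid, frame_types, sel, config, w,
                cache_dir,
            )

        stage = "cross-narrative"
        reports: dict = {"excluded_subjects": excluded,
                         "kept_subjects": kept}
        if "pro" in per_sel and "anti" in per_sel:
            maps_pro, _, peaks_pro, _ = per_sel["pro"]
            maps_anti, _, peaks_anti, _ = per_sel["anti"]
            nonempty = [df for df in (peaks_pro, peaks_anti) if len(df)]
            union = (
                pd.concat(nonempty, ignore_index=True)
                if nonempty else peaks_pro.iloc[:0].copy()
            )
            union["peak_id"] = np.arange(len(union))
            if len(union):
                sc_pro = pk.score_peaks(maps_pro, union)
                sc_anti = pk.score_peaks(maps_anti, union)
                cross = pk.cross_narrative_contrast(sc_pro, sc_anti,
                                                    q_level=config.q_level)
                w.csv("cross_narrative_contrast.csv", cross)
                # pooled score across the union of pro+anti peaks
                pooled = pk.pooled_peak_contrast(
                    pd.concat([sc_pro[sc_pro.peak_id.isin(
                        union.loc[union.source == "pro", "peak_id"])],
                        sc_anti[sc_anti.peak_id.isin(
                            union.loc[union.source == "anti", "peak_id"])]],
                        ignore_index=True)
                )
                w.json("pooled_pro_anti_contrast.json",
                       {k: v for k, v in pooled.items()
                        if k != "pooled_by_subject"})
                pooled_by_subject = pooled["pooled_by_subject"].set_index(
                    "subject_id"
                )
                ias = scores.set_index("subject_id")["ias"]
                behavior = pd.concat([ias, scale_scores], axis=1)
                linkage = pk.correlate_peaks_with_behavior(
                    pooled_by_subject[["diff"]].rename(
                        columns={"diff": "pooled_peak_score"}),
                    behavior, q_level=config.q_level,
                )
                w.csv("peak_behavior_correlations.csv", linkage)
                # interaction: per-subject diff under pro vs anti frames,
                # averaged over the peak union
                d_pro = sc_pro.groupby("subject_id")["diff"].mean()
                d_anti = sc_anti.groupby("subject_id")["diff"].mean()
                diffs = pd.DataFrame({"pro": d_pro, "anti": d_anti})
                reports["interaction_anova"] = pk.interaction_anova(
                    diffs, assignment
                )
                # between-group-ISC sign comparison: anti-source peaks vs
                # pro-source peaks, all subjects pooled
                anti_ids = union.loc[union.source == "anti", "peak_id"]
                pro_ids = union.loc[union.source == "pro", "peak_id"]
                if len(anti_ids) and len(pro_ids):
                    b_anti = (
                        sc_anti[sc_anti.peak_id.isin(anti_ids)]
                        .groupby("subject_id")["between_r"].mean().to_numpy()
                    )
                    b_pro = (
                        sc_pro[sc_pro.peak_id.isin(pro_ids)]
                        .groupby("subject_id")["between_r"].mean().to_numpy()
                    )
                    reports["between_group_sign_comparison"] = (
                        pk.between_group_sign_comparison(b_anti, b_pro)
                    )
        w.json("reports.json", reports)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "config_hash": config.config_hash,
        "package_version": _package_version(),
        "config": config.to_dict(),
        "artifacts": dict(sorted(w.artifacts.items())),
    }
    (out / "manifest.json").write_text(
        json.dumps(_to_jsonable(manifest), indent=2, sort_keys=True)
    )
    return manifest
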
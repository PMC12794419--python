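"""Synthetic naturalistic-listening cohorts with plantable polarization.

Generates everything the analysis consumes — BOLD-like 4D volumes, a
statement schedule, agreement ratings, multi-item questionnaires, motion
confounds and framewise-displacement traces — with the statistical
structure the ISC contrast assumes, plus ground-truth labels for
recovery tests.  The defaults emulate the study design the package
targets: 40 subjects in two latent attitude groups of 20, 44 statements
(22 pro- / 22 anti-immigration) of ~16.3 s separated by jittered 16-17 s
breaks, sampled at TR = 1.26 s on a 12x12x12 grid of 3 mm voxels.

Signal model per voxel class (amplitudes chosen so each class has unit
total variance):

* ``common``:    sqrt(common_share) * c(t) + sqrt(noise_share) * eps_i(t)
* ``polarized``: sqrt(group_share) * w(r) * s_g(i)(t) + noise to unit var
* ``null``:      eps_i(t)

where c is a cohort-common smooth unit-variance process, s_g a
group-specific one (optionally active only during one narrative type's
statement frames), eps_i subject-specific AR(1) noise, and w(r) a
deterministic radial taper (1 at the region center) that makes the
planted peak locatable.  Ground truth is stored alongside the data and
never read by any analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .behavioral import ScaleDefinition
from .prep import CONFOUND_COLUMNS, MOTION_PARAMS

__all__ = [
    "Region",
    "SimulationConfig",
    "SyntheticCohort",
    "DEFAULT_SCALES",
    "generate_cohort",
    "generate_schedule",
    "generate_ratings",
    "generate_questionnaires",
    "generate_fd_traces",
    "save_cohort",
]


@dataclass(frozen=True)
class Region:
    """A spherical voxel region: center (i,j,k), radius in voxels, and the
    narrative type during which its group signal is active."""

    center: tuple[int, int, int]
    radius_vox: float
    narrative: str = "both"  # pro | anti | both

    def __post_init__(self):
        if self.narrative not in ("pro", "anti", "both"):
            raise ValueError("narrative must be 'pro', 'anti' or 'both'")
        if self.radius_vox <= 0:
            raise ValueError("radius must be positive")


# Questionnaire battery mirroring a typical explicit-attitude protocol:
# item counts and bounds follow the scales the analysis reports on.
DEFAULT_SCALES: tuple[ScaleDefinition, ...] = (
    ScaleDefinition("competence", tuple(f"comp_{i}" for i in range(1, 4)),
                    (), 1, 5),
    ScaleDefinition("empathic_emotions", tuple(f"emp_{i}" for i in range(1, 4)),
                    (), 1, 5),
    ScaleDefinition("negative_emotions", tuple(f"neg_{i}" for i in range(1, 6)),
                    (), 1, 5),
    ScaleDefinition("perceived_threat", tuple(f"thr_{i}" for i in range(1, 5)),
                    ("thr_4",), 1, 7),
    ScaleDefinition("rwa", tuple(f"rwa_{i}" for i in range(1, 8)),
                    ("rwa_3", "rwa_6"), 1, 7),
    ScaleDefinition("multiculturalism", tuple(f"mc_{i}" for i in range(1, 11)),
                    ("mc_2", "mc_7"), 1, 7),
    ScaleDefinition("resistance_to_change", tuple(f"rtc_{i}" for i in range(1, 8)),
                    ("rtc_5",), 1, 7),
    ScaleDefinition("group_superiority", tuple(f"gs_{i}" for i in range(1, 9)),
                    (), 1, 7),
    ScaleDefinition("workplace_attitudes", tuple(f"wp_{i}" for i in range(1, 11)),
                    ("wp_1", "wp_9"), 1, 7),
    ScaleDefinition("political_inclination", ("pol_1",), (), 1, 7),
)

# loading of each scale on the latent attitude (positive = more supportive
# subjects score higher after reverse-coding)
DEFAULT_SCALE_LOADINGS: dict[str, float] = {
    "competence": 0.6,
    "empathic_emotions": 0.6,
    "negative_emotions": -0.4,
    "perceived_threat": -0.4,
    "rwa": -0.6,
    "multiculturalism": 0.6,
    "resistance_to_change": -0.3,
    "group_superiority": -0.5,
    "workplace_attitudes": -0.5,
    "political_inclination": 0.4,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and signal parameters of the synthetic cohort.

    Variance shares are per voxel class: ``common`` voxels mix
    {common_share, noise_share}, ``polarized`` voxels {group_share,
    noise_share}; each pair must sum to 1.
    """

    n_per_group: int = 20
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0
    tr_s: float = 1.26
    n_statements: int = 44
    statement_mean_s: float = 16.3
    statement_sd_s: float = 2.0
    gap_s: float = 16.5
    gap_jitter_s: float = 0.5
    pre_rating_gap_s: float = 1.5
    common_share: float = 0.3
    group_share: float = 0.3
    noise_share: float = 0.7
    polarized_region_spec: tuple[Region, ...] = (
        Region((3, 3, 3), 2.0, "both"),
        Region((8, 8, 8), 2.0, "anti"),
    )
    common_region_spec: tuple[Region, ...] = (Region((8, 3, 8), 2.0),)
    region_edge_weight: float = 0.8
    ar1_coef: float = 0.3
    signal_fwhm_s: float = 6.0
    group_signal_corr: float = 0.0
    rating_group_means: tuple[tuple[float, float], tuple[float, float]] = (
        (4.5, 1.2),
        (3.5, 1.9),
    )
    rating_sd: float = 0.7
    scale_loadings: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_SCALE_LOADINGS.items()
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid dimensions must be positive")
        for name in ("tr_s", "statement_mean_s", "voxel_size_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_statements < 2 or self.n_statements % 2:
            raise ValueError("n_statements must be a positive even count")
        for share in ("common_share", "group_share", "noise_share"):
            v = getattr(self, share)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{share} must lie in [0, 1]")
        for pair in ("common_share", "group_share"):
            if abs(getattr(self, pair) + self.noise_share - 1.0) > 1e-12:
                raise ValueError(
                    f"{pair} + noise_share must sum to 1 within each class"
                )
        if not -1.0 <= self.group_signal_corr <= 1.0:
            raise ValueError("group_signal_corr must lie in [-1, 1]")
        if not 0.0 < self.region_edge_weight <= 1.0:
            raise ValueError("region_edge_weight must lie in (0, 1]")
        for reg in self.polarized_region_spec + self.common_region_spec:
            for c, dim in zip(reg.center, self.grid_shape):
                if not 0 <= c < dim:
                    raise ValueError(f"region center {reg.center} outside grid")
        (p1, a1), (p2, a2) = self.rating_group_means
        if p1 - a1 <= p2 - a2:
            raise ValueError(
                "group 1 must have the higher pro-minus-anti rating mean"
            )

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_per_group

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus sealed ground truth."""

    config: SimulationConfig
    subject_ids: list[str]
    volumes: list[np.ndarray]  # per subject, (X, Y, Z, T) float32
    mask: np.ndarray  # (X, Y, Z) bool
    affine: np.ndarray
    schedule: pd.DataFrame
    ratings: pd.DataFrame
    questionnaires: pd.DataFrame  # wide, subject_id index x item columns
    scale_definitions: tuple[ScaleDefinition, ...]
    fd_traces: pd.DataFrame  # frames x subjects
    confounds: dict[str, pd.DataFrame]
    truth: dict = field(repr=False, default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.volumes[0].shape[-1]


def _smooth_unit_process(rng, n_frames: int, tr_s: float, fwhm_s: float):
    """Unit-variance band-limited process: Gaussian white noise smoothed
    with a Gaussian kernel of the given FWHM (seconds), then standardized."""
    sigma_frames = fwhm_s / (2.0 * np.sqrt(2.0 * np.log(2.0))) / tr_s
    x = gaussian_filter1d(rng.standard_normal(n_frames), sigma_frames,
                          mode="reflect")
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _ar1_noise(rng, shape: tuple[int, int], phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) noise, rows independent."""
    n_series, n_frames = shape
    innov = rng.standard_normal(shape) * np.sqrt(1.0 - phi**2)
    x = lfilter([1.0], [1.0, -phi], innov, axis=1)
    x0 = rng.standard_normal(n_series)
    x += x0[:, None] * phi ** np.arange(n_frames)[None, :]
    return x


def generate_schedule(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Statement schedule: interleaved pro/anti order with at most two
    consecutive same-type statements, Gaussian durations (truncated at
    5 s), and a jittered inter-statement break of pre_rating_gap_s +
    gap_s +- gap_jitter_s."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    half = config.n_statements // 2
    types = _constrained_type_order(rng, half)
    durations = np.maximum(
        rng.normal(config.statement_mean_s, config.statement_sd_s,
                   config.n_statements),
        5.0,
    )
    gaps = config.pre_rating_gap_s + config.gap_s + rng.uniform(
        -config.gap_jitter_s, config.gap_jitter_s, config.n_statements
    )
    onsets = np.empty(config.n_statements)
    t = 10.0  # lead-in before the first statement
    for i in range(config.n_statements):
        onsets[i] = t
        t += durations[i] + gaps[i]
    return pd.DataFrame(
        {"onset_s": onsets, "duration_s": durations, "type": types}
    )


def _constrained_type_order(rng, half: int) -> list[str]:
    """Random pro/anti order with no run longer than 2."""
    while True:
        remaining = {"pro": half, "anti": half}
        order: list[str] = []
        ok = True
        while remaining["pro"] or remaining["anti"]:
            opts = [
                t for t in ("pro", "anti")
                if remaining[t] > 0 and order[-2:] != [t, t]
            ]
            if not opts:
                ok = False
                break
            pick = opts[rng.integers(len(opts))] if len(opts) > 1 else opts[0]
            order.append(pick)
            remaining[pick] -= 1
        if ok:
            return order


def _voxel_classes(config: SimulationConfig):
    """Label every voxel {null=0, common=1, polarized=2}; polarized wins
    overlaps.  Also return per-voxel amplitude weights and, for polarized
    voxels, the index of the owning region."""
    shape = config.grid_shape
    coords = np.indices(shape).reshape(3, -1).T.astype(float)
    classes = np.zeros(int(np.prod(shape)), dtype=int)
    weight = np.zeros(classes.shape)
    region_of = np.full(classes.shape, -1, dtype=int)

    def taper(dist, radius):
        w = 1.0 - (1.0 - config.region_edge_weight) * (dist / radius)
        return np.clip(w, 0.0, 1.0)

    for reg in config.common_region_spec:
        d = np.linalg.norm(coords - np.array(reg.center), axis=1)
        inside = d <= reg.radius_vox
        classes[inside] = 1
        weight[inside] = np.maximum(weight[inside], taper(d[inside], reg.radius_vox))
    for ri, reg in enumerate(config.polarized_region_spec):
        d = np.linalg.norm(coords - np.array(reg.center), axis=1)
        inside = d <= reg.radius_vox
        classes[inside] = 2
        weight[inside] = taper(d[inside], reg.radius_vox)
        region_of[inside] = ri
    return (
        classes.reshape(shape),
        weight.reshape(shape),
        region_of.reshape(shape),
    )


def _narrative_frame_mask(
    schedule: pd.DataFrame, n_frames: int, tr_s: float, narrative: str
) -> np.ndarray:
    """1.0 on frames whose midpoint falls inside a statement of the given
    type ('both' selects every frame)."""
    if narrative == "both":
        return np.ones(n_frames)
    mid = (np.arange(n_frames) + 0.5) * tr_s
    mask = np.zeros(n_frames, dtype=bool)
    for _, row in schedule.iterrows():
        if row["type"] == narrative:
            mask |= (mid >= row["onset_s"]) & (
                mid < row["onset_s"] + row["duration_s"]
            )
    return mask.astype(float)


def generate_ratings(config: SimulationConfig, rng,
                     schedule: pd.DataFrame,
                     subject_ids: list[str],
                     group_of: dict[str, int]) -> pd.DataFrame:
    """Agreement ratings: discretized Gaussians around per-group
    pro/anti means, clipped to 1..5."""
    rows = []
    for sid in subject_ids:
        means = config.rating_group_means[group_of[sid]]
        for stmt_id, row in schedule.iterrows():
            mu = means[0] if row["type"] == "pro" else means[1]
            r = int(np.clip(np.rint(rng.normal(mu, config.rating_sd)), 1, 5))
            rows.append(
                dict(subject_id=sid, statement_id=f"stmt-{stmt_id:02d}",
                     statement_type=row["type"], rating=r)
            )
    return pd.DataFrame(rows)


def generate_questionnaires(
    config: SimulationConfig, rng, subject_ids: list[str],
    group_of: dict[str, int],
    scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> pd.DataFrame:
    """Item responses from a single latent attitude factor.

    The latent attitude is +1/-1 by group plus N(0, 0.5) noise; each item
    deflects from its scale midpoint by loading * attitude * span/4 plus
    unit item noise, then is rounded and clipped to bounds.  Reverse-coded
    items are stored reflected so scoring recovers the construct.
    """
    loadings = dict(config.scale_loadings)
    records = {}
    for sid in subject_ids:
        attitude = (1.0 if group_of[sid] == 0 else -1.0) + rng.normal(0, 0.5)
        row = {}
        for scale in scales:
            lam = loadings.get(scale.scale_name, 0.0)
            lo, hi = scale.range_min, scale.range_max
            mid, span = (lo + hi) / 2.0, hi - lo
            for item in scale.item_ids:
                val = mid + lam * attitude * span / 4.0 + rng.normal(0, 1.0)
                val = int(np.clip(np.rint(val), lo, hi))
                if item in scale.reverse_items:
                    val = lo + hi - val
                row[item] = val
        records[sid] = row
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "subject_id"
    return out


def generate_fd_traces(
    config: SimulationConfig,
    frac_high: float = 0.0,
    threshold_mm: float = 0.5,
    high_motion_subjects: tuple[str, ...] = (),
    n_frames: int | None = None,
    rng=None,
) -> pd.DataFrame:
    """Framewise-displacement traces (frames x subjects, mm).

    Ordinary subjects stay below ``threshold_mm`` everywhere; designated
    high-motion subjects get exactly ``round(frac_high * n_frames)``
    frames above it, so an exclusion rule with a strict inequality at
    ``frac = frac_high`` does *not* flag them, while any smaller cutoff
    does.
    """
    if not 0.0 <= frac_high <= 1.0:
        raise ValueError("frac_high must lie in [0, 1]")
    if threshold_mm < 0:
        raise ValueError("threshold_mm must be non-negative")
    rng = np.random.default_rng(config.seed + 7) if rng is None else rng
    if n_frames is None:
        sched = generate_schedule(config)
        last = sched.iloc[-1]
        n_frames = int(np.ceil((last["onset_s"] + last["duration_s"] + 10.0)
                               / config.tr_s))
    ids = [f"sub-{i + 1:02d}" for i in range(config.n_subjects)]
    base_hi = min(threshold_mm, 0.45)
    fd = rng.uniform(0.02, max(base_hi, 0.03), size=(n_frames, len(ids)))
    out = pd.DataFrame(fd, columns=ids)
    n_high = int(np.rint(frac_high * n_frames))
    for sid in high_motion_subjects:
        if sid not in out.columns:
            raise ValueError(f"unknown subject {sid!r}")
        idx = rng.choice(n_frames, size=n_high, replace=False)
        col = out[sid].to_numpy()
        col[idx] = threshold_mm + rng.uniform(0.1, 0.5, size=n_high)
        out[sid] = col
    return out


def _generate_confounds(rng, n_frames: int, volume: np.ndarray) -> pd.DataFrame:
    """fMRIPrep-style 23-column nuisance table for one subject."""
    data = {}
    motion = {}
    for name in MOTION_PARAMS:
        scale = 0.05 if name.startswith("trans") else 0.001
        motion[name] = np.cumsum(rng.normal(0, scale, n_frames))
        data[name] = motion[name]
    for name in MOTION_PARAMS:
        d = np.diff(motion[name], prepend=motion[name][0])
        data[f"{name}_derivative1"] = d
    data["global_signal"] = volume.reshape(-1, n_frames).mean(axis=0)
    trans_d = sum(
        np.abs(data[f"{n}_derivative1"]) for n in MOTION_PARAMS[:3]
    )
    rot_d = sum(
        np.abs(data[f"{n}_derivative1"]) * 50.0 for n in MOTION_PARAMS[3:]
    )
    data["framewise_displacement"] = trans_d + rot_d
    for i in range(6):
        data[f"a_comp_cor_{i:02d}"] = rng.standard_normal(n_frames)
    t = np.linspace(-1, 1, n_frames)
    data["poly_0"] = np.ones(n_frames)
    data["poly_1"] = t
    data["poly_2"] = 0.5 * (3 * t**2 - 1)
    return pd.DataFrame(data)[list(CONFOUND_COLUMNS)]


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort under the configured signal model.

    Deterministic given ``config.seed``: identical configs give
    byte-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    schedule = generate_schedule(config, rng)
    last = schedule.iloc[-1]
    n_frames = int(np.ceil((last["onset_s"] + last["duration_s"] + 10.0)
                           / config.tr_s))
    shape = config.grid_shape
    n_voxels = int(np.prod(shape))
    classes, weight, region_of = _voxel_classes(config)
    cls_flat = classes.ravel()
    w_flat = weight.ravel()
    reg_flat = region_of.ravel()

    ids = [f"sub-{i + 1:02d}" for i in range(config.n_subjects)]
    group_of = {sid: (0 if i < config.n_per_group else 1)
                for i, sid in enumerate(ids)}

    # shared processes
    c_t = _smooth_unit_process(rng, n_frames, config.tr_s, config.signal_fwhm_s)
    s1 = _smooth_unit_process(rng, n_frames, config.tr_s, config.signal_fwhm_s)
    s2_raw = _smooth_unit_process(rng, n_frames, config.tr_s,
                                  config.signal_fwhm_s)
    rho = config.group_signal_corr
    s2 = rho * s1 + np.sqrt(max(0.0, 1.0 - rho**2)) * s2_raw
    group_signals = (s1, s2)

    # per-region narrative activity masks
    region_masks = [
        _narrative_frame_mask(schedule, n_frames, config.tr_s, reg.narrative)
        for reg in config.polarized_region_spec
    ]

    amp_common = np.where(cls_flat == 1,
                          np.sqrt(config.common_share) * w_flat, 0.0)
    amp_group = np.where(cls_flat == 2,
                         np.sqrt(config.group_share) * w_flat, 0.0)
    amp_noise = np.sqrt(
        np.clip(1.0 - amp_common**2 - amp_group**2, 0.0, 1.0)
    )

    volumes = []
    confounds = {}
    for sid in ids:
        eps = _ar1_noise(rng, (n_voxels, n_frames), config.ar1_coef)
        sig = amp_noise[:, None] * eps
        sig += amp_common[:, None] * c_t[None, :]
        g = group_of[sid]
        for ri in range(len(config.polarized_region_spec)):
            sel = reg_flat == ri
            if sel.any():
                sig[sel] += (
                    amp_group[sel, None]
                    * (group_signals[g] * region_masks[ri])[None, :]
                )
        vol = sig.reshape(shape + (n_frames,)).astype(np.float32)
        volumes.append(vol)
        confounds[sid] = _generate_confounds(rng, n_frames, vol)

    ratings = generate_ratings(config, rng, schedule, ids, group_of)
    questionnaires = generate_questionnaires(config, rng, ids, group_of)
    fd = generate_fd_traces(config, n_frames=n_frames,
                            rng=np.random.default_rng(config.seed + 7))

    truth = {
        "group": {sid: f"g{group_of[sid] + 1}" for sid in ids},
        "voxel_class": np.where(
            cls_flat == 2, "polarized", np.where(cls_flat == 1, "common", "null")
        ).reshape(shape),
        "region_of_voxel": region_of,
        "amplitude_weight": weight,
        "expected_share": {
            "common": amp_common.reshape(shape) ** 2,
            "group": amp_group.reshape(shape) ** 2,
            "noise": amp_noise.reshape(shape) ** 2,
        },
    }
    return SyntheticCohort(
        config=config,
        subject_ids=ids,
        volumes=volumes,
        mask=np.ones(shape, dtype=bool),
        affine=config.affine,
        schedule=schedule,
        ratings=ratings,
        questionnaires=questionnaires,
        scale_definitions=DEFAULT_SCALES,
        fd_traces=fd,
        confounds=confounds,
        truth=truth,
    )


def save_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict:
    """Write the cohort to disk in open formats.

    Per-subject NIfTI-1 volumes and a mask NIfTI; schedule as TSV
    (onset_s, duration_s, type); ratings and questionnaires as CSV; FD as
    one column per subject (CSV); confounds as per-subject TSV.  Returns
    the path manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {"volumes": {}, "confounds": {}}
    for sid, vol in zip(cohort.subject_ids, cohort.volumes):
        img = nib.Nifti1Image(vol, cohort.affine)
        img.header["pixdim"][4] = cohort.config.tr_s
        p = out / f"{sid}_bold.nii"
        nib.save(img, p)
        paths["volumes"][sid] = str(p)
        cp = out / f"{sid}_confounds.tsv"
        cohort.confounds[sid].to_csv(cp, sep="\t", index=False)
        paths["confounds"][sid] = str(cp)
    mask_p = out / "mask.nii"
    nib.save(nib.Nifti1Image(cohort.mask.astype(np.uint8), cohort.affine),
             mask_p)
    sched_p = out / "schedule.tsv"
    cohort.schedule.to_csv(sched_p, sep="\t", index=False)
    ratings_p = out / "ratings.csv"
    cohort.ratings.to_csv(ratings_p, index=False)
    quest_p = out / "questionnaires.csv"
    cohort.questionnaires.to_csv(quest_p)
    fd_p = out / "fd.csv"
    cohort.fd_traces.to_csv(fd_p, index=False)
    paths.update(mask=str(mask_p), schedule=str(sched_p),
                 ratings=str(ratings_p), questionnaires=str(quest_p),
                 fd=str(fd_p))
    return paths
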
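"""Synthetic lesion-cohort generator with recorded ground truth.

Emulates the statistical structure the analysis pipeline assumes: a small
MNI-like grid (2 mm scale) carrying 11 tubular white-matter tract
probability fields; spatially clustered binary lesion maps whose
prevalence is highest in periventricular and frontal white matter; and
cognitive compound scores that are linear in demographic covariates plus
tract-specific lesion-volume effects with Gaussian noise. Cohort-level
defaults (n = 167; age 72.8 +/- 9.1 y; 46% male; education 6.1 +/- 5.0 y;
median total WMH volume ~14.7 ml; 29% with lacunes; 57% with microbleeds,
4 subjects missing that status; BPF 0.64 +/- 0.06; 25% AD diagnoses)
match the memory-clinic cohort the pipeline was designed around.

A master integer seed fans out to per-stage sub-seeds (atlas, lesions,
covariates, noise) so stages can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import CANONICAL_TRACTS, MIDLINE_TRACTS, threshold_atlas, merge_bilateral
from .io import LesionMap, ProbabilisticAtlas, TractROISet
from .volumetrics import regional_volume_table

__all__ = [
    "SynthTruth",
    "generate_atlas",
    "generate_lesions",
    "generate_covariates",
    "generate_cognition",
    "simulate_cohort",
]

DEFAULT_SHAPE = (48, 56, 48)
#: 2 mm isotropic grid, origin placed so the box is roughly MNI-centred.
DEFAULT_AFFINE = np.array(
    [[2.0, 0, 0, -47.0], [0, 2.0, 0, -63.0], [0, 0, 2.0, -46.0], [0, 0, 0, 1.0]]
)

#: True standardized lesion-location effects on each cognitive domain.
DEFAULT_TRACT_EFFECTS: dict[str, dict[str, float]] = {
    "executive": {"anterior_thalamic_radiation": -0.30},
    "speed": {"forceps_minor": -0.30},
    "memory": {"forceps_minor": -0.25},
}

#: Standardized covariate effects shared by all domains (age in z-units etc.).
DEFAULT_COVARIATE_EFFECTS = {"age": -0.45, "education": 0.35, "sex": 0.15}

DEFAULT_NOISE_SD = 0.75

# Tract centre-line control points in fractional grid coordinates
# (x: lateral with 0.5 = midline, y: posterior 0 -> anterior 1, z: inferior
# 0 -> superior 1). Bilateral tracts are defined for the left hemisphere
# (x < 0.5) and mirrored. The two "strategic" tracts sit anterior-medially.
_TRACT_PATHS: dict[str, list[tuple[float, float, float]]] = {
    "forceps_minor": [(0.27, 0.84, 0.54), (0.50, 0.92, 0.54), (0.73, 0.84, 0.54)],
    "forceps_major": [(0.27, 0.18, 0.50), (0.50, 0.09, 0.50), (0.73, 0.18, 0.50)],
    "anterior_thalamic_radiation": [(0.43, 0.46, 0.44), (0.40, 0.64, 0.48), (0.36, 0.80, 0.52)],
    "uncinate_fasciculus": [(0.31, 0.78, 0.32), (0.28, 0.66, 0.25), (0.32, 0.56, 0.28)],
    "inferior_fronto_occipital_fasciculus": [(0.34, 0.84, 0.42), (0.31, 0.50, 0.40), (0.33, 0.16, 0.42)],
    "cingulum_cingulate_gyrus": [(0.45, 0.76, 0.68), (0.44, 0.50, 0.74), (0.45, 0.26, 0.68)],
    "inferior_longitudinal_fasciculus": [(0.26, 0.20, 0.34), (0.25, 0.42, 0.30), (0.29, 0.62, 0.30)],
    "corticospinal_tract": [(0.40, 0.46, 0.10), (0.39, 0.50, 0.50), (0.37, 0.54, 0.90)],
    "superior_longitudinal_fasciculus": [(0.30, 0.72, 0.66), (0.28, 0.48, 0.68), (0.30, 0.26, 0.66)],
    "superior_longitudinal_fasciculus_temporal": [(0.28, 0.30, 0.38), (0.27, 0.44, 0.50), (0.30, 0.58, 0.58)],
    "cingulum_hippocampus": [(0.37, 0.28, 0.28), (0.40, 0.40, 0.24), (0.42, 0.50, 0.28)],
}


@dataclass
class SynthTruth:
    """Ground truth that fully determines a generated cohort given its seed."""

    seed: int
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    tract_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRACT_EFFECTS.items()}
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    noise_sd: float = DEFAULT_NOISE_SD
    cluster_effect_sd: float = 0.0  # focal-cluster score shift in noise-SD units
    cluster_voxels: list[int] = field(default_factory=list)  # flat voxel indices
    cluster_subjects: list[int] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=lambda o: list(o))

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["shape"] = tuple(d["shape"])
        return cls(**d)


def _subseed(master: int, stage: str) -> np.random.Generator:
    stage_codes = {"atlas": 0, "lesions": 1, "covariates": 2, "noise": 3, "cluster": 4}
    ss = np.random.SeedSequence([int(master), stage_codes[stage]])
    return np.random.default_rng(ss)


def _rasterize_path(points: np.ndarray, shape, n_samples: int = 400) -> np.ndarray:
    """Mark voxels along a piecewise-linear path through control points."""
    vol = np.zeros(shape, dtype=bool)
    for seg in range(len(points) - 1):
        t = np.linspace(0, 1, n_samples // (len(points) - 1))[:, None]
        pts = points[seg] * (1 - t) + points[seg + 1] * t
        ijk = np.clip(np.round(pts).astype(int), 0, np.array(shape) - 1)
        vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    return vol


def generate_atlas(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    seed: int = 0,
    tube_sigma_vox: float = 2.5,
    jitter_vox: float = 0.8,
    affine: np.ndarray = DEFAULT_AFFINE,
) -> ProbabilisticAtlas:
    """Generate tubular probability fields for the 11 canonical tracts.

    Bilateral tracts produce ``<name>_l`` / ``<name>_r`` volumes (mirrored
    across the sagittal midplane); forceps minor/major are single midline
    volumes. Probability falls off as a Gaussian of distance to the tract
    centre line, scaled to percent (peak 100).
    """
    rng = _subseed(seed, "atlas")
    dims = np.array(shape, dtype=float)
    vols, names = [], []
    for tract in CANONICAL_TRACTS:
        base = np.array(_TRACT_PATHS[tract], dtype=float)
        sides = [("", base)] if tract in MIDLINE_TRACTS else [
            ("_l", base),
            ("_r", np.column_stack([1.0 - base[:, 0], base[:, 1], base[:, 2]])),
        ]
        for suffix, frac_pts in sides:
            pts = frac_pts * (dims - 1) + rng.normal(0, jitter_vox, frac_pts.shape)
            path = _rasterize_path(pts, shape)
            dist = ndimage.distance_transform_edt(~path)
            prob = 100.0 * np.exp(-(dist**2) / (2.0 * tube_sigma_vox**2))
            vols.append(prob)
            names.append(f"{tract}{suffix}")
    return ProbabilisticAtlas(names, np.stack(vols, axis=-1), np.asarray(affine))


def _prevalence_weight(shape) -> np.ndarray:
    """Periventricular + frontal lesion-prevalence field in [0, 1]."""
    x, y, z = np.meshgrid(*[np.linspace(0, 1, s) for s in shape], indexing="ij")
    # periventricular core: two parasagittal bands around the midline
    lat = np.minimum(np.abs(x - 0.38), np.abs(x - 0.62))
    pv = np.exp(-(lat**2) / (2 * 0.10**2)) * np.exp(-((z - 0.52) ** 2) / (2 * 0.16**2))
    pv *= np.exp(-np.maximum(0, np.abs(y - 0.5) - 0.30) ** 2 / (2 * 0.08**2))
    frontal = 0.55 + 0.9 * y  # anterior gradient
    w = pv * frontal
    return w / w.max()


def generate_lesions(
    n_subjects: int = 167,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    seed: int = 0,
    median_volume_ml: float = 14.7,
    log_sd: float = 0.95,
    fine_sigma_vox: float = 1.5,
    coarse_sigma_vox: float = 6.0,
    fine_amp: float = 1.5,
    coarse_amp: float = 3.0,
    affine: np.ndarray = DEFAULT_AFFINE,
    severity_scale: float = 1.0,
) -> list[LesionMap]:
    """Generate spatially clustered binary lesion maps for a cohort.

    Per subject, a total lesion volume is drawn from a log-normal
    distribution (median ``median_volume_ml``, right-skewed so the cohort
    spans roughly 0.5-140 ml) and placed as the top-scoring voxels of a
    random field multiplied by the periventricular/frontal prevalence
    weight. The field is the sum of a fine-scale component (blob texture)
    and a coarse-scale component giving each subject their own regional
    emphasis — without the coarse component, regional tract loads would be
    nearly collinear across subjects and lesion location would carry no
    identifiable signal. ``severity_scale`` rescales all volumes (0 gives
    empty maps).
    """
    rng = _subseed(seed, "lesions")
    w = _prevalence_weight(shape)
    eligible = w > 0.01
    n_eligible = int(eligible.sum())
    voxel_vol = float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))
    # the coarse field is drawn at half resolution and block-upsampled; the
    # light extra smoothing removes the 2-voxel blocking
    low_shape = tuple(-(-s // 2) for s in shape)
    maps = []
    for i in range(n_subjects):
        target_ml = severity_scale * rng.lognormal(np.log(median_volume_ml), log_sd)
        k = int(round(target_ml * 1000.0 / voxel_vol))
        k = min(k, n_eligible)
        data = np.zeros(shape, dtype=np.uint8)
        if k > 0:
            fine = ndimage.gaussian_filter(
                rng.standard_normal(shape, dtype=np.float32), fine_sigma_vox
            )
            fine /= fine.std()
            low = ndimage.gaussian_filter(
                rng.standard_normal(low_shape, dtype=np.float32), coarse_sigma_vox / 2.0
            )
            coarse = low.repeat(2, 0).repeat(2, 1).repeat(2, 2)[
                : shape[0], : shape[1], : shape[2]
            ]
            coarse = ndimage.gaussian_filter(coarse, 1.0)
            coarse /= coarse.std()
            score = w * np.exp(coarse_amp * coarse + fine_amp * fine)
            score[~eligible] = 0.0
            thresh = np.partition(score.ravel(), -k)[-k]
            data = (score >= thresh).astype(np.uint8)
        maps.append(LesionMap(subject_id=f"sub-{i:03d}", data=data, affine=np.asarray(affine)))
    return maps


def generate_covariates(n_subjects: int = 167, seed: int = 0) -> pd.DataFrame:
    """Demographics and imaging markers with the cohort's moments."""
    rng = _subseed(seed, "covariates")
    age = rng.normal(72.8, 9.1, n_subjects)
    sex = (rng.random(n_subjects) < 0.461).astype(int)
    education = np.maximum(rng.normal(6.1, 5.0, n_subjects), 0.0)
    lacunes = (rng.random(n_subjects) < 0.287).astype(int)
    microbleeds = (rng.random(n_subjects) < 0.569).astype(float)
    n_missing_mb = min(4, n_subjects)
    microbleeds[rng.choice(n_subjects, n_missing_mb, replace=False)] = np.nan
    bpf = np.clip(rng.normal(0.64, 0.06, n_subjects), 0.35, 0.95)
    diagnosis = np.where(rng.random(n_subjects) < 0.251, "AD", "other")
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n_subjects)],
            "age": age,
            "sex": sex,
            "education": education,
            "lacunes_present": lacunes,
            "microbleeds_present": microbleeds,
            "bpf": bpf,
            "diagnosis": diagnosis,
        }
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cognition(
    volumes: pd.DataFrame,
    covariates: pd.DataFrame,
    truth: SynthTruth,
    rng: np.random.Generator | None = None,
    cluster_hit: np.ndarray | None = None,
) -> pd.DataFrame:
    """Domain compound scores linear in covariates and tract lesion burden.

    score_d = sum_c beta_c z(covariate_c)
            + sum_t beta_(d,t) z(regional volume_t)
            + cluster shift + Gaussian noise.

    ``cluster_hit`` marks subjects carrying the implanted focal cluster;
    they receive an additional shift of ``truth.cluster_effect_sd`` times
    the noise SD (the focal lesion-symptom signal VLSM should recover).
    """
    if rng is None:
        rng = _subseed(truth.seed, "noise")
    n = len(covariates)
    cov_z = {
        name: _zscore(covariates[name].to_numpy(dtype=float))
        for name in truth.covariate_effects
    }
    out = pd.DataFrame({"subject_id": covariates["subject_id"].to_numpy()})
    for domain, effects in truth.tract_effects.items():
        score = np.zeros(n)
        for name, beta in truth.covariate_effects.items():
            score += beta * cov_z[name]
        for tract, beta in effects.items():
            col = f"wmh_{tract}_ml"
            if col not in volumes.columns:
                raise KeyError(f"truth references tract {tract!r} missing from volumes")
            score += beta * _zscore(volumes[col].to_numpy(dtype=float))
        if cluster_hit is not None and truth.cluster_effect_sd:
            score += truth.cluster_effect_sd * truth.noise_sd * np.where(cluster_hit, -1.0, 0.0)
        score += rng.normal(0.0, truth.noise_sd, n)
        out[domain] = score
    return out


def _implant_cluster(
    maps: list[LesionMap],
    rois: TractROISet,
    rng: np.random.Generator,
    tract: str = "anterior_thalamic_radiation",
    radius_vox: int = 3,
    hit_prob: float = 0.22,
) -> tuple[np.ndarray, np.ndarray]:
    """Plant a coherent focal voxel cluster in a strategic tract.

    A sphere of ``radius_vox`` is centred inside the tract where the
    background lesion prevalence is lowest, so that lesion status at the
    cluster voxels is dominated by cluster carriers rather than diluted by
    incidental blobs; each subject independently carries the whole cluster
    with probability ``hit_prob``. Returns (flat voxel indices, boolean
    per-subject hit vector).
    """
    mask = rois[tract]
    core = ndimage.binary_erosion(mask, iterations=radius_vox)
    if not core.any():
        core = mask
    prev = sum(m.data.astype(np.int32) for m in maps)
    local_prev = ndimage.uniform_filter(prev.astype(float), size=2 * radius_vox + 1)
    ijk = np.argwhere(core)
    centre = ijk[np.argmin(local_prev[tuple(ijk.T)])]
    shape = mask.shape
    grid = np.indices(shape)
    dist2 = sum((grid[d] - centre[d]) ** 2 for d in range(3))
    cluster = dist2 <= radius_vox**2
    flat = np.flatnonzero(cluster.ravel())
    hit = rng.random(len(maps)) < hit_prob
    for m, h in zip(maps, hit):
        if h:
            m.data.ravel()[flat] = 1
    return flat, hit


def simulate_cohort(
    seed: int = 0,
    n_subjects: int = 167,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    truth: SynthTruth | None = None,
    threshold_pct: float = 10.0,
    cluster_effect_sd: float = 0.0,
    severity_scale: float = 1.0,
):
    """Generate a full synthetic cohort end to end.

    Returns ``(maps, atlas, rois, cohort, truth)`` where ``cohort`` is a
    single DataFrame with covariates, total and regional WMH volumes and
    the three domain compound scores — the input shape the regression and
    VLSM model objects expect.
    """
    if truth is None:
        truth = SynthTruth(seed=seed, shape=tuple(shape), cluster_effect_sd=cluster_effect_sd)
    atlas = generate_atlas(shape=shape, seed=seed)
    rois = merge_bilateral(threshold_atlas(atlas, threshold_pct))
    maps = generate_lesions(
        n_subjects=n_subjects, shape=shape, seed=seed, severity_scale=severity_scale
    )
    cluster_hit = None
    if truth.cluster_effect_sd:
        rng_cluster = _subseed(seed, "cluster")
        flat, hit = _implant_cluster(maps, rois, rng_cluster)
        truth.cluster_voxels = [int(v) for v in flat]
        truth.cluster_subjects = [int(i) for i in np.flatnonzero(hit)]
        cluster_hit = hit
    covariates = generate_covariates(n_subjects=n_subjects, seed=seed)
    volumes = regional_volume_table(maps, rois)
    scores = generate_cognition(volumes, covariates, truth, cluster_hit=cluster_hit)
    cohort = covariates.merge(volumes, on="subject_id").merge(scores, on="subject_id")
    return maps, atlas, rois, cohort, truth
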
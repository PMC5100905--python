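"""Monte-Carlo calibration of the screening and mapping pipelines.

These routines quantify, on synthetic cohorts with known ground truth, the
operating characteristics the analysis relies on: power to recover an
implanted strategic-tract effect, per-comparison type-I error at the
Bonferroni threshold, voxelwise sensitivity to a focal lesion-symptom
cluster, and empirical false-discovery proportions under BH-FDR. They are
used by the test suite and the reproduction script; replicate counts are
arguments so callers choose their own precision/runtime trade-off.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import merge_bilateral, threshold_atlas
from .regression import TractScreen, delta_r2_test, fit_ols
from .simulate import (
    SynthTruth,
    _subseed,
    generate_atlas,
    generate_cognition,
    generate_covariates,
    generate_lesions,
    simulate_cohort,
)
from .vlsm import residualize_scores, vlsm_map
from .volumetrics import prevalence_map, regional_volume_table

__all__ = [
    "tract_recovery_rate",
    "null_type1_rate",
    "vlsm_cluster_performance",
    "vlsm_null_fdp",
]


def _spawn_ints(seed: int, n: int, tag: int) -> np.ndarray:
    """Deterministic per-replicate sub-seeds below 2^31."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))
    return rng.integers(0, 2**31 - 1, size=n)


def tract_recovery_rate(
    n_reps: int = 200,
    seed: int = 0,
    effect: float = -0.3,
    tract: str = "anterior_thalamic_radiation",
    outcome: str = "executive",
    n_subjects: int = 167,
) -> dict:
    """Fraction of replicates in which the screen's top delta-R^2 tract is
    the one carrying the implanted standardized effect.

    Each replicate draws a fresh lesion cohort, covariates and noise; the
    atlas (tract geometry) is fixed across replicates.
    """
    atlas = generate_atlas(seed=seed)
    rois = merge_bilateral(threshold_atlas(atlas, 10))
    sub = _spawn_ints(seed, n_reps, tag=1)
    truth_effects = {outcome: {tract: effect}}
    hits = 0
    for r in range(n_reps):
        s = int(sub[r])
        maps = generate_lesions(n_subjects=n_subjects, seed=s)
        cov = generate_covariates(n_subjects=n_subjects, seed=s)
        vols = regional_volume_table(maps, rois)
        truth = SynthTruth(seed=s, tract_effects=truth_effects)
        scores = generate_cognition(vols, cov, truth)
        cohort = cov.merge(vols, on="subject_id").merge(scores, on="subject_id")
        res = TractScreen(cohort, outcomes=(outcome,)).fit()
        hits += res.top_tract(outcome) == tract
    return {"rate": hits / n_reps, "n_reps": n_reps, "tract": tract}


def null_type1_rate(
    n_draws: int = 2200,
    seed: int = 0,
    alpha: float = 0.05,
    m: int = 13,
    n_subjects: int = 167,
) -> dict:
    """Per-comparison type-I error of the tract delta-R^2 test at alpha/m.

    The lesion cohort (hence the design matrix) is fixed; each draw
    generates scores with no lesion-location effect, fits model 2 and one
    tract model (tracts cycled), and records whether p(dR^2) falls below
    the Bonferroni threshold. Draws are mutually independent, so the count
    is binomial under correct calibration.
    """
    atlas = generate_atlas(seed=seed)
    rois = merge_bilateral(threshold_atlas(atlas, 10))
    maps = generate_lesions(n_subjects=n_subjects, seed=seed)
    cov = generate_covariates(n_subjects=n_subjects, seed=seed)
    vols = regional_volume_table(maps, rois)
    data = cov.merge(vols, on="subject_id")
    covariate_cols = ["age", "sex", "education", "lacunes_present", "total_wmh_ml"]
    tract_cols = [c for c in vols.columns if c.startswith("wmh_")]
    truth = SynthTruth(seed=seed, tract_effects={"score": {}})
    threshold = alpha / m
    rng = _subseed(seed, "noise")
    rejections = 0
    for d in range(n_draws):
        scores = generate_cognition(vols, cov, truth, rng=rng)
        y = scores["score"]
        tract_col = tract_cols[d % len(tract_cols)]
        small = fit_ols(y, data[covariate_cols])
        big = fit_ols(y, data[covariate_cols + [tract_col]])
        _, _, p = delta_r2_test(small, big)
        rejections += p < threshold
    return {
        "rate": rejections / n_draws,
        "n_draws": n_draws,
        "threshold": threshold,
        "se": float(np.sqrt(threshold * (1 - threshold) / n_draws)),
    }


def _cluster_scores(cov, truth, hit, rng):
    """Scores with covariate effects plus the focal-cluster shift."""
    n = len(cov)
    vols = pd.DataFrame({"subject_id": cov["subject_id"]})
    score_truth = SynthTruth(
        seed=truth.seed,
        tract_effects={"score": {}},
        covariate_effects=truth.covariate_effects,
        noise_sd=truth.noise_sd,
        cluster_effect_sd=truth.cluster_effect_sd,
    )
    return generate_cognition(vols, cov, score_truth, rng=rng, cluster_hit=hit)["score"]


def vlsm_cluster_performance(
    seed: int = 0,
    n_reps: int = 20,
    n_subjects: int = 167,
    effect_sd: float = 1.5,
    min_subjects: int = 10,
    q: float = 0.05,
) -> dict:
    """Sensitivity and false-discovery proportion for an implanted cluster.

    One lesion cohort carries a coherent voxel cluster inside the anterior
    thalamic radiation whose carriers' scores are shifted by
    ``effect_sd`` noise-SDs. Scores (not lesions) are redrawn per
    replicate. Sensitivity is the fraction of tested cluster voxels
    declared significant. For the false-discovery proportion, a
    significant voxel counts as false when its lesion pattern is
    essentially uncorrelated with cluster-carrier status (|r| < 0.1) —
    voxels whose lesion status tracks the carriers are genuinely
    score-associated under this generative model and are not false
    positives.
    """
    maps, _, rois, cohort, truth = simulate_cohort(
        seed=seed, n_subjects=n_subjects, cluster_effect_sd=effect_sd
    )
    hit = np.zeros(n_subjects, dtype=bool)
    hit[truth.cluster_subjects] = True
    prev = prevalence_map(maps)
    cov_table = cohort[["age", "sex", "education"]]
    cluster = np.array(truth.cluster_voxels)

    # per-voxel correlation of lesion status with carrier status
    lesions = np.stack([m.data.ravel() for m in maps]).astype(float)
    hz = (hit - hit.mean()) / hit.std()
    with np.errstate(invalid="ignore"):
        ls = lesions.std(axis=0)
        corr = np.abs((lesions - lesions.mean(0)).T @ hz) / (len(hit) * np.where(ls > 0, ls, np.inf))
    null_voxels = corr < 0.1

    rng = _subseed(seed, "noise")
    sens, fdps = [], []
    for _ in range(n_reps):
        scores = _cluster_scores(cohort, truth, hit, rng)
        resid = residualize_scores(scores, cov_table).to_numpy()
        res = vlsm_map(maps, resid, min_subjects=min_subjects, q=q, prevalence=prev)
        sig = res.significant.ravel()
        tested = res.tested.ravel()
        cl_tested = cluster[tested[cluster]]
        sens.append(sig[cl_tested].mean() if len(cl_tested) else np.nan)
        n_sig = sig.sum()
        fdps.append((sig & null_voxels).sum() / n_sig if n_sig else 0.0)
    return {
        "sensitivity": float(np.nanmean(sens)),
        "fdp": float(np.mean(fdps)),
        "n_reps": n_reps,
        "n_cluster_tested": int(len(cl_tested)),
    }


def vlsm_null_fdp(
    seed: int = 0,
    n_reps: int = 200,
    n_subjects: int = 167,
    min_subjects: int = 10,
    q: float = 0.05,
) -> dict:
    """Mean false-discovery proportion when scores are independent of lesions.

    Under the complete null every discovery is false, so the per-replicate
    FDP is 1 when anything is rejected and 0 otherwise; its mean is the
    empirical FDR, which BH should keep at or below q.
    """
    maps, _, _, cohort, truth = simulate_cohort(seed=seed, n_subjects=n_subjects)
    prev = prevalence_map(maps)
    cov_table = cohort[["age", "sex", "education"]]
    vols = pd.DataFrame({"subject_id": cohort["subject_id"]})
    null_truth = SynthTruth(seed=seed, tract_effects={"score": {}},
                            covariate_effects=truth.covariate_effects,
                            noise_sd=truth.noise_sd)
    rng = _subseed(seed, "noise")
    fdps = []
    for _ in range(n_reps):
        scores = generate_cognition(vols, cohort, null_truth, rng=rng)["score"]
        resid = residualize_scores(scores, cov_table).to_numpy()
        res = vlsm_map(maps, resid, min_subjects=min_subjects, q=q, prevalence=prev)
        fdps.append(1.0 if res.n_significant else 0.0)
    return {"fdr": float(np.mean(fdps)), "n_reps": n_reps,
            "se": float(np.sqrt(q * (1 - q) / n_reps))}
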
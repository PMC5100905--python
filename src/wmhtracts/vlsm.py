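"""Voxel-based lesion-symptom mapping (VLSM).

At every voxel lesioned in enough subjects, subjects are split into
lesion-present vs lesion-absent groups and their (covariate-residualised)
cognitive scores are compared with the Brunner-Munzel rank test — a
two-sample test of the stochastic-superiority probability
P(X < Y) + 0.5 P(X = Y) that remains valid under unequal variances.
Voxelwise p-values are corrected with the Benjamini-Hochberg step-up
procedure over the tested-voxel family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .io import LesionMap, TractROISet
from .regression import fit_ols
from .volumetrics import PrevalenceMap, prevalence_map, tested_voxel_mask

__all__ = [
    "BrunnerMunzelOutcome",
    "brunner_munzel",
    "fdr_bh",
    "residualize_scores",
    "vlsm_map",
    "tract_voxel_summary",
    "VLSM",
    "VLSMResult",
]

#: Degrees-of-freedom floor; below this the t-approximation is meaningless.
DF_FLOOR = 2.0


@dataclass
class BrunnerMunzelOutcome:
    statistic: float
    df: float
    p_value: float
    p_hat: float  # estimate of P(A < B) + 0.5 P(A = B)
    degenerate: bool = False


def _bm_core(ra, rb, wa, wb, sided: str) -> BrunnerMunzelOutcome:
    """Brunner-Munzel from pooled (ra, rb) and within-group (wa, wb) mid-ranks."""
    na, nb = len(ra), len(rb)
    n = na + nb
    ra_bar, rb_bar = ra.mean(), rb.mean()
    # rank-based variances: pooled minus within-group ranks, n_k - 1 denominator
    da = ra - wa - ra_bar + (na + 1) / 2.0
    db = rb - wb - rb_bar + (nb + 1) / 2.0
    s2a = (da @ da) / (na - 1)
    s2b = (db @ db) / (nb - 1)
    p_hat = (rb_bar - (nb + 1) / 2.0) / na
    pooled = na * s2a + nb * s2b
    if pooled <= 0:
        # complete separation or all-tied groups: no finite statistic exists
        return BrunnerMunzelOutcome(np.nan, np.nan, np.nan, float(p_hat), degenerate=True)
    stat = (rb_bar - ra_bar) * na * nb / (n * np.sqrt(pooled))
    df = pooled**2 / ((na * s2a) ** 2 / (na - 1) + (nb * s2b) ** 2 / (nb - 1))
    df = max(float(df), DF_FLOOR)
    if sided == "two":
        p = 2.0 * stats.t.sf(abs(stat), df)
    elif sided == "less":  # lesion-present scores stochastically smaller
        p = stats.t.cdf(stat, df)
    else:
        raise ValueError("sided must be 'two' or 'less'")
    return BrunnerMunzelOutcome(float(stat), df, float(min(p, 1.0)), float(p_hat))


def brunner_munzel(a, b, sided: str = "two") -> BrunnerMunzelOutcome:
    """Brunner-Munzel test of group ``b`` being stochastically larger than ``a``.

    Mid-ranks are used for ties; the null distribution is approximated by a
    t distribution with Satterthwaite-type degrees of freedom. Degenerate
    inputs (both rank variances zero, e.g. complete separation) are
    flagged rather than assigned a p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = rankdata(np.concatenate([a, b]))
    return _bm_core(pooled[: len(a)], pooled[len(a):], rankdata(a), rankdata(b), sided)


def _bm_vectorized(scores: np.ndarray, lesions: np.ndarray, sided: str):
    """Brunner-Munzel across many voxels at once (tie-free scores).

    ``lesions`` is a subjects x voxels boolean matrix; the pooled sample is
    the same score vector at every voxel, so pooled ranks are shared and
    within-group ranks reduce to cumulative counts in score order.
    Returns (statistic, df, p, p_hat) arrays with NaN statistic/p at
    degenerate voxels.
    """
    n, n_vox = lesions.shape
    order = np.argsort(scores)
    ls = lesions[order].astype(np.float64)  # sorted by score, members of b
    la = 1.0 - ls
    r = np.arange(1, n + 1, dtype=np.float64)[:, None]  # pooled ranks, no ties
    nb = ls.sum(axis=0)
    na = n - nb
    wb = np.cumsum(ls, axis=0)  # within-group rank for members of b
    wa = np.cumsum(la, axis=0)
    rb_bar = (r * ls).sum(axis=0) / nb
    ra_bar = (r * la).sum(axis=0) / na
    db = r - wb
    da = r - wa
    mb = rb_bar - (nb + 1) / 2.0
    ma = ra_bar - (na + 1) / 2.0
    sum_db = (db * ls).sum(axis=0)
    sum_db2 = (db * db * ls).sum(axis=0)
    sum_da = (da * la).sum(axis=0)
    sum_da2 = (da * da * la).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2b = (sum_db2 - 2 * mb * sum_db + nb * mb**2) / (nb - 1)
        s2a = (sum_da2 - 2 * ma * sum_da + na * ma**2) / (na - 1)
        pooled = na * s2a + nb * s2b
        p_hat = mb / na
        stat = (rb_bar - ra_bar) * na * nb / (n * np.sqrt(pooled))
        df = pooled**2 / ((na * s2a) ** 2 / (na - 1) + (nb * s2b) ** 2 / (nb - 1))
    degenerate = ~(pooled > 0)
    df = np.maximum(df, DF_FLOOR)
    if sided == "two":
        p = 2.0 * stats.t.sf(np.abs(stat), df)
    elif sided == "less":
        p = stats.t.cdf(stat, df)
    else:
        raise ValueError("sided must be 'two' or 'less'")
    p = np.minimum(p, 1.0)
    stat[degenerate] = np.nan
    df[degenerate] = np.nan
    p[degenerate] = np.nan
    return stat, df, p, p_hat


#: cache of permutation null tables keyed by (n_total, n_lesioned, n_perm)
_PERM_NULL_CACHE: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray, int]] = {}


def _perm_null_stats(n: int, nb: int, n_perm: int = 20000):
    """Permutation null of the BM statistic for group sizes (n-nb, nb).

    With tie-free scores the statistic depends on the data only through
    which pooled ranks fall in the lesion group, so its permutation
    distribution is universal given (n, nb) and can be shared across
    voxels, outcomes and replicates. Returns (sorted statistics, sorted
    absolute statistics, number of degenerate permutations); degenerate
    draws (complete separation) count as more extreme than any finite
    statistic.
    The table RNG is fixed: this is a numerical calibration table, not a
    source of experimental randomness.
    """
    key = (n, nb, n_perm)
    if key in _PERM_NULL_CACHE:
        return _PERM_NULL_CACHE[key]
    rng = np.random.default_rng(np.random.SeedSequence([987654321, n, nb, n_perm]))
    scores = np.arange(1, n + 1, dtype=float)  # any tie-free vector is equivalent
    draws = rng.random((n, n_perm)).argpartition(nb - 1, axis=0) < nb
    stat, _, _, _ = _bm_vectorized(scores, draws, "two")
    finite = stat[np.isfinite(stat)]
    n_degen = int(n_perm - finite.size)
    tables = (np.sort(finite), np.sort(np.abs(finite)), n_degen)
    _PERM_NULL_CACHE[key] = tables
    return tables


def _permutation_p(stat: np.ndarray, nb: np.ndarray, n: int, sided: str,
                   n_perm: int = 20000) -> np.ndarray:
    """Monte-Carlo permutation p-values for BM statistics, grouped by nb."""
    p = np.full(stat.shape, np.nan)
    for size in np.unique(nb[np.isfinite(stat)]):
        signed, absolute, n_degen = _perm_null_stats(n, int(size), n_perm)
        sel = (nb == size) & np.isfinite(stat)
        s = stat[sel]
        if sided == "two":
            count = absolute.size - np.searchsorted(absolute, np.abs(s), side="left")
        else:  # lesion-present stochastically smaller -> left tail
            count = np.searchsorted(signed, s, side="right")
        p[sel] = (1.0 + count + n_degen) / (n_perm + 1.0)
    return p


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over ``p_values``.

    Returns (boolean reject flags, critical p). The critical p is the
    largest p_(k) with p_(k) <= k*q/m; NaN when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), float("nan")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = q * (np.arange(1, m + 1)) / m
    ok = p[order] <= thresholds
    if not ok.any():
        return np.zeros(m, dtype=bool), float("nan")
    k = np.max(np.nonzero(ok)[0])
    crit = p[order][k]
    return p <= crit, float(crit)


def residualize_scores(y: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """Residuals of ``y`` regressed on covariates plus intercept.

    This is the "individualised correction" applied before the voxel loop:
    each subject's score is replaced by the part not explained by age, sex
    and education (optionally also total WMH volume and lacunes).
    """
    fit = fit_ols(y, covariates)
    return pd.Series(fit.result.resid, index=y.index, name=y.name)


@dataclass
class VLSMResult:
    """Voxelwise lesion-symptom maps and the masks derived from them."""

    statistic: np.ndarray = field(repr=False)
    df: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    p_hat: np.ndarray = field(repr=False)
    tested: np.ndarray = field(repr=False)
    significant: np.ndarray = field(repr=False)
    affine: np.ndarray = field(repr=False)
    q: float
    min_subjects: int
    sided: str
    p_method: str
    n_tested: int
    n_significant: int
    n_degenerate: int
    critical_p: float

    def summary(self) -> str:
        return (
            f"Voxel-based lesion-symptom mapping (Brunner-Munzel {self.p_method}, BH-FDR)\n"
            f"  tested voxels (lesioned in >= {self.min_subjects}): {self.n_tested}\n"
            f"  degenerate voxels excluded from FDR family: {self.n_degenerate}\n"
            f"  significant voxels at q = {self.q}: {self.n_significant}"
            + (f" (critical p = {self.critical_p:.3g})" if self.n_significant else "")
        )

    def to_nifti(self, out_dir, prefix: str = "vlsm") -> None:
        import nibabel as nib
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, arr in (
            ("stat", self.statistic),
            ("p", self.p),
            ("tested", self.tested.astype(np.uint8)),
            ("significant", self.significant.astype(np.uint8)),
        ):
            nib.save(
                nib.Nifti1Image(np.asarray(arr, dtype=np.float32), self.affine),
                str(out_dir / f"{prefix}_{name}.nii.gz"),
            )


def vlsm_map(
    maps: Sequence[LesionMap],
    scores: Sequence[float],
    min_subjects: int = 10,
    q: float = 0.05,
    sided: str = "two",
    prevalence: PrevalenceMap | None = None,
    p_method: str = "permutation",
) -> VLSMResult:
    """Run the full voxelwise lesion-symptom analysis.

    ``scores`` are the (already residualised) cognitive scores, aligned
    with ``maps``. Voxels lesioned in fewer than ``min_subjects`` subjects
    are not tested; voxels with a degenerate rank variance are excluded
    from the FDR family and counted separately.

    ``p_method`` selects the null calibration of the BM statistic:
    ``"permutation"`` (default) draws the statistic's exact randomisation
    distribution conditional on the lesion count at each voxel, which
    keeps the FDR family honest — the classical t approximation
    (``"t"``) is badly anticonservative in the far tail when only ~10
    subjects carry a lesion, and a mass-univariate FDR procedure lives in
    exactly that tail. Scores with ties fall back to the t approximation.
    """
    scores = np.asarray(scores, dtype=float)
    if len(maps) != len(scores):
        raise ValueError("maps and scores must be index-aligned")
    if np.isnan(scores).any():
        raise ValueError("scores contain missing values")
    if np.ptp(scores) == 0:
        raise ValueError("scores are constant; every voxel would be degenerate")
    prev = prevalence if prevalence is not None else prevalence_map(maps)
    tested = tested_voxel_mask(prev, min_subjects)
    # also require at least min(2, ...) lesion-absent subjects for a two-sample test
    tested &= prev.counts <= len(maps) - 2
    if not tested.any():
        raise ValueError(f"no voxel lesioned in >= {min_subjects} subjects")

    idx = np.flatnonzero(tested.ravel())
    lesions = np.stack([m.data.ravel()[idx] for m in maps])  # subjects x voxels

    shape = prev.counts.shape
    stat = np.full(shape, np.nan).ravel()
    dfm = np.full(shape, np.nan).ravel()
    pmap = np.full(shape, np.nan).ravel()
    phat = np.full(shape, np.nan).ravel()

    if p_method not in ("permutation", "t"):
        raise ValueError("p_method must be 'permutation' or 't'")
    if np.unique(scores).size == scores.size:
        s, d, p, ph = _bm_vectorized(scores, lesions.astype(bool), sided)
        if p_method == "permutation":
            p = _permutation_p(s, lesions.sum(axis=0), len(maps), sided)
        stat[idx], dfm[idx], pmap[idx], phat[idx] = s, d, p, ph
    else:
        pooled_ranks = rankdata(scores)
        # cache per lesion pattern: identical voxel columns share the work
        cache: dict[bytes, BrunnerMunzelOutcome] = {}
        for j, vox in enumerate(idx):
            col = lesions[:, j].astype(bool)
            key = col.tobytes()
            res = cache.get(key)
            if res is None:
                a_scores, b_scores = scores[~col], scores[col]
                res = _bm_core(
                    pooled_ranks[~col], pooled_ranks[col],
                    rankdata(a_scores), rankdata(b_scores), sided,
                )
                cache[key] = res
            stat[vox], dfm[vox], pmap[vox], phat[vox] = (
                res.statistic, res.df, res.p_value, res.p_hat,
            )

    p_tested = pmap[idx]
    valid = ~np.isnan(p_tested)
    n_degenerate = int((~valid).sum())
    flags, crit = fdr_bh(p_tested[valid], q)
    significant = np.zeros(np.prod(shape), dtype=bool)
    significant[idx[valid]] = flags
    return VLSMResult(
        statistic=stat.reshape(shape),
        df=dfm.reshape(shape),
        p=pmap.reshape(shape),
        p_hat=phat.reshape(shape),
        tested=tested,
        significant=significant.reshape(shape),
        affine=prev.affine,
        q=q,
        min_subjects=min_subjects,
        sided=sided,
        p_method=p_method,
        n_tested=int(tested.sum()),
        n_significant=int(flags.sum()),
        n_degenerate=n_degenerate,
        critical_p=crit,
    )


def tract_voxel_summary(
    results: Mapping[str, VLSMResult] | VLSMResult, rois: TractROISet
) -> pd.DataFrame:
    """Region size, tested and significant voxel counts per tract.

    ``results`` may be a single VLSMResult or a mapping outcome -> result
    (yielding one significant-voxel column per outcome). Voxels inside
    overlapping tracts are counted in each tract.
    """
    if isinstance(results, VLSMResult):
        results = {"score": results}
    first = next(iter(results.values()))
    rows = []
    for name in rois.roi_names:
        mask = rois[name]
        row = {
            "tract": name,
            "region_size": int(mask.sum()),
            "tested": int((mask & first.tested).sum()),
        }
        for outcome, res in results.items():
            row[f"significant_{outcome}"] = int((mask & res.significant).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("tract")


class VLSM:
    """Model object bundling maps, scores and covariate correction.

    Parameters
    ----------
    maps
        Cohort lesion maps on a shared grid.
    scores
        Per-subject compound z-scores, aligned with ``maps``.
    covariates
        Optional DataFrame (age, sex, education; optionally total WMH
        volume and lacunes for the extended correction). Scores are
        residualised on these before the voxel loop.
    """

    def __init__(
        self,
        maps: Sequence[LesionMap],
        scores: pd.Series,
        covariates: pd.DataFrame | None = None,
        min_subjects: int = 10,
        q: float = 0.05,
        sided: str = "two",
        p_method: str = "permutation",
    ) -> None:
        self.maps = list(maps)
        self.scores = pd.Series(scores).astype(float)
        self.covariates = covariates
        self.min_subjects = min_subjects
        self.q = q
        self.sided = sided
        self.p_method = p_method
        if len(self.maps) != len(self.scores):
            raise ValueError("maps and scores must have equal length")

    def fit(self) -> VLSMResult:
        scores = self.scores
        if self.covariates is not None:
            scores = residualize_scores(scores, self.covariates)
        return vlsm_map(
            self.maps,
            scores.to_numpy(),
            min_subjects=self.min_subjects,
            q=self.q,
            sided=self.sided,
            p_method=self.p_method,
        )
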
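"""Nested OLS models, incremental-variance (delta R^2) tests and the
tract-screening / marker-comparison model objects.

The screening logic: per cognitive domain, model 1 regresses the compound
z-score on age, sex and education; model 2 adds presence of lacunes and
total WMH volume; models 3a-k each add one tract's regional WMH volume to
model 2. A tract is "strategic" when its delta R^2 over model 2 survives
Bonferroni correction across the 13 comparisons in the table — i.e. its
lesion burden carries information about cognition beyond global lesion
burden. The marker comparison then sizes regional WMH volume against total
WMH volume and brain atrophy (BPF) as predictors of cognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .atlas import CANONICAL_TRACTS

__all__ = [
    "OLSFit",
    "HierModelResult",
    "fit_ols",
    "delta_r2_test",
    "standardized_betas",
    "bonferroni_threshold",
    "TractScreen",
    "TractScreenResults",
    "MarkerComparison",
    "MarkerComparisonResults",
    "run_sensitivity",
]

STRATEGIC_TRACTS = ("forceps_minor", "anterior_thalamic_radiation")


@dataclass
class OLSFit:
    """A fitted linear model plus the data it was fitted on."""

    outcome: str
    predictors: list[str]
    y: pd.Series = field(repr=False)
    X: pd.DataFrame = field(repr=False)
    result: object = field(repr=False)  # statsmodels RegressionResults

    @property
    def n(self) -> int:
        return int(self.result.nobs)

    @property
    def k(self) -> int:
        return len(self.predictors)

    @property
    def r2(self) -> float:
        return float(self.result.rsquared) if self.predictors else 0.0

    @property
    def rss(self) -> float:
        return float(self.result.ssr)

    @property
    def params(self) -> pd.Series:
        return self.result.params


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    scale = X.std(ddof=0).replace(0, 1.0)
    _, R = np.linalg.qr((X / scale).to_numpy())
    diag = np.abs(np.diag(R))
    tol = diag.max() * 1e-8 if diag.size else 0.0
    return [c for c, d in zip(X.columns, diag) if d <= tol]


def fit_ols(y: pd.Series, X: pd.DataFrame) -> OLSFit:
    """Ordinary least squares of ``y`` on ``X`` plus an intercept.

    ``y`` and ``X`` must be complete (no missing values) and index-aligned;
    callers handle complete-case selection so that nested models compare
    the same subjects. Rank deficiency is an error naming the offending
    columns.
    """
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X).astype(float)
    if y.isna().any() or X.isna().any().any():
        raise ValueError("missing values in y or X; select complete cases first")
    if len(y) <= X.shape[1] + 1:
        raise ValueError(
            f"n={len(y)} too small for {X.shape[1]} predictors plus intercept"
        )
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        bad = _collinear_columns(X - X.mean())
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    result = sm.OLS(y, design).fit()
    name = y.name if y.name is not None else "y"
    return OLSFit(outcome=str(name), predictors=list(X.columns), y=y, X=X, result=result)


def delta_r2_test(fit_small: OLSFit, fit_big: OLSFit) -> tuple[float, float, float]:
    """Partial F-test for the variance added by ``fit_big`` over ``fit_small``.

    Returns ``(delta_r2, F, p)`` with
    F = (dR^2 / df_delta) / ((1 - R^2_big) / (n - k_big - 1)).
    """
    if not set(fit_small.predictors) <= set(fit_big.predictors):
        raise ValueError("models are not nested (small's predictors not a subset)")
    if fit_small.n != fit_big.n or not fit_small.y.index.equals(fit_big.y.index):
        raise ValueError("nested models must be fitted on the same subjects")
    df_delta = fit_big.k - fit_small.k
    if df_delta == 0:
        return 0.0, 0.0, 1.0
    n, k_big = fit_big.n, fit_big.k
    dr2 = fit_big.r2 - fit_small.r2
    df_resid = n - k_big - 1
    denom = (1.0 - fit_big.r2) / df_resid
    if denom <= 0:  # saturated fit: big model explains everything
        return dr2, np.inf, 0.0
    f_stat = (dr2 / df_delta) / denom
    f_stat = max(f_stat, 0.0)  # clip numerical negatives of order eps
    p = float(stats.f.sf(f_stat, df_delta, df_resid))
    return float(dr2), float(f_stat), p


def standardized_betas(fit: OLSFit, ci_mult: float = 1.96) -> pd.DataFrame:
    """Standardized coefficients with 95% CIs.

    beta = b * SD(x) / SD(y); the CI uses the same rescaling of the
    coefficient standard error, with a normal 1.96 multiplier.
    """
    sd_y = fit.y.std(ddof=1)
    rows = []
    for name in fit.predictors:
        sd_x = fit.X[name].std(ddof=1)
        if not sd_x > 0:
            raise ValueError(f"predictor {name!r} has zero variance")
        scale = sd_x / sd_y
        beta = fit.result.params[name] * scale
        se = fit.result.bse[name] * scale
        rows.append(
            {
                "predictor": name,
                "beta": float(beta),
                "ci_low": float(beta - ci_mult * se),
                "ci_high": float(beta + ci_mult * se),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def bonferroni_threshold(alpha: float = 0.05, m: int = 13) -> float:
    """Per-comparison threshold alpha / m (13 comparisons in the tract table)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class HierModelResult:
    """One row of a nested-model comparison table."""

    model_id: str
    outcome: str
    predictors: list[str]
    n: int
    r2: float
    delta_r2: float
    f_stat: float
    p_delta: float
    parent_id: str | None
    betas: pd.DataFrame | None = field(default=None, repr=False)
    significant: bool | None = None

    def beta_of(self, predictor: str) -> tuple[float, float, float]:
        row = self.betas.loc[predictor]
        return float(row.beta), float(row.ci_low), float(row.ci_high)


def _null_fit(y: pd.Series) -> OLSFit:
    X0 = pd.DataFrame(index=y.index)
    design = pd.DataFrame({"const": np.ones(len(y))}, index=y.index)
    result = sm.OLS(y.astype(float), design).fit()
    return OLSFit(outcome=str(y.name), predictors=[], y=y.astype(float), X=X0, result=result)


def _compare(model_id, parent_id, fit_small, fit_big, threshold=None) -> HierModelResult:
    dr2, f_stat, p = delta_r2_test(fit_small, fit_big)
    return HierModelResult(
        model_id=model_id,
        outcome=fit_big.outcome,
        predictors=list(fit_big.predictors),
        n=fit_big.n,
        r2=fit_big.r2,
        delta_r2=dr2,
        f_stat=f_stat,
        p_delta=p,
        parent_id=parent_id,
        betas=standardized_betas(fit_big),
        significant=(p < threshold) if threshold is not None else None,
    )


class _ResultsBase:
    """Shared table/summary plumbing for screening results."""

    results: list[HierModelResult]
    title: str = "Nested model comparison"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "model": r.model_id,
                    "outcome": r.outcome,
                    "n": r.n,
                    "r2": r.r2,
                    "delta_r2": r.delta_r2,
                    "f": r.f_stat,
                    "p_delta": r.p_delta,
                    "significant": r.significant,
                    "added": ", ".join(
                        sorted(set(r.predictors) - set(self._parent_predictors(r)))
                    ),
                }
            )
        return pd.DataFrame(rows)

    def _parent_predictors(self, r: HierModelResult) -> list[str]:
        if r.parent_id is None:
            return []
        for cand in self.results:
            if cand.model_id == r.parent_id and cand.outcome == r.outcome:
                return cand.predictors
        return []

    def get(self, model_id: str, outcome: str) -> HierModelResult:
        for r in self.results:
            if r.model_id == model_id and r.outcome == outcome:
                return r
        raise KeyError(f"no result for model {model_id!r}, outcome {outcome!r}")

    def summary(self) -> str:
        df = self.to_frame()
        lines = [self.title, "=" * len(self.title)]
        for outcome, block in df.groupby("outcome", sort=False):
            lines.append(f"\nOutcome: {outcome} (n = {block['n'].iloc[0]})")
            lines.append(f"{'model':<8}{'R2':>8}{'dR2':>8}{'p(dR2)':>10}  added")
            for _, row in block.iterrows():
                star = " *" if row.significant else ""
                lines.append(
                    f"{row.model:<8}{row.r2:>8.3f}{row.delta_r2:>8.3f}"
                    f"{row.p_delta:>10.4g}{star}  {row.added}"
                )
        return "\n".join(lines)


@dataclass
class TractScreenResults(_ResultsBase):
    results: list[HierModelResult]
    bonferroni_p: float
    title: str = "Tract WMH-volume screen (nested OLS, delta R^2)"

    def significant_tracts(self, outcome: str) -> list[str]:
        out = []
        for r in self.results:
            if r.outcome == outcome and r.model_id.startswith("3") and r.significant:
                out.append(r.model_id.split(":", 1)[1])
        return out

    def top_tract(self, outcome: str) -> str:
        """Tract with the largest delta R^2 over model 2 for this outcome."""
        tract_rows = [
            r for r in self.results if r.outcome == outcome and r.model_id.startswith("3")
        ]
        if not tract_rows:
            raise ValueError(f"no tract models for outcome {outcome!r}")
        best = max(tract_rows, key=lambda r: r.delta_r2)
        return best.model_id.split(":", 1)[1]


class TractScreen:
    """Screen tract-wise WMH volumes for association with cognition.

    Parameters
    ----------
    data
        One row per subject with the outcome z-scores, covariates,
        ``total_wmh_ml`` and one ``wmh_<tract>_ml`` column per tract.
    outcomes
        Compound-score columns to analyse (default executive, speed, memory).
    tracts
        Tract names; default the 11 canonical tracts.
    alpha, m_comparisons
        Family-wise error level and Bonferroni divisor (13: models 1, 2 and
        the 11 tract models in the reporting table).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcomes: Sequence[str] = ("executive", "speed", "memory"),
        covariates: Sequence[str] = ("age", "sex", "education"),
        markers: Sequence[str] = ("lacunes_present", "total_wmh_ml"),
        tracts: Sequence[str] = CANONICAL_TRACTS,
        alpha: float = 0.05,
        m_comparisons: int = 13,
    ) -> None:
        self.data = data
        self.outcomes = list(outcomes)
        self.covariates = list(covariates)
        self.markers = list(markers)
        self.tracts = list(tracts)
        self.alpha = alpha
        self.m_comparisons = m_comparisons
        missing_tracts = [t for t in self.tracts if f"wmh_{t}_ml" not in data.columns]
        if missing_tracts:
            raise KeyError(f"cohort table lacks regional volumes for: {missing_tracts}")

    def fit(self) -> TractScreenResults:
        threshold = bonferroni_threshold(self.alpha, self.m_comparisons)
        tract_cols = [f"wmh_{t}_ml" for t in self.tracts]
        results: list[HierModelResult] = []
        for outcome in self.outcomes:
            cols = [outcome, *self.covariates, *self.markers, *tract_cols]
            d = self.data[cols].dropna()
            y = d[outcome]
            fit0 = _null_fit(y)
            fit1 = fit_ols(y, d[self.covariates])
            results.append(_compare("1", None, fit0, fit1, threshold))
            fit2 = fit_ols(y, d[self.covariates + self.markers])
            results.append(_compare("2", "1", fit1, fit2, threshold))
            for letter, tract in zip("abcdefghijk", self.tracts):
                fit3 = fit_ols(y, d[self.covariates + self.markers + [f"wmh_{tract}_ml"]])
                results.append(_compare(f"3{letter}:{tract}", "2", fit2, fit3, threshold))
        return TractScreenResults(results=results, bonferroni_p=threshold)


@dataclass
class MarkerComparisonResults(_ResultsBase):
    results: list[HierModelResult]
    single_marker: list[HierModelResult] = field(default_factory=list)
    bpf_association: list[HierModelResult] = field(default_factory=list)
    title: str = "Imaging-marker comparison (WMH volumes vs brain atrophy)"


class MarkerComparison:
    """Compare global WMH volume, strategic-tract WMH volume and atrophy.

    Builds, per outcome: model 1 (age, sex, education); models 2a-d adding
    one marker each (total WMH, forceps minor WMH, anterior thalamic
    radiation WMH, BPF); models 3a-c adding each WMH measure on top of the
    BPF model 2d. Lacunes and microbleeds enter single-marker models only
    (their beta and CI are reported; microbleed models are complete-case on
    microbleed status). ``fit_bpf_association`` regresses BPF itself on
    each WMH measure with age, sex, education, lacunes and microbleeds as
    covariates, one marker per model.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcomes: Sequence[str] = ("executive", "speed", "memory"),
        covariates: Sequence[str] = ("age", "sex", "education"),
        strategic_tracts: Sequence[str] = STRATEGIC_TRACTS,
    ) -> None:
        self.data = data
        self.outcomes = list(outcomes)
        self.covariates = list(covariates)
        self.strategic_tracts = list(strategic_tracts)
        if "bpf" not in data.columns:
            raise KeyError("marker comparison requires a 'bpf' column")

    @property
    def _wmh_measures(self) -> list[str]:
        return ["total_wmh_ml"] + [f"wmh_{t}_ml" for t in self.strategic_tracts]

    def fit(self) -> MarkerComparisonResults:
        markers_2 = self._wmh_measures + ["bpf"]
        results: list[HierModelResult] = []
        single: list[HierModelResult] = []
        for outcome in self.outcomes:
            cols = [outcome, *self.covariates, *markers_2]
            d = self.data[cols].dropna()
            y = d[outcome]
            fit1 = fit_ols(y, d[self.covariates])
            results.append(_compare("1", None, _null_fit(y), fit1, 0.05))
            for letter, marker in zip("abcd", markers_2):
                fitm = fit_ols(y, d[self.covariates + [marker]])
                results.append(_compare(f"2{letter}:{marker}", "1", fit1, fitm, 0.05))
            fit2d = fit_ols(y, d[self.covariates + ["bpf"]])
            for letter, marker in zip("abc", self._wmh_measures):
                fit3 = fit_ols(y, d[self.covariates + ["bpf", marker]])
                results.append(_compare(f"3{letter}:{marker}", "2d:bpf", fit2d, fit3, 0.05))
            # single-marker models for the focal-lesion markers
            for marker in ("lacunes_present", "microbleeds_present"):
                if marker not in self.data.columns:
                    continue
                dm = self.data[[outcome, *self.covariates, marker]].dropna()
                ym = dm[outcome]
                f_small = fit_ols(ym, dm[self.covariates])
                f_big = fit_ols(ym, dm[self.covariates + [marker]])
                single.append(_compare(f"single:{marker}", None, f_small, f_big, 0.05))
        bpf_assoc = self.fit_bpf_association()
        return MarkerComparisonResults(
            results=results, single_marker=single, bpf_association=bpf_assoc
        )

    def fit_bpf_association(self) -> list[HierModelResult]:
        out: list[HierModelResult] = []
        covs = self.covariates + [
            c for c in ("lacunes_present", "microbleeds_present") if c in self.data.columns
        ]
        for marker in self._wmh_measures:
            cols = ["bpf", *covs, marker]
            d = self.data[cols].dropna()
            y = d["bpf"]
            f_small = fit_ols(y, d[covs])
            f_big = fit_ols(y, d[covs + [marker]])
            out.append(_compare(f"bpf~{marker}", None, f_small, f_big, 0.05))
        return out


def run_sensitivity(
    data: pd.DataFrame,
    diagnosis_col: str = "diagnosis",
    exclude: str = "AD",
    **kwargs,
) -> MarkerComparisonResults:
    """Marker comparison restricted to subjects without the given diagnosis."""
    if diagnosis_col not in data.columns:
        raise KeyError(f"no {diagnosis_col!r} column for the sensitivity analysis")
    subset = data[data[diagnosis_col] != exclude]
    return MarkerComparison(subset, **kwargs).fit()
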
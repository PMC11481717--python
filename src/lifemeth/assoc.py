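"""Associations of top DMPs, the lifestyle index and its components with
T2DM (logistic regression) and the glycaemic markers FBG and HbA1c
(linear regression), in base (unadjusted) and adjusted (age, sex, site,
BMI) models.

Methylation predictors are reported either per 1% beta increase
(betas × 100) or after a rank-based inverse-normal transform; both
conventions appear in routine EWAS follow-up reporting, so the scaling
is an explicit argument rather than a silent default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "AssociationResult",
    "SeparationError",
    "inverse_normal_transform",
    "fit_logistic",
    "fit_linear",
    "associate_predictors",
    "association_table",
]

ADJUSTED_COVARIATES = ["age", "sex", "site", "bmi"]
OUTCOMES = {"t2dm": "logistic", "fbg": "linear", "hba1c": "linear"}


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class AssociationResult:
    predictor: str
    outcome: str
    model: str  # "base" | "adjusted"
    estimate: float  # OR for logistic, slope for linear
    ci_low: float
    ci_high: float
    p: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("estimate outside its confidence interval")


def inverse_normal_transform(values) -> np.ndarray:
    """Blom rank-based inverse-normal transform, Φ⁻¹((r − 3/8)/(n + 1/4)).

    Ties receive average ranks.  The result is strictly monotone in the
    input ranks, so any monotone rescaling of the input maps to the same
    output.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("inverse-normal transform needs >= 2 distinct values")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.375) / (v.size + 0.25))


def _design(predictor: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    cols = [np.ones_like(predictor, dtype=float), predictor.astype(float)]
    names = ["intercept", "predictor"]
    if covariates is not None:
        for c in covariates.columns:
            v = covariates[c]
            if v.dtype == object or str(v.dtype) == "category" or v.dtype == bool:
                dummies = pd.get_dummies(v, prefix=c, drop_first=True)
                for name in dummies.columns:
                    cols.append(dummies[name].to_numpy(float))
                    names.append(str(name))
            else:
                cols.append(v.to_numpy(float))
                names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear design in association model: {names}")
    return X


def fit_logistic(
    outcome,
    predictor,
    covariates: pd.DataFrame | None = None,
    predictor_name: str = "predictor",
    outcome_name: str = "t2dm",
    model_name: str = "base",
) -> AssociationResult:
    """Logistic regression of a binary outcome on one predictor.

    Maximum likelihood via iteratively reweighted least squares; the
    estimate is reported as an odds ratio with a Wald 95% interval.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes coded 0/1")
    X = _design(x, covariates)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
    except PerfectSeparationError as err:
        raise SeparationError(str(err)) from err
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError(
            f"logistic fit did not converge in {res.mle_retvals.get('iterations')} "
            "iterations"
        )
    if abs(res.params[1]) > 15:  # log-OR beyond any plausible effect
        raise SeparationError("diverging coefficient suggests separation")
    coef, se = res.params[1], res.bse[1]
    zcrit = stats.norm.ppf(0.975)
    return AssociationResult(
        predictor=predictor_name,
        outcome=outcome_name,
        model=model_name,
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - zcrit * se)),
        ci_high=float(np.exp(coef + zcrit * se)),
        p=float(res.pvalues[1]),
    )


def fit_linear(
    outcome,
    predictor,
    covariates: pd.DataFrame | None = None,
    predictor_name: str = "predictor",
    outcome_name: str = "fbg",
    model_name: str = "base",
) -> AssociationResult:
    """OLS of a continuous outcome on one predictor, 95% t-interval."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    X = _design(x, covariates)
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than observations")
    res = sm.OLS(y, X).fit()
    lo, hi = res.conf_int()[1]
    return AssociationResult(
        predictor=predictor_name,
        outcome=outcome_name,
        model=model_name,
        estimate=float(res.params[1]),
        ci_low=float(lo),
        ci_high=float(hi),
        p=float(res.pvalues[1]),
    )


LIFESTYLE_PREDICTORS = [
    "cli_index",
    "smoking_points",
    "alcohol_points",
    "activity_points",
    "diet_points",
]


def associate_predictors(
    phenotype: pd.DataFrame,
    methylation,
    dmp_ids: list[str],
    scale: str = "per_1pct",
    models: tuple[str, ...] = ("base", "adjusted"),
) -> list[AssociationResult]:
    """Fit every predictor × outcome × model association.

    Predictors are the given DMPs' beta values (scaled per 1% or
    inverse-normal transformed) plus the binary lifestyle index and its
    four component scores.  Outcomes: T2DM (logistic), FBG and HbA1c
    (linear).  The adjusted model controls for age, sex, site and BMI.
    """
    if scale not in ("per_1pct", "inverse_normal"):
        raise ValueError(f"unknown scale {scale!r}")
    missing = [p for p in dmp_ids if p not in set(methylation.probe_ids)]
    if missing:
        raise KeyError(f"probes absent from methylation data: {missing}")
    for col in list(OUTCOMES):
        if col not in phenotype.columns:
            raise ValueError(f"phenotype table lacks outcome column {col!r}")

    pheno = phenotype.loc[list(methylation.sample_ids)]
    predictors: dict[str, np.ndarray] = {}
    for pid in dmp_ids:
        b = methylation.beta.loc[pid].to_numpy(dtype=float)
        predictors[pid] = (
            b * 100.0 if scale == "per_1pct" else inverse_normal_transform(b)
        )
    for name in LIFESTYLE_PREDICTORS:
        if name in pheno.columns:
            predictors[name] = pheno[name].to_numpy(dtype=float)

    cov_adj = pheno[[c for c in ADJUSTED_COVARIATES if c in pheno.columns]]
    results = []
    for name, x in predictors.items():
        for outcome, kind in OUTCOMES.items():
            y = pheno[outcome].to_numpy(dtype=float)
            for model in models:
                cov = cov_adj if model == "adjusted" else None
                fit = fit_logistic if kind == "logistic" else fit_linear
                results.append(
                    fit(
                        y,
                        x,
                        cov,
                        predictor_name=name,
                        outcome_name=outcome,
                        model_name=model,
                    )
                )
    return results


def associate_region(
    phenotype: pd.DataFrame,
    methylation,
    probe_ids: list[str],
    region_name: str = "dmr",
    scale: str = "per_1pct",
    models: tuple[str, ...] = ("base", "adjusted"),
) -> list[AssociationResult]:
    """Region-level association: the mean beta across the region's probes
    is the predictor, fitted against every outcome and model."""
    missing = [p for p in probe_ids if p not in set(methylation.probe_ids)]
    if missing:
        raise KeyError(f"probes absent from methylation data: {missing}")
    pheno = phenotype.loc[list(methylation.sample_ids)]
    b = methylation.beta.loc[probe_ids].mean(axis=0).to_numpy(dtype=float)
    x = b * 100.0 if scale == "per_1pct" else inverse_normal_transform(b)
    cov_adj = pheno[[c for c in ADJUSTED_COVARIATES if c in pheno.columns]]
    results = []
    for outcome, kind in OUTCOMES.items():
        y = pheno[outcome].to_numpy(dtype=float)
        for model in models:
            cov = cov_adj if model == "adjusted" else None
            fit = fit_logistic if kind == "logistic" else fit_linear
            results.append(
                fit(y, x, cov, predictor_name=region_name,
                    outcome_name=outcome, model_name=model)
            )
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "predictor": r.predictor,
                "outcome": r.outcome,
                "model": r.model,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
            }
            for r in results
        ]
    )
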
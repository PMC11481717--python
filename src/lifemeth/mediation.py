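"""Product-of-coefficients mediation of the lifestyle-index → T2DM effect
through DNA methylation, with bootstrap confidence intervals.

Three regressions give the paths: the mediator on the exposure (path a),
the outcome on exposure and mediator jointly (path b and the direct
effect), and the outcome on the exposure alone (total effect).  The
indirect effect is the product a·b; its uncertainty comes from
resampling participants with replacement and recomputing a·b per
replicate (percentile interval).  For a binary outcome the outcome-side
coefficients are on the log-odds scale, so the product is scale-hybrid;
the all-linear identity total = direct + indirect holds only for
continuous outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PathEstimates",
    "MediationResult",
    "estimate_paths",
    "indirect_effect",
    "bootstrap_mediation",
    "run_mediation",
]


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates failed to fit."""


@dataclass(frozen=True)
class PathEstimates:
    path_a: float  # exposure → mediator
    path_b: float  # mediator → outcome, exposure-adjusted
    direct_effect: float  # exposure → outcome holding mediator
    total_effect: float  # exposure → outcome
    p_path_a: float
    p_path_b: float


@dataclass(frozen=True)
class MediationResult:
    mediator: str
    path_a: float
    path_b: float
    direct_effect: float
    indirect_effect: float
    total_effect: float
    ci_low: float
    ci_high: float
    p_indirect: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if abs(self.indirect_effect - self.path_a * self.path_b) > 1e-12 * max(
            1.0, abs(self.indirect_effect)
        ):
            raise ValueError("indirect effect is not the product of the paths")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")


def _with_covariates(cols: list[np.ndarray], covariates) -> np.ndarray:
    X = np.column_stack([np.ones_like(cols[0])] + cols)
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    return X


def _fit_outcome(y: np.ndarray, X: np.ndarray, binary: bool):
    if binary:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("logistic outcome model did not converge")
        return res
    return sm.OLS(y, X).fit()


def estimate_paths(
    exposure,
    mediator,
    outcome,
    covariates=None,
    binary_outcome: bool | None = None,
) -> PathEstimates:
    """Estimate the mediation path coefficients from three regressions.

    ``binary_outcome`` defaults to auto-detection (outcome only takes
    values 0/1 → logistic; otherwise linear).  The mediator model is
    always linear.
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.std(x) == 0:
        raise ValueError("exposure has zero variance")
    if np.std(m) == 0:
        raise ValueError("mediator has zero variance")
    if binary_outcome is None:
        binary_outcome = set(np.unique(y)) <= {0.0, 1.0}

    med_model = sm.OLS(m, _with_covariates([x], covariates)).fit()
    joint = _fit_outcome(y, _with_covariates([x, m], covariates), binary_outcome)
    total = _fit_outcome(y, _with_covariates([x], covariates), binary_outcome)
    return PathEstimates(
        path_a=float(med_model.params[1]),
        path_b=float(joint.params[2]),
        direct_effect=float(joint.params[1]),
        total_effect=float(total.params[1]),
        p_path_a=float(med_model.pvalues[1]),
        p_path_b=float(joint.pvalues[2]),
    )


def indirect_effect(path_a: float, path_b: float) -> float:
    """The product-of-coefficients indirect effect, a·b."""
    if not (np.isfinite(path_a) and np.isfinite(path_b)):
        raise ValueError("path coefficients must be finite")
    return path_a * path_b


def bootstrap_mediation(
    exposure,
    mediator,
    outcome,
    covariates=None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    mediator_name: str = "mediator",
    binary_outcome: bool | None = None,
) -> MediationResult:
    """Percentile-bootstrap mediation analysis.

    Participants are resampled with replacement ``n_boot`` times and the
    indirect effect a·b recomputed per replicate.  Replicates whose fits
    fail (separation, non-convergence, degenerate resample) are dropped
    and counted; more than 10% failures aborts.  The two-sided p-value
    is the add-one-adjusted proportion of replicates crossing zero.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    n = x.size

    point = estimate_paths(x, m, y, cov, binary_outcome)
    rng = np.random.default_rng(seed)
    ab = np.empty(n_boot)
    failures = 0
    kept = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            est = estimate_paths(
                x[idx],
                m[idx],
                y[idx],
                None if cov is None else cov[idx],
                binary_outcome,
            )
            ab[kept] = est.path_a * est.path_b
            kept += 1
        except Exception:
            failures += 1
    if failures > 0.10 * n_boot:
        raise BootstrapError(
            f"{failures}/{n_boot} bootstrap replicates failed to fit"
        )
    ab = ab[:kept]
    lo, hi = np.quantile(ab, [alpha / 2, 1 - alpha / 2])
    n_le = int(np.sum(ab <= 0))
    n_ge = int(np.sum(ab >= 0))
    p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (kept + 1))
    return MediationResult(
        mediator=mediator_name,
        path_a=point.path_a,
        path_b=point.path_b,
        direct_effect=point.direct_effect,
        indirect_effect=indirect_effect(point.path_a, point.path_b),
        total_effect=point.total_effect,
        ci_low=float(lo),
        ci_high=float(hi),
        p_indirect=float(p),
        n_boot=kept,
        seed=seed,
    )


def run_mediation(
    phenotype: pd.DataFrame,
    methylation,
    dmp_ids: list[str],
    n_boot: int = 1000,
    seed: int = 0,
    exposure: str = "cli_index",
    outcome: str = "t2dm",
    covariates: list[str] | None = None,
) -> list[MediationResult]:
    """Mediation of exposure → outcome through each DMP and their mean beta.

    Returns one result per DMP plus one for the across-DMP mean beta
    (``mean_top_dmps``): |dmp_ids| + 1 rows.
    """
    missing = [p for p in dmp_ids if p not in set(methylation.probe_ids)]
    if missing:
        raise KeyError(f"probes absent from methylation data: {missing}")
    pheno = phenotype.loc[list(methylation.sample_ids)]
    x = pheno[exposure].to_numpy(dtype=float)
    y = pheno[outcome].to_numpy(dtype=float)
    cov = (
        pheno[covariates].to_numpy(dtype=float) if covariates else None
    )

    mediators = {
        pid: methylation.beta.loc[pid].to_numpy(dtype=float) for pid in dmp_ids
    }
    mediators["mean_top_dmps"] = (
        methylation.beta.loc[dmp_ids].mean(axis=0).to_numpy(dtype=float)
    )
    return [
        bootstrap_mediation(
            x, m, y, cov, n_boot=n_boot, seed=seed, mediator_name=name
        )
        for name, m in mediators.items()
    ]


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mediator": r.mediator,
                "path_a": r.path_a,
                "path_b": r.path_b,
                "direct_effect": r.direct_effect,
                "indirect_effect": r.indirect_effect,
                "total_effect": r.total_effect,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_indirect": r.p_indirect,
                "n_boot": r.n_boot,
            }
            for r in results
        ]
    )


def path_diagram(result: MediationResult) -> str:
    """Plain-text summary of the mediation decomposition."""
    return (
        f"mediator: {result.mediator}\n"
        f"  exposure -> mediator (a):      {result.path_a:+.4g}\n"
        f"  mediator -> outcome (b):       {result.path_b:+.4g}\n"
        f"  direct effect (c'):            {result.direct_effect:+.4g}\n"
        f"  indirect effect (a*b):         {result.indirect_effect:+.4g}\n"
        f"  total effect (c):              {result.total_effect:+.4g}\n"
        f"  95% bootstrap CI (indirect):   [{result.ci_low:.4g}, {result.ci_high:.4g}]\n"
        f"  p (indirect, {result.n_boot} replicates): {result.p_indirect:.3g}\n"
    )
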
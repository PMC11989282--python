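"""Kaplan-Meier estimation and penalized Weibull AFT regression.

The PFS model is an accelerated failure time model with Weibull baseline:
log T = intercept + x'beta + error, fitted by lifelines with an L2 penalty on
the covariate coefficients. The penalizer is chosen automatically by AIC over
a small grid, with the AIC computed from the unpenalized log-likelihood at the
penalized estimates. Because the Weibull family is the one AFT family that is
also proportional-hazards, coefficients convert to hazard ratios as
HR_j = exp(-k * beta_j) with k the fitted shape; time ratios exp(beta_j) are
available as an alternative report. Covariates are scaled beforehand:
continuous covariates are z-scored, binary ones left 0/1 for interpretability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, WeibullAFTFitter

logger = logging.getLogger("msikit")

DEFAULT_PENALIZER_GRID = (0.0, 0.001, 0.01, 0.1, 1.0)


@dataclass
class KMEstimate:
    survival: pd.DataFrame  # columns: time, survival
    median: Optional[float]  # None when the curve never reaches 0.5
    n: int
    n_events: int


@dataclass
class ScalingRecord:
    """Per-covariate (mean, sd) used for z-scoring; identity for binaries."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    binary: list[str] = field(default_factory=list)


@dataclass
class AFTFit:
    coefficients: pd.Series  # log-time scale, per covariate
    intercept: float
    shape: float  # Weibull shape k (rho)
    penalizer: float
    aic: float
    log_likelihood: float
    summary: pd.DataFrame  # per covariate: coef, se, HR, HR CI, p
    n: int
    n_events: int


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> KMEstimate:
    """Product-limit survival estimate with the median survival time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_.reset_index()
    surv.columns = ["time", "survival"]
    median = kmf.median_survival_time_
    return KMEstimate(
        survival=surv,
        median=None if np.isinf(median) else float(median),
        n=int(times.size),
        n_events=int(events.sum()),
    )


def _is_binary(values: pd.Series) -> bool:
    unique = set(values.dropna().unique())
    return unique <= {0, 1, 0.0, 1.0, True, False}


def scale_covariates(
    data: pd.DataFrame,
    covariates: Sequence[str],
    scale_binary: bool = False,
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Z-score continuous covariates; keep 0/1 covariates unless ``scale_binary``.

    Zero-variance covariates are dropped with a warning. The returned record
    holds the means/SDs needed to back-transform coefficients.
    """
    scaled = data.copy()
    record = ScalingRecord()
    for cov in covariates:
        values = scaled[cov].astype(float)
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        if sd == 0.0 or np.isnan(sd):
            logger.warning("covariate %r has zero variance; dropped", cov)
            record.dropped.append(cov)
            scaled = scaled.drop(columns=[cov])
            continue
        if _is_binary(values) and not scale_binary:
            record.binary.append(cov)
            scaled[cov] = values
            continue
        mean = float(values.mean())
        record.means[cov] = mean
        record.sds[cov] = sd
        scaled[cov] = (values - mean) / sd
    return scaled, record


def fit_weibull_aft(
    data: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    penalizer: float = 0.0,
    report: str = "hr",
) -> AFTFit:
    """Weibull AFT fit with an L2 penalty on the covariate coefficients.

    ``report="hr"`` converts coefficients to hazard ratios via the Weibull
    PH equivalence HR = exp(-k * beta); ``report="time_ratio"`` reports
    exp(beta) instead. Wald CIs and p-values come from the fitted covariance.
    """
    if report not in ("hr", "time_ratio"):
        raise ValueError(f"unknown report type {report!r}")
    events = data[event_col].astype(bool)
    if events.sum() < 2:
        raise ValueError("need at least 2 observed events")
    fitter = WeibullAFTFitter(penalizer=penalizer)
    fitter.fit(data, duration_col=duration_col, event_col=event_col)
    shape = float(fitter.summary.loc[("rho_", "Intercept"), "coef"])
    shape = float(np.exp(shape))
    lam = fitter.summary.loc["lambda_"]
    intercept = float(lam.loc["Intercept", "coef"])
    covs = [c for c in lam.index if c != "Intercept"]
    coef = lam.loc[covs, "coef"].astype(float)
    se = lam.loc[covs, "se(coef)"].astype(float)
    lo = lam.loc[covs, "coef lower 95%"].astype(float)
    hi = lam.loc[covs, "coef upper 95%"].astype(float)
    p = lam.loc[covs, "p"].astype(float)

    if report == "hr":
        effect = np.exp(-shape * coef)
        eff_lo = np.exp(-shape * hi)  # sign flip swaps the bounds
        eff_hi = np.exp(-shape * lo)
        label = "HR"
    else:
        effect = np.exp(coef)
        eff_lo = np.exp(lo)
        eff_hi = np.exp(hi)
        label = "TR"

    summary = pd.DataFrame(
        {
            "coef": coef,
            "se(coef)": se,
            label: effect,
            f"{label} lower 95%": eff_lo,
            f"{label} upper 95%": eff_hi,
            "p": p,
        }
    )
    ll = float(fitter.log_likelihood_)
    n_params = len(covs) + 2  # covariate coefs + scale intercept + shape
    return AFTFit(
        coefficients=coef,
        intercept=intercept,
        shape=shape,
        penalizer=penalizer,
        aic=2.0 * n_params - 2.0 * ll,
        log_likelihood=ll,
        summary=summary,
        n=len(data),
        n_events=int(events.sum()),
    )


def select_penalizer(
    data: pd.DataFrame,
    grid: Sequence[float] = DEFAULT_PENALIZER_GRID,
    duration_col: str = "time",
    event_col: str = "event",
    report: str = "hr",
) -> tuple[float, AFTFit]:
    """Fit at every penalizer in the grid and keep the AIC-minimizing one.

    AIC uses the unpenalized log-likelihood evaluated at the penalized
    estimates; exact ties go to the smallest penalizer.
    """
    if len(grid) == 0:
        raise ValueError("penalizer grid must be non-empty")
    best: Optional[tuple[float, AFTFit]] = None
    failures = []
    for lam in sorted(grid):
        try:
            fit = fit_weibull_aft(
                data, duration_col=duration_col, event_col=event_col,
                penalizer=lam, report=report,
            )
        except Exception as exc:  # noqa: BLE001 - convergence failures recorded
            failures.append((lam, exc))
            continue
        if best is None or fit.aic < best[1].aic:
            best = (lam, fit)
    if best is None:
        raise RuntimeError(f"all penalizer fits failed: {failures}")
    return best
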
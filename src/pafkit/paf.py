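"""Population attributable fraction (PAF) estimation for case-control data.

The point estimator is Miettinen's case-load formula

    PAF = pc * (1 - 1/RR)

with ``pc`` the exposure prevalence among analyzed cases and the relative
risk RR approximated by the (adjusted) odds ratio under the rare-disease
assumption.  Confounding is handled by taking the odds ratio from a
multivariable logistic fit and computing ``pc`` on that same complete-case
sample.  The model-based (Bruzzi) estimator averages each case's
odds-ratio reversal and coincides with Miettinen's formula for a single
binary exposure.

Joint attributable fractions for independent, non-interacting exposures
combine multiplicatively: ``PAF_joint = 1 - prod(1 - PAF_i)``; interval
bounds propagate by applying the same formula to the component lower and
upper bounds.  The primary interval for a single adjusted PAF is a
stratified case-control bootstrap (cases and controls resampled as
separate strata); a delta-method variance is available as a cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    LogisticFit,
    ModelSpec,
    SeparationError,
    CollinearityError,
    ConvergenceError,
    fit_logit_arrays,
    fit_logistic,
    _stratum_frame,
)
from .cohort import SubjectRecord

__all__ = [
    "PAFResult",
    "JointPAFResult",
    "miettinen_paf",
    "adjusted_paf",
    "bruzzi_paf",
    "paf_bootstrap_ci",
    "paf_delta_ci",
    "joint_paf",
    "joint_paf_bounds",
    "joint_adjusted_paf",
]


@dataclass
class PAFResult:
    """A PAF point estimate with the quantities that produced it."""

    paf: float
    pc: float
    or_adjusted: float
    n_cases_used: int
    method: str  # "miettinen" | "bruzzi"
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_method: str = "none"  # "bootstrap" | "delta" | "bound_propagation" | "none"
    protective: bool = False
    label: str = ""


@dataclass
class JointPAFResult:
    """Joint PAF over several exposures with propagated interval bounds."""

    paf_joint: float
    components: list[PAFResult]
    ci_lower: float | None = None
    ci_upper: float | None = None


def miettinen_paf(pc: float, or_adjusted: float) -> float:
    """Miettinen's PAF = pc * (1 - 1/OR).

    ``pc`` is the exposure prevalence among cases; the odds ratio stands in
    for the relative risk (rare disease).  Protective factors (OR < 1)
    yield a negative PAF, returned as-is with a warning.
    """
    if not 0 <= pc <= 1:
        raise ValueError("pc must lie in [0, 1]")
    if or_adjusted <= 0:
        raise ValueError("or_adjusted must be positive")
    paf = pc * (1 - 1 / or_adjusted)
    if paf < 0:
        warnings.warn(
            "protective factor (OR < 1) yields a negative PAF",
            stacklevel=2,
        )
    return paf


def bruzzi_paf(
    fit: LogisticFit, case_rows: pd.DataFrame, exposure: str
) -> float:
    """Model-based PAF: average odds-ratio reversal over analyzed cases.

    ``PAF = 1 - mean_i exp(-x_i beta_e)`` over the cases' observed exposure
    values, confounders held at their observed values.  For a single binary
    exposure this equals ``pc * (1 - 1/OR)`` exactly.
    """
    if exposure not in fit.params.index:
        raise ValueError(f"exposure {exposure!r} is not in the fitted model")
    if exposure not in case_rows.columns:
        raise ValueError(f"case_rows lacks column {exposure!r}")
    beta = float(fit.params[exposure])
    x = case_rows[exposure].to_numpy(dtype=float)
    return float(1.0 - np.mean(np.exp(-x * beta)))


def _design(sub: pd.DataFrame, outcome: str, covariates: Sequence[str]):
    y = sub[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)),
                         sub[list(covariates)].to_numpy(dtype=float)])
    return X, y


def _paf_from_subframe(
    sub: pd.DataFrame, outcome: str, covariates: Sequence[str],
    exposure: str, method: str,
) -> tuple[float, float, float, int]:
    """(paf, pc, or_adjusted, n_cases) on an already complete-case frame."""
    y = sub[outcome].to_numpy(dtype=float)
    cases = sub[y == 1]
    n_cases = len(cases)
    x_cases = cases[exposure].to_numpy(dtype=float)
    pc = float(x_cases.mean()) if n_cases else 0.0
    if pc == 0.0:
        warnings.warn("no exposed cases; PAF is 0", stacklevel=3)
        return 0.0, 0.0, math.nan, n_cases
    if float(sub[exposure].nunique()) <= 1:
        raise ValueError(
            f"exposure {exposure!r} has no variation in the analysis sample"
        )
    X, y = _design(sub, outcome, covariates)
    names = ["intercept", *covariates]
    beta, _, _, _ = fit_logit_arrays(X, y, names)
    b = float(beta[names.index(exposure)])
    or_adj = math.exp(b)
    if method == "miettinen":
        paf = pc * (1 - 1 / or_adj)
    elif method == "bruzzi":
        paf = float(1.0 - np.mean(np.exp(-x_cases * b)))
    else:
        raise ValueError(f"bad method {method!r}")
    return paf, pc, or_adj, n_cases


def adjusted_paf(
    records: Sequence[SubjectRecord],
    spec: ModelSpec,
    exposure: str,
    method: str = "miettinen",
    ten_year_window: float = 10.0,
) -> PAFResult:
    """Covariate-adjusted PAF for one exposure of a conditional model.

    The odds ratio is the exposure coefficient of the multivariable fit on
    the model's complete-case subset, and ``pc`` is the exposed fraction
    among the cases of that same subset (so the prevalence matches the
    sample that produced the OR).
    """
    covariates = spec.resolved_covariates()
    resolve = dict(zip(spec.covariates, covariates))
    if exposure not in resolve:
        raise ValueError(f"exposure {exposure!r} is not in the model covariates")
    exposure_r = resolve[exposure]
    frame = _stratum_frame(records, spec.stratum, ten_year_window)
    sub = frame[[spec.outcome, *covariates]].dropna()
    if sub.empty:
        raise ValueError("complete-case subset is empty for this model")
    paf, pc, or_adj, n_cases = _paf_from_subframe(
        sub, spec.outcome, covariates, exposure_r, method)
    return PAFResult(
        paf=paf, pc=pc, or_adjusted=or_adj, n_cases_used=n_cases,
        method=method, protective=paf < 0, label=exposure,
    )


def paf_bootstrap_ci(
    records: Sequence[SubjectRecord],
    spec: ModelSpec,
    exposure: str,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    method: str = "miettinen",
    ten_year_window: float = 10.0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the adjusted PAF.

    Cases and controls are resampled with replacement as separate strata
    (fixed case-control margins), the adjusted PAF recomputed per resample,
    and the ``level`` percentile interval returned.  Deterministic for a
    fixed seed.  More than 5% failed resample fits is an error.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    covariates = spec.resolved_covariates()
    resolve = dict(zip(spec.covariates, covariates))
    if exposure not in resolve:
        raise ValueError(f"exposure {exposure!r} is not in the model covariates")
    exposure_r = resolve[exposure]
    frame = _stratum_frame(records, spec.stratum, ten_year_window)
    cols = frame[[spec.outcome, *covariates]]
    status = cols[spec.outcome].to_numpy()
    case_idx = np.flatnonzero(status == 1)
    control_idx = np.flatnonzero(status == 0)
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    failures = 0
    kept = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-resample zero-pc warnings
        for _ in range(B):
            idx = np.concatenate([
                rng.choice(case_idx, size=len(case_idx), replace=True),
                rng.choice(control_idx, size=len(control_idx), replace=True),
            ])
            sub = cols.iloc[idx].dropna()
            try:
                paf, _, _, _ = _paf_from_subframe(
                    sub, spec.outcome, covariates, exposure_r, method)
            except (SeparationError, CollinearityError, ConvergenceError,
                    ValueError):
                failures += 1
                continue
            values[kept] = paf
            kept += 1
    if failures > 0.05 * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap resamples failed to fit"
        )
    alpha = 1 - level
    lo, hi = np.quantile(values[:kept], [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def paf_delta_ci(
    records: Sequence[SubjectRecord],
    spec: ModelSpec,
    exposure: str,
    level: float = 0.95,
    ten_year_window: float = 10.0,
) -> tuple[float, float]:
    """Delta-method interval for the adjusted Miettinen PAF.

    Treats ``pc`` as binomial over the analyzed cases and the exposure
    coefficient as normal with its Wald variance, ignoring their
    covariance; intended as a fast cross-check of the bootstrap.
    """
    result = adjusted_paf(records, spec, exposure,
                          ten_year_window=ten_year_window)
    fit = fit_logistic(records, spec, ten_year_window)
    exposure_r = dict(zip(spec.covariates, spec.resolved_covariates()))[exposure]
    beta = float(fit.params[exposure_r])
    var_beta = float(fit.cov_params.loc[exposure_r, exposure_r])
    pc, n = result.pc, result.n_cases_used
    var_pc = pc * (1 - pc) / n if n else 0.0
    d_pc = 1 - math.exp(-beta)
    d_beta = pc * math.exp(-beta)
    se = math.sqrt(d_pc ** 2 * var_pc + d_beta ** 2 * var_beta)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return result.paf - z * se, result.paf + z * se


def joint_paf(components: Sequence[float]) -> float:
    """Joint PAF of independent exposures: 1 - prod(1 - PAF_i)."""
    if not len(components):
        raise ValueError("components must be non-empty")
    for p in components:
        if p >= 1:
            raise ValueError("component PAFs must be < 1")
    return float(1.0 - np.prod([1.0 - p for p in components]))


def joint_paf_bounds(
    component_bounds: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Propagate interval bounds through the joint-PAF formula.

    Applies ``1 - prod(1 - x)`` separately to the set of lower bounds and
    the set of upper bounds.
    """
    lowers, uppers = [], []
    for lo, hi in component_bounds:
        if lo > hi:
            raise ValueError("component lower bound exceeds upper bound")
        lowers.append(lo)
        uppers.append(hi)
    return joint_paf(lowers), joint_paf(uppers)


def joint_adjusted_paf(
    records: Sequence[SubjectRecord],
    spec: ModelSpec,
    exposures: Sequence[str],
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    ten_year_window: float = 10.0,
) -> JointPAFResult:
    """Adjusted component PAFs with bootstrap CIs, combined jointly.

    Each exposure's PAF and interval come from the same conditional model;
    the joint point estimate and bounds follow the multiplicative formula.
    """
    components = []
    for i, exposure in enumerate(exposures):
        res = adjusted_paf(records, spec, exposure,
                           ten_year_window=ten_year_window)
        res.ci_lower, res.ci_upper = paf_bootstrap_ci(
            records, spec, exposure, B=B, seed=seed + i, level=level,
            ten_year_window=ten_year_window)
        res.ci_method = "bootstrap"
        components.append(res)
    lo, hi = joint_paf_bounds([(c.ci_lower, c.ci_upper) for c in components])
    return JointPAFResult(
        paf_joint=joint_paf([c.paf for c in components]),
        components=components, ci_lower=lo, ci_upper=hi,
    )
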
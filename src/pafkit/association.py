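"""Exposure-disease association estimators for case-control cohorts.

Implements the two estimation routes used throughout the package:

* 2x2 cross-product odds ratios with Woolf confidence intervals,
  optionally Haldane-Anscombe continuity-corrected (add 0.5 to every
  cell), which is required when a cell is zero;
* maximum-likelihood logistic regression (Newton/IRLS) for covariate-
  adjusted ("conditional") odds ratios, pairwise interaction screens and
  Wald inference.

Risk-factor hypotheses are directional (exposure increases risk), so the
reporting convention is one-sided: a one-sided 95% lower bound is the
lower bound of the two-sided 90% Wald interval, with an upper-tail Wald
p-value.  Two-sided intervals are used for descriptive feature tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SubjectRecord, to_analysis_frame, ANALYSIS_VARIABLES

__all__ = [
    "TwoByTwoTable",
    "ORResult",
    "ModelSpec",
    "LogisticFit",
    "InteractionResult",
    "ZeroCellError",
    "SeparationError",
    "CollinearityError",
    "ConvergenceError",
    "MODEL_ALL",
    "MODEL_MALE",
    "MODEL_FEMALE",
    "DEFAULT_MODELS",
    "two_by_two",
    "odds_ratio",
    "fit_logistic",
    "fit_logit_arrays",
    "conditional_table",
    "interaction_test",
    "one_proportion_test",
]


class ZeroCellError(ValueError):
    """A 2x2 cell is zero and no continuity correction was requested."""


class SeparationError(RuntimeError):
    """The likelihood is maximized at infinity (perfect separation)."""


class CollinearityError(RuntimeError):
    """The design matrix is rank-deficient; the message names a column."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure-by-status counts: a/b exposed/unexposed cases, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass
class ORResult:
    """An odds ratio with its interval, p-value and provenance."""

    or_point: float
    ci_lower: float
    ci_upper: float
    p_value: float
    sidedness: str  # "one" | "two"
    method: str  # "woolf_raw" | "woolf_corrected" | "wald_logistic"
    label: str = ""
    n_cases: int | None = None
    n_controls: int | None = None


@dataclass(frozen=True)
class ModelSpec:
    """A logistic model: outcome, ordered covariates, stratum, censoring.

    ``exposure_censoring="ten_year"`` swaps the pre-onset-censored MTBI
    indicator for its 10-year sensitivity recode.  Sex may not be a
    covariate in a sex stratum (it would be constant / collinear).
    """

    covariates: tuple[str, ...]
    outcome: str = "status"
    stratum: str = "all"  # "all" | "male" | "female"
    exposure_censoring: str = "precensored"  # "precensored" | "ten_year"

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValueError("covariates must be non-empty")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariates must be distinct")
        if self.stratum not in ("all", "male", "female"):
            raise ValueError(f"bad stratum {self.stratum!r}")
        if self.exposure_censoring not in ("precensored", "ten_year"):
            raise ValueError(f"bad exposure_censoring {self.exposure_censoring!r}")
        if self.stratum != "all" and "sex" in self.covariates:
            raise ValueError(
                "sex cannot be a covariate within a sex stratum (collinear)"
            )
        for name in self.covariates:
            if name not in ANALYSIS_VARIABLES:
                raise ValueError(f"unknown covariate {name!r}")

    def resolved_covariates(self) -> tuple[str, ...]:
        if self.exposure_censoring == "ten_year":
            return tuple("mtbi_10yr" if c == "mtbi" else c for c in self.covariates)
        return self.covariates


#: Full conditional model over all subjects: age plus the five risk factors.
MODEL_ALL = ModelSpec(
    covariates=("age", "family_history", "mtbi", "repeated_blows",
                "pesticide", "agent_orange"),
    stratum="all",
)
#: Same model restricted to males.
MODEL_MALE = ModelSpec(covariates=MODEL_ALL.covariates, stratum="male")
#: Female model; the structurally male-only exposures are excluded.
MODEL_FEMALE = ModelSpec(
    covariates=("age", "family_history", "mtbi", "pesticide"),
    stratum="female",
)
DEFAULT_MODELS = {"all": MODEL_ALL, "male": MODEL_MALE, "female": MODEL_FEMALE}


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit: coefficients, covariance, composition."""

    params: pd.Series  # index: ["intercept", *covariates]
    cov_params: pd.DataFrame
    n_cases: int
    n_controls: int
    converged: bool
    log_likelihood: float
    n_iter: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())),
                         index=self.params.index)

    def conf_int(self, level: float = 0.95, sided: str = "two") -> pd.DataFrame:
        """Wald interval per coefficient; ``sided="one"`` gives the one-sided
        lower bound (the two-sided ``2*level - 1`` lower bound) with +inf above."""
        if sided == "two":
            z = stats.norm.ppf(1 - (1 - level) / 2)
            lo = self.params - z * self.bse
            hi = self.params + z * self.bse
        elif sided == "one":
            z = stats.norm.ppf(level)
            lo = self.params - z * self.bse
            hi = pd.Series(np.inf, index=self.params.index)
        else:
            raise ValueError(f"bad sided {sided!r}")
        return pd.DataFrame({"lower": lo, "upper": hi})


def _stratum_frame(
    records: Sequence[SubjectRecord], stratum: str, ten_year_window: float = 10.0
) -> pd.DataFrame:
    frame = to_analysis_frame(records, ten_year_window)
    if stratum == "all":
        return frame
    if stratum not in ("male", "female"):
        raise ValueError(f"bad stratum {stratum!r}")
    sub = frame[frame["sex"] == stratum]
    if sub.empty:
        raise ValueError(f"stratum {stratum!r} contains no records")
    return sub


def two_by_two(
    records: Sequence[SubjectRecord], exposure: str, stratum: str = "all",
    ten_year_window: float = 10.0,
) -> TwoByTwoTable:
    """Exposed/unexposed x case/control counts on the complete-case subset."""
    if exposure not in ANALYSIS_VARIABLES:
        raise ValueError(f"unknown exposure {exposure!r}")
    frame = _stratum_frame(records, stratum, ten_year_window)
    sub = frame[["status", exposure]].dropna()
    y = sub["status"].to_numpy()
    x = sub[exposure].to_numpy()
    return TwoByTwoTable(
        a=int(np.sum((y == 1) & (x == 1))),
        b=int(np.sum((y == 1) & (x == 0))),
        c=int(np.sum((y == 0) & (x == 1))),
        d=int(np.sum((y == 0) & (x == 0))),
    )


def odds_ratio(
    table: TwoByTwoTable,
    correction: str = "none",
    ci_level: float = 0.95,
    sidedness: str = "two",
) -> ORResult:
    """Cross-product odds ratio with a Woolf (log-scale Wald) interval.

    ``correction="haldane"`` adds 0.5 to every cell (Haldane-Anscombe)
    before both the point estimate and the variance; this is the
    continuity-corrected estimator used for feature tables and is required
    whenever a cell is zero.  With ``sidedness="one"`` the interval is the
    one-sided ``ci_level`` lower bound — i.e. the lower bound of the
    two-sided ``2*ci_level - 1`` interval — with an upper-tail Wald p for
    OR > 1 and +inf as the upper limit.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    if correction == "haldane":
        cells = cells + 0.5
        method = "woolf_corrected"
    elif correction == "none":
        if np.any(cells == 0):
            raise ZeroCellError(
                "2x2 table has a zero cell; use correction='haldane'"
            )
        method = "woolf_raw"
    else:
        raise ValueError(f"bad correction {correction!r}")
    a, b, c, d = cells
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt((1 / cells).sum())
    z0 = log_or / se
    if sidedness == "two":
        z = stats.norm.ppf(1 - (1 - ci_level) / 2)
        lo, hi = math.exp(log_or - z * se), math.exp(log_or + z * se)
        p = 2 * stats.norm.sf(abs(z0))
    elif sidedness == "one":
        z = stats.norm.ppf(ci_level)
        lo, hi = math.exp(log_or - z * se), math.inf
        p = stats.norm.sf(z0)
    else:
        raise ValueError(f"bad sidedness {sidedness!r}")
    return ORResult(
        or_point=math.exp(log_or), ci_lower=lo, ci_upper=hi,
        p_value=float(p), sidedness=sidedness, method=method,
        n_cases=table.n_cases, n_controls=table.n_controls,
    )


# -- logistic core ----------------------------------------------------------

_SEPARATION_BOUND = 15.0  # |log-odds| beyond this is treated as divergence
_MAX_ITER = 100
_LL_RTOL = 1e-10


def _name_collinear_column(X: np.ndarray, names: Sequence[str]) -> str:
    # the right singular vector of the smallest singular value points at the
    # most involved column of the (near-)null space
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    null_vec = np.abs(vt[-1])
    null_vec[0] = 0.0  # never blame the intercept
    return names[int(np.argmax(null_vec))]


def fit_logit_arrays(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    max_iter: int = _MAX_ITER,
    tol: float = _LL_RTOL,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Newton/IRLS logistic MLE on a design matrix with intercept column.

    Returns ``(beta, covariance, log_likelihood, n_iter)``.  Raises
    :class:`CollinearityError` on rank deficiency, :class:`SeparationError`
    on divergent coefficients, :class:`ConvergenceError` otherwise.
    """
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise CollinearityError(
            f"design matrix is rank-deficient; offending column: "
            f"{_name_collinear_column(X, list(names))!r}"
        )
    beta = np.zeros(p)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    for it in range(1, max_iter + 1):
        w = mu * (1 - mu)
        xtw = X.T * w
        hess = xtw @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(
                f"singular information matrix; offending column: "
                f"{_name_collinear_column(X, list(names))!r}"
            ) from exc
        # damped Newton: halve the step until the log-likelihood improves
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta = X @ cand
            mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-300, 1 - 1e-16)
            ll_new = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            j = int(np.argmax(np.abs(beta[1:])) + 1) if p > 1 else 0
            raise SeparationError(
                f"perfect separation suspected (|coef| > {_SEPARATION_BOUND}); "
                f"offending column: {names[j]!r}"
            )
        if abs(ll_new - ll) <= tol * (abs(ll) + 1e-30):
            ll = ll_new
            w = mu * (1 - mu)
            cov = np.linalg.inv((X.T * w) @ X)
            return beta, cov, ll, it
        ll = ll_new
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")


def fit_logistic(
    records: Sequence[SubjectRecord],
    spec: ModelSpec,
    ten_year_window: float = 10.0,
) -> LogisticFit:
    """Fit the complete-case logistic model described by ``spec``.

    The fit maximizes the binomial log-likelihood by damped Newton steps;
    the covariance is the inverse observed information.  A single binary
    covariate reproduces the 2x2 cross-product odds ratio exactly.
    """
    covariates = spec.resolved_covariates()
    frame = _stratum_frame(records, spec.stratum, ten_year_window)
    sub = frame[[spec.outcome, *covariates]].dropna()
    if sub.empty:
        raise ValueError("complete-case subset is empty for this model")
    y = sub[spec.outcome].to_numpy(dtype=float)
    n_cases = int(y.sum())
    n_controls = int(len(y) - y.sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("both outcome classes must be present")
    X = np.column_stack([np.ones(len(sub)),
                         sub[list(covariates)].to_numpy(dtype=float)])
    names = ["intercept", *covariates]
    beta, cov, ll, n_iter = fit_logit_arrays(X, y, names)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        n_cases=n_cases, n_controls=n_controls,
        converged=True, log_likelihood=ll, n_iter=n_iter,
    )


def conditional_table(
    records: Sequence[SubjectRecord],
    spec: ModelSpec,
    ci_level: float = 0.95,
    ten_year_window: float = 10.0,
) -> list[ORResult]:
    """Adjusted odds ratios: all covariates fitted simultaneously.

    One :class:`ORResult` per covariate, with adjusted OR = exp(coef), the
    one-sided ``ci_level`` lower bound and the upper-tail Wald p-value.
    """
    fit = fit_logistic(records, spec, ten_year_window)
    ci = fit.conf_int(level=ci_level, sided="one")
    out = []
    for name in fit.params.index:
        if name == "intercept":
            continue
        coef = fit.params[name]
        se = fit.bse[name]
        out.append(ORResult(
            or_point=math.exp(coef),
            ci_lower=math.exp(ci.loc[name, "lower"]),
            ci_upper=math.inf,
            p_value=float(stats.norm.sf(coef / se)),
            sidedness="one", method="wald_logistic", label=name,
            n_cases=fit.n_cases, n_controls=fit.n_controls,
        ))
    return out


@dataclass
class InteractionResult:
    """Wald test of a pairwise product term added to a conditional model."""

    pair: tuple[str, str]
    coefficient: float
    se: float
    p_value: float  # two-sided
    n_cases: int
    n_controls: int


def interaction_test(
    records: Sequence[SubjectRecord],
    spec: ModelSpec,
    pair: tuple[str, str],
    ten_year_window: float = 10.0,
) -> InteractionResult:
    """Augment ``spec`` with the product of two exposures and Wald-test it.

    Separation or collinearity in the joint-exposure cell is raised as the
    corresponding named error, never masked.
    """
    e1, e2 = pair
    if e1 not in spec.covariates or e2 not in spec.covariates:
        raise ValueError(f"both exposures of {pair!r} must be in the model")
    covariates = spec.resolved_covariates()
    resolve = dict(zip(spec.covariates, covariates))
    e1r, e2r = resolve[e1], resolve[e2]
    frame = _stratum_frame(records, spec.stratum, ten_year_window)
    sub = frame[[spec.outcome, *covariates]].dropna()
    if sub.empty:
        raise ValueError("complete-case subset is empty for this model")
    y = sub[spec.outcome].to_numpy(dtype=float)
    product = (sub[e1r] * sub[e2r]).to_numpy(dtype=float)
    inter_name = f"{e1r}:{e2r}"
    X = np.column_stack([
        np.ones(len(sub)),
        sub[list(covariates)].to_numpy(dtype=float),
        product,
    ])
    names = ["intercept", *covariates, inter_name]
    beta, cov, _, _ = fit_logit_arrays(X, y, names)
    coef = float(beta[-1])
    se = float(math.sqrt(cov[-1, -1]))
    return InteractionResult(
        pair=pair, coefficient=coef, se=se,
        p_value=float(2 * stats.norm.sf(abs(coef / se))),
        n_cases=int(y.sum()), n_controls=int(len(y) - y.sum()),
    )


def one_proportion_test(k: int, n: int, p0: float) -> float:
    """Two-sided one-proportion z-test of k successes in n against p0."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    z = (k / n - p0) / math.sqrt(p0 * (1 - p0) / n)
    return float(2 * stats.norm.sf(abs(z)))
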
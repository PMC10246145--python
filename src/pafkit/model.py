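"""Model/Results interface for case-control risk-factor analysis.

:class:`CaseControlLogit` is the package's front door: build it from a
list of subject records (or a cohort CSV loaded into a DataFrame), call
:meth:`~CaseControlLogit.fit`, and read estimates, intervals, attributable
fractions and a formatted summary off the returned
:class:`CaseControlResults`.

Example
-------
>>> from pafkit import CaseControlLogit, MODEL_MALE, default_study_config
>>> from pafkit.simulate import simulate_cohort
>>> records = simulate_cohort(default_study_config(seed=7))
>>> res = CaseControlLogit(records, MODEL_MALE).fit()
>>> res.params["pesticide"]          # adjusted log OR          # doctest: +SKIP
>>> print(res.summary())                                        # doctest: +SKIP
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    LogisticFit,
    ModelSpec,
    ORResult,
    InteractionResult,
    conditional_table,
    fit_logistic,
    interaction_test,
)
from .cohort import SubjectRecord
from .paf import (
    JointPAFResult,
    PAFResult,
    adjusted_paf,
    joint_adjusted_paf,
    paf_bootstrap_ci,
)

__all__ = ["CaseControlLogit", "CaseControlResults"]


class CaseControlLogit:
    """Multivariable logistic disease model on a case-control cohort.

    Parameters
    ----------
    records : sequence of SubjectRecord
        The cohort; complete-case filtering on the model variables happens
        at fit time.
    spec : ModelSpec
        Outcome, covariates, stratum and MTBI censoring variant.
    ten_year_window : float
        Width (years) of the head-injury sensitivity censoring window.
    """

    def __init__(
        self,
        records: Sequence[SubjectRecord],
        spec: ModelSpec,
        ten_year_window: float = 10.0,
    ) -> None:
        self.records = list(records)
        self.spec = spec
        self.ten_year_window = ten_year_window

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        covariates: Sequence[str],
        stratum: str = "all",
        exposure_censoring: str = "precensored",
        ten_year_window: float = 10.0,
    ) -> "CaseControlLogit":
        """Build from a cohort table in the canonical CSV schema."""
        import os
        import tempfile

        from .cohort import read_cohort_csv

        fd, tmp = tempfile.mkstemp(suffix=".csv")
        os.close(fd)
        try:
            frame.to_csv(tmp, index=False)
            records = read_cohort_csv(tmp)
        finally:
            os.unlink(tmp)
        spec = ModelSpec(
            covariates=tuple(covariates),
            stratum=stratum,
            exposure_censoring=exposure_censoring,
        )
        return cls(records, spec, ten_year_window)

    def fit(self) -> "CaseControlResults":
        """Maximum-likelihood fit; returns the results object."""
        fit = fit_logistic(self.records, self.spec, self.ten_year_window)
        return CaseControlResults(self, fit)


class CaseControlResults:
    """Estimates, uncertainties and derived quantities of a fitted model."""

    def __init__(self, model: CaseControlLogit, fit: LogisticFit) -> None:
        self.model = model
        self._fit = fit

    # -- statsmodels-like accessors --------------------------------------

    @property
    def params(self) -> pd.Series:
        """Coefficients (log odds ratios) including the intercept."""
        return self._fit.params

    @property
    def bse(self) -> pd.Series:
        return self._fit.bse

    @property
    def cov_params(self) -> pd.DataFrame:
        return self._fit.cov_params

    @property
    def llf(self) -> float:
        return self._fit.log_likelihood

    @property
    def n_cases(self) -> int:
        return self._fit.n_cases

    @property
    def n_controls(self) -> int:
        return self._fit.n_controls

    def conf_int(self, level: float = 0.95, sided: str = "two") -> pd.DataFrame:
        return self._fit.conf_int(level=level, sided=sided)

    def pvalues(self, sided: str = "one") -> pd.Series:
        z = self.params / self.bse
        if sided == "one":
            return pd.Series(stats.norm.sf(z), index=self.params.index)
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    # -- domain quantities ------------------------------------------------

    def or_table(self, ci_level: float = 0.95) -> list[ORResult]:
        """Adjusted odds ratios with one-sided lower bounds, per covariate."""
        return conditional_table(
            self.model.records, self.model.spec, ci_level,
            self.model.ten_year_window)

    def interaction(self, pair: tuple[str, str]) -> InteractionResult:
        """Wald screen of a pairwise product term added to the model."""
        return interaction_test(
            self.model.records, self.model.spec, pair,
            self.model.ten_year_window)

    def paf(
        self,
        exposure: str,
        method: str = "miettinen",
        ci: str | None = "bootstrap",
        B: int = 1000,
        seed: int = 0,
        level: float = 0.95,
    ) -> PAFResult:
        """Adjusted PAF for one exposure of this model."""
        result = adjusted_paf(
            self.model.records, self.model.spec, exposure, method,
            self.model.ten_year_window)
        if ci == "bootstrap":
            result.ci_lower, result.ci_upper = paf_bootstrap_ci(
                self.model.records, self.model.spec, exposure,
                B=B, seed=seed, level=level, method=method,
                ten_year_window=self.model.ten_year_window)
            result.ci_method = "bootstrap"
        return result

    def joint_paf(
        self,
        exposures: Sequence[str],
        B: int = 1000,
        seed: int = 0,
        level: float = 0.95,
    ) -> JointPAFResult:
        """Joint adjusted PAF over several exposures of this model."""
        return joint_adjusted_paf(
            self.model.records, self.model.spec, exposures,
            B=B, seed=seed, level=level,
            ten_year_window=self.model.ten_year_window)

    # -- presentation ------------------------------------------------------

    def summary(self, ci_level: float = 0.95) -> str:
        """Plain-text table of adjusted ORs, lower bounds and p-values."""
        spec = self.model.spec
        lines = [
            "Case-control logistic model",
            f"  stratum: {spec.stratum}   censoring: {spec.exposure_censoring}",
            f"  cases: {self.n_cases}   controls: {self.n_controls}   "
            f"log-likelihood: {self.llf:.3f}",
            "",
            f"{'covariate':<20}{'coef':>9}{'adj. OR':>9}"
            f"{'LB' + format(ci_level * 100, '.0f') + '%':>9}{'P(one-sided)':>14}",
        ]
        table = self.or_table(ci_level)
        for row in table:
            lines.append(
                f"{row.label:<20}{math.log(row.or_point):>9.4f}"
                f"{row.or_point:>9.2f}{row.ci_lower:>9.2f}{row.p_value:>14.2e}"
            )
        return "\n".join(lines)

    def plot_forest(self, ci_level: float = 0.95, ax=None):
        """Forest plot of adjusted ORs with one-sided lower bounds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.5 + 0.4 * len(self.params)))
        table = self.or_table(ci_level)
        ys = np.arange(len(table))[::-1]
        for y, row in zip(ys, table):
            ax.plot([row.ci_lower, row.or_point * 1.0], [y, y], color="0.4")
            ax.plot(row.or_point, y, "o", color="C0")
        ax.axvline(1.0, color="0.7", linestyle="--")
        ax.set_yticks(ys)
        ax.set_yticklabels([row.label for row in table])
        ax.set_xscale("log")
        ax.set_xlabel("adjusted odds ratio (log scale)")
        return ax
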
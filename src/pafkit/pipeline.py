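"""End-to-end study pipeline: feature, unadjusted, conditional, interaction
and PAF tables from any cohort CSV, with reproducible seeds and an audit log
of complete-case counts at every step.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from .association import (
    DEFAULT_MODELS,
    ModelSpec,
    ZeroCellError,
    odds_ratio,
    one_proportion_test,
    two_by_two,
    fit_logistic,
    conditional_table,
    interaction_test,
    SeparationError,
    CollinearityError,
    ConvergenceError,
)
from .cohort import SubjectRecord, read_cohort_csv, to_analysis_frame
from .paf import adjusted_paf, joint_paf, joint_paf_bounds, paf_bootstrap_ci

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_feature_table",
    "run_unadjusted_table",
    "run_full_study",
]

logger = logging.getLogger("pafkit.pipeline")

#: Default binary risk factors of the unadjusted table.
DEFAULT_RISK_FACTORS = (
    "family_history", "mtbi", "repeated_blows", "pesticide", "agent_orange",
)
DEFAULT_CONTINUOUS = ("age", "pesticide_duration")
DEFAULT_FEATURES = ("constipation", "rbd", "weight_loss")
DEFAULT_INTERACTION_PAIRS = (
    ("pesticide", "agent_orange"),
    ("agent_orange", "repeated_blows"),
    ("pesticide", "repeated_blows"),
)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything needed to run the full analysis reproducibly."""

    cohort_path: str
    output_dir: str
    strata: tuple[str, ...] = ("all", "male", "female")
    censoring_variants: tuple[str, ...] = ("precensored", "ten_year")
    features: tuple[str, ...] = DEFAULT_FEATURES
    risk_factors: tuple[str, ...] = DEFAULT_RISK_FACTORS
    continuous_factors: tuple[str, ...] = DEFAULT_CONTINUOUS
    paf_exposures: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: {
        "all": ("pesticide",),
        "male": ("pesticide", "agent_orange", "repeated_blows"),
        "female": ("pesticide",),
    })
    joint_strata: tuple[str, ...] = ("male",)
    interaction_pairs: tuple[tuple[str, str], ...] = DEFAULT_INTERACTION_PAIRS
    interaction_stratum: str = "male"
    bootstrap_b: int = 1000
    seed: int = 0
    ten_year_window: float = 10.0

    def validate(self) -> "PipelineConfig":
        if self.bootstrap_b < 100:
            raise ValueError("bootstrap_b must be >= 100 when PAF CIs are run")
        return self


def run_feature_table(
    records: Sequence[SubjectRecord],
    features: Sequence[str] = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Descriptive feature comparison (cases vs. controls).

    One row per feature with per-arm complete-case counts, positives and
    the Haldane-Anscombe continuity-corrected OR with a two-sided 95%
    Woolf interval; a leading row tests the male fraction among cases
    against 0.5 with the one-proportion z-test.
    """
    frame = to_analysis_frame(records)
    rows = []
    sexed = frame[frame["sex"].notna() & (frame["status"] == 1)]
    n_male = int((sexed["sex"] == "male").sum())
    rows.append({
        "variable": "sex_male", "n_cases": len(sexed), "n_controls": None,
        "cases_positive": n_male, "controls_positive": None,
        "or": None, "ci_lower": None, "ci_upper": None,
        "p_value": one_proportion_test(n_male, len(sexed), 0.5)
        if len(sexed) else None,
    })
    for name in features:
        table = two_by_two(records, name)
        res = odds_ratio(table, correction="haldane", sidedness="two")
        rows.append({
            "variable": name,
            "n_cases": table.n_cases, "n_controls": table.n_controls,
            "cases_positive": table.a, "controls_positive": table.c,
            "or": res.or_point, "ci_lower": res.ci_lower,
            "ci_upper": res.ci_upper, "p_value": res.p_value,
        })
        logger.info("feature %s: %d cases / %d controls with data",
                    name, table.n_cases, table.n_controls)
    return pd.DataFrame(rows)


def _continuous_or(records, name, stratum, ten_year_window):
    spec = ModelSpec(covariates=(name,), stratum=stratum)
    fit = fit_logistic(records, spec, ten_year_window)
    coef = float(fit.params[name])
    se = float(fit.bse[name])
    from scipy import stats

    return {
        "or": math.exp(coef),
        "ci_lower": math.exp(coef - stats.norm.ppf(0.95) * se),
        "p_value": float(stats.norm.sf(coef / se)),
        "n_cases": fit.n_cases,
        "n_controls": fit.n_controls,
    }


def run_unadjusted_table(
    records: Sequence[SubjectRecord],
    risk_factors: Sequence[str] = DEFAULT_RISK_FACTORS,
    continuous_factors: Sequence[str] = DEFAULT_CONTINUOUS,
    strata: Sequence[str] = ("all", "male", "female"),
    censoring_variants: Sequence[str] = ("precensored", "ten_year"),
    ten_year_window: float = 10.0,
) -> pd.DataFrame:
    """One-at-a-time risk-factor table per stratum.

    Binary factors use the uncorrected cross-product OR with the one-sided
    95% lower bound and upper-tail p; a row with any empty 2x2 cell is
    marked not-estimable rather than corrected.  Continuous factors use a
    single-covariate logistic fit (per-year OR).  The MTBI row is repeated
    under the 10-year censoring variant when requested.
    """
    rows = []
    for stratum in strata:
        factor_list: list[tuple[str, str]] = []
        factor_list.append(("age", "continuous"))
        for name in risk_factors:
            factor_list.append((name, "binary"))
            if name == "mtbi" and "ten_year" in censoring_variants:
                factor_list.append(("mtbi_10yr", "binary"))
        for name in continuous_factors:
            if name != "age":
                factor_list.append((name, "continuous"))
        for name, kind in factor_list:
            row = {"stratum": stratum, "variable": name, "estimable": True}
            try:
                if kind == "continuous":
                    row.update(_continuous_or(records, name, stratum,
                                              ten_year_window))
                else:
                    table = two_by_two(records, name, stratum, ten_year_window)
                    row["n_cases"] = table.n_cases
                    row["n_controls"] = table.n_controls
                    row["cases_positive"] = table.a
                    row["controls_positive"] = table.c
                    if 0 in (table.a, table.b, table.c, table.d):
                        row["estimable"] = False
                    else:
                        res = odds_ratio(table, correction="none",
                                         sidedness="one")
                        row.update({"or": res.or_point,
                                    "ci_lower": res.ci_lower,
                                    "p_value": res.p_value})
            except (ValueError, SeparationError, CollinearityError,
                    ConvergenceError) as exc:
                logger.info("unadjusted %s/%s not estimable: %s",
                            stratum, name, exc)
                row["estimable"] = False
            rows.append(row)
    out = pd.DataFrame(rows)
    return out


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        value = value.item()
    if isinstance(value, float) and not math.isfinite(value):
        return None if math.isnan(value) else ("inf" if value > 0 else "-inf")
    if isinstance(value, float):
        return round(value, 10)
    return value


def run_full_study(config: PipelineConfig) -> dict:
    """Run the whole analysis and write report files plus a JSON of
    every estimate.

    Outputs in ``config.output_dir``: ``features.csv``, ``unadjusted.csv``,
    ``conditional.csv``, ``interactions.csv``, ``paf.csv`` and
    ``estimates.json``.  Identical config (including seed) yields
    byte-identical JSON.  A stage failure raises
    :class:`PipelineStageError` naming the stage; files already written
    are preserved.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    estimates: dict = {"seed": config.seed}
    stage = "load_cohort"
    try:
        records = read_cohort_csv(config.cohort_path)
        logger.info("loaded %d records from %s", len(records),
                    config.cohort_path)
        n_cases = sum(1 for r in records if r.status == "case")
        estimates["cohort"] = {
            "n_records": len(records),
            "n_cases": n_cases,
            "n_controls": len(records) - n_cases,
        }

        stage = "feature_table"
        features = run_feature_table(records, config.features)
        features.to_csv(outdir / "features.csv", index=False)
        estimates["features"] = [
            {k: _jsonable(v) for k, v in row.items()}
            for row in features.to_dict("records")
        ]

        stage = "unadjusted_table"
        unadjusted = run_unadjusted_table(
            records, config.risk_factors, config.continuous_factors,
            config.strata, config.censoring_variants, config.ten_year_window)
        unadjusted.to_csv(outdir / "unadjusted.csv", index=False)
        estimates["unadjusted"] = [
            {k: _jsonable(v) for k, v in row.items()}
            for row in unadjusted.to_dict("records")
        ]

        stage = "conditional_table"
        conditional_rows = []
        for stratum in config.strata:
            spec = DEFAULT_MODELS[stratum]
            try:
                for res in conditional_table(records, spec,
                                             ten_year_window=config.ten_year_window):
                    conditional_rows.append({
                        "stratum": stratum, "variable": res.label,
                        "n_cases": res.n_cases, "n_controls": res.n_controls,
                        "or": res.or_point, "ci_lower": res.ci_lower,
                        "p_value": res.p_value,
                    })
                logger.info("conditional model (%s): %d cases / %d controls",
                            stratum, res.n_cases, res.n_controls)
            except (SeparationError, CollinearityError, ConvergenceError,
                    ValueError) as exc:
                logger.warning("conditional model (%s) failed: %s", stratum, exc)
                conditional_rows.append({
                    "stratum": stratum, "variable": None, "error": str(exc)})
        conditional = pd.DataFrame(conditional_rows)
        conditional.to_csv(outdir / "conditional.csv", index=False)
        estimates["conditional"] = [
            {k: _jsonable(v) for k, v in row.items()}
            for row in conditional_rows
        ]

        stage = "interaction_screen"
        interaction_rows = []
        spec = DEFAULT_MODELS[config.interaction_stratum]
        for pair in config.interaction_pairs:
            try:
                res = interaction_test(records, spec, pair,
                                       config.ten_year_window)
                interaction_rows.append({
                    "stratum": config.interaction_stratum,
                    "pair": f"{pair[0]}*{pair[1]}",
                    "coefficient": res.coefficient, "se": res.se,
                    "p_value": res.p_value,
                    "n_cases": res.n_cases, "n_controls": res.n_controls,
                })
            except (SeparationError, CollinearityError, ConvergenceError,
                    ValueError) as exc:
                interaction_rows.append({
                    "stratum": config.interaction_stratum,
                    "pair": f"{pair[0]}*{pair[1]}", "error": str(exc)})
        pd.DataFrame(interaction_rows).to_csv(
            outdir / "interactions.csv", index=False)
        estimates["interactions"] = [
            {k: _jsonable(v) for k, v in row.items()}
            for row in interaction_rows
        ]

        stage = "paf_table"
        paf_rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for stratum, exposures in config.paf_exposures.items():
                spec = DEFAULT_MODELS[stratum]
                component_bounds = []
                component_pafs = []
                for i, exposure in enumerate(exposures):
                    try:
                        res = adjusted_paf(records, spec, exposure,
                                           ten_year_window=config.ten_year_window)
                        lo, hi = paf_bootstrap_ci(
                            records, spec, exposure, B=config.bootstrap_b,
                            seed=config.seed + 1000 * i, level=0.95,
                            ten_year_window=config.ten_year_window)
                    except (SeparationError, CollinearityError,
                            ConvergenceError, ValueError, RuntimeError) as exc:
                        paf_rows.append({"stratum": stratum,
                                         "exposure": exposure,
                                         "error": str(exc)})
                        continue
                    component_bounds.append((lo, hi))
                    component_pafs.append(res.paf)
                    paf_rows.append({
                        "stratum": stratum, "exposure": exposure,
                        "paf": res.paf, "ci_lower": lo, "ci_upper": hi,
                        "or_adjusted": res.or_adjusted, "pc": res.pc,
                        "n_cases_used": res.n_cases_used,
                    })
                if (stratum in config.joint_strata
                        and len(component_pafs) == len(exposures)
                        and len(component_pafs) > 1):
                    jlo, jhi = joint_paf_bounds(component_bounds)
                    paf_rows.append({
                        "stratum": stratum,
                        "exposure": "joint:" + "+".join(exposures),
                        "paf": joint_paf(component_pafs),
                        "ci_lower": jlo, "ci_upper": jhi,
                    })
        pd.DataFrame(paf_rows).to_csv(outdir / "paf.csv", index=False)
        estimates["paf"] = [
            {k: _jsonable(v) for k, v in row.items()} for row in paf_rows
        ]
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "estimates.json").write_text(
        json.dumps(estimates, indent=2, sort_keys=True) + "\n")
    return estimates
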
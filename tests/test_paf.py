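"""Miettinen/Bruzzi attributable fractions, joint combination and intervals."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pafkit.association import ModelSpec, fit_logistic, two_by_two
from pafkit.cohort import SubjectRecord, TriBool, to_analysis_frame
from pafkit.paf import (
    adjusted_paf,
    bruzzi_paf,
    joint_paf,
    joint_paf_bounds,
    miettinen_paf,
    paf_bootstrap_ci,
    paf_delta_ci,
)
from pafkit.simulate import ExposureSpec, SyntheticConfig, simulate_cohort, true_paf

from conftest import make_binary_records


# -- Miettinen formula ------------------------------------------------------

@pytest.mark.parametrize("pc,or_adj,expected_pct", [
    (0.35, 2.85, 23),  # pesticide exposure, females
    (0.20, 2.00, 10),  # repeated blows, males
    (0.07, 6.03, 6),   # chemical-warfare agent, males
])
def test_miettinen_reproduces_reported_percentages(pc, or_adj, expected_pct):
    assert round(100 * miettinen_paf(pc, or_adj)) == expected_pct


def test_null_effect_gives_zero_paf():
    assert miettinen_paf(0.4, 1.0) == 0.0


def test_protective_factor_warns_and_stays_negative():
    with pytest.warns(UserWarning, match="protective"):
        assert miettinen_paf(0.3, 0.5) == pytest.approx(-0.3)


def test_miettinen_input_validation():
    with pytest.raises(ValueError):
        miettinen_paf(1.2, 2.0)
    with pytest.raises(ValueError):
        miettinen_paf(0.5, 0.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(pc=st.floats(0.01, 1.0), ratio=st.floats(1.0, 50.0),
       bump=st.floats(0.01, 10.0))
def test_miettinen_monotone_and_bounded(pc, ratio, bump):
    base = miettinen_paf(pc, ratio)
    assert base <= pc  # limit OR -> inf gives pc
    assert miettinen_paf(pc, ratio + bump) >= base
    if pc + 0.01 <= 1.0:
        assert miettinen_paf(pc + 0.01, ratio) >= base


# -- joint combination ------------------------------------------------------

def test_joint_paf_matches_reported_male_combination():
    components = [miettinen_paf(0.28, 2.52), miettinen_paf(0.07, 6.03),
                  miettinen_paf(0.20, 2.00)]
    assert round(100 * joint_paf(components)) == 30


def test_joint_bound_propagation_matches_reported_interval():
    lo, hi = joint_paf_bounds([(0.07, 0.27), (0.0003, 0.12), (0.003, 0.20)])
    assert round(100 * lo) == 7
    assert round(100 * hi) == 49


def test_joint_paf_identities():
    assert joint_paf([0.3]) == pytest.approx(0.3)
    assert joint_paf([0.0, 0.0, 0.0]) == 0.0
    assert joint_paf_bounds([(0.2, 0.2), (0.1, 0.1)]) == (
        pytest.approx(joint_paf([0.2, 0.1])),) * 2
    with pytest.raises(ValueError):
        joint_paf([0.5, 1.0])
    with pytest.raises(ValueError):
        joint_paf_bounds([(0.4, 0.2)])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 0.8), min_size=1, max_size=5))
def test_joint_paf_between_max_and_sum(components):
    joint = joint_paf(components)
    assert max(components) - 1e-12 <= joint
    assert joint <= min(1.0, sum(components)) + 1e-12


# -- model-based (Bruzzi) estimator -----------------------------------------

def test_bruzzi_equals_miettinen_for_single_binary_exposure():
    records = make_binary_records(30, 70, 20, 80, "pesticide")
    spec = ModelSpec(covariates=("pesticide",))
    fit = fit_logistic(records, spec)
    frame = to_analysis_frame(records)
    cases = frame[frame["status"] == 1]
    table = two_by_two(records, "pesticide")
    expected = miettinen_paf(table.a / table.n_cases,
                             (table.a * table.d) / (table.b * table.c))
    assert bruzzi_paf(fit, cases, "pesticide") == pytest.approx(
        expected, abs=1e-10)


def test_zero_coefficient_gives_zero_bruzzi_paf():
    records = make_binary_records(25, 75, 25, 75, "pesticide")
    fit = fit_logistic(records, ModelSpec(covariates=("pesticide",)))
    frame = to_analysis_frame(records)
    cases = frame[frame["status"] == 1]
    assert bruzzi_paf(fit, cases, "pesticide") == pytest.approx(0.0, abs=1e-12)


def test_bruzzi_closer_to_truth_than_crude_under_confounding():
    """Sex links two male-only exposures; adjustment must help."""
    config = SyntheticConfig(
        n_cases=10000, n_controls=10000, baseline_logit=-5.0,
        exposures=[
            ExposureSpec("pesticide", 0.3, math.log(2.0), male_only=True),
            ExposureSpec("repeated_blows", 0.4, math.log(3.0), male_only=True),
        ],
        male_fraction=0.5, seed=7)
    records = simulate_cohort(config)
    truth = true_paf(config, "pesticide")
    table = two_by_two(records, "pesticide")
    crude = miettinen_paf(table.a / table.n_cases,
                          (table.a * table.d) / (table.b * table.c))
    spec = ModelSpec(covariates=("pesticide", "repeated_blows"))
    fit = fit_logistic(records, spec)
    frame = to_analysis_frame(records)
    sub = frame[["status", "pesticide", "repeated_blows"]].dropna()
    adjusted = bruzzi_paf(fit, sub[sub["status"] == 1], "pesticide")
    assert abs(adjusted - truth) < abs(crude - truth)


# -- adjusted PAF and intervals ---------------------------------------------

def test_adjusted_paf_single_exposure_equals_marginal_miettinen():
    records = make_binary_records(188, 406, 45, 269, "pesticide")
    result = adjusted_paf(records, ModelSpec(covariates=("pesticide",)),
                          "pesticide")
    table = two_by_two(records, "pesticide")
    expected = miettinen_paf(table.a / table.n_cases,
                             (table.a * table.d) / (table.b * table.c))
    assert result.paf == pytest.approx(expected, abs=1e-10)
    assert result.pc == pytest.approx(188 / 594)
    assert result.n_cases_used == 594


def test_adjusted_paf_null_exposure_is_near_zero():
    config = SyntheticConfig(
        n_cases=3000, n_controls=1500, baseline_logit=-3.0,
        exposures=[ExposureSpec("family_history", 0.2, math.log(2.5)),
                   ExposureSpec("pesticide", 0.3, 0.0)], seed=17)
    records = simulate_cohort(config)
    spec = ModelSpec(covariates=("family_history", "pesticide"))
    result = adjusted_paf(records, spec, "pesticide")
    assert abs(result.paf) < 0.07


def test_bootstrap_interval_is_deterministic(study_cohort):
    spec = ModelSpec(covariates=("family_history", "pesticide"),
                     stratum="female")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        first = paf_bootstrap_ci(study_cohort, spec, "pesticide",
                                 B=150, seed=11)
        second = paf_bootstrap_ci(study_cohort, spec, "pesticide",
                                  B=150, seed=11)
    assert first == second


def test_bootstrap_degenerate_constant_exposure():
    records = [SubjectRecord(subject_id=f"d{i}",
                             status="case" if i < 40 else "control",
                             pesticide=TriBool.NO).validate()
               for i in range(80)]
    spec = ModelSpec(covariates=("pesticide",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = adjusted_paf(records, spec, "pesticide")
        lo, hi = paf_bootstrap_ci(records, spec, "pesticide", B=100, seed=1)
    assert result.paf == 0.0
    assert (lo, hi) == (0.0, 0.0)


def test_bootstrap_requires_minimum_replicates(study_cohort):
    spec = ModelSpec(covariates=("pesticide",))
    with pytest.raises(ValueError, match="at least 100"):
        paf_bootstrap_ci(study_cohort, spec, "pesticide", B=50, seed=1)


def test_delta_interval_roughly_matches_bootstrap(study_cohort):
    spec = ModelSpec(covariates=("family_history", "pesticide"))
    point = adjusted_paf(study_cohort, spec, "pesticide").paf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        blo, bhi = paf_bootstrap_ci(study_cohort, spec, "pesticide",
                                    B=400, seed=5)
    dlo, dhi = paf_delta_ci(study_cohort, spec, "pesticide")
    assert dlo < point < dhi and blo < point < bhi
    assert (dhi - dlo) == pytest.approx(bhi - blo, rel=0.5)
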
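"""Odds ratios, logistic fits, interaction screens and the proportion test."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pafkit.association import (
    CollinearityError,
    ModelSpec,
    MODEL_FEMALE,
    SeparationError,
    TwoByTwoTable,
    ZeroCellError,
    conditional_table,
    fit_logistic,
    fit_logit_arrays,
    interaction_test,
    odds_ratio,
    one_proportion_test,
    two_by_two,
)
from pafkit.cohort import SubjectRecord, TriBool, complete_case_subset
from pafkit.simulate import ExposureSpec, SyntheticConfig, simulate_cohort

from conftest import make_binary_records


# -- 2x2 counting -----------------------------------------------------------

def test_two_by_two_counts_hand_built_records():
    records = make_binary_records(2, 1, 1, 2, exposure="pesticide")
    table = two_by_two(records, "pesticide")
    assert (table.a, table.b, table.c, table.d) == (2, 1, 1, 2)


def test_two_by_two_excludes_unknowns():
    records = make_binary_records(2, 1, 1, 2)
    records.append(SubjectRecord(subject_id="u", status="case").validate())
    table = two_by_two(records, "pesticide")
    assert table.n_cases == 3 and table.n_controls == 3


def test_two_by_two_structural_zero_in_female_stratum(study_cohort):
    table = two_by_two(study_cohort, "repeated_blows", stratum="female")
    assert table.a == 0 and table.c == 0


def test_two_by_two_empty_stratum_errors():
    records = make_binary_records(2, 2, 2, 2, sex="male")
    with pytest.raises(ValueError, match="female"):
        two_by_two(records, "pesticide", stratum="female")


def test_stratified_counts_sum_to_totals(study_cohort):
    sexed = [r for r in study_cohort if r.sex != "unknown"]
    total = two_by_two(sexed, "pesticide")
    male = two_by_two(sexed, "pesticide", stratum="male")
    female = two_by_two(sexed, "pesticide", stratum="female")
    for cell in "abcd":
        assert getattr(total, cell) == getattr(male, cell) + getattr(female, cell)


# -- odds ratios ------------------------------------------------------------

def test_one_sided_woolf_matches_printed_family_history_row():
    res = odds_ratio(TwoByTwoTable(245, 506, 59, 344), sidedness="one")
    assert res.or_point == pytest.approx(2.82, abs=0.005)
    assert res.ci_lower == pytest.approx(2.17, abs=0.005)
    assert res.ci_upper == math.inf
    assert res.p_value == pytest.approx(6e-11, rel=0.2)


def test_haldane_correction_handles_zero_cell():
    res = odds_ratio(TwoByTwoTable(47, 432, 0, 229), correction="haldane")
    assert res.or_point == pytest.approx(50.4, abs=0.05)
    assert res.ci_lower == pytest.approx(3.1, abs=0.05)
    assert res.ci_upper == pytest.approx(821.5, abs=0.5)
    with pytest.raises(ZeroCellError, match="haldane"):
        odds_ratio(TwoByTwoTable(47, 432, 0, 229), correction="none")


@pytest.mark.parametrize("k", [1, 7, 50])
def test_balanced_table_is_null(k):
    res = odds_ratio(TwoByTwoTable(k, k, k, k), sidedness="one")
    assert res.or_point == pytest.approx(1.0)
    assert res.p_value == pytest.approx(0.5)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(1, 300)] * 4))
def test_exposure_recoding_inverts_odds_ratio(cells):
    """Swapping exposed/unexposed labels maps OR to 1/OR."""
    a, b, c, d = cells
    fwd = odds_ratio(TwoByTwoTable(a, b, c, d))
    rev = odds_ratio(TwoByTwoTable(b, a, d, c))
    assert fwd.or_point * rev.or_point == pytest.approx(1.0, rel=1e-12)
    assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(1, 300)] * 4))
def test_one_sided_bound_nests_inside_two_sided(cells):
    one = odds_ratio(TwoByTwoTable(*cells), sidedness="one")
    two = odds_ratio(TwoByTwoTable(*cells), sidedness="two")
    assert one.ci_lower >= two.ci_lower


# -- logistic fitting -------------------------------------------------------

def test_single_covariate_fit_reproduces_cross_product():
    records = make_binary_records(245, 506, 59, 344, "family_history")
    fit = fit_logistic(records, ModelSpec(covariates=("family_history",)))
    expected = (245 * 344) / (506 * 59)
    assert math.exp(fit.params["family_history"]) == pytest.approx(
        expected, rel=1e-8)
    z = fit.params["family_history"] / fit.bse["family_history"]
    assert stats.norm.sf(z) == pytest.approx(6e-11, rel=0.2)
    assert (fit.n_cases, fit.n_controls) == (751, 403)


def test_fit_matches_brute_force_grid_maximizer():
    """30-row fixture: IRLS equals coarse-to-fine grid maximization."""
    rng = np.random.default_rng(42)
    X = np.column_stack([
        np.ones(30), rng.normal(size=30),
        rng.integers(0, 2, 30).astype(float), rng.normal(size=30)])
    beta_true = np.array([-0.3, 0.8, -0.5, 0.4])
    y = (rng.random(30) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
    beta, _, _, _ = fit_logit_arrays(X, y)

    def loglik(b):
        eta = X @ b
        return float(np.sum(y * eta - np.log1p(np.exp(eta))))

    import itertools
    center, width = np.zeros(4), 8.0
    for _ in range(12):
        grids = [np.linspace(center[j] - width, center[j] + width, 9)
                 for j in range(4)]
        best, best_ll = center, -np.inf
        for combo in itertools.product(*grids):
            ll = loglik(np.array(combo))
            if ll > best_ll:
                best_ll, best = ll, np.array(combo)
        center, width = best, width / 3.5
    assert np.max(np.abs(beta - center)) < 1e-4


def test_fit_agrees_with_statsmodels(study_cohort):
    import statsmodels.api as sm

    from pafkit.cohort import to_analysis_frame

    covariates = ("age", "family_history", "mtbi", "pesticide")
    spec = ModelSpec(covariates=covariates, stratum="female")
    fit = fit_logistic(study_cohort, spec)
    frame = to_analysis_frame(study_cohort)
    sub = frame[frame["sex"] == "female"][["status", *covariates]].dropna()
    sm_fit = sm.Logit(sub["status"], sm.add_constant(sub[list(covariates)])).fit(
        disp=0)
    assert np.allclose(fit.params.to_numpy(), sm_fit.params.to_numpy(),
                       atol=1e-6)
    assert np.allclose(fit.bse.to_numpy(), sm_fit.bse.to_numpy(), atol=1e-6)


def test_null_covariate_recovers_or_of_one():
    config = SyntheticConfig(
        n_cases=2500, n_controls=2500, baseline_logit=0.0,
        exposures=[ExposureSpec("pesticide", 0.4, 0.0)], seed=21)
    records = simulate_cohort(config)
    fit = fit_logistic(records, ModelSpec(covariates=("pesticide",)))
    assert math.exp(fit.params["pesticide"]) == pytest.approx(1.0, abs=0.15)


def test_separation_raises_named_error():
    # exposure perfectly predicts case status
    records = make_binary_records(40, 0, 0, 40, "pesticide")
    with pytest.raises(SeparationError, match="pesticide"):
        fit_logistic(records, ModelSpec(covariates=("pesticide",)))


def test_collinear_design_raises_named_error():
    # without censoring, mtbi and its 10-year recode are identical columns
    records = make_binary_records(30, 20, 15, 35, "mtbi")
    with pytest.raises(CollinearityError, match="mtbi"):
        fit_logistic(records, ModelSpec(covariates=("mtbi", "mtbi_10yr")))


def test_sex_is_rejected_as_stratum_covariate():
    with pytest.raises(ValueError, match="collinear"):
        ModelSpec(covariates=("age", "sex"), stratum="male")


# -- conditional tables and interactions ------------------------------------

def test_female_model_reports_four_terms(study_cohort):
    rows = conditional_table(study_cohort, MODEL_FEMALE)
    assert [r.label for r in rows] == ["age", "family_history", "mtbi",
                                       "pesticide"]
    assert all(r.sidedness == "one" and r.ci_upper == math.inf for r in rows)
    n = len(complete_case_subset(
        [r for r in study_cohort if r.sex == "female"],
        ["status", "age", "family_history", "mtbi", "pesticide"]))
    assert rows[0].n_cases + rows[0].n_controls == n


def test_null_covariate_in_loaded_model_is_near_one():
    config = SyntheticConfig(
        n_cases=3000, n_controls=1500, baseline_logit=-3.0,
        exposures=[ExposureSpec("family_history", 0.2, math.log(2.5)),
                   ExposureSpec("pesticide", 0.3, 0.0)], seed=13)
    records = simulate_cohort(config)
    rows = conditional_table(
        records, ModelSpec(covariates=("family_history", "pesticide")))
    by_name = {r.label: r for r in rows}
    assert by_name["pesticide"].or_point == pytest.approx(1.0, abs=0.2)
    assert by_name["family_history"].or_point == pytest.approx(2.5, rel=0.2)


def test_interaction_requires_model_membership(study_cohort):
    with pytest.raises(ValueError, match="must be in the model"):
        interaction_test(study_cohort, MODEL_FEMALE,
                         ("pesticide", "agent_orange"))


def test_interaction_of_identical_columns_is_an_error():
    records = make_binary_records(30, 20, 15, 35, "mtbi")
    spec = ModelSpec(covariates=("mtbi", "mtbi_10yr"))
    with pytest.raises((CollinearityError, SeparationError)):
        interaction_test(records, spec, ("mtbi", "mtbi_10yr"))


def test_interaction_power_at_strong_product_term():
    config = SyntheticConfig(
        n_cases=2500, n_controls=2500, baseline_logit=-3.0,
        exposures=[ExposureSpec("pesticide", 0.3, math.log(2.0)),
                   ExposureSpec("mtbi", 0.3, math.log(1.5))],
        seed=31)
    from pafkit.simulate import InteractionSpec

    config.interactions = [InteractionSpec(("pesticide", "mtbi"), 1.0)]
    records = simulate_cohort(config)
    res = interaction_test(records,
                           ModelSpec(covariates=("pesticide", "mtbi")),
                           ("pesticide", "mtbi"))
    assert res.p_value < 0.05
    assert res.coefficient == pytest.approx(1.0, abs=0.4)


# -- one-proportion test ----------------------------------------------------

def test_male_excess_among_cases_is_significant():
    assert one_proportion_test(512, 808, 0.5) < 1e-5


def test_exact_null_proportion_gives_p_one():
    assert one_proportion_test(50, 100, 0.5) == pytest.approx(1.0)


def test_proportion_test_tracks_exact_binomial():
    exact = stats.binomtest(60, 100, 0.5).pvalue
    assert one_proportion_test(60, 100, 0.5) == pytest.approx(exact, abs=0.015)


def test_proportion_test_input_validation():
    with pytest.raises(ValueError):
        one_proportion_test(1, 0, 0.5)
    with pytest.raises(ValueError):
        one_proportion_test(5, 4, 0.5)
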
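"""Policy simulation: row arithmetic, oracles, intervals, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from cd4rd import (
    CD4Distribution,
    GlobalRDFit,
    PolicyScenario,
    UptakeCurve,
    complete_rows,
    confidence_band,
    national_projection,
    predict_uptake,
    propagate_uncertainty,
    sensitivity_scenario,
    simulate_policy,
)


def _dist_from_counts(counts):
    pmf = np.asarray(counts, float)
    pmf = pmf / pmf.sum()
    return CD4Distribution(
        pmf=pmf,
        n=int(np.sum(counts)),
        range_masses=(float(pmf[:350].sum()), float(pmf[350:500].sum()), float(pmf[500:].sum())),
    )


def _curve(p, label="if_eligible"):
    p = np.asarray(p, float)
    return UptakeCurve(grid=np.arange(p.size), p=p, lo95=p, hi95=p, regime_label=label)


@pytest.fixture(scope="module")
def flat_setup():
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 40, size=1000)
    fcd4 = _dist_from_counts(counts)
    p_e = expit(-0.37 - 0.002 * (np.arange(1000) - 350))
    p_i = np.full(1000, 0.08)
    return fcd4, _curve(p_e), _curve(p_i, "if_ineligible")


def test_no_effect_identity(flat_setup):
    fcd4, ce, ci = flat_setup
    impact = simulate_policy(fcd4, ci, ci, PolicyScenario.eliminate_threshold(), 8000, 2200)
    assert impact.pct_new_initiators == pytest.approx(0.0, abs=1e-12)
    assert impact.pct_increase_in_initiators == pytest.approx(0.0, abs=1e-12)


def test_conservation_identities(flat_setup):
    fcd4, ce, ci = flat_setup
    for scenario in (PolicyScenario.raise_to_500(), PolicyScenario.eliminate_threshold()):
        im = simulate_policy(fcd4, ce, ci, scenario, 8000, 2200)
        assert im.pct_initiate_old_regime + im.pct_new_initiators == pytest.approx(
            im.pct_initiate_expanded, abs=1e-9
        )
        assert im.pct_initiate_expanded + im.pct_not_initiating == pytest.approx(100.0, abs=1e-9)


def test_scenario_additivity_in_absolute_new_initiators(flat_setup):
    fcd4, ce, ci = flat_setup
    refs = dict(n_presenters_ref=7973, n_initiators_ref=2233)

    def absolute(lo, hi):
        im = simulate_policy(
            fcd4, ce, ci, PolicyScenario((lo, hi), f"r{lo}"), **refs
        )
        return im.pct_new_initiators / 100 * im.pct_of_presenters / 100 * 7973

    assert absolute(350, 500) + absolute(500, 1000) == pytest.approx(
        absolute(350, 1000), abs=1e-9
    )


def test_monotonicity_in_range_size(flat_setup):
    fcd4, ce, ci = flat_setup

    def absolute(lo, hi):
        im = simulate_policy(fcd4, ce, ci, PolicyScenario((lo, hi), "x"), 8000, 2200)
        return im.pct_new_initiators / 100 * im.pct_of_presenters / 100 * 8000

    vals = [absolute(350, hi) for hi in (450, 600, 800, 1000)]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


def test_per_patient_brute_force_equals_pmf_integration(reg_sample, global_fit, fcd4_2013):
    """Summing predictions patient-by-patient matches the pmf-weighted sum."""
    ce = confidence_band(global_fit, eligible=True)
    ci = confidence_band(global_fit, eligible=False)
    # pmf built from the same records the brute force iterates over
    from datetime import date
    from cd4rd import estimate_cd4_distribution

    cohort_df = reg_sample.records
    dist = estimate_cd4_distribution(reg_sample, date(2011, 8, 12), date(2013, 6, 30))
    for lo, hi in ((350, 500), (500, 1000)):
        im = simulate_policy(dist, ce, ci, PolicyScenario((lo, hi), "x"), 7973, 2233)
        sub = cohort_df[(cohort_df["cd4"] >= lo) & (cohort_df["cd4"] < hi)]
        p_e = predict_uptake(global_fit, sub["cd4"].to_numpy(), eligible=True)
        p_i = predict_uptake(global_fit, sub["cd4"].to_numpy(), eligible=False)
        assert im.pct_initiate_expanded == pytest.approx(100 * p_e.mean(), abs=1e-9)
        assert im.pct_initiate_old_regime == pytest.approx(100 * p_i.mean(), abs=1e-9)
        assert im.pct_new_initiators == pytest.approx(100 * (p_e - p_i).mean(), abs=1e-9)


def test_empty_range_rejected(flat_setup):
    fcd4, ce, ci = flat_setup
    pmf = fcd4.pmf.copy()
    pmf[600:] = 0.0
    gutted = CD4Distribution(pmf=pmf / pmf.sum(), n=fcd4.n, range_masses=fcd4.range_masses)
    with pytest.raises(ValueError, match="no probability mass"):
        simulate_policy(gutted, ce, ci, PolicyScenario((700, 900), "x"), 8000, 2200)


@given(
    row1=st.floats(1.0, 100.0),
    row2=st.floats(0.0, 50.0),
    gain=st.floats(0.0, 50.0),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_row_arithmetic_identities_hold_generally(row1, row2, gain):
    row3 = row2 + gain
    rows = complete_rows(row1, row2, row3, 7973, 2233)
    assert row2 + rows["pct_new_initiators"] == pytest.approx(row3, abs=1e-9)
    assert row3 + rows["pct_not_initiating"] == pytest.approx(100.0, abs=1e-9)
    assert rows["pct_increase_in_initiators"] >= 0.0


def test_national_projection_rounding():
    up = national_projection(26.7, 614_000, 3_000_000)
    assert up.additional_initiators_per_year == pytest.approx(163_938, abs=1)
    assert up.additional_initiators_rounded == 164_000

    mid = national_projection(21.2, 614_000, 3_000_000)
    assert mid.additional_initiators_per_year == pytest.approx(130_168, abs=1)
    assert mid.additional_initiators_rounded == 130_000
    assert mid.pct_increase_on_art == pytest.approx(4.3, abs=0.05)

    assert national_projection(0.0).additional_initiators_per_year == 0.0


def test_zero_vcov_gives_degenerate_intervals(global_fit, fcd4_2013):
    fit0 = GlobalRDFit(
        threshold=350, coef=global_fit.coef, vcov=np.zeros((4, 4)),
        n_obs=global_fit.n_obs, loglik=global_fit.loglik,
    )
    iv = propagate_uncertainty(
        fit0, fcd4_2013, PolicyScenario.eliminate_threshold(), 7973, 2233,
        n_draws=1000, seed=0,
    )
    for lo, hi in iv.values():
        assert hi - lo == pytest.approx(0.0, abs=1e-12)


def test_intervals_contain_point_estimate(global_fit, fcd4_2013):
    """Percentile intervals bracket the MLE point estimate (rare misses only)."""
    ce = confidence_band(global_fit, eligible=True)
    ci = confidence_band(global_fit, eligible=False)
    scenario = PolicyScenario.eliminate_threshold()
    point = simulate_policy(fcd4_2013, ce, ci, scenario, 7973, 2233)
    misses = 0
    for seed in range(40):
        iv = propagate_uncertainty(
            global_fit, fcd4_2013, scenario, 7973, 2233, n_draws=1000, seed=seed
        )
        lo, hi = iv["pct_initiate_expanded"]
        misses += not (lo <= point.pct_initiate_expanded <= hi)
    assert misses <= 2


def test_more_data_tightens_intervals(global_fit, fcd4_2013):
    """Shrinking the coefficient covariance shrinks interval width."""
    scenario = PolicyScenario.eliminate_threshold()
    wide = propagate_uncertainty(global_fit, fcd4_2013, scenario, 7973, 2233,
                                 n_draws=4000, seed=1)
    tight_fit = GlobalRDFit(
        threshold=350, coef=global_fit.coef, vcov=global_fit.vcov / 4,
        n_obs=global_fit.n_obs, loglik=global_fit.loglik,
    )
    tight = propagate_uncertainty(tight_fit, fcd4_2013, scenario, 7973, 2233,
                                  n_draws=4000, seed=1)
    for key in wide:
        assert tight[key][1] - tight[key][0] < wide[key][1] - wide[key][0]


def test_sensitivity_dominates_primary_for_declining_uptake(global_fit, fcd4_2013):
    assert global_fit.beta_below < 0
    ce = confidence_band(global_fit, eligible=True)
    ci = confidence_band(global_fit, eligible=False)
    for scenario in (PolicyScenario.raise_to_500(), PolicyScenario.eliminate_threshold()):
        primary = simulate_policy(fcd4_2013, ce, ci, scenario, 7973, 2233)
        sens = sensitivity_scenario(global_fit, fcd4_2013, scenario, 7973, 2233)
        assert sens.pct_initiate_expanded >= primary.pct_initiate_expanded


def test_sensitivity_equals_primary_with_flat_slope(fcd4_2013):
    fit = GlobalRDFit(
        threshold=350, coef=np.array([-2.0, 1.5, 0.0, 0.0]), vcov=np.zeros((4, 4)),
        n_obs=100, loglik=-1.0,
    )
    ce = confidence_band(fit, eligible=True)
    ci = confidence_band(fit, eligible=False)
    scenario = PolicyScenario.eliminate_threshold()
    primary = simulate_policy(fcd4_2013, ce, ci, scenario, 7973, 2233)
    sens = sensitivity_scenario(fit, fcd4_2013, scenario, 7973, 2233)
    assert sens.pct_initiate_expanded == pytest.approx(primary.pct_initiate_expanded, abs=1e-12)
    assert sens.pct_new_initiators == pytest.approx(primary.pct_new_initiators, abs=1e-12)
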
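"""Case-cohort Cox fitting: oracles, errors, and the PH assumption test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from thrombopaf import (
    CaseCohortSample,
    check_proportional_hazards,
    fit_cox_casecohort,
)
from thrombopaf.genotypes import carrier_indicator

from conftest import make_sample


def brute_force_breslow_loglik(beta, entry, exit_, event, x):
    """Direct summation of the Breslow partial likelihood: independent of
    the package's vectorized implementation."""
    ll = 0.0
    for t in sorted(set(exit_[event == 1])):
        events_at_t = [i for i in range(len(x)) if event[i] and exit_[i] == t]
        risk = [i for i in range(len(x)) if entry[i] < t <= exit_[i]]
        s0 = sum(np.exp(beta * x[i]) for i in risk)
        for i in events_at_t:
            ll += beta * x[i]
        ll -= len(events_at_t) * np.log(s0)
    return ll


def test_tiny_fixture_matches_grid_search_oracle(tiny_sample, tiny_exposure):
    """Newton maximizer agrees with brute-force grid search to 1e-4."""
    fit = fit_cox_casecohort(tiny_sample, tiny_exposure, ties="breslow")
    entry = tiny_sample.data["entry_age"].to_numpy()
    exit_ = tiny_sample.data["exit_age"].to_numpy()
    event = tiny_sample.data["event"].to_numpy()
    grid = np.arange(-3.0, 3.0, 1e-4)
    lls = [brute_force_breslow_loglik(b, entry, exit_, event, tiny_exposure)
           for b in grid]
    best = grid[int(np.argmax(lls))]
    assert abs(fit.coef[0] - best) <= 1e-4
    # and the reported log-likelihood matches the direct evaluation
    assert fit.log_partial_likelihood == pytest.approx(
        brute_force_breslow_loglik(fit.coef[0], entry, exit_, event,
                                   tiny_exposure), abs=1e-10)


def test_full_cohort_fit_matches_independent_implementation(sim_casecohort):
    """With subcohort = full cohort, Prentice weighting degenerates and the
    fit must agree with a standard delayed-entry Cox fit (lifelines)."""
    from lifelines import CoxPHFitter

    from thrombopaf import sample_case_cohort, simulate_cohort, CohortConfig
    from thrombopaf.panel import Panel, SnpDef

    panel = Panel([SnpDef("rs0", "T", risk_allele_freq=0.106,
                          log_hr_female=np.log(2), log_hr_male=np.log(2))])
    cohort = simulate_cohort(CohortConfig(
        n_individuals=4_000, panel=panel, seed=17, baseline_lambda=2.5e-5))
    full = sample_case_cohort(cohort, len(cohort), seed=0)
    x = carrier_indicator(full.data["rs0"])
    bmi = full.data["bmi"].to_numpy()
    z = (bmi - bmi.mean()) / bmi.std()
    fit = fit_cox_casecohort(full, x, z, ties="efron")

    df = pd.DataFrame({
        "entry": full.data["entry_age"], "exit": full.data["exit_age"],
        "event": full.data["event"], "x": x, "z": z,
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="exit", event_col="event", entry_col="entry")
    assert np.allclose(fit.coef, cph.params_.values, atol=2e-5)


def test_prentice_differs_from_unweighted(sim_casecohort):
    """Outside-subcohort cases carry full risk time only when unweighted."""
    x = carrier_indicator(sim_casecohort.data["rs0"])
    fit_p = fit_cox_casecohort(sim_casecohort, x, weighting="prentice")
    fit_u = fit_cox_casecohort(sim_casecohort, x, weighting="unweighted")
    assert fit_p.coef[0] != fit_u.coef[0]
    assert fit_p.n_events == fit_u.n_events


def test_zero_events_and_constant_exposure_error(tiny_sample):
    df = tiny_sample.data.copy()
    df["event"] = 0
    df["is_case"] = False
    censored = CaseCohortSample(df, 6, 6)
    with pytest.raises(ValueError, match="no events"):
        fit_cox_casecohort(censored, np.array([1.0, 0, 1, 0, 1, 0]))
    with pytest.raises(ValueError, match="constant"):
        fit_cox_casecohort(tiny_sample, np.ones(6))


def test_complete_separation_flagged_not_fabricated():
    """All events among exposed, none among unexposed, no overlap in risk
    sets that could bound the estimate: monotone likelihood."""
    df = pd.DataFrame({
        "id": range(6),
        "sex": ["male"] * 6,
        "entry_age": [40.0] * 6,
        "exit_age": [41, 42, 43, 50, 51, 52.0],
        "event": [1, 1, 1, 0, 0, 0],
        "bmi": 25.0,
    })
    sample = make_sample(df)
    expo = np.array([1.0, 1, 1, 0, 0, 0])
    fit = fit_cox_casecohort(sample, expo)
    assert not fit.converged
    assert "separation" in fit.diagnostic or "convergence" in fit.diagnostic
    assert np.isnan(fit.se_robust).all()


def test_missing_rows_dropped_complete_case(sim_casecohort):
    x = carrier_indicator(sim_casecohort.data["rs0"]).copy()
    x[:50] = np.nan
    fit = fit_cox_casecohort(sim_casecohort, x)
    assert fit.n_dropped == 50
    assert fit.n_used == sim_casecohort.n - 50


def test_fit_invariant_to_row_order_and_ids(sim_casecohort):
    x = carrier_indicator(sim_casecohort.data["rs0"])
    fit = fit_cox_casecohort(sim_casecohort, x)
    rng = np.random.default_rng(0)
    perm = rng.permutation(sim_casecohort.n)
    df = sim_casecohort.data.iloc[perm].reset_index(drop=True)
    df["id"] = np.arange(len(df)) + 10_000
    shuffled = CaseCohortSample(
        df, sim_casecohort.subcohort_size, sim_casecohort.source_size)
    fit2 = fit_cox_casecohort(shuffled, x[perm])
    assert np.allclose(fit.coef, fit2.coef, atol=1e-10)
    assert np.allclose(fit.se_robust, fit2.se_robust, atol=1e-10)


def _simulate_ph_data(rng, n=300, reverse=False):
    """Exponential event times; optionally the exposure effect flips sign at
    t = 1 (a gross proportional-hazards violation). The baseline rate is
    kept low enough that both periods contribute events."""
    x = rng.integers(0, 2, n).astype(float)
    t = np.empty(n)
    for i in range(n):
        if not reverse:
            t[i] = rng.exponential(1.0)
        else:
            # hazard 0.35 e^{+1.5 x} before t=1, 0.35 e^{-1.5 x} after
            rate1 = 0.35 * np.exp(1.5 * x[i])
            t1 = rng.exponential(1 / rate1)
            if t1 < 1.0:
                t[i] = t1
            else:
                rate2 = 0.35 * np.exp(-1.5 * x[i])
                t[i] = 1.0 + rng.exponential(1 / rate2)
    cens = rng.uniform(2.5, 4.0, n) if reverse else rng.uniform(1.5, 3.0, n)
    event = (t <= cens).astype(int)
    df = pd.DataFrame({
        "id": range(n), "sex": ["female"] * n,
        "entry_age": 1e-6, "exit_age": np.minimum(t, cens) + 1e-5,
        "event": event, "bmi": 25.0,
    })
    return make_sample(df), x


def test_ph_test_calibrated_under_null():
    """Under proportional hazards the score test rejects at ~ alpha."""
    rng = np.random.default_rng(1234)
    rejections = 0
    n_reps = 200
    for _ in range(n_reps):
        sample, x = _simulate_ph_data(rng)
        fit = fit_cox_casecohort(sample, x)
        stat, p = check_proportional_hazards(fit)["exposure"]
        rejections += p < 0.05
    assert 0.005 <= rejections / n_reps <= 0.11


def test_ph_test_detects_reversing_effect():
    """An effect that flips sign mid-follow-up is flagged far above alpha."""
    rng = np.random.default_rng(99)
    rejections = 0
    for _ in range(20):
        sample, x = _simulate_ph_data(rng, n=600, reverse=True)
        fit = fit_cox_casecohort(sample, x)
        stat, p = check_proportional_hazards(fit)["exposure"]
        rejections += p < 0.05
    assert rejections >= 15


def test_ph_statistic_zero_when_residuals_vanish():
    """Exposure perfectly balanced at every event time -> all Schoenfeld
    residuals zero -> statistic exactly 0."""
    df = pd.DataFrame({
        "id": range(4), "sex": ["male"] * 4,
        "entry_age": [0.0] * 4,
        "exit_age": [1.0, 1.0, 2.0, 2.0],
        "event": [1, 1, 1, 1], "bmi": 25.0,
    })
    sample = make_sample(df)
    expo = np.array([1.0, 0.0, 1.0, 0.0])
    fit = fit_cox_casecohort(sample, expo, ties="breslow")
    stat, p = check_proportional_hazards(fit)["exposure"]
    assert stat == pytest.approx(0.0, abs=1e-20)
    assert p == pytest.approx(1.0)


def test_ph_test_requires_enough_events(tiny_sample, tiny_exposure):
    fit = fit_cox_casecohort(tiny_sample, tiny_exposure)
    df = tiny_sample.data.copy()
    df.loc[df.index[1:], "event"] = 0
    df.loc[df.index[1:], "is_case"] = False
    one_event = CaseCohortSample(df, 6, 6)
    # a single event with a binary exposure has a monotone likelihood, so
    # the test refuses either way: too few events or no converged fit
    fit1 = fit_cox_casecohort(one_event, tiny_exposure)
    with pytest.raises(ValueError, match="events|converged"):
        check_proportional_hazards(fit1)
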
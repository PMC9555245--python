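"""Economic model: risk combination, Markov trace, cohort outcomes."""

import math
from dataclasses import replace

import numpy as np
import pytest

from bootce import (EconParams, TreatmentEffects, combined_relative_risk,
                    markov_trace, run_cohort_model)

DEFAULTS = EconParams()


# --- combined relative risk -------------------------------------------------

def test_rr_identity_when_effects_are_zero():
    assert combined_relative_risk(TreatmentEffects(), DEFAULTS) == 1.0


def test_rr_null_switch_overrides_any_effects():
    eff = TreatmentEffects(-5.0, -8.0, -0.17)
    assert combined_relative_risk(eff, replace(DEFAULTS, null_effect=True)) == 1.0


def test_rr_closed_form_single_factor():
    # log-RR of log(1/0.98) per mg/dL, 5 mg/dL reduction -> RR = 0.98^5
    params = replace(DEFAULTS, beta_ldl=-math.log(0.98))
    eff = TreatmentEffects(ldl_change=-5.0)
    assert combined_relative_risk(eff, params) == pytest.approx(0.98 ** 5,
                                                                abs=1e-12)


def test_rr_smoking_scaling():
    # removing every baseline smoker applies the full quit RR
    params = replace(DEFAULTS, beta_ldl=0.0, beta_sbp=0.0,
                     baseline_smoking_prev=0.4)
    eff = TreatmentEffects(smoking_prev_change=-0.4)
    assert combined_relative_risk(eff, params) == pytest.approx(
        params.rr_smoking_quit, abs=1e-12)


def test_rr_zero_baseline_prevalence_is_an_error():
    params = replace(DEFAULTS, baseline_smoking_prev=0.0)
    with pytest.raises(ValueError, match="baseline"):
        combined_relative_risk(TreatmentEffects(smoking_prev_change=-0.1),
                               params)


# --- Markov trace ------------------------------------------------------------

def _path_enumeration_oracle(rr, params):
    """Expected discounted per-patient cost and QALYs by exhaustive
    enumeration of every state/branch path through the model."""
    pe = params.annual_event_rate * rr
    bm = params.background_mortality
    cf = params.case_fatality
    r = params.discount_rate

    def rec(state, t):
        if t == params.horizon_years:
            return 0.0, 0.0
        disc = (1.0 + r) ** -t
        if state == "D":
            return 0.0, 0.0
        if state == "F":
            qaly_here = disc * params.utility_well
            branches = [
                (1.0 - pe - bm, "F", 0.0),
                (pe * (1.0 - cf), "P", params.event_cost),
                (pe * cf, "D", params.event_cost),
                (bm, "D", 0.0),
            ]
            cost_here = 0.0
        else:  # post-event
            qaly_here = disc * params.utility_post_event
            cost_here = disc * params.annual_care_cost
            branches = [(1.0 - bm, "P", 0.0), (bm, "D", 0.0)]
        cost = cost_here
        qaly = qaly_here
        for prob, nxt, event_cost in branches:
            if prob == 0.0:
                continue
            c_next, q_next = rec(nxt, t + 1)
            cost += prob * (disc * event_cost + c_next)
            qaly += prob * q_next
        return cost, qaly

    return rec("F", 0)


def test_trace_matches_path_enumeration_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(10):
        params = EconParams(
            annual_event_rate=rng.uniform(0.01, 0.3),
            case_fatality=rng.uniform(0.0, 0.5),
            background_mortality=rng.uniform(0.0, 0.2),
            event_cost=rng.uniform(1e3, 5e4),
            annual_care_cost=rng.uniform(0, 5e3),
            utility_well=rng.uniform(0.7, 1.0),
            utility_post_event=rng.uniform(0.3, 0.7),
            horizon_years=int(rng.integers(1, 5)),
            discount_rate=rng.uniform(0.0, 0.1),
        )
        rr = rng.uniform(0.3, 1.5)
        trace = markov_trace(rr, params)
        cost, qaly = _path_enumeration_oracle(rr, params)
        assert trace.cost == pytest.approx(cost, abs=1e-9 * max(1.0, cost))
        assert trace.qaly == pytest.approx(qaly, abs=1e-9)


def test_trace_occupancy_conserved():
    rng = np.random.default_rng(7)
    for _ in range(10):
        params = EconParams(
            annual_event_rate=rng.uniform(0.01, 0.3),
            case_fatality=rng.uniform(0.0, 0.5),
            background_mortality=rng.uniform(0.0, 0.2),
            horizon_years=int(rng.integers(1, 40)),
        )
        occ = markov_trace(rng.uniform(0.2, 2.0), params).occupancy
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        assert (occ >= -1e-15).all()


def test_trace_annuity_limit_without_events_or_deaths():
    params = replace(DEFAULTS, annual_event_rate=0.0,
                     background_mortality=0.0)
    trace = markov_trace(1.0, params)
    r = params.discount_rate
    annuity = sum(params.utility_well / (1 + r) ** t
                  for t in range(params.horizon_years))
    assert trace.qaly == pytest.approx(annuity, abs=1e-12)
    assert trace.cost == 0.0


def test_trace_discounting():
    undisc = markov_trace(1.0, replace(DEFAULTS, discount_rate=0.0))
    disc = markov_trace(1.0, DEFAULTS)
    assert disc.qaly < undisc.qaly
    assert disc.cost < undisc.cost


def test_trace_rejects_impossible_event_probability():
    with pytest.raises(ValueError, match="exceeds 1"):
        markov_trace(30.0, DEFAULTS)  # 0.04 * 30 > 1
    with pytest.raises(ValueError):
        markov_trace(0.0, DEFAULTS)


# --- cohort outcomes ----------------------------------------------------------

def test_null_effect_costs_programme_and_buys_nothing():
    out = run_cohort_model(TreatmentEffects(-5.0, -8.0, -0.17),
                           replace(DEFAULTS, null_effect=True))
    assert out.delta_cost == DEFAULTS.cohort_size * DEFAULTS.cost_per_patient
    assert out.delta_qaly == 0.0
    assert out.rr_applied == 1.0


def test_identity_effects_same_as_null_economics():
    out = run_cohort_model(TreatmentEffects(), DEFAULTS)
    assert out.rr_applied == 1.0
    assert out.delta_qaly == 0.0
    assert out.delta_cost == DEFAULTS.cohort_size * DEFAULTS.cost_per_patient


def test_benefit_monotone_in_relative_risk():
    eff_template = [-20.0, -10.0, -5.0, -1.0, 0.0, 1.0]
    qalys = []
    for ldl in eff_template:
        out = run_cohort_model(TreatmentEffects(ldl_change=ldl), DEFAULTS)
        qalys.append(out.delta_qaly)
    # lower LDL -> lower rr -> more QALYs; sequence decreasing in ldl change
    assert all(a >= b for a, b in zip(qalys, qalys[1:]))
    # genuine risk reduction buys health and saves downstream cost
    saving = run_cohort_model(TreatmentEffects(ldl_change=-20.0), DEFAULTS)
    assert saving.delta_qaly > 0
    gross = saving.delta_cost - DEFAULTS.cohort_size * DEFAULTS.cost_per_patient
    assert gross < 0


def test_cohort_outputs_scale_linearly_in_cohort_size():
    eff = TreatmentEffects(-5.0, -8.0, -0.17)
    small = run_cohort_model(eff, replace(DEFAULTS, cohort_size=25_000))
    large = run_cohort_model(eff, replace(DEFAULTS, cohort_size=50_000))
    assert large.delta_cost == pytest.approx(2 * small.delta_cost, rel=1e-12)
    assert large.delta_qaly == pytest.approx(2 * small.delta_qaly, rel=1e-12)


def test_params_validation():
    with pytest.raises(ValueError):
        EconParams(case_fatality=1.2)
    with pytest.raises(ValueError):
        EconParams(utility_post_event=0.9, utility_well=0.8)
    with pytest.raises(ValueError):
        EconParams(horizon_years=0)
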
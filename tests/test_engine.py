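"""Risk engine: hazard closed forms, trajectory policies, simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import telecoach_cea as tc
from telecoach_cea.engine import ENDPOINTS, EVENT_ORDER

from conftest import constant_coeffs, flat_patient


def make_state(**overrides) -> tc.AnnualState:
    base = dict(age=65.0, duration=7.0, male=1, bmi=30.0, smoker=0,
                tchol=176.0, hdl=52.0, sbp=133.0, hba1c=7.0)
    base.update(overrides)
    return tc.AnnualState(**base)


# ---------------------------------------------------------------------------
# annual probabilities
# ---------------------------------------------------------------------------

def test_zero_hazard_gives_zero_probabilities():
    cs = constant_coeffs({})
    probs = tc.annual_event_probabilities(make_state(), cs)
    assert set(probs) == set(EVENT_ORDER)
    assert all(p == 0.0 for p in probs.values())


@pytest.mark.parametrize("h", [0.01, 0.1, 1.0])
def test_constant_hazard_closed_form(h):
    """With beta = 0 the annual probability is exactly 1 - exp(-h)."""
    cs = constant_coeffs({"mi": h})
    probs = tc.annual_event_probabilities(make_state(), cs)
    assert probs["mi"] == pytest.approx(1.0 - np.exp(-h), rel=1e-12)


def test_weibull_and_gompertz_integrated_hazard():
    eq_w = tc.EndpointEquation("mi", family="weibull", scale=0.001, shape=1.5)
    t = 7.0
    assert eq_w.integrated_hazard(t, t + 1) == pytest.approx(
        0.001 * (8.0 ** 1.5 - 7.0 ** 1.5))
    eq_g = tc.EndpointEquation("mi", family="gompertz", scale=0.001, shape=0.1)
    assert eq_g.integrated_hazard(t, t + 1) == pytest.approx(
        0.001 / 0.1 * (np.exp(0.8) - np.exp(0.7)))


def test_probability_monotone_in_hba1c(coeffs):
    lo = tc.annual_event_probabilities(make_state(hba1c=7.0), coeffs)
    hi = tc.annual_event_probabilities(make_state(hba1c=9.0), coeffs)
    for name in EVENT_ORDER:  # every equation has a positive HbA1c slope
        assert hi[name] > lo[name]


def test_prior_event_blocks_recurrence(coeffs):
    state = make_state(flags={"mi": True})
    probs = tc.annual_event_probabilities(state, coeffs)
    assert probs["mi"] == 0.0
    assert probs["stroke"] > 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    age=st.floats(35, 75), duration=st.floats(0.5, 40), male=st.integers(0, 1),
    bmi=st.floats(15, 60), smoker=st.integers(0, 1), tchol=st.floats(50, 400),
    hdl=st.floats(10, 150), sbp=st.floats(80, 220), hba1c=st.floats(4, 15))
def test_probabilities_always_in_unit_interval(age, duration, male, bmi, smoker,
                                               tchol, hdl, sbp, hba1c):
    cs = tc.default_coefficient_set()
    probs = tc.annual_event_probabilities(
        make_state(age=age, duration=duration, male=male, bmi=bmi,
                   smoker=smoker, tchol=tchol, hdl=hdl, sbp=sbp, hba1c=hba1c), cs)
    for p in probs.values():
        assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def test_horizon_two_returns_observed_visits():
    p = flat_patient(hba1c_v0=7.9, hba1c_v1=7.4, hba1c_v2=7.2)
    for policy in ("hold_last",):
        tr = tc.extrapolate_risk_factors(p, horizon=2, policy=policy)
        assert list(tr.values["hba1c"]) == [7.9, 7.4, 7.2]


def test_hold_last_carries_year2_value_forward():
    p = flat_patient(hba1c_v0=7.9, hba1c_v1=7.4, hba1c_v2=7.4)
    tr = tc.extrapolate_risk_factors(p, horizon=10)
    assert np.all(tr.values["hba1c"][3:] == 7.4)
    assert list(tr.values["hba1c"][:3]) == [7.9, 7.4, 7.4]


def test_converge_to_control_equals_reference_beyond_year_2(small_cohort):
    ref = tc.control_reference_path(small_cohort, horizon=10)
    p = flat_patient(hba1c_v2=6.2)
    tr = tc.extrapolate_risk_factors(p, 10, "converge_to_control", ref)
    assert np.allclose(tr.values["hba1c"][3:], ref["hba1c"][3:])
    assert tr.values["hba1c"][2] == 6.2  # observed window untouched


def test_maintain_difference_preserves_year2_offset(small_cohort):
    ref = tc.control_reference_path(small_cohort, horizon=10)
    p = flat_patient(hba1c_v2=6.2)
    tr = tc.extrapolate_risk_factors(p, 10, "maintain_difference", ref)
    offset = 6.2 - ref["hba1c"][2]
    assert np.allclose(tr.values["hba1c"][3:], ref["hba1c"][3:] + offset)


def test_unknown_policy_and_short_horizon_rejected():
    p = flat_patient()
    with pytest.raises(ValueError, match="policy"):
        tc.extrapolate_risk_factors(p, 10, "linear_fade")
    with pytest.raises(ValueError, match="horizon"):
        tc.extrapolate_risk_factors(p, 1)


def test_cohort_trajectories_only_modify_intervention_arm(small_cohort):
    tr_hold = tc.build_trajectories(small_cohort, 10, "hold_last")
    tr_conv = tc.build_trajectories(small_cohort, 10, "converge_to_control")
    ctrl = (small_cohort["arm"] == "control").to_numpy()
    assert np.allclose(tr_hold["hba1c"][ctrl], tr_conv["hba1c"][ctrl])
    isint = ~ctrl
    ref = tc.control_reference_path(small_cohort, 10)
    assert np.allclose(tr_conv["hba1c"][isint, 3:], ref["hba1c"][3:])


# ---------------------------------------------------------------------------
# single-patient simulation
# ---------------------------------------------------------------------------

def test_zero_hazards_survive_full_horizon():
    cs = constant_coeffs({})
    p = flat_patient()
    tr = tc.extrapolate_risk_factors(p, 40)
    h = tc.simulate_patient(p, tr, cs, 40, np.random.default_rng(0))
    assert h.death_year is None
    assert h.event_years == {}
    assert h.life_years() == 40.0


def test_fixed_seed_reproduces_history(coeffs):
    p = flat_patient(hba1c_v0=9.0, hba1c_v1=9.0, hba1c_v2=9.0)
    tr = tc.extrapolate_risk_factors(p, 40)
    h1 = tc.simulate_patient(p, tr, coeffs, 40, np.random.default_rng(123))
    h2 = tc.simulate_patient(p, tr, coeffs, 40, np.random.default_rng(123))
    assert h1.event_years == h2.event_years
    assert h1.death_year == h2.death_year


def test_event_flags_monotone_and_no_state_after_death(coeffs):
    p = flat_patient(hba1c_v0=11.0, hba1c_v1=11.0, hba1c_v2=11.0, age=74)
    tr = tc.extrapolate_risk_factors(p, 40)
    h = tc.simulate_patient(p, tr, coeffs, 40, np.random.default_rng(5))
    if h.death_year is not None:
        assert len(h.states) == h.death_year + 1
        assert h.death_year <= 40
    seen = set()
    for s in h.states:
        for e, on in s.flags.items():
            if e in seen:
                assert on, "a set flag was cleared"
        seen |= {e for e, on in s.flags.items() if on}


@pytest.mark.parametrize("p_death", [0.02, 0.1, 0.3])
def test_life_expectancy_matches_geometric_oracle(p_death):
    """Constant annual death probability p: mean life-years equal the
    closed-form sum over the geometric survival curve (half-year convention),
    within 3 Monte Carlo SEs at 10,000 replicates."""
    H = 40
    h = -np.log(1.0 - p_death)  # hazard whose annual probability is p_death
    cs = constant_coeffs({"death": h})
    # independent enumeration oracle: die in year t w.p. (1-p)^t p -> t + 0.5
    t = np.arange(H)
    pmf = (1 - p_death) ** t * p_death
    expected = float(np.sum(pmf * (t + 0.5)) + (1 - p_death) ** H * H)
    var = float(np.sum(pmf * (t + 0.5) ** 2) + (1 - p_death) ** H * H ** 2
                - expected ** 2)

    n = 10_000
    patient = flat_patient()
    cohort = pd.DataFrame([patient] * n)
    cohort["arm"] = "control"
    cohort["id"] = np.arange(n)
    res = tc.simulate_cohort(cohort, cs, horizon=H, replicates=1, seed=0)
    dy = res.death_year[0]
    ly = np.where(dy >= 0, dy + 0.5, float(H))
    se = np.sqrt(var / n)
    assert abs(ly.mean() - expected) < 3 * se


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def test_empty_cohort_rejected(coeffs):
    with pytest.raises(ValueError, match="empty"):
        tc.simulate_cohort(pd.DataFrame(columns=["arm"]), coeffs)


def test_constant_hazard_cumulative_incidence_closed_form():
    """One endpoint, no death: cumulative incidence is 1 - exp(-h t)."""
    h = 0.05
    cs = constant_coeffs({"stroke": h})
    n = 4000
    cohort = pd.DataFrame([flat_patient()] * n)
    cohort["arm"] = "control"
    res = tc.simulate_cohort(cohort, cs, horizon=40, replicates=1, seed=7)
    rates = res.cumulative_event_rates([5, 10, 20, 40])
    for _, row in rates[rates["endpoint"] == "stroke"].iterrows():
        expected = 100 * (1 - np.exp(-h * row["year"]))
        se = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / n)
        assert abs(row["control"] - expected) < 3.5 * se


def test_cumulative_death_rate_non_decreasing(small_cohort, coeffs):
    res = tc.simulate_cohort(small_cohort, coeffs, horizon=40, replicates=3, seed=1)
    rates = res.cumulative_event_rates([5, 10, 20, 30, 40])
    death = rates[rates["endpoint"] == "death"]
    for arm in ("intervention", "control"):
        assert death[arm].is_monotonic_increasing


def test_zero_hazards_give_zero_rates(small_cohort):
    cs = constant_coeffs({})
    res = tc.simulate_cohort(small_cohort, cs, horizon=40, replicates=1, seed=0)
    rates = res.cumulative_event_rates()
    assert (rates[["intervention", "control"]].to_numpy() == 0).all()


def test_lower_hazards_give_nonpositive_rate_difference():
    """Coupling: the arm with pointwise lower hazards accumulates fewer
    events in expectation (checked by simulation)."""
    n = 3000
    int_arm = pd.DataFrame([flat_patient()] * n)
    int_arm["arm"] = "intervention"
    ctl_arm = pd.DataFrame([flat_patient()] * n)
    ctl_arm["arm"] = "control"
    cohort = pd.concat([int_arm, ctl_arm], ignore_index=True)
    # lower hazard in the intervention arm via a negative HbA1c offset
    cohort.loc[cohort["arm"] == "intervention",
               [f"hba1c_v{v}" for v in range(3)]] = 6.0
    cs = constant_coeffs({"mi": 0.03, "death": 0.04})
    eq = cs.equations["mi"]
    cs.equations["mi"] = tc.EndpointEquation(
        "mi", "constant", eq.scale * np.exp(-0.3 * 7.0),
        coefficients={"hba1c": 0.3})
    res = tc.simulate_cohort(cohort, cs, horizon=40, replicates=2, seed=3)
    rates = res.cumulative_event_rates([10, 20, 40])
    mi = rates[rates["endpoint"] == "mi"]
    assert (mi["difference"] < 0).all()


def test_simulation_deterministic_given_seed(small_cohort, coeffs):
    a = tc.simulate_cohort(small_cohort, coeffs, horizon=20, replicates=2, seed=11)
    b = tc.simulate_cohort(small_cohort, coeffs, horizon=20, replicates=2, seed=11)
    assert np.array_equal(a.event_year, b.event_year)
    assert np.array_equal(a.death_year, b.death_year)


def test_histories_long_format_export(small_cohort, coeffs):
    res = tc.simulate_cohort(small_cohort, coeffs, horizon=10, replicates=2, seed=2)
    df = tc.histories_to_frame(res)
    assert len(df) == 2 * len(small_cohort)
    assert {"replicate", "patient", "arm", "death_year", "mi_year"} <= set(df.columns)


def test_coefficient_set_json_round_trip(coeffs):
    text = coeffs.to_json()
    back = tc.CoefficientSet.from_json(text)
    for name in EVENT_ORDER:
        assert back.equations[name].scale == pytest.approx(
            coeffs.equations[name].scale)
        assert back.equations[name].coefficients == dict(
            coeffs.equations[name].coefficients)
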
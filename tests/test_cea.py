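"""ICER assembly, bootstrap PSA, CEAC, horizon sweep and scenarios."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import telecoach_cea as tc


@pytest.fixture(scope="module")
def eff_cohort():
    """Synthetic cohort with a deliberately strong, persistent trial effect
    (intervention HbA1c/SBP well below control) so incremental QALYs are
    positive with high probability — used to probe pipeline behaviour."""
    spec = tc.default_cohort_spec(n_per_arm=200, seed=31)
    arm = spec.arms["intervention"]
    arm.visits["hba1c"] = ((7.0, 1.0), (5.3, 0.8), (5.3, 0.8))
    arm.visits["sbp"] = ((133.0, 17.0), (118.0, 14.0), (118.0, 14.0))
    return tc.generate_cohort(spec)


@pytest.fixture(scope="module")
def pipe_cfg(coeffs, econ):
    """Complication costs scaled down so the survival gain keeps the cost
    increment positive — a well-behaved northeast-quadrant configuration."""
    cheap = tc.cea._scale_complications(econ, cost_factor=0.05)
    return tc.PipelineConfig(coeffs=coeffs, econ=cheap, horizon=40,
                             replicates=30, program_cost_per_patient=300.3)


# ---------------------------------------------------------------------------
# ICER
# ---------------------------------------------------------------------------

def test_icer_division_oracle():
    r = tc.icer(1000.0, 0.5)
    assert r.value == pytest.approx(2000.0)
    assert r.dominance == "none"


def test_zero_cost_increment_gives_zero_icer():
    assert tc.icer(0.0, 0.4).value == 0.0


def test_cost_saving_intervention_flagged_dominant():
    r = tc.icer(-10.0, 0.1)
    assert r.dominance == "dominant"
    assert r.value is None  # negative ratio suppressed


def test_dominated_and_undefined_cases():
    assert tc.icer(500.0, -0.1).dominance == "dominated"
    assert tc.icer(500.0, 0.0).dominance == "undefined"


# ---------------------------------------------------------------------------
# CEAC
# ---------------------------------------------------------------------------

def test_ceac_hand_count_oracle():
    """4-point cloud at lambda=2,000: net benefit >= 0 for exactly 2 points."""
    cloud = np.array([[100.0, 0.1], [300.0, 0.1], [-50.0, 0.2], [500.0, 0.05]])
    out = tc.ceac(cloud, [2000.0])
    assert out["probability"].iloc[0] == pytest.approx(2 / 4)


def test_ceac_all_cost_saving_is_one_everywhere():
    cloud = np.array([[-10.0, 0.1], [-5.0, 0.3]])
    out = tc.ceac(cloud, [0.0, 1000.0, 1e6])
    assert (out["probability"] == 1.0).all()


def test_ceac_empty_threshold_list_gives_empty_curve():
    cloud = np.array([[1.0, 0.1]])
    assert len(tc.ceac(cloud, [])) == 0


def test_ceac_at_zero_threshold_equals_prob_nonpositive_cost():
    rng = np.random.default_rng(1)
    cloud = np.column_stack([rng.normal(200, 300, 500),
                             rng.uniform(0.01, 0.5, 500)])
    p0 = tc.ceac(cloud, [0.0])["probability"].iloc[0]
    assert p0 == pytest.approx((cloud[:, 0] <= 0).mean())


def test_ceac_monotone_when_all_gains_positive():
    rng = np.random.default_rng(2)
    cloud = np.column_stack([rng.normal(500, 400, 400),
                             rng.uniform(0.05, 0.4, 400)])
    out = tc.ceac(cloud, np.linspace(0, 30_000, 40))
    assert out["probability"].is_monotonic_increasing


def test_prob_cost_saving_counts_southeast_quadrant():
    cloud = np.array([[-1.0, 0.1], [-1.0, -0.1], [1.0, 0.1], [-2.0, 0.2]])
    assert tc.prob_cost_saving(cloud) == pytest.approx(2 / 4)


# ---------------------------------------------------------------------------
# bootstrap PSA
# ---------------------------------------------------------------------------

def test_bootstrap_default_replicates_is_999(eff_cohort, pipe_cfg):
    import inspect
    assert inspect.signature(tc.bootstrap_psa).parameters["n_bootstrap"].default == 999


def test_single_bootstrap_gives_single_point_cloud(eff_cohort, pipe_cfg):
    res = tc.bootstrap_psa(eff_cohort, pipe_cfg, n_bootstrap=1, seed=5)
    assert res.cloud.shape == (1, 2)
    assert np.isfinite(res.cloud).all()


def test_bootstrap_cloud_mean_consistent_with_point_estimate(eff_cohort, pipe_cfg):
    """The resampling distribution is centred on the full-sample estimate."""
    res = tc.bootstrap_psa(eff_cohort, pipe_cfg, n_bootstrap=400, seed=9)
    for k, point in ((0, res.delta_cost), (1, res.delta_qaly)):
        se = res.cloud[:, k].std() / np.sqrt(len(res.cloud))
        assert abs(res.cloud[:, k].mean() - point) < 3.5 * se


def test_bootstrap_percentile_ci_covers_point_estimate(eff_cohort, pipe_cfg):
    """Calibration smoke test over several seeds at reduced n."""
    hits = 0
    for seed in range(6):
        r = tc.bootstrap_psa(eff_cohort, pipe_cfg, n_bootstrap=150, seed=seed)
        if r.delta_qaly_ci[0] <= r.delta_qaly <= r.delta_qaly_ci[1]:
            hits += 1
    assert hits >= 5


def test_bootstrap_deterministic_given_seed(eff_cohort, pipe_cfg):
    a = tc.bootstrap_psa(eff_cohort, pipe_cfg, n_bootstrap=50, seed=3)
    b = tc.bootstrap_psa(eff_cohort, pipe_cfg, n_bootstrap=50, seed=3)
    assert np.array_equal(a.cloud, b.cloud)


def test_ratio_of_bounds_ci_brackets_cloud_median_icer(eff_cohort, pipe_cfg):
    """On a well-behaved cloud (all dE > 0) the crude ratio-of-CI-bounds
    interval brackets the median of the per-point ICERs."""
    res = tc.bootstrap_psa(eff_cohort, pipe_cfg, n_bootstrap=300, seed=17)
    pos = res.cloud[:, 1] > 0
    assert pos.mean() > 0.95, "fixture should give mostly positive gains"
    med = np.median(res.cloud[pos, 0] / res.cloud[pos, 1])
    lo, hi = res.icer_ci_ratio_of_bounds
    assert lo <= med <= hi


def test_parameter_resampling_mode_runs(eff_cohort, pipe_cfg):
    res = tc.bootstrap_psa(eff_cohort, pipe_cfg, n_bootstrap=100, seed=2,
                           mode="parameters")
    assert res.cloud.shape == (100, 2)
    assert res.cloud[:, 0].std() > 0


# ---------------------------------------------------------------------------
# horizon sweep
# ---------------------------------------------------------------------------

def test_full_horizon_entry_matches_base_case(eff_cohort, pipe_cfg):
    res = tc.run_pipeline(eff_cohort, pipe_cfg, seed=4)
    sweep = tc.horizon_sweep(eff_cohort, pipe_cfg, [40], seed=4, result=res)
    assert len(sweep) == 1
    assert sweep["icer"].iloc[0] == pytest.approx(res.icer().value)


def test_icer_falls_with_horizon_for_frontloaded_cost(eff_cohort, pipe_cfg):
    """Persistent effect + up-front program/trial cost: the ICER declines
    as the horizon extends (the benefit keeps accruing, the cost does not)."""
    sweep = tc.horizon_sweep(eff_cohort, pipe_cfg, [5, 10, 20, 40], seed=4)
    vals = sweep["icer"].to_numpy(dtype=float)
    assert np.all(np.diff(vals) < 0)


def test_out_of_range_horizon_rejected(eff_cohort, pipe_cfg):
    with pytest.raises(ValueError):
        tc.horizon_sweep(eff_cohort, pipe_cfg, [0, 10])


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def test_base_scenario_reproduces_base_case_bit_identically(eff_cohort, pipe_cfg):
    res = tc.run_pipeline(eff_cohort, pipe_cfg, seed=8)
    res2 = tc.run_pipeline(eff_cohort, tc.apply_scenario(pipe_cfg, "base"), seed=8)
    assert res.increments() == res2.increments()


def test_program_cost_scenario_shifts_cost_linearly(eff_cohort, pipe_cfg):
    base = tc.run_pipeline(eff_cohort, pipe_cfg, seed=8).increments()
    low = tc.run_pipeline(eff_cohort,
                          tc.apply_scenario(pipe_cfg, "program_cost_low"),
                          seed=8).increments()
    assert base["delta_cost"] - low["delta_cost"] == pytest.approx(
        0.5 * pipe_cfg.program_cost_per_patient)
    assert low["delta_qaly"] == pytest.approx(base["delta_qaly"])


def test_lifetime_effect_dominates_vanishing_effect(eff_cohort, pipe_cfg):
    """On common random numbers, keeping the trial effect for life yields at
    least the QALY gain of letting it vanish after 18 months."""
    van = tc.run_pipeline(eff_cohort,
                          tc.apply_scenario(pipe_cfg, "effect_vanishes_18mo"),
                          seed=12).increments()
    life = tc.run_pipeline(eff_cohort,
                           tc.apply_scenario(pipe_cfg, "effect_lifetime"),
                           seed=12).increments()
    assert life["delta_qaly"] >= van["delta_qaly"]


def test_economic_scenarios_share_event_histories(eff_cohort, pipe_cfg):
    """Common random numbers: discount-rate overrides must not change the
    underlying life-year streams, only their valuation."""
    r0 = tc.run_pipeline(eff_cohort, tc.apply_scenario(pipe_cfg, "discount_0"),
                         seed=13)
    r5 = tc.run_pipeline(eff_cohort, tc.apply_scenario(pipe_cfg, "discount_5"),
                         seed=13)
    assert np.array_equal(r0.life_year_stream, r5.life_year_stream)
    assert r0.increments()["delta_cost"] != r5.increments()["delta_cost"]


def test_biannual_repeat_adds_discounted_program_deliveries(pipe_cfg):
    cfg = tc.apply_scenario(pipe_cfg, "biannual_repeat")
    per = pipe_cfg.program_cost_per_patient
    r = pipe_cfg.econ.cost_discount
    expected = per + sum(per / (1 + r) ** y for y in range(2, 20, 2))
    assert tc.cea.program_cost_contribution(cfg) == pytest.approx(expected)
    assert cfg.policy == "maintain_difference"


def test_unknown_scenario_rejected(pipe_cfg):
    with pytest.raises(ValueError, match="scenario"):
        tc.apply_scenario(pipe_cfg, "butter_prices")


def test_scenario_table_layout(eff_cohort, coeffs, econ):
    cfg = tc.PipelineConfig(coeffs=coeffs, econ=econ, horizon=15, replicates=4,
                            program_cost_per_patient=300.3)
    tab = tc.run_scenarios(eff_cohort, cfg,
                           scenario_ids=("program_cost_low", "discount_5"),
                           seed=1)
    assert list(tab["scenario"]) == ["base", "program_cost_low", "discount_5"]
    assert {"delta_cost", "delta_qaly", "icer", "dominance"} <= set(tab.columns)
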
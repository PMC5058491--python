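"""Default parameter sets for the telecoaching cost-effectiveness analysis.

Three kinds of defaults live here:

- the synthetic-cohort specification (arm sizes, per-visit risk-factor
  moments, comorbidity prevalences, claims-cost distributions, dropout
  rates) describing the 574-participant Belgian telecoaching trial;
- the economic parameters: complication costs and utility decrements in
  2013 EUR, the base annual diabetes cost (EUR 3,921), baseline EQ-5D
  utility (0.785) and differential discount rates (3.0% costs / 1.5% QALYs);
- an ILLUSTRATIVE coefficient set for the risk engine. The fitted
  UKPDS Outcomes Model equations are licensed material and are not
  distributed with this package; the set below has the same functional form
  and plausible effect directions, with baseline scales calibrated so the
  reference patient (65-year-old with 7 years of diabetes, HbA1c 7%) has an
  undiscounted life expectancy of about 10 years and endpoint hazards on the
  scale of published 40-year cumulative event rates. It is a stand-in for
  exercising the machinery, not a clinically validated model.
"""

from __future__ import annotations

import math
from typing import Dict

from .cohort import ArmTargets, CohortSpec
from .costing import ProgramCostModel
from .econ import ComplicationEcon, EconParameters
from .engine import CoefficientSet, EndpointEquation


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------

def default_cohort_spec(n_per_arm: int = 287, seed: int = 0) -> CohortSpec:
    """Two arms of 287 with the trial's printed moments and dropout rates."""
    intervention = ArmTargets(
        male_prev=0.60, age_mean=65.9, age_sd=8.0,
        duration_mean=7.0, duration_sd=5.2,
        weight_mean=86.1, weight_sd=16.9,
        visits={
            "hba1c": ((7.0, 1.1), (6.8, 0.9), (6.9, 1.0)),
            "tchol": ((173.0, 37.0), (165.0, 36.0), (162.0, 34.0)),
            "hdl": ((52.0, 16.0), (53.0, 15.0), (52.0, 15.0)),
            "sbp": ((133.0, 18.0), (128.0, 16.0), (128.0, 14.0)),
            "bmi": ((30.2, 4.9), (29.6, 4.9), (29.9, 5.0)),
        },
        smoker_prev=(0.143, 0.122, 0.114),
        comorbidity_prev={"ihd": 0.12, "heart_failure": 0.07,
                          "mi": 0.04, "stroke": 0.04},
        costs={("ambulatory", "baseline"): (3697.0, 3106.0, 4288.0),
               ("ambulatory", "trial"): (4012.0, 3437.0, 4587.0),
               ("hospital", "baseline"): (1846.0, 1067.0, 2626.0),
               ("hospital", "trial"): (1504.0, 992.0, 2016.0)},
        missingness=(0.11, 0.16),
    )
    control = ArmTargets(
        male_prev=0.63, age_mean=63.9, age_sd=8.0,
        duration_mean=7.0, duration_sd=5.2,
        weight_mean=88.3, weight_sd=16.6,
        visits={
            "hba1c": ((7.0, 1.0), (7.0, 1.1), (7.0, 1.1)),
            "tchol": ((178.0, 39.0), (176.0, 39.0), (170.0, 49.0)),
            "hdl": ((51.0, 14.0), (53.0, 16.0), (52.0, 15.0)),
            "sbp": ((132.0, 17.0), (130.0, 16.0), (130.0, 15.0)),
            "bmi": ((30.6, 5.2), (30.4, 5.1), (30.4, 5.1)),
        },
        smoker_prev=(0.193, 0.187, 0.160),
        comorbidity_prev={"ihd": 0.14, "heart_failure": 0.05,
                          "mi": 0.05, "stroke": 0.014},
        costs={("ambulatory", "baseline"): (3148.0, 2804.0, 3492.0),
               ("ambulatory", "trial"): (3271.0, 2909.0, 3633.0),
               ("hospital", "baseline"): (953.0, 445.0, 1461.0),
               ("hospital", "trial"): (1486.0, 878.0, 2094.0)},
        missingness=(0.09, 0.14),
    )
    return CohortSpec(n_per_arm=n_per_arm, seed=seed,
                      arms={"intervention": intervention, "control": control})


#: default per-arm dropout rates at the 6- and 18-month visits
DEFAULT_MISSINGNESS = {"intervention": (0.11, 0.16), "control": (0.09, 0.14)}


# ---------------------------------------------------------------------------
# economics
# ---------------------------------------------------------------------------

def default_econ_parameters() -> EconParameters:
    """Complication costs / utility decrements (2013 EUR, EQ-5D magnitudes)."""
    comp = {
        "ihd": ComplicationEcon(None, 10976.0, 6044.0, 0.090, 0.046),
        "mi": ComplicationEcon(3829.0, 7989.0, 6044.0, 0.055, 0.032),
        "heart_failure": ComplicationEcon(10416.0, 10416.0, 7431.0, 0.108, 0.050),
        "stroke": ComplicationEcon(16658.0, 16658.0, 6030.0, 0.164, 0.061),
        "amputation": ComplicationEcon(46387.0, 46387.0, 781.0, 0.280, 0.130),
        "blindness": ComplicationEcon(None, 5382.0, 5382.0, 0.175, 0.175),
        "esrd": ComplicationEcon(57078.0, 57078.0, 57078.0, 0.263, 0.248),
    }
    return EconParameters(complications=comp, base_annual_cost=3921.0,
                          baseline_utility=0.785,
                          cost_discount=0.03, qaly_discount=0.015)


def default_program_cost_model() -> ProgramCostModel:
    """The telecoaching program's prospective cost ledger."""
    return ProgramCostModel(
        recruitment_total=3900.0,
        fixed_annual_total=3790.0,
        variable_per_patient={"welcome_package": 20.0, "software_license": 50.0,
                              "nurse_time": 192.5, "communication": 11.0},
        investment_items={"program_management_training": 14400.0,
                          "program_translation": 7500.0,
                          "software_configuration": 8800.0,
                          "coach_training": 8575.0},
        n_enrolled=287, n_allocation=287, include_investment=False)


# ---------------------------------------------------------------------------
# illustrative risk equations
# ---------------------------------------------------------------------------

#: covariate profile of the "reference patient" used to anchor baseline scales
REFERENCE_PATIENT: Dict[str, float] = {
    "age": 65.0, "male": 0.62, "duration": 7.0, "bmi": 30.4, "smoker": 0.17,
    "tchol": 176.0, "hdl": 52.0, "sbp": 133.0, "hba1c": 7.0,
    **{f"prior_{e}": 0.0 for e in
       ("ihd", "mi", "heart_failure", "stroke", "amputation", "blindness", "esrd")},
}

#: target annual hazards at the reference profile (illustrative calibration)
_REFERENCE_HAZARDS = {
    "ihd": 0.0075, "mi": 0.030, "heart_failure": 0.013, "stroke": 0.014,
    "amputation": 0.0018, "blindness": 0.0068, "esrd": 0.0015,
}

#: all-cause death hazard of the reference patient, calibrated numerically so
#: that the simulated undiscounted life expectancy of the default control arm
#: is ~10 years (competing fatal events included)
_DEATH_REFERENCE_HAZARD = 0.035

_COEFFICIENTS = {
    "ihd": {"age": 0.040, "male": 0.30, "sbp": 0.012, "hba1c": 0.100,
            "tchol": 0.004, "hdl": -0.020, "smoker": 0.40},
    "mi": {"age": 0.050, "male": 0.45, "sbp": 0.012, "hba1c": 0.125,
           "tchol": 0.005, "hdl": -0.025, "smoker": 0.50,
           "prior_ihd": 0.40, "prior_heart_failure": 0.30},
    "heart_failure": {"age": 0.060, "bmi": 0.050, "sbp": 0.010, "hba1c": 0.100,
                      "prior_mi": 0.60, "prior_ihd": 0.30},
    "stroke": {"age": 0.060, "male": 0.20, "sbp": 0.020, "hba1c": 0.080,
               "smoker": 0.40, "duration": 0.015, "prior_mi": 0.30},
    "amputation": {"age": 0.020, "sbp": 0.008, "hba1c": 0.180, "smoker": 0.40},
    "blindness": {"age": 0.020, "sbp": 0.008, "hba1c": 0.140},
    "esrd": {"sbp": 0.012, "hba1c": 0.120},
    "death": {"age": 0.095, "male": 0.20, "smoker": 0.35, "hba1c": 0.060,
              "prior_ihd": 0.25, "prior_mi": 0.50, "prior_heart_failure": 0.60,
              "prior_stroke": 0.45, "prior_amputation": 0.50,
              "prior_blindness": 0.10, "prior_esrd": 1.00},
}

_FAMILIES = {
    "ihd": ("constant", 1.0), "mi": ("constant", 1.0),
    "heart_failure": ("constant", 1.0), "stroke": ("constant", 1.0),
    "amputation": ("weibull", 1.4), "blindness": ("weibull", 1.4),
    "esrd": ("weibull", 1.6), "death": ("constant", 1.0),
}

_FATALITY = {"ihd": 0.0, "mi": 0.25, "heart_failure": 0.20, "stroke": 0.20,
             "amputation": 0.10, "blindness": 0.0, "esrd": 0.30}


def _scale_for(h_ref: float, family: str, shape: float) -> float:
    """Baseline scale giving integrated hazard ``h_ref`` over the reference
    patient's next cycle, once the linear predictor is divided out."""
    t0 = REFERENCE_PATIENT["duration"]
    if family == "constant":
        dH = 1.0
    elif family == "weibull":
        dH = (t0 + 1.0) ** shape - t0 ** shape
    else:
        dH = (math.exp(shape * (t0 + 1.0)) - math.exp(shape * t0)) / shape
    return h_ref / dH


def default_coefficient_set() -> CoefficientSet:
    """Illustrative (non-validated) hazard equations for all eight endpoints."""
    eqs = {}
    hazards = dict(_REFERENCE_HAZARDS, death=_DEATH_REFERENCE_HAZARD)
    for name, beta in _COEFFICIENTS.items():
        family, shape = _FAMILIES[name]
        lp_ref = sum(b * REFERENCE_PATIENT[k] for k, b in beta.items())
        scale = _scale_for(hazards[name], family, shape) * math.exp(-lp_ref)
        eqs[name] = EndpointEquation(
            endpoint=name, family=family, scale=scale, shape=shape,
            coefficients=dict(beta), fatality=_FATALITY.get(name, 0.0))
    cs = CoefficientSet(equations=eqs,
                        provenance="illustrative in-package calibration; "
                                   "not the published UKPDS-OM fit",
                        version="1")
    cs.validate()
    return cs
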
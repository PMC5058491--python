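import numpy as np
import pandas as pd
import pytest

import telecoach_cea as tc


@pytest.fixture(scope="session")
def default_spec():
    return tc.default_cohort_spec(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-per-arm cohort with default targets, imputed, for pipeline tests."""
    spec = tc.default_cohort_spec(n_per_arm=60, seed=7)
    cohort = tc.generate_cohort(spec)
    return tc.inject_and_impute_missing(cohort, tc.DEFAULT_MISSINGNESS, seed=8)


@pytest.fixture(scope="session")
def coeffs():
    return tc.default_coefficient_set()


@pytest.fixture(scope="session")
def econ():
    return tc.default_econ_parameters()


def constant_coeffs(rates: dict, fatality: dict | None = None) -> tc.CoefficientSet:
    """Coefficient set with covariate-free constant hazards (test helper)."""
    fatality = fatality or {}
    eqs = {}
    for name in tc.EVENT_ORDER:
        eqs[name] = tc.EndpointEquation(
            endpoint=name, family="constant", scale=rates.get(name, 0.0),
            coefficients={}, fatality=fatality.get(name, 0.0))
    return tc.CoefficientSet(equations=eqs, provenance="test", version="0")


def flat_patient(**overrides) -> dict:
    """A minimal patient record with flat risk factors across visits."""
    base = {"age": 65.0, "male": 1, "diabetes_duration": 7.0}
    for var, val in (("hba1c", 7.0), ("sbp", 133.0), ("tchol", 176.0),
                     ("hdl", 52.0), ("bmi", 30.0), ("smoker", 0)):
        for v in range(3):
            base[f"{var}_v{v}"] = val
    base.update(overrides)
    return base
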
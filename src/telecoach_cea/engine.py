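"""Annual-cycle patient-level Monte Carlo over diabetes endpoints.

Seven diabetes-related endpoints — ischemic heart disease (IHD), myocardial
infarction (MI), heart failure, stroke, amputation, blindness and end-stage
renal disease (ESRD) — plus all-cause death are simulated year by year from
parametric hazard equations of the proportional-hazards form

    p_year = 1 - exp(-[H0(t+1) - H0(t)] * exp(x' beta)),

where ``H0`` is the integrated baseline hazard of a constant, Weibull or
Gompertz family on the diabetes-duration time scale and ``x`` collects the
patient's current risk factors (age, sex, BMI, smoking, total and HDL
cholesterol, systolic blood pressure, HbA1c) and prior-event flags.

Within a cycle the endpoints are evaluated in a fixed documented order with
independent draws, death last; an event can be fatal with a per-endpoint
split probability; flags feed the *next* year's equations. Events are
assumed to occur mid-cycle, so the death year contributes half a life-year.

The engine accepts any :class:`CoefficientSet`. The published risk-equation
coefficient values of the UKPDS Outcomes Model are not distributed here; the
package ships a clearly labelled illustrative set (see ``defaults``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ARMS, visit_col

ENDPOINTS = ("ihd", "mi", "heart_failure", "stroke", "amputation", "blindness", "esrd")
DEATH = "death"
#: fixed within-cycle evaluation order; death is always drawn last
EVENT_ORDER = ENDPOINTS + (DEATH,)

HAZARD_FAMILIES = ("constant", "weibull", "gompertz")

#: risk factors read from the trajectory each year
TRAJECTORY_VARS = ("hba1c", "sbp", "tchol", "hdl", "smoker", "bmi")

#: feature names a linear predictor may reference
FEATURES = ("age", "male", "duration", "bmi", "smoker", "tchol", "hdl", "sbp",
            "hba1c") + tuple(f"prior_{e}" for e in ENDPOINTS)


# ---------------------------------------------------------------------------
# equations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndpointEquation:
    """One parametric hazard equation.

    ``scale`` is the baseline-hazard scale (lambda0 >= 0), ``shape`` the
    Weibull/Gompertz shape parameter (ignored for the constant family), and
    ``fatality`` the probability that an occurrence is immediately fatal.
    """

    endpoint: str
    family: str = "constant"
    scale: float = 0.0
    shape: float = 1.0
    coefficients: Mapping[str, float] = field(default_factory=dict)
    fatality: float = 0.0

    def validate(self) -> None:
        if self.family not in HAZARD_FAMILIES:
            raise ValueError(f"unknown hazard family {self.family!r}")
        if self.scale < 0:
            raise ValueError(f"{self.endpoint}: scale must be >= 0")
        if self.family != "constant" and self.shape <= 0:
            raise ValueError(f"{self.endpoint}: shape must be > 0")
        if not 0.0 <= self.fatality <= 1.0:
            raise ValueError(f"{self.endpoint}: fatality split outside [0, 1]")
        unknown = set(self.coefficients) - set(FEATURES)
        if unknown:
            raise ValueError(f"{self.endpoint}: unknown feature(s) {sorted(unknown)}")

    def integrated_hazard(self, t0, t1):
        """Integrated baseline hazard H0(t1) - H0(t0) (vectorized in t)."""
        t0 = np.asarray(t0, dtype=float)
        t1 = np.asarray(t1, dtype=float)
        if self.family == "constant":
            return self.scale * (t1 - t0)
        if self.family == "weibull":
            return self.scale * (np.power(t1, self.shape) - np.power(t0, self.shape))
        # gompertz
        return self.scale / self.shape * (np.exp(self.shape * t1) - np.exp(self.shape * t0))


@dataclass
class CoefficientSet:
    """A complete system of eight equations (seven endpoints + death)."""

    equations: Dict[str, EndpointEquation]
    provenance: str = ""
    version: str = ""

    def validate(self) -> None:
        missing = set(EVENT_ORDER) - set(self.equations)
        if missing:
            raise ValueError(f"missing equation(s) for: {sorted(missing)}")
        for eq in self.equations.values():
            eq.validate()

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "version": self.version,
            "equations": {k: asdict(eq) for k, eq in self.equations.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CoefficientSet":
        payload = json.loads(text)
        eqs = {k: EndpointEquation(**v) for k, v in payload["equations"].items()}
        out = cls(equations=eqs, provenance=payload.get("provenance", ""),
                  version=payload.get("version", ""))
        out.validate()
        return out


# ---------------------------------------------------------------------------
# states and histories
# ---------------------------------------------------------------------------

@dataclass
class AnnualState:
    """Risk-factor values and event flags at the start of one cycle."""

    age: float
    duration: float
    male: int
    bmi: float
    smoker: int
    tchol: float
    hdl: float
    sbp: float
    hba1c: float
    flags: Dict[str, bool] = field(default_factory=dict)
    alive: bool = True

    def features(self) -> Dict[str, float]:
        f = {"age": self.age, "male": float(self.male), "duration": self.duration,
             "bmi": self.bmi, "smoker": float(self.smoker), "tchol": self.tchol,
             "hdl": self.hdl, "sbp": self.sbp, "hba1c": self.hba1c}
        for e in ENDPOINTS:
            f[f"prior_{e}"] = float(self.flags.get(e, False))
        return f


@dataclass
class PatientHistory:
    """Simulated annual course of one patient replicate."""

    states: list
    event_years: Dict[str, int]          # endpoint -> year of first occurrence
    fatal_events: Dict[str, bool]        # endpoint -> occurrence was fatal
    death_year: int | None               # None = alive at horizon
    horizon: int

    def life_years(self) -> float:
        """Undiscounted life-years with the half-cycle death correction."""
        if self.death_year is None:
            return float(self.horizon)
        return self.death_year + 0.5


# ---------------------------------------------------------------------------
# risk-factor trajectories
# ---------------------------------------------------------------------------

POLICIES = ("hold_last", "converge_to_control", "maintain_difference")


@dataclass
class RiskFactorTrajectory:
    """Per-year risk-factor values, years 0..horizon inclusive."""

    values: Dict[str, np.ndarray]
    policy: str = "hold_last"

    def at(self, var: str, year: int) -> float:
        arr = self.values[var]
        return float(arr[min(year, len(arr) - 1)])


def control_reference_path(cohort: pd.DataFrame, horizon: int) -> Dict[str, np.ndarray]:
    """Arm-level reference path: control-arm mean visit values, held flat.

    Used by the ``converge_to_control`` and ``maintain_difference`` policies
    as the path the intervention arm is pulled toward (or offset from) once
    the observation window ends.
    """
    ctrl = cohort[cohort["arm"] == "control"]
    if len(ctrl) == 0:
        raise ValueError("cohort has no control arm to build a reference path from")
    path: Dict[str, np.ndarray] = {}
    for var in TRAJECTORY_VARS:
        vals = [float(ctrl[visit_col(var, v)].mean()) for v in range(3)]
        arr = np.empty(horizon + 1)
        arr[:3] = vals
        arr[3:] = vals[2]
        path[var] = arr
    return path


def extrapolate_risk_factors(patient: Mapping[str, float], horizon: int,
                             policy: str = "hold_last",
                             reference: Mapping[str, np.ndarray] | None = None,
                             ) -> RiskFactorTrajectory:
    """Extend the three observed visits over the simulation horizon.

    Years 0-2 always equal the observed visit values. Beyond year 2:

    - ``hold_last``: the year-2 value is carried forward (base case);
    - ``converge_to_control``: the trajectory equals the control-arm
      reference path — the trial effect vanishes after the 18-month visit;
    - ``maintain_difference``: the patient's year-2 offset from the
      reference path is preserved at every later year.

    ``reference`` (from :func:`control_reference_path`) is required for the
    two reference-based policies. Control-arm patients keep ``hold_last``
    behaviour under ``converge_to_control`` by passing their own values.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if horizon < 2:
        raise ValueError(f"horizon must cover the 3-visit observation span, got {horizon}")
    if policy != "hold_last" and reference is None:
        raise ValueError(f"policy {policy!r} requires a control reference path")
    values: Dict[str, np.ndarray] = {}
    for var in TRAJECTORY_VARS:
        obs = np.array([float(patient[visit_col(var, v)]) for v in range(3)])
        arr = np.empty(horizon + 1)
        arr[:3] = obs
        if policy == "hold_last":
            arr[3:] = obs[2]
        elif policy == "converge_to_control":
            ref = np.asarray(reference[var], dtype=float)
            arr[3:] = ref[3: horizon + 1]
        else:  # maintain_difference
            ref = np.asarray(reference[var], dtype=float)
            arr[3:] = ref[3: horizon + 1] + (obs[2] - ref[2])
        values[var] = arr
    return RiskFactorTrajectory(values=values, policy=policy)


# ---------------------------------------------------------------------------
# annual probabilities
# ---------------------------------------------------------------------------

def annual_event_probabilities(state: AnnualState, coeffs: CoefficientSet,
                               ) -> Dict[str, float]:
    """Map endpoint -> probability of occurrence in the coming cycle.

    Endpoints whose first occurrence is already on record get probability 0
    (events are first occurrences; the flag persists instead).
    """
    if not state.alive:
        raise ValueError("annual probabilities are undefined for a dead state")
    feats = state.features()
    out: Dict[str, float] = {}
    for name in EVENT_ORDER:
        eq = coeffs.equations[name]
        if name != DEATH and state.flags.get(name, False):
            out[name] = 0.0
            continue
        lp = sum(beta * feats[k] for k, beta in eq.coefficients.items())
        if not np.isfinite(lp):
            raise ValueError(f"{name}: non-finite linear predictor")
        dH = eq.integrated_hazard(state.duration, state.duration + 1.0)
        out[name] = float(-np.expm1(-dH * np.exp(lp)))
    return out


# ---------------------------------------------------------------------------
# vectorized simulation kernel
# ---------------------------------------------------------------------------

def _linear_predictor(eq: EndpointEquation, feats: Mapping[str, np.ndarray],
                      n: int) -> np.ndarray:
    lp = np.zeros(n)
    for k, beta in eq.coefficients.items():
        lp += beta * feats[k]
    return lp


def simulate_arrays(static: Mapping[str, np.ndarray],
                    traj: Mapping[str, np.ndarray],
                    flags0: Mapping[str, np.ndarray],
                    coeffs: CoefficientSet,
                    horizon: int,
                    rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Simulate ``n`` patients in lockstep for ``horizon`` annual cycles.

    ``static`` holds ``age``, ``duration``, ``male`` arrays of shape (n,);
    ``traj`` holds (n, horizon+1) risk-factor arrays; ``flags0`` the baseline
    event-history booleans. Two uniforms are drawn per endpoint per cycle
    (occurrence, fatality) and one for death, *unconditionally*, so runs with
    the same seed use common random numbers across parameter scenarios.

    Returns ``event_year`` (n, 7) int (-1 = never), ``event_fatal`` (n, 7)
    bool and ``death_year`` (n,) int (-1 = alive at horizon).
    """
    coeffs.validate()
    n = len(static["age"])
    event_year = np.full((n, len(ENDPOINTS)), -1, dtype=np.int32)
    event_fatal = np.zeros((n, len(ENDPOINTS)), dtype=bool)
    death_year = np.full(n, -1, dtype=np.int32)
    flags = {e: np.asarray(flags0.get(e, np.zeros(n, dtype=bool))).copy()
             for e in ENDPOINTS}
    alive = np.ones(n, dtype=bool)

    for y in range(horizon):
        t0 = static["duration"] + y
        yv = min(y, traj["hba1c"].shape[1] - 1)
        feats = {
            "age": static["age"] + y,
            "male": static["male"].astype(float),
            "duration": t0,
            "bmi": traj["bmi"][:, yv],
            "smoker": traj["smoker"][:, yv],
            "tchol": traj["tchol"][:, yv],
            "hdl": traj["hdl"][:, yv],
            "sbp": traj["sbp"][:, yv],
            "hba1c": traj["hba1c"][:, yv],
        }
        # flags feed next-year equations: snapshot at cycle start
        start_flags = {e: flags[e].copy() for e in ENDPOINTS}
        for e in ENDPOINTS:
            feats[f"prior_{e}"] = start_flags[e].astype(float)

        fatal_now = np.zeros(n, dtype=bool)
        for j, name in enumerate(ENDPOINTS):
            eq = coeffs.equations[name]
            u_event = rng.random(n)
            u_fatal = rng.random(n)
            lp = _linear_predictor(eq, feats, n)
            p = -np.expm1(-eq.integrated_hazard(t0, t0 + 1.0) * np.exp(lp))
            new = alive & ~start_flags[name] & (u_event < p)
            fatal = new & (u_fatal < eq.fatality)
            event_year[new, j] = y
            event_fatal[fatal, j] = True
            flags[name] |= new
            fatal_now |= fatal

        eq_d = coeffs.equations[DEATH]
        u_death = rng.random(n)
        lp = _linear_predictor(eq_d, feats, n)
        p_death = -np.expm1(-eq_d.integrated_hazard(t0, t0 + 1.0) * np.exp(lp))
        dies = alive & (fatal_now | (u_death < p_death))
        death_year[dies] = y
        alive &= ~dies
        if not alive.any():
            break

    return {"event_year": event_year, "event_fatal": event_fatal,
            "death_year": death_year}


def _static_from_patient(patient: Mapping[str, float]) -> Dict[str, np.ndarray]:
    return {"age": np.array([float(patient["age"])]),
            "duration": np.array([float(patient["diabetes_duration"])]),
            "male": np.array([int(patient["male"])])}


def _flags_from_patient(patient: Mapping[str, float]) -> Dict[str, np.ndarray]:
    out = {}
    for e in ENDPOINTS:
        key = f"hist_{e}"
        out[e] = np.array([bool(patient.get(key, 0))])
    return out


def simulate_patient(patient: Mapping[str, float],
                     trajectory: RiskFactorTrajectory,
                     coeffs: CoefficientSet,
                     horizon: int,
                     rng: np.random.Generator) -> PatientHistory:
    """Simulate a single patient replicate and return its annual history."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    traj = {var: np.asarray(arr, dtype=float)[None, :]
            for var, arr in trajectory.values.items()}
    res = simulate_arrays(_static_from_patient(patient), traj,
                          _flags_from_patient(patient), coeffs, horizon, rng)
    ev = {name: int(res["event_year"][0, j])
          for j, name in enumerate(ENDPOINTS) if res["event_year"][0, j] >= 0}
    fatal = {name: bool(res["event_fatal"][0, j])
             for j, name in enumerate(ENDPOINTS) if res["event_year"][0, j] >= 0}
    dy = int(res["death_year"][0])
    death_year = dy if dy >= 0 else None
    last = horizon if death_year is None else death_year + 1
    states = []
    flags = {e: bool(patient.get(f"hist_{e}", 0)) for e in ENDPOINTS}
    for y in range(last):
        states.append(AnnualState(
            age=float(patient["age"]) + y,
            duration=float(patient["diabetes_duration"]) + y,
            male=int(patient["male"]),
            bmi=trajectory.at("bmi", y), smoker=int(trajectory.at("smoker", y)),
            tchol=trajectory.at("tchol", y), hdl=trajectory.at("hdl", y),
            sbp=trajectory.at("sbp", y), hba1c=trajectory.at("hba1c", y),
            flags=dict(flags), alive=True))
        for name, year in ev.items():
            if year == y:
                flags[name] = True
    return PatientHistory(states=states, event_years=ev, fatal_events=fatal,
                          death_year=death_year, horizon=horizon)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimResult:
    """Stacked replicate-level simulation output for one cohort.

    Arrays have shape (replicates, n_patients) or (replicates, n_patients, 7).
    ``patient_index`` maps array columns back to cohort row labels.
    """

    event_year: np.ndarray
    event_fatal: np.ndarray
    death_year: np.ndarray
    arms: np.ndarray
    patient_index: np.ndarray
    horizon: int

    def cumulative_event_rates(self,
                               years: Sequence[int] = (5, 10, 20, 30, 40),
                               ) -> pd.DataFrame:
        """Per-arm cumulative incidence (%) by endpoint and year.

        Mirrors the standard modelled-event-rate report: one row per
        endpoint x year with intervention, control and difference columns.
        """
        rows = []
        for j, name in enumerate(ENDPOINTS + (DEATH,)):
            for year in years:
                if year > self.horizon:
                    continue
                rec = {"endpoint": name, "year": year}
                for arm in ARMS:
                    mask = self.arms == arm
                    if not mask.any():
                        rec[arm] = np.nan
                        continue
                    if name == DEATH:
                        occ = (self.death_year[:, mask] >= 0) & (self.death_year[:, mask] < year)
                    else:
                        ey = self.event_year[:, mask, j]
                        occ = (ey >= 0) & (ey < year)
                    rec[arm] = 100.0 * occ.mean()
                rec["difference"] = rec[ARMS[0]] - rec[ARMS[1]]
                rows.append(rec)
        return pd.DataFrame(rows)


def build_trajectories(cohort: pd.DataFrame, horizon: int, policy: str,
                       reference: Mapping[str, np.ndarray] | None = None,
                       ) -> Dict[str, np.ndarray]:
    """(n, horizon+1) trajectory arrays for a whole cohort under one policy.

    Under the reference-based policies only the intervention arm is pulled
    toward / offset from the control reference; control patients always hold
    their last observed value.
    """
    n = len(cohort)
    out = {var: np.empty((n, horizon + 1)) for var in TRAJECTORY_VARS}
    if policy != "hold_last" and reference is None:
        reference = control_reference_path(cohort, horizon)
    is_int = (cohort["arm"] == "intervention").to_numpy()
    for var in TRAJECTORY_VARS:
        obs = np.column_stack([cohort[visit_col(var, v)].to_numpy(dtype=float)
                               for v in range(3)])
        arr = out[var]
        arr[:, :3] = obs
        arr[:, 3:] = obs[:, [2]]
        if policy == "converge_to_control":
            ref = np.asarray(reference[var], dtype=float)
            arr[is_int, 3:] = ref[3: horizon + 1]
        elif policy == "maintain_difference":
            ref = np.asarray(reference[var], dtype=float)
            arr[is_int, 3:] = ref[3: horizon + 1] + (obs[is_int, 2:3] - ref[2])
    return out


def simulate_cohort(cohort: pd.DataFrame, coeffs: CoefficientSet,
                    horizon: int = 40, replicates: int = 1,
                    seed: int = 0, policy: str = "hold_last",
                    reference: Mapping[str, np.ndarray] | None = None,
                    ) -> CohortSimResult:
    """Monte Carlo simulation of every cohort patient, ``replicates`` times.

    Each replicate draws fresh event histories from an independent stream of
    a seeded generator; risk-factor trajectories are deterministic given the
    policy. Raises on an empty cohort.
    """
    if len(cohort) == 0:
        raise ValueError("cannot simulate an empty cohort")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    coeffs.validate()
    traj = build_trajectories(cohort, horizon, policy, reference)
    static = {"age": cohort["age"].to_numpy(dtype=float),
              "duration": cohort["diabetes_duration"].to_numpy(dtype=float),
              "male": cohort["male"].to_numpy(dtype=int)}
    flags0 = {e: cohort[f"hist_{e}"].to_numpy(dtype=bool)
              if f"hist_{e}" in cohort.columns else np.zeros(len(cohort), dtype=bool)
              for e in ENDPOINTS}
    streams = np.random.SeedSequence(seed).spawn(replicates)
    ev, fat, dy = [], [], []
    for ss in streams:
        res = simulate_arrays(static, traj, flags0, coeffs, horizon,
                              np.random.default_rng(ss))
        ev.append(res["event_year"])
        fat.append(res["event_fatal"])
        dy.append(res["death_year"])
    return CohortSimResult(
        event_year=np.stack(ev), event_fatal=np.stack(fat),
        death_year=np.stack(dy), arms=cohort["arm"].to_numpy(),
        patient_index=cohort.index.to_numpy(), horizon=horizon)


def histories_to_frame(result: CohortSimResult) -> pd.DataFrame:
    """Long-format export: one row per (replicate, patient) with event years."""
    R, n = result.death_year.shape
    rows = {"replicate": np.repeat(np.arange(R), n),
            "patient": np.tile(result.patient_index, R),
            "arm": np.tile(result.arms, R),
            "death_year": result.death_year.ravel()}
    for j, name in enumerate(ENDPOINTS):
        rows[f"{name}_year"] = result.event_year[:, :, j].ravel()
        rows[f"{name}_fatal"] = result.event_fatal[:, :, j].ravel()
    return pd.DataFrame(rows)
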
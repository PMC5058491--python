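"""Discounted cost, life-year and QALY accrual over simulated histories.

Every alive year accrues the base annual diabetes treatment cost; a new
complication adds its acute event-year cost (the fatal acute cost if the
occurrence was fatal) and each previously acquired complication adds its
subsequent-year cost. Utility starts from the cohort baseline utility and is
reduced additively by the event-year decrement of each new complication and
the subsequent-year decrement of each established one. Decrements are stored
as positive magnitudes and subtracted.

Costs and QALYs are discounted at separate annual rates (differential
discounting: base case 3.0% for costs, 1.5% for QALYs); year 0 is
undiscounted. Events fall mid-cycle, so the death year contributes half a
year of base cost, subsequent-year costs and utility — acute event costs are
one-off amounts and accrue in full.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Dict, Iterable, Mapping

import numpy as np

from .engine import ENDPOINTS, PatientHistory


@dataclass
class ComplicationEcon:
    """Costs (EUR) and utility decrements (magnitudes) for one complication."""

    fatal_cost: float | None    # None where a fatal form is not priced
    event_cost: float           # acute cost in the year of a non-fatal event
    subsequent_cost: float      # every later alive year
    event_decrement: float      # utility loss in the event year (magnitude)
    subsequent_decrement: float  # utility loss in later years (magnitude)

    def validate(self, name: str) -> None:
        for label, v in (("event_cost", self.event_cost),
                         ("subsequent_cost", self.subsequent_cost)):
            if v < 0:
                raise ValueError(f"{name}: {label} must be >= 0")
        if self.fatal_cost is not None and self.fatal_cost < 0:
            raise ValueError(f"{name}: fatal_cost must be >= 0")
        if self.event_decrement < 0 or self.subsequent_decrement < 0:
            raise ValueError(f"{name}: decrements are stored as magnitudes >= 0")


@dataclass
class EconParameters:
    """Economic inputs: costs, utilities and discount rates."""

    complications: Dict[str, ComplicationEcon]
    base_annual_cost: float = 3921.0
    baseline_utility: float = 0.785
    cost_discount: float = 0.03
    qaly_discount: float = 0.015
    utility_floor: float | None = None
    #: whether the base annual cost also accrues in event years (additive
    #: composition of base + complication costs); switchable for sensitivity
    base_cost_in_event_years: bool = True

    def validate(self) -> None:
        if self.base_annual_cost < 0:
            raise ValueError("base_annual_cost must be >= 0")
        if not -0.59 <= self.baseline_utility <= 1.0:
            raise ValueError("baseline utility outside the EQ-5D range [-0.59, 1]")
        if self.cost_discount < 0 or self.qaly_discount < 0:
            raise ValueError("discount rates must be >= 0")
        missing = set(ENDPOINTS) - set(self.complications)
        if missing:
            raise ValueError(f"missing complication parameters for: {sorted(missing)}")
        for name, c in self.complications.items():
            c.validate(name)

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EconParameters":
        payload = json.loads(text)
        comp = {k: ComplicationEcon(**v) for k, v in payload.pop("complications").items()}
        out = cls(complications=comp, **payload)
        out.validate()
        return out


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def discount(amount, year: int, rate: float):
    """Present value of ``amount`` accruing in ``year`` at annual ``rate``.

    Year 0 is undiscounted by convention: value = amount / (1 + rate)^year.
    """
    if np.any(np.asarray(year) < 0):
        raise ValueError("discounting year must be >= 0")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return amount / (1.0 + rate) ** year


def annual_cost(new_events: Mapping[str, bool], prior_events: Iterable[str],
                params: EconParameters, year_fraction: float = 1.0) -> float:
    """Healthcare cost (EUR) of one simulated year.

    ``new_events`` maps complications first occurring this year to whether
    the occurrence was fatal; ``prior_events`` lists complications acquired
    in earlier years. ``year_fraction`` scales the recurring components
    (base cost, subsequent-year costs) for a partial death year; acute
    event costs are one-off and never scaled.
    """
    total = 0.0
    if params.base_cost_in_event_years or (not new_events and not prior_events):
        total += params.base_annual_cost * year_fraction
    for name, fatal in new_events.items():
        c = _lookup(params, name)
        if fatal and c.fatal_cost is not None:
            total += c.fatal_cost
        else:
            total += c.event_cost
    for name in prior_events:
        total += _lookup(params, name).subsequent_cost * year_fraction
    return total


def annual_utility(new_events: Iterable[str], prior_events: Iterable[str],
                   params: EconParameters) -> float:
    """Health-state utility of one alive year (before the partial-year weight).

    Baseline utility minus event-year decrements for this year's new
    complications and subsequent-year decrements for established ones,
    combined additively; the optional floor is applied last.
    """
    u = params.baseline_utility
    for name in new_events:
        u -= _lookup(params, name).event_decrement
    for name in prior_events:
        u -= _lookup(params, name).subsequent_decrement
    if params.utility_floor is not None:
        u = max(u, params.utility_floor)
    return u


def _lookup(params: EconParameters, name: str) -> ComplicationEcon:
    try:
        return params.complications[name]
    except KeyError:
        raise KeyError(f"no cost/utility parameters for endpoint {name!r}") from None


# ---------------------------------------------------------------------------
# accrual over one history (reference implementation)
# ---------------------------------------------------------------------------

def accumulate(history: PatientHistory, params: EconParameters,
               horizon: int | None = None) -> Dict[str, float]:
    """Discounted cost, QALYs and life-years of one simulated history.

    Walks the history year by year using :func:`annual_cost` and
    :func:`annual_utility`; the death year carries weight 0.5. This scalar
    walk is the reference the vectorized cohort accrual is checked against.
    """
    params.validate()
    H = history.horizon if horizon is None else min(horizon, history.horizon)
    cost = qaly = ly = 0.0
    for y in range(H):
        if history.death_year is not None and y > history.death_year:
            break
        w = 0.5 if history.death_year == y else 1.0
        new = {e: history.fatal_events.get(e, False)
               for e, yr in history.event_years.items() if yr == y}
        prior = [e for e, yr in history.event_years.items() if 0 <= yr < y]
        cost += discount(annual_cost(new, prior, params, year_fraction=w),
                         y, params.cost_discount)
        qaly += discount(annual_utility(new, prior, params) * w,
                         y, params.qaly_discount)
        ly += w
    return {"cost": cost, "qaly": qaly, "life_years": ly}


# ---------------------------------------------------------------------------
# vectorized accrual over simulated arrays
# ---------------------------------------------------------------------------

@dataclass
class AccrualStreams:
    """Per-patient, per-year discounted accrual components.

    Shapes are (n, horizon). ``cost`` and ``qaly`` are the assembled
    discounted streams; ``wly_cost`` / ``wly_qaly`` are the discounted
    partial-year-weighted alive indicators at the two discount rates, and
    ``life_years`` the undiscounted weights — kept separate so totals can be
    re-assembled under perturbed base cost / baseline utility without
    re-simulating (used by the parameter-resampling PSA mode).
    """

    cost: np.ndarray
    qaly: np.ndarray
    wly_cost: np.ndarray
    wly_qaly: np.ndarray
    event_cost: np.ndarray
    decrement: np.ndarray
    life_years: np.ndarray

    def totals(self, horizon: int | None = None) -> Dict[str, np.ndarray]:
        s = slice(None, horizon)
        return {"cost": self.cost[:, s].sum(axis=1),
                "qaly": self.qaly[:, s].sum(axis=1),
                "life_years": self.life_years[:, s].sum(axis=1)}


def accumulate_arrays(event_year: np.ndarray, event_fatal: np.ndarray,
                      death_year: np.ndarray, params: EconParameters,
                      horizon: int) -> AccrualStreams:
    """Vectorized accrual over ``n`` simulated patients.

    ``event_year`` (n, 7), ``event_fatal`` (n, 7) and ``death_year`` (n,)
    follow the engine's conventions (-1 = never). Returns per-year discounted
    streams whose prefix sums give totals at any truncated horizon.
    """
    params.validate()
    n = len(death_year)
    years = np.arange(horizon)
    dy = death_year[:, None]                      # (n, 1)
    # partial-year weight: 1 while alive, 0.5 in the death year, 0 after
    weight = np.where((dy >= 0) & (years == dy), 0.5,
                      np.where((dy >= 0) & (years > dy), 0.0, 1.0))
    disc_c = 1.0 / (1.0 + params.cost_discount) ** years
    disc_q = 1.0 / (1.0 + params.qaly_discount) ** years

    event_cost = np.zeros((n, horizon))
    decrement = np.zeros((n, horizon))
    for j, name in enumerate(ENDPOINTS):
        c = _lookup(params, name)
        ey = event_year[:, j][:, None]            # (n, 1)
        occurred = ey >= 0
        is_new = occurred & (years == ey)
        is_prior = occurred & (years > ey)
        fatal = event_fatal[:, j][:, None]
        acute = np.where(fatal & (c.fatal_cost is not None),
                         c.fatal_cost if c.fatal_cost is not None else 0.0,
                         c.event_cost)
        event_cost += np.where(is_new, acute, 0.0)
        event_cost += np.where(is_prior, c.subsequent_cost, 0.0) * weight
        decrement += np.where(is_new, c.event_decrement, 0.0)
        decrement += np.where(is_prior, c.subsequent_decrement, 0.0)

    base = params.base_annual_cost * weight
    if not params.base_cost_in_event_years:
        has_any = ((event_year[:, :, None] >= 0)
                   & (years[None, None, :] >= event_year[:, :, None])).any(axis=1)
        base = np.where(has_any, 0.0, base)
    cost = (base + event_cost) * disc_c

    utility = params.baseline_utility - decrement
    if params.utility_floor is not None:
        utility = np.maximum(utility, params.utility_floor)
    qaly = utility * weight * disc_q

    return AccrualStreams(cost=cost, qaly=qaly,
                          wly_cost=weight * disc_c, wly_qaly=weight * disc_q,
                          event_cost=event_cost * disc_c,
                          decrement=decrement * weight * disc_q,
                          life_years=weight)
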
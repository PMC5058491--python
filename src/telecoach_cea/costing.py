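"""Within-trial incremental healthcare costs and program costing.

The trial-year claims cost of each patient is adjusted for the chance
between-arm imbalance in baseline costs by the regression method

    HC2_adj = HC2 - beta * (HC1 - mean(HC1)),

with ``beta`` from a single ordinary-least-squares fit of the trial-year
cost on the baseline cost pooled over both arms. The within-trial
incremental cost is then the difference of per-arm adjusted means
(ambulatory costs only in the base case — hospitalization swings in a small
trial are chance-confoundable).

The telecoaching program cost itself is a ledger of recruitment, fixed and
variable items divided over the enrolled patients, with one-off set-up
investment kept out of the base case and spread over a configurable
allocation size in sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import ARMS


# ---------------------------------------------------------------------------
# regression-based baseline adjustment
# ---------------------------------------------------------------------------

@dataclass
class BaselineAdjustment:
    """Result of the regression-based baseline-cost adjustment."""

    beta: float
    pooled_baseline_mean: float
    adjusted_means: Dict[str, float]
    adjusted: pd.Series            # per-record adjusted trial-year costs

    @property
    def incremental(self) -> float:
        return self.adjusted_means["intervention"] - self.adjusted_means["control"]


def adjust_baseline(records: pd.DataFrame, arm_col: str = "arm",
                    baseline_col: str = "amb_cost_base",
                    trial_col: str = "amb_cost_trial") -> BaselineAdjustment:
    """Shift each trial-year cost by ``-beta (HC1 - pooled baseline mean)``.

    ``beta`` comes from one pooled OLS regression of the trial-year on the
    baseline cost, so the adjustment is symmetric across arms. Raises when an
    arm has fewer than 2 records or the baseline costs have zero variance.
    """
    for arm in ARMS:
        if (records[arm_col] == arm).sum() < 2:
            raise ValueError(f"need >= 2 records in arm {arm!r} for the adjustment")
    hc1 = records[baseline_col].to_numpy(dtype=float)
    hc2 = records[trial_col].to_numpy(dtype=float)
    if np.var(hc1) == 0:
        raise ValueError("baseline costs have zero variance; beta is not estimable")
    fit = sm.OLS(hc2, sm.add_constant(hc1)).fit()
    beta = float(fit.params[1])
    grand = float(hc1.mean())
    adjusted = pd.Series(hc2 - beta * (hc1 - grand), index=records.index,
                         name="adjusted_trial_cost")
    means = {arm: float(adjusted[records[arm_col] == arm].mean()) for arm in ARMS}
    return BaselineAdjustment(beta=beta, pooled_baseline_mean=grand,
                              adjusted_means=means, adjusted=adjusted)


def incremental_within_trial_cost(adjusted_means: Mapping[str, float]) -> float:
    """Intervention minus control adjusted trial-year mean cost (EUR)."""
    return float(adjusted_means["intervention"]) - float(adjusted_means["control"])


# ---------------------------------------------------------------------------
# program costing
# ---------------------------------------------------------------------------

@dataclass
class ProgramCostModel:
    """Ledger of telecoaching program costs (all amounts in EUR).

    ``investment_items`` are one-off set-up costs (training, translation,
    software configuration); they are excluded from the operational
    per-patient cost unless ``include_investment`` is set, in which case the
    investment total is spread over ``n_allocation`` patients.
    """

    recruitment_total: float
    fixed_annual_total: float
    variable_per_patient: Dict[str, float]
    investment_items: Dict[str, float] = field(default_factory=dict)
    n_enrolled: int = 287
    n_allocation: int = 287
    include_investment: bool = False

    def validate(self) -> None:
        amounts = ([self.recruitment_total, self.fixed_annual_total]
                   + list(self.variable_per_patient.values())
                   + list(self.investment_items.values()))
        if any(a < 0 for a in amounts):
            raise ValueError("all program cost amounts must be >= 0")
        if self.n_enrolled <= 0:
            raise ValueError("n_enrolled must be > 0")
        if self.include_investment and self.n_allocation <= 0:
            raise ValueError("n_allocation must be > 0 when investment is included")

    @property
    def investment_total(self) -> float:
        return float(sum(self.investment_items.values()))


@dataclass
class ProgramCostBreakdown:
    """Per-patient program cost components (unrounded EUR)."""

    recruitment: float
    fixed: float
    variable: float
    investment: float

    @property
    def operational(self) -> float:
        return self.recruitment + self.fixed + self.variable

    @property
    def total(self) -> float:
        return self.operational + self.investment

    def report(self) -> Dict[str, float]:
        """Ledger-style rounding: operational lines to EUR 0.1, investment to cents."""
        return {"recruitment": round(self.recruitment, 1),
                "fixed": round(self.fixed, 1),
                "variable": round(self.variable, 1),
                "operational": round(self.operational, 1),
                "investment": round(self.investment, 2),
                "total": round(self.total, 2)}


def per_patient_program_cost(model: ProgramCostModel) -> ProgramCostBreakdown:
    """Divide the ledger into per-patient components.

    Recruitment and fixed totals are spread over the enrolled patients;
    variable items are already per patient; investment (when included) is
    spread over ``n_allocation``.
    """
    model.validate()
    inv = model.investment_total / model.n_allocation if model.include_investment else 0.0
    return ProgramCostBreakdown(
        recruitment=model.recruitment_total / model.n_enrolled,
        fixed=model.fixed_annual_total / model.n_enrolled,
        variable=float(sum(model.variable_per_patient.values())),
        investment=inv)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def percent_change(baseline: float, trial: float) -> float:
    """Percent change 100 * (trial - baseline) / baseline (report at 1 dp)."""
    if baseline == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (trial - baseline) / baseline


def total_intervention_increment(within_trial: float, program: float,
                                 long_term: float) -> float:
    """Total incremental cost: modelled long-term + within-trial + program."""
    return within_trial + program + long_term
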
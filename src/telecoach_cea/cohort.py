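"""Synthetic two-arm trial cohorts for diabetes telecoaching evaluation.

The generator reproduces the *statistical shape* of an 18-month randomized
telecoaching trial in type 2 diabetes — per-arm baseline demographics and
comorbidity prevalences, risk-factor means/SDs at three measurement points
(baseline, 6 months, 18 months), and right-skewed annual claims costs — so the
downstream microsimulation and costing layers can be exercised and tested
without access to private patient-level claims data.

Continuous risk factors are drawn as truncated normals (physiologic bounds)
linked across visits through a Gaussian AR(1) copula; claims costs are
lognormal with parameters solved from a published mean and its 95% CI.
Visit-level dropout is injected completely at random and repaired by
conditional-mean imputation under a multivariate normal fitted to the
complete records — the single-imputation scheme used in trial analyses.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

ARMS = ("intervention", "control")

#: continuous risk factors measured at each of the three visits
VISIT_VARS = ("hba1c", "tchol", "hdl", "sbp", "bmi")

#: baseline complication-history flags carried into the risk engine
HISTORY_FLAGS = ("ihd", "mi", "heart_failure", "stroke")

#: physiologic truncation bounds for continuous variables
BOUNDS: Dict[str, Tuple[float, float]] = {
    "hba1c": (4.0, 15.0),
    "tchol": (50.0, 400.0),
    "hdl": (10.0, 150.0),
    "sbp": (80.0, 220.0),
    "bmi": (15.0, 60.0),
    "age": (35.0, 75.0),
    "duration": (0.25, 40.0),
    "weight": (40.0, 180.0),
}

#: (cost category, year) keys for the four annual claims-cost columns
COST_KEYS = (
    ("ambulatory", "baseline"),
    ("ambulatory", "trial"),
    ("hospital", "baseline"),
    ("hospital", "trial"),
)

COST_COLUMNS = {
    ("ambulatory", "baseline"): "amb_cost_base",
    ("ambulatory", "trial"): "amb_cost_trial",
    ("hospital", "baseline"): "hosp_cost_base",
    ("hospital", "trial"): "hosp_cost_trial",
}


def visit_col(var: str, visit: int) -> str:
    """Column name of risk factor ``var`` at visit 0, 1 or 2."""
    if visit not in (0, 1, 2):
        raise ValueError(f"visit index must be 0, 1 or 2, got {visit}")
    return f"{var}_v{visit}"


@dataclass
class ArmTargets:
    """Per-arm distributional targets.

    Visit-wise entries are ``(mean, sd)`` triples indexed by visit; cost
    entries are ``(mean, ci_lo, ci_hi)`` for the mean's 95% CI.
    """

    male_prev: float
    age_mean: float
    age_sd: float
    duration_mean: float
    duration_sd: float
    weight_mean: float
    weight_sd: float
    # var -> ((mean, sd), (mean, sd), (mean, sd)) for visits 0..2
    visits: Dict[str, Sequence[Tuple[float, float]]] = field(default_factory=dict)
    # smoking prevalence (= 1 - non-smoker share) per visit
    smoker_prev: Sequence[float] = (0.15, 0.13, 0.12)
    comorbidity_prev: Dict[str, float] = field(default_factory=dict)
    # (category, year) -> (mean, ci_lo, ci_hi)
    costs: Dict[Tuple[str, str], Tuple[float, float, float]] = field(default_factory=dict)
    # dropout proportion at visits 1 and 2
    missingness: Tuple[float, float] = (0.0, 0.0)


@dataclass
class CohortSpec:
    """Full two-arm generator specification (seeded, hence reproducible)."""

    n_per_arm: int = 287
    arms: Dict[str, ArmTargets] = field(default_factory=dict)
    visit_rho: float = 0.7      # latent AR(1) correlation across visits
    cost_rho: float = 0.7       # latent correlation baseline vs trial-year cost
    n_cost_ci: int = 287        # sample size behind the printed cost CIs
    baseline_utility: float = 0.785
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 0:
            raise ValueError(f"n_per_arm must be >= 0, got {self.n_per_arm}")
        if not -1.0 < self.visit_rho < 1.0 or not -1.0 < self.cost_rho < 1.0:
            raise ValueError("copula correlations must lie in (-1, 1)")
        for arm, t in self.arms.items():
            for name, sd in (("age_sd", t.age_sd), ("duration_sd", t.duration_sd),
                             ("weight_sd", t.weight_sd)):
                if sd < 0:
                    raise ValueError(f"{arm}: {name} must be >= 0, got {sd}")
            for var, per_visit in t.visits.items():
                for v, (_, sd) in enumerate(per_visit):
                    if sd < 0:
                        raise ValueError(
                            f"{arm}: sd of {var} at visit {v} must be >= 0, got {sd}")
            for p in list(t.comorbidity_prev.values()) + [t.male_prev] + list(t.smoker_prev):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{arm}: prevalence {p} outside [0, 1]")
            for r in t.missingness:
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"{arm}: missingness {r} outside [0, 1]")

    def content_hash(self) -> str:
        """Stable hash of the spec contents, for provenance sidecars."""
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float,
                   bounds: Tuple[float, float]) -> np.ndarray:
    """Quantile transform of uniforms into a truncated normal."""
    if sd == 0:
        return np.full_like(u, mean, dtype=float)
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _ar1_latents(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    """(n, k) standard-normal latents with AR(1) dependence along axis 1."""
    z = np.empty((n, k))
    z[:, 0] = rng.standard_normal(n)
    for j in range(1, k):
        z[:, j] = rho * z[:, j - 1] + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
    return z


def lognormal_params_from_mean_ci(mean: float, ci_lo: float, ci_hi: float,
                                  n: int) -> Tuple[float, float]:
    """Solve lognormal (mu, sigma) from a sample mean and its 95% CI.

    The CI is read as a normal approximation of the mean, so the per-patient
    SD is ``(ci_hi - ci_lo)/2 / 1.96 * sqrt(n)``; the lognormal is then
    moment-matched to that mean and SD.
    """
    if mean <= 0:
        raise ValueError("cost mean must be positive for a lognormal fit")
    sd = (ci_hi - ci_lo) / 2.0 / 1.959963984540054 * np.sqrt(n)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _generate_arm(spec: CohortSpec, arm: str, rng: np.random.Generator) -> pd.DataFrame:
    t = spec.arms[arm]
    n = spec.n_per_arm
    cols: Dict[str, np.ndarray] = {}

    cols["male"] = (rng.random(n) < t.male_prev).astype(int)
    cols["age"] = _truncnorm_ppf(rng.random(n), t.age_mean, t.age_sd, BOUNDS["age"])
    # duration since diagnosis is right-skewed and strictly positive: gamma
    # moment-matched to the target mean/SD keeps the mean exact (a truncated
    # normal at these moments would inflate it)
    if t.duration_sd == 0:
        cols["diabetes_duration"] = np.full(n, t.duration_mean)
        rng.random(n)  # keep the draw count stable
    else:
        shape = (t.duration_mean / t.duration_sd) ** 2
        scale = t.duration_sd ** 2 / t.duration_mean
        cols["diabetes_duration"] = np.clip(
            stats.gamma.ppf(rng.random(n), shape, scale=scale),
            BOUNDS["duration"][0], BOUNDS["duration"][1])
    cols["ethnicity"] = np.zeros(n, dtype=int)  # single-ethnicity recruitment
    weight = _truncnorm_ppf(rng.random(n), t.weight_mean, t.weight_sd, BOUNDS["weight"])
    cols["weight_kg"] = weight

    # visit-wise continuous risk factors: AR(1) Gaussian copula with
    # truncated-normal marginals matched per visit
    for var in VISIT_VARS:
        per_visit = t.visits[var]
        z = _ar1_latents(rng, n, len(per_visit), spec.visit_rho)
        u = stats.norm.cdf(z)
        for v, (mean, sd) in enumerate(per_visit):
            cols[visit_col(var, v)] = _truncnorm_ppf(u[:, v], mean, sd, BOUNDS[var])

    # height from baseline weight and BMI; weight is only collected once
    cols["height_m"] = np.clip(np.sqrt(weight / cols[visit_col("bmi", 0)]), 1.40, 2.10)

    # smoking: one latent uniform per patient against the per-visit prevalence,
    # so quitting between visits is monotone when prevalence declines
    u_smoke = rng.random(n)
    for v, p in enumerate(t.smoker_prev):
        cols[visit_col("smoker", v)] = (u_smoke < p).astype(int)

    for flag in HISTORY_FLAGS:
        p = t.comorbidity_prev.get(flag, 0.0)
        cols[f"hist_{flag}"] = (rng.random(n) < p).astype(int)

    # claims costs: lognormal marginals, baseline/trial-year linked by a
    # Gaussian copula within each category; categories independent
    for cat in ("ambulatory", "hospital"):
        z = _ar1_latents(rng, n, 2, spec.cost_rho)
        u = stats.norm.cdf(z)
        for j, year in enumerate(("baseline", "trial")):
            mean, lo, hi = t.costs[(cat, year)]
            mu, sigma = lognormal_params_from_mean_ci(mean, lo, hi, spec.n_cost_ci)
            cols[COST_COLUMNS[(cat, year)]] = np.exp(mu + sigma * stats.norm.ppf(u[:, j]))

    df = pd.DataFrame(cols)
    df.insert(0, "arm", arm)
    df["baseline_utility"] = spec.baseline_utility
    return df


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate a seeded two-arm cohort of ``2 * n_per_arm`` patient records.

    Parameters
    ----------
    spec
        Distributional targets per arm plus copula/seed settings.
    seed
        Overrides ``spec.seed`` when given.

    Returns
    -------
    pandas.DataFrame
        One row per patient; visit-indexed columns carry ``_v0/_v1/_v2``
        suffixes. Identical spec + seed yields a bit-identical frame.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    arm_seeds = root.spawn(len(ARMS))
    frames = []
    for arm, ss in zip(ARMS, arm_seeds):
        if spec.n_per_arm == 0:
            continue
        frames.append(_generate_arm(spec, arm, np.random.default_rng(ss)))
    if not frames:
        df = pd.DataFrame(columns=cohort_columns())
    else:
        df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", np.arange(len(df)))
    return df


def cohort_columns() -> list[str]:
    """Documented column dictionary of a generated cohort (in order)."""
    cols = ["arm", "male", "age", "diabetes_duration", "ethnicity", "weight_kg"]
    for var in VISIT_VARS:
        cols += [visit_col(var, v) for v in range(3)]
    cols += ["height_m"]
    cols += [visit_col("smoker", v) for v in range(3)]
    cols += [f"hist_{f}" for f in HISTORY_FLAGS]
    cols += [COST_COLUMNS[k] for k in COST_KEYS]
    cols += ["baseline_utility"]
    return cols


# ---------------------------------------------------------------------------
# missing data: MCAR injection + conditional-mean imputation
# ---------------------------------------------------------------------------

#: variables imputed jointly under the multivariate-normal model
IMPUTE_VARS = ("hba1c", "tchol", "hdl", "sbp", "bmi", "smoker")


def _imputation_columns() -> list[str]:
    cols = ["age", "diabetes_duration"]
    for var in IMPUTE_VARS:
        cols += [visit_col(var, v) for v in range(3)]
    return cols


def inject_missing(cohort: pd.DataFrame,
                   rates: Mapping[str, Tuple[float, float]],
                   seed: int = 0) -> pd.DataFrame:
    """Blank out whole follow-up visits completely at random.

    ``rates[arm] = (p_visit1, p_visit2)`` is the per-arm dropout proportion at
    the 6- and 18-month visits. A dropped visit loses every risk factor
    measured at it; baseline and claims data are never removed.
    """
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    for arm, (r1, r2) in rates.items():
        for r in (r1, r2):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate {r} outside [0, 1]")
        idx = out.index[out["arm"] == arm]
        for visit, rate in ((1, r1), (2, r2)):
            lost = idx[rng.random(len(idx)) < rate]
            cols = [visit_col(var, visit) for var in IMPUTE_VARS]
            out.loc[lost, cols] = np.nan
    return out


def conditional_mean_impute(df: pd.DataFrame,
                            columns: Sequence[str] | None = None,
                            tol: float = 1e-12) -> pd.DataFrame:
    """Impute missing entries with the multivariate-normal conditional mean.

    A mean vector and covariance matrix are fitted to the complete rows of
    ``columns``; each missing block is then replaced by

        E[x_m | x_o] = mu_m + S_mo S_oo^{-1} (x_o - mu_o),

    the conditional mean of the missing coordinates given the observed ones.
    Observed values are never modified.
    """
    cols = list(columns) if columns is not None else list(df.columns)
    out = df.copy()
    X = out[cols].to_numpy(dtype=float)
    missing = np.isnan(X)
    if not missing.any():
        return out
    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = [c for c, m in zip(cols, all_missing) if m]
        raise ValueError(f"variable(s) missing for every record: {bad}")
    complete = ~missing.any(axis=1)
    if complete.sum() < 2:
        raise ValueError("need at least 2 complete records to fit the "
                         "multivariate-normal imputation model")
    mu = X[complete].mean(axis=0)
    cov = np.cov(X[complete], rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    for i in np.flatnonzero(missing.any(axis=1)):
        m = missing[i]
        o = ~m
        if not o.any():
            X[i, m] = mu[m]
            continue
        S_oo = cov[np.ix_(o, o)] + tol * np.eye(o.sum())
        S_mo = cov[np.ix_(m, o)]
        X[i, m] = mu[m] + S_mo @ np.linalg.solve(S_oo, X[i, o] - mu[o])
    out[cols] = X
    return out


def inject_and_impute_missing(cohort: pd.DataFrame,
                              rates: Mapping[str, Tuple[float, float]],
                              seed: int = 0) -> pd.DataFrame:
    """Inject MCAR visit dropout, then repair it by conditional-mean imputation.

    Imputation is fitted per arm over age, diabetes duration and all
    visit-wise risk factors. Imputed smoking status is rounded back to {0, 1}.
    The completed cohort keeps the original record count and all observed
    values untouched.
    """
    masked = inject_missing(cohort, rates, seed=seed)
    cols = _imputation_columns()
    pieces = []
    for arm in ARMS:
        sub = masked[masked["arm"] == arm]
        if len(sub) == 0:
            continue
        pieces.append(conditional_mean_impute(sub, cols))
    out = pd.concat(pieces).sort_index() if pieces else masked
    for v in range(3):
        c = visit_col("smoker", v)
        out[c] = out[c].round().clip(0, 1).astype(int)
    return out


# ---------------------------------------------------------------------------
# subgroup filter
# ---------------------------------------------------------------------------

def subgroup_elevated_hba1c(cohort: pd.DataFrame, threshold: float = 7.0) -> pd.DataFrame:
    """Records with baseline HbA1c at or above ``threshold`` (default 7.0%).

    The boundary value is included: a patient measured at exactly the
    threshold belongs to the poorly-controlled subgroup.
    """
    if threshold <= 0:
        raise ValueError(f"HbA1c threshold must be positive, got {threshold}")
    return cohort[cohort[visit_col("hba1c", 0)] >= threshold]
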
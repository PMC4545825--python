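"""Synthetic APHRI-like cohort generation.

Emulates the rural Andhra Pradesh screening subset (N = 1066) whose
gender-stratified means, standard deviations and prevalences are the
generator defaults: continuous risk factors are drawn from a Gaussian
copula whose marginals are truncated normals moment-matched to the
target mean/sd, so that sample moments recover the configured values
at large n despite the physiological truncation bounds.  Binary
fields follow the configured prevalences, with hypertension-treatment
probability increasing in measured SBP and history flags enriched
among subjects with high measured glucose / cholesterol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .charts import Subject, GLUCOSE_DIABETES_THRESHOLD

_VARS = ("age", "sbp", "dbp", "glucose", "tc", "bmi")

#: physiological truncation bounds per variable
DEFAULT_BOUNDS = {
    "age": (30.0, 90.0),
    "sbp": (80.0, 230.0),
    "dbp": (50.0, 130.0),
    "glucose": (50.0, 400.0),
    "tc": (80.0, 400.0),
    "bmi": (13.0, 45.0),
}

# Cross-correlations of the latent Gaussian (not reported for the
# source study; chosen so that chart-level LI/HI disagreement
# concentrates in older, higher-SBP subjects).
DEFAULT_CORRELATIONS = {
    ("age", "sbp"): 0.40,
    ("age", "tc"): 0.20,
    ("sbp", "dbp"): 0.70,
    ("age", "glucose"): 0.15,
}

#: total-cholesterol level (mg/dl) above which a history of high
#: cholesterol is substantially more likely
_HIGH_TC_MGDL = 240.0
_HISTORY_ODDS_RATIO = 4.0
_TREATMENT_SBP_SLOPE = 0.04  # logit per mmHg


@dataclass
class GenderParams:
    mean: dict[str, float]
    sd: dict[str, float]
    smoking_prev: float
    treated_prev: float

    def validate(self) -> None:
        for v in _VARS:
            if v not in self.mean or v not in self.sd:
                raise ValueError(f"missing mean/sd for {v}")
            if not self.sd[v] > 0:
                raise ValueError(f"sd must be positive for {v}")
        for p in (self.smoking_prev, self.treated_prev):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence out of [0,1]: {p}")


@dataclass
class CohortParams:
    male_fraction: float
    male: GenderParams
    female: GenderParams
    hist_diabetes_prev: float = 0.06
    hist_high_chol_prev: float = 0.03
    correlations: dict = field(default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def validate(self) -> None:
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0,1]")
        for p in (self.hist_diabetes_prev, self.hist_high_chol_prev):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence out of [0,1]: {p}")
        self.male.validate()
        self.female.validate()
        np.linalg.cholesky(self.corr_matrix())  # must be positive definite

    def corr_matrix(self) -> np.ndarray:
        r = np.eye(len(_VARS))
        for (a, b), v in self.correlations.items():
            i, j = _VARS.index(a), _VARS.index(b)
            r[i, j] = r[j, i] = v
        return r


def default_aphri_params() -> CohortParams:
    """Generator defaults: the published cohort table's moments.

    BMI (not reported in that table) defaults to 21.5 +- 3.5 kg/m^2, a
    plausible rural-South-Asian adult value; history-of-diabetes and
    history-of-high-cholesterol prevalences (also unreported) default
    to 6% and 3%.
    """
    male = GenderParams(
        mean={"age": 50.6, "sbp": 126.1, "dbp": 77.2,
              "glucose": 99.8, "tc": 177.8, "bmi": 21.5},
        sd={"age": 14.1, "sbp": 20.1, "dbp": 11.5,
            "glucose": 28.7, "tc": 40.4, "bmi": 3.5},
        smoking_prev=0.406, treated_prev=0.138)
    female = GenderParams(
        mean={"age": 48.2, "sbp": 122.4, "dbp": 76.2,
              "glucose": 102.4, "tc": 191.1, "bmi": 21.5},
        sd={"age": 13.4, "sbp": 20.5, "dbp": 10.7,
            "glucose": 35.9, "tc": 38.7, "bmi": 3.5},
        smoking_prev=0.051, treated_prev=0.148)
    return CohortParams(male_fraction=0.488, male=male, female=female)


@lru_cache(maxsize=256)
def _truncnorm_parent(target_mean: float, target_sd: float,
                      lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncation has the target moments."""

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - target_mean, np.sqrt(v) - target_sd]

    sol = optimize.fsolve(moments, [target_mean, np.log(target_sd)], full_output=True)
    (mu, log_sigma), _, ier, msg = sol
    if ier != 1:
        raise RuntimeError(f"truncated-normal moment match failed: {msg}")
    return float(mu), float(np.exp(log_sigma))


def _truncnorm_ppf(u: np.ndarray, target_mean: float, target_sd: float,
                   lo: float, hi: float) -> np.ndarray:
    mu, sigma = _truncnorm_parent(target_mean, target_sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def _truncnorm_cdf(x: float, target_mean: float, target_sd: float,
                   lo: float, hi: float) -> float:
    mu, sigma = _truncnorm_parent(target_mean, target_sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return float(stats.truncnorm.cdf(x, a, b, loc=mu, scale=sigma))


def _marginal_grid(target_mean, target_sd, lo, hi, m: int = 801) -> np.ndarray:
    """Quantile grid of the truncated marginal, for deterministic averaging."""
    u = (np.arange(m) + 0.5) / m
    return _truncnorm_ppf(u, target_mean, target_sd, lo, hi)


def _solve_intercept_for_prevalence(values: np.ndarray, slope: float,
                                    center: float, prev: float) -> float:
    """Intercept a with mean(expit(a + slope*(v - center))) = prev."""
    if prev <= 0.0:
        return -np.inf
    if prev >= 1.0:
        return np.inf

    def gap(a):
        return np.mean(expit(a + slope * (values - center))) - prev

    return optimize.brentq(gap, -30.0, 30.0)


def _history_base_rate(prev: float, frac_elevated: float, odds_ratio: float) -> float:
    """Base probability p0 with p0*(1-q) + p1*q = prev and odds(p1)=OR*odds(p0)."""
    if prev <= 0.0 or prev >= 1.0:
        return prev

    def gap(p0):
        p1 = expit(logit(p0) + np.log(odds_ratio))
        return p0 * (1 - frac_elevated) + p1 * frac_elevated - prev

    return optimize.brentq(gap, 1e-9, 1 - 1e-9)


@dataclass
class GeneratedCohort:
    subjects: list[Subject]
    n: int
    seed: int
    params: CohortParams

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)


def generate_cohort(params: CohortParams, n: int, seed: int) -> GeneratedCohort:
    """Draw a cohort of ``n`` subjects, deterministically under ``seed``."""
    params.validate()
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    corr = params.corr_matrix()
    chol = np.linalg.cholesky(corr)

    genders = np.where(rng.random(n) < params.male_fraction, "male", "female")
    values = np.zeros((n, len(_VARS)))
    smoker = np.zeros(n, dtype=bool)
    treated = np.zeros(n, dtype=bool)
    hist_dm = np.zeros(n, dtype=bool)
    hist_hc = np.zeros(n, dtype=bool)

    for gender, gp in (("male", params.male), ("female", params.female)):
        idx = np.flatnonzero(genders == gender)
        if idx.size == 0:
            continue
        z = rng.standard_normal((idx.size, len(_VARS))) @ chol.T
        u = stats.norm.cdf(z)
        for j, v in enumerate(_VARS):
            lo, hi = params.bounds[v]
            values[idx, j] = _truncnorm_ppf(u[:, j], gp.mean[v], gp.sd[v], lo, hi)

        smoker[idx] = rng.random(idx.size) < gp.smoking_prev

        # treatment probability rises with measured SBP; intercept solved on
        # the marginal so the gender prevalence is preserved
        lo, hi = params.bounds["sbp"]
        grid = _marginal_grid(gp.mean["sbp"], gp.sd["sbp"], lo, hi)
        a = _solve_intercept_for_prevalence(grid, _TREATMENT_SBP_SLOPE,
                                            gp.mean["sbp"], gp.treated_prev)
        sbp_j = _VARS.index("sbp")
        p_treat = expit(a + _TREATMENT_SBP_SLOPE * (values[idx, sbp_j] - gp.mean["sbp"]))
        treated[idx] = rng.random(idx.size) < p_treat

        # history flags enriched among subjects with elevated measurements
        glu_j, tc_j = _VARS.index("glucose"), _VARS.index("tc")
        q_glu = 1.0 - _truncnorm_cdf(GLUCOSE_DIABETES_THRESHOLD, gp.mean["glucose"],
                                     gp.sd["glucose"], *params.bounds["glucose"])
        p0 = _history_base_rate(params.hist_diabetes_prev, q_glu, _HISTORY_ODDS_RATIO)
        p1 = expit(logit(p0) + np.log(_HISTORY_ODDS_RATIO)) if 0 < p0 < 1 else p0
        elevated = values[idx, glu_j] >= GLUCOSE_DIABETES_THRESHOLD
        hist_dm[idx] = rng.random(idx.size) < np.where(elevated, p1, p0)

        q_tc = 1.0 - _truncnorm_cdf(_HIGH_TC_MGDL, gp.mean["tc"],
                                    gp.sd["tc"], *params.bounds["tc"])
        p0 = _history_base_rate(params.hist_high_chol_prev, q_tc, _HISTORY_ODDS_RATIO)
        p1 = expit(logit(p0) + np.log(_HISTORY_ODDS_RATIO)) if 0 < p0 < 1 else p0
        elevated = values[idx, tc_j] >= _HIGH_TC_MGDL
        hist_hc[idx] = rng.random(idx.size) < np.where(elevated, p1, p0)

    subjects = []
    for i in range(n):
        v = dict(zip(_VARS, values[i]))
        subjects.append(Subject(
            id=f"s{i:06d}",
            gender=str(genders[i]),
            age=float(v["age"]),
            smoker=bool(smoker[i]),
            diabetes=bool(hist_dm[i]),
            sbp=float(v["sbp"]),
            dbp=float(v["dbp"]),
            glucose=float(v["glucose"]),
            tc=float(v["tc"]),
            on_htn_treatment=bool(treated[i]),
            bmi=float(v["bmi"]),
            hist_high_chol=bool(hist_hc[i]),
        ))
    return GeneratedCohort(subjects=subjects, n=n, seed=seed, params=params)


def summarize_cohort(cohort) -> pd.DataFrame:
    """Gender-stratified mean +- sd / prevalence summary table."""
    subjects = list(cohort)
    if not subjects:
        raise ValueError("cannot summarize an empty cohort")
    df = pd.DataFrame({
        "gender": [s.gender for s in subjects],
        "age": [s.age for s in subjects],
        "sbp": [s.sbp for s in subjects],
        "dbp": [s.dbp for s in subjects],
        "glucose": [s.glucose for s in subjects],
        "tc": [s.tc for s in subjects],
        "bmi": [s.bmi for s in subjects],
        "smoker": [float(s.smoker) for s in subjects],
        "on_htn_treatment": [float(s.on_htn_treatment) for s in subjects],
    })
    rows = []
    for gender, g in df.groupby("gender"):
        for feat in ("age", "sbp", "dbp", "glucose", "tc", "bmi"):
            rows.append({"gender": gender, "feature": feat, "kind": "continuous",
                         "n": len(g), "mean": g[feat].mean(),
                         "sd": g[feat].std(ddof=1) if len(g) > 1 else np.nan})
        for feat in ("smoker", "on_htn_treatment"):
            rows.append({"gender": gender, "feature": feat, "kind": "binary",
                         "n": int(g[feat].sum()), "pct": 100.0 * g[feat].mean()})
    return pd.DataFrame(rows)


def params_metadata(params: CohortParams, n: int, seed: int) -> dict:
    meta = asdict(params)
    meta["correlations"] = {f"{a}~{b}": v for (a, b), v in params.correlations.items()}
    return {"n": n, "seed": seed, "params": meta}
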
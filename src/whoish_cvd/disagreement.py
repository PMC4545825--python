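"""LI-vs-HI chart disagreement analysis.

Per-subject comparison of the two chart variants, T_HR cross
tabulation, an ordinal significance test (Friedman, k = 2, tie
corrected), profiling of the discordant subpopulation against the full
cohort, and the policy-scale over-treatment projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .charts import ChartTable, Cohort, RiskBand, RISK_BAND_LABELS, predict_risk
from .guidelines import is_treatment_high_risk


@dataclass(frozen=True)
class ComparisonRecord:
    subject_id: str
    li_band: RiskBand
    hi_band: RiskBand
    li_thr: bool
    hi_thr: bool

    @property
    def discordant(self) -> bool:
        return self.li_band != self.hi_band


def compare_cohort(
    cohort: Cohort, li_chart: ChartTable, hi_chart: ChartTable
) -> tuple[list[ComparisonRecord], list[str]]:
    """Score every subject under both chart variants.

    Subjects without a total cholesterol value cannot be scored by the
    HI chart; they are returned as the second element (a rejects list)
    and excluded from the records.
    """
    records, rejects = [], []
    for s in cohort:
        if s.tc is None:
            rejects.append(s.id)
            continue
        li = predict_risk(s, li_chart).band
        hi = predict_risk(s, hi_chart).band
        records.append(ComparisonRecord(
            subject_id=s.id,
            li_band=li,
            hi_band=hi,
            li_thr=is_treatment_high_risk(li, s.sbp).is_thr,
            hi_thr=is_treatment_high_risk(hi, s.sbp).is_thr,
        ))
    return records, rejects


@dataclass
class ConcordanceSummary:
    """Counts and percentages of LI/HI band and T_HR disagreement.

    Both disagreement denominators reported in practice are exposed:
    ``pct_thr_disagree_of_either`` (union of the two T_HR sets) and
    ``pct_thr_disagree_of_hi`` (the HI T_HR set alone).
    """

    n: int
    n_discordant: int
    n_li_thr: int
    n_hi_thr: int
    n_both_thr: int

    pct_discordant: float = field(init=False)
    n_either_thr: int = field(init=False)
    n_thr_disagree: int = field(init=False)
    n_li_only_thr: int = field(init=False)
    n_hi_only_thr: int = field(init=False)
    pct_thr_disagree_of_either: Optional[float] = field(init=False)
    pct_thr_disagree_of_hi: Optional[float] = field(init=False)

    def __post_init__(self) -> None:
        self.pct_discordant = 100.0 * self.n_discordant / self.n if self.n else 0.0
        self.n_either_thr = self.n_li_thr + self.n_hi_thr - self.n_both_thr
        self.n_thr_disagree = self.n_either_thr - self.n_both_thr
        self.n_li_only_thr = self.n_li_thr - self.n_both_thr
        self.n_hi_only_thr = self.n_hi_thr - self.n_both_thr
        self.pct_thr_disagree_of_either = (
            round(100.0 * self.n_thr_disagree / self.n_either_thr)
            if self.n_either_thr > 0 else None)
        self.pct_thr_disagree_of_hi = (
            round(100.0 * self.n_li_only_thr / self.n_hi_thr)
            if self.n_hi_thr > 0 else None)


def concordance_summary(records: Sequence[ComparisonRecord]) -> ConcordanceSummary:
    return ConcordanceSummary(
        n=len(records),
        n_discordant=sum(r.discordant for r in records),
        n_li_thr=sum(r.li_thr for r in records),
        n_hi_thr=sum(r.hi_thr for r in records),
        n_both_thr=sum(r.li_thr and r.hi_thr for r in records),
    )


def band_contingency(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    """5x5 LI-band (rows) vs HI-band (columns) count matrix."""
    m = np.zeros((5, 5), dtype=int)
    for r in records:
        m[int(r.li_band), int(r.hi_band)] += 1
    labels = [RISK_BAND_LABELS[i] for i in range(5)]
    return pd.DataFrame(m, index=pd.Index(labels, name="li_band"),
                        columns=pd.Index(labels, name="hi_band"))


def friedman_ordinal_test(paired_bands: Sequence[tuple[int, int]]) -> tuple[float, float]:
    """Friedman test for two related ordinal samples, with tie correction.

    Each pair is ranked within-subject (average ranks on ties); the
    tie-corrected chi-square has 1 degree of freedom.  When every pair
    is tied the statistic is 0 and p = 1.  Two related samples is below
    the k >= 3 floor of the usual library routine, hence the direct
    implementation.
    """
    pairs = np.asarray(paired_bands, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("paired_bands must be a sequence of (li, hi) pairs")
    n, k = pairs.shape
    if n < 2:
        raise ValueError("need at least 2 pairs")
    ranks = np.apply_along_axis(stats.rankdata, 1, pairs)
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    denom = float(np.sum(ranks ** 2)) - n * k * (k + 1) ** 2 / 4.0
    if denom == 0.0:  # every pair tied
        return 0.0, 1.0
    chi2 = numer / denom
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


_CONTINUOUS_FEATURES = ["age", "sbp", "dbp", "glucose", "tc"]
_BINARY_FEATURES = ["smoker", "on_htn_treatment"]


@dataclass
class SubpopulationProfile:
    """Gender-stratified profile of a subpopulation vs. the full cohort.

    ``table`` holds mean +- sd rows for continuous features and % (n)
    rows for binary features; ``p_values`` holds per-(feature, gender)
    two-sample p-values (t-test for continuous features, Wilcoxon
    rank-sum for binary ones) comparing subpopulation to cohort.
    """

    n: int
    table: pd.DataFrame
    p_values: pd.DataFrame
    empty: bool = False


def _feature_frame(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame({
        "id": [s.id for s in cohort],
        "gender": [s.gender for s in cohort],
        "age": [s.age for s in cohort],
        "sbp": [s.sbp for s in cohort],
        "dbp": [s.dbp for s in cohort],
        "glucose": [s.glucose for s in cohort],
        "tc": [s.tc for s in cohort],
        "smoker": [float(s.smoker) for s in cohort],
        "on_htn_treatment": [float(s.on_htn_treatment) for s in cohort],
    })


def subpopulation_profile(
    records: Sequence[ComparisonRecord], cohort: Cohort
) -> SubpopulationProfile:
    """Profile the discordant subpopulation against the full cohort."""
    discordant_ids = {r.subject_id for r in records if r.discordant}
    frame = _feature_frame(cohort)
    sub = frame[frame["id"].isin(discordant_ids)]
    if sub.empty:
        return SubpopulationProfile(n=0, table=pd.DataFrame(),
                                    p_values=pd.DataFrame(), empty=True)
    rows, prows = [], []
    for gender in ("male", "female"):
        g_sub = sub[sub["gender"] == gender]
        g_all = frame[frame["gender"] == gender]
        for feat in _CONTINUOUS_FEATURES:
            x, y = g_sub[feat].dropna(), g_all[feat].dropna()
            rows.append({"gender": gender, "feature": feat, "kind": "continuous",
                         "mean": x.mean(), "sd": x.std(ddof=1), "n": len(x)})
            if len(x) >= 2 and len(y) >= 2:
                stat, p = stats.ttest_ind(x, y)
                prows.append({"gender": gender, "feature": feat,
                              "test": "t", "statistic": stat, "p": p})
        for feat in _BINARY_FEATURES:
            x, y = g_sub[feat], g_all[feat]
            rows.append({"gender": gender, "feature": feat, "kind": "binary",
                         "pct": 100.0 * x.mean() if len(x) else np.nan,
                         "n": int(x.sum())})
            if len(x) and len(y):
                stat, p = stats.ranksums(x, y)
                prows.append({"gender": gender, "feature": feat,
                              "test": "ranksum", "statistic": stat, "p": p})
    return SubpopulationProfile(
        n=len(sub), table=pd.DataFrame(rows), p_values=pd.DataFrame(prows))


@dataclass(frozen=True)
class PolicyInputs:
    """Inputs of the national over-treatment cost projection."""

    population: float
    frac_over_40: float
    frac_high_risk: float
    frac_overtreated: float
    cost_per_day_low: float
    cost_per_day_high: float
    days_per_month: int = 30

    def __post_init__(self) -> None:
        for name in ("frac_over_40", "frac_high_risk", "frac_overtreated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0,1], got {v}")
        if self.cost_per_day_low > self.cost_per_day_high:
            raise ValueError("cost range must satisfy low <= high")


@dataclass(frozen=True)
class PolicyProjection:
    n_over_40: float
    n_high_risk: float
    n_overtreated: float
    monthly_cost_low: float
    monthly_cost_high: float


def project_overtreatment(inputs: PolicyInputs) -> PolicyProjection:
    """Headcounts and monthly cost range of over-treatment at national scale.

    over40 = population * frac_over_40; high-risk = over40 * frac_high_risk;
    over-treated = high-risk * frac_overtreated; monthly cost =
    over-treated * daily cost * days per month.
    """
    over40 = inputs.population * inputs.frac_over_40
    high_risk = over40 * inputs.frac_high_risk
    overtreated = high_risk * inputs.frac_overtreated
    return PolicyProjection(
        n_over_40=over40,
        n_high_risk=high_risk,
        n_overtreated=overtreated,
        monthly_cost_low=overtreated * inputs.cost_per_day_low * inputs.days_per_month,
        monthly_cost_high=overtreated * inputs.cost_per_day_high * inputs.days_per_month,
    )


def records_to_frame(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "li_band": [int(r.li_band) for r in records],
        "hi_band": [int(r.hi_band) for r in records],
        "discordant": [r.discordant for r in records],
        "li_thr": [r.li_thr for r in records],
        "hi_thr": [r.hi_thr for r in records],
    })


def summary_to_text(s: ConcordanceSummary) -> str:
    lines = [
        f"subjects scored:              {s.n}",
        f"band disagreement:            {s.n_discordant} ({s.pct_discordant:.1f}%)",
        f"T_HR by LI chart:             {s.n_li_thr}",
        f"T_HR by HI chart:             {s.n_hi_thr}",
        f"T_HR by both:                 {s.n_both_thr}",
        f"T_HR by either:               {s.n_either_thr}",
        f"T_HR disagreement:            {s.n_thr_disagree} "
        f"(LI-only {s.n_li_only_thr}, HI-only {s.n_hi_only_thr})",
    ]
    if s.pct_thr_disagree_of_either is not None:
        lines.append(f"  as % of either-model T_HR:  {s.pct_thr_disagree_of_either}%")
    if s.pct_thr_disagree_of_hi is not None:
        lines.append(f"  LI-only as % of HI T_HR:    {s.pct_thr_disagree_of_hi}%")
    return "\n".join(lines)
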
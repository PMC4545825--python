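"""LI-vs-HI comparison records, T_HR cross-tabulation, ordinal test, projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from whoish_cvd import (
    ComparisonRecord,
    PolicyInputs,
    RiskBand,
    Subject,
    band_contingency,
    compare_cohort,
    concordance_summary,
    friedman_ordinal_test,
    project_overtreatment,
    subpopulation_profile,
)
from whoish_cvd.disagreement import summary_to_text


def rec(i, li, hi, li_thr=False, hi_thr=False):
    return ComparisonRecord(subject_id=f"s{i}", li_band=RiskBand(li),
                            hi_band=RiskBand(hi), li_thr=li_thr, hi_thr=hi_thr)


def records_with_thr_marginals(n=1066, li_thr=108, hi_thr=88, both=80):
    """Records whose T_HR marginals match given counts."""
    out = []
    i = 0
    for _ in range(both):
        out.append(rec(i, 3, 3, True, True)); i += 1
    for _ in range(li_thr - both):
        out.append(rec(i, 3, 1, True, False)); i += 1
    for _ in range(hi_thr - both):
        out.append(rec(i, 1, 3, False, True)); i += 1
    while i < n:
        out.append(rec(i, 0, 0)); i += 1
    return out


class TestConcordanceSummary:
    def test_published_marginals_cross_tabulate(self):
        """LI 108 / HI 88 / both 80 imply 36 disagreements, 28 LI-only, 31%."""
        s = concordance_summary(records_with_thr_marginals())
        assert s.n_li_thr == 108 and s.n_hi_thr == 88 and s.n_both_thr == 80
        assert s.n_thr_disagree == 36
        assert s.n_li_only_thr == 28
        assert s.n_hi_only_thr == 8
        assert s.n_either_thr == 116
        assert s.pct_thr_disagree_of_either == 31
        assert s.pct_thr_disagree_of_hi == 32

    def test_all_concordant(self):
        s = concordance_summary([rec(i, 2, 2, True, True) for i in range(5)])
        assert s.n_thr_disagree == 0 and s.n_discordant == 0

    def test_counts_equal_enumeration(self):
        records = [rec(0, 0, 1), rec(1, 3, 3, True, True), rec(2, 2, 3, False, True),
                   rec(3, 4, 2, True, False), rec(4, 1, 1)]
        s = concordance_summary(records)
        assert s.n == 5
        assert s.n_discordant == sum(r.li_band != r.hi_band for r in records) == 3
        assert s.n_li_thr == 2 and s.n_hi_thr == 2 and s.n_both_thr == 1
        assert s.n_either_thr == 3 and s.n_thr_disagree == 2

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 4),
                              st.booleans(), st.booleans()), min_size=1, max_size=40))
    def test_inclusion_exclusion_identities(self, raw):
        records = [rec(i, li, hi, lt, ht) for i, (li, hi, lt, ht) in enumerate(raw)]
        s = concordance_summary(records)
        assert s.n_either_thr == s.n_li_thr + s.n_hi_thr - s.n_both_thr
        assert s.n_thr_disagree == s.n_li_only_thr + s.n_hi_only_thr
        assert s.n_thr_disagree == s.n_either_thr - s.n_both_thr
        for count in (s.n_discordant, s.n_li_thr, s.n_hi_thr, s.n_both_thr,
                      s.n_either_thr):
            assert 0 <= count <= s.n

    def test_text_report_mentions_key_counts(self):
        text = summary_to_text(concordance_summary(records_with_thr_marginals()))
        assert "36" in text and "31%" in text


class TestCompareCohort:
    def test_empty_cohort(self, charts_pair):
        li, hi = charts_pair
        records, rejects = compare_cohort([], li, hi)
        assert records == [] and rejects == []

    def test_missing_tc_rejected(self, charts_pair):
        li, hi = charts_pair
        s = Subject(id="no-tc", gender="male", age=50, smoker=False, diabetes=False,
                    sbp=120, dbp=80, glucose=90.0, tc=None)
        records, rejects = compare_cohort([s], li, hi)
        assert records == [] and rejects == ["no-tc"]

    def test_constructed_discordant_subject(self, charts_pair):
        """A TC band far from the LI reference pushes the HI cell off the LI cell."""
        li, hi = charts_pair
        key_li = ("female", False, False, 60, 160)
        assert hi.lookup(key_li + (8,)) > li.lookup(key_li)
        s = Subject(id="d", gender="female", age=65, smoker=False, diabetes=False,
                    sbp=165, dbp=90, glucose=100.0, tc=8.5 * 38.67)
        records, _ = compare_cohort([s], li, hi)
        assert records[0].discordant

    def test_permutation_equivariance(self, cohort_1066, charts_pair):
        li, hi = charts_pair
        subset = cohort_1066[:40]
        fwd, _ = compare_cohort(subset, li, hi)
        rev, _ = compare_cohort(subset[::-1], li, hi)
        assert fwd == rev[::-1]

    def test_thr_flags_use_each_models_band(self, records_1066, cohort_1066):
        by_id = {s.id: s for s in cohort_1066}
        some_disagree = False
        for r in records_1066:
            if r.li_thr != r.hi_thr:
                some_disagree = True
                assert r.li_band != r.hi_band or by_id[r.subject_id].sbp > 140
        assert some_disagree

    def test_band_contingency_totals(self, records_1066):
        m = band_contingency(records_1066)
        assert m.to_numpy().sum() == len(records_1066)
        off_diag = m.to_numpy().sum() - np.trace(m.to_numpy())
        assert off_diag == sum(r.discordant for r in records_1066)


class TestFriedman:
    def test_identical_pairs(self):
        chi2, p = friedman_ordinal_test([(1, 1)] * 10)
        assert chi2 == 0.0 and p == 1.0

    def test_untied_closed_form_equals_n(self):
        for n in (6, 10, 25):
            chi2, p = friedman_ordinal_test([(0, 1)] * n)
            assert chi2 == pytest.approx(n)
            if n >= 6:
                assert p < 0.05

    def test_matches_independent_sign_formula(self):
        """For k=2 the tie-corrected statistic is (n+ - n-)^2 / (n+ + n-)."""
        rng = np.random.default_rng(3)
        pairs = list(zip(rng.integers(0, 5, 20), rng.integers(0, 5, 20)))
        n_pos = sum(b > a for a, b in pairs)
        n_neg = sum(a > b for a, b in pairs)
        expected = (n_pos - n_neg) ** 2 / (n_pos + n_neg)
        chi2, p = friedman_ordinal_test(pairs)
        assert chi2 == pytest.approx(expected, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 4)),
                    min_size=2, max_size=30))
    def test_invariant_under_monotone_relabeling(self, pairs):
        chi2_a, _ = friedman_ordinal_test(pairs)
        relabeled = [(2 * a + 1, 2 * b + 1) for a, b in pairs]  # strictly monotone
        chi2_b, _ = friedman_ordinal_test(relabeled)
        assert chi2_a == pytest.approx(chi2_b, abs=1e-10)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            friedman_ordinal_test([(0, 1)])


class TestSubpopulationProfile:
    def test_full_cohort_as_subpopulation(self, cohort_1066, charts_pair):
        li, hi = charts_pair
        # every record discordant -> subpopulation is the full cohort
        records = [ComparisonRecord(s.id, RiskBand(0), RiskBand(1), False, False)
                   for s in cohort_1066[:200]]
        prof = subpopulation_profile(records, cohort_1066[:200])
        assert prof.n == 200
        assert (prof.p_values["p"] > 0.999).all()

    def test_empty_subpopulation(self, cohort_1066):
        records = [ComparisonRecord(s.id, RiskBand(0), RiskBand(0), False, False)
                   for s in cohort_1066[:50]]
        prof = subpopulation_profile(records, cohort_1066[:50])
        assert prof.empty and prof.n == 0

    def test_discordant_subjects_older_and_higher_sbp(self, records_1066, cohort_1066):
        """The disagreement region of the charts sits at older age / higher SBP."""
        prof = subpopulation_profile(records_1066, cohort_1066)
        t = prof.table
        cohort_age = np.mean([s.age for s in cohort_1066])
        cohort_sbp = np.mean([s.sbp for s in cohort_1066])
        sub_age = t[(t.feature == "age")]["mean"].mean()
        sub_sbp = t[(t.feature == "sbp")]["mean"].mean()
        assert sub_age > cohort_age
        assert sub_sbp > cohort_sbp

    def test_t_statistic_matches_hand_formula(self, cohort_1066):
        sub = cohort_1066[:30]
        records = [ComparisonRecord(s.id, RiskBand(0), RiskBand(1), False, False)
                   for s in sub]
        prof = subpopulation_profile(records, cohort_1066)
        x = np.array([s.age for s in sub if s.gender == "male"])
        y = np.array([s.age for s in cohort_1066 if s.gender == "male"])
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        row = prof.p_values.query("gender == 'male' and feature == 'age'")
        assert row["statistic"].iloc[0] == pytest.approx(t_hand, abs=1e-10)


class TestPolicyProjection:
    def test_over40_headcount(self):
        proj = project_overtreatment(PolicyInputs(1.252e9, 0.294, 0.15, 0.32, 15, 25))
        assert proj.n_over_40 == pytest.approx(368e6, rel=0.001)
        assert proj.n_high_risk == pytest.approx(55.2e6, rel=0.001)

    def test_zero_overtreated_zero_cost(self):
        proj = project_overtreatment(PolicyInputs(1e9, 0.3, 0.2, 0.0, 15, 25))
        assert proj.n_overtreated == 0 and proj.monthly_cost_high == 0

    def test_monthly_cost_range(self):
        proj = project_overtreatment(PolicyInputs(1e6, 1.0, 1.0, 1.0, 15, 25))
        assert proj.monthly_cost_low == pytest.approx(1e6 * 15 * 30)
        assert proj.monthly_cost_high == pytest.approx(1e6 * 25 * 30)

    @pytest.mark.parametrize("kw", [
        {"frac_over_40": 1.2}, {"frac_high_risk": -0.1},
        {"cost_per_day_low": 30, "cost_per_day_high": 20},
    ])
    def test_invalid_inputs(self, kw):
        base = dict(population=1e9, frac_over_40=0.3, frac_high_risk=0.15,
                    frac_overtreated=0.3, cost_per_day_low=15, cost_per_day_high=25)
        base.update(kw)
        with pytest.raises(ValueError):
            PolicyInputs(**base)
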
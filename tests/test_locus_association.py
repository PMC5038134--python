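"""Carrier counting, Fisher exact test, odds ratios and power."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rarecnv.cnv_data import CnvCall, ContingencyTable, LocusDef, SampleRecord
from rarecnv.locus_association import (
    CohortCounts,
    LocusAssociationModel,
    associate,
    case_frequency_from_or,
    count_carriers,
    fisher_exact_two_sided,
    genomewide_threshold,
    match_call_to_locus,
    odds_ratio,
    pool_counts,
    power_two_proportion,
    woolf_ci,
)

LOCUS = LocusDef("16p11.2 dup", "16", 29_640_000, 30_200_000, "dup")


def enumerate_fisher_p(a, b, c, d):
    """Independent oracle: sum hypergeometric pmfs no larger than observed."""
    n1, k, n = a + b, a + c, a + b + c + d
    obs = stats.hypergeom.pmf(a, n, k, n1)
    total = 0.0
    for x in range(max(0, k - (n - n1)), min(k, n1) + 1):
        p = stats.hypergeom.pmf(x, n, k, n1)
        if p <= obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


class TestLocusMatching:
    def test_identical_interval_same_type(self):
        call = CnvCall("S", "16", 29_640_000, 30_200_000, "dup")
        assert match_call_to_locus(call, LOCUS)

    def test_type_mismatch_never_matches(self):
        call = CnvCall("S", "16", 29_640_000, 30_200_000, "del")
        assert not match_call_to_locus(call, LOCUS)

    def test_half_coverage_rule_matches_brute_force(self, rng):
        locus = LocusDef("L", "1", 1_000, 2_000, "del")
        bp_locus = set(range(1_000, 2_001))
        for _ in range(300):
            s = int(rng.integers(1, 3_000))
            e = s + int(rng.integers(0, 2_500))
            call = CnvCall("S", "1", s, e, "del")
            expected = len(bp_locus & set(range(s, e + 1))) >= 0.5 * len(bp_locus)
            assert match_call_to_locus(call, locus, 0.5) == expected


class TestCarrierCounting:
    def make_roster(self, n_case, n_control):
        return (
            [SampleRecord(f"A{i}", "case") for i in range(n_case)]
            + [SampleRecord(f"B{i}", "control") for i in range(n_control)]
        )

    def test_published_style_counts(self):
        roster = self.make_roster(2591, 8842)
        calls = [CnvCall(f"A{i}", "16", 29_640_000, 30_200_000, "dup")
                 for i in range(3)]
        t = count_carriers(calls, roster, LOCUS)
        assert (t.a, t.b, t.c, t.d) == (3, 2588, 0, 8842)

    def test_no_calls(self):
        t = count_carriers([], self.make_roster(10, 20), LOCUS)
        assert (t.a, t.b, t.c, t.d) == (0, 10, 0, 20)

    def test_multiple_calls_count_one_carrier(self):
        roster = self.make_roster(5, 5)
        calls = [CnvCall("A0", "16", 29_640_000, 30_200_000, "dup"),
                 CnvCall("A0", "16", 29_700_000, 30_190_000, "dup")]
        assert count_carriers(calls, roster, LOCUS).a == 1

    def test_unknown_sample_rejected(self):
        calls = [CnvCall("ghost", "16", 29_640_000, 30_200_000, "dup")]
        with pytest.raises(ValueError, match="ghost"):
            count_carriers(calls, self.make_roster(2, 2), LOCUS)


class TestPooling:
    def test_identity(self):
        assert pool_counts([CohortCounts("bdrn", 3, 2591)]).carriers == 3

    def test_published_pool(self):
        parts = [CohortCounts("bdrn", 3, 2591), CohortCounts("meta", 9, 6538)]
        pooled = pool_counts(parts)
        assert (pooled.carriers, pooled.total) == (12, 9129)

    def test_order_invariant(self):
        parts = [CohortCounts("a", 1, 10), CohortCounts("b", 2, 20),
                 CohortCounts("c", 0, 5)]
        for perm in itertools.permutations(parts):
            assert pool_counts(list(perm)).total == 35

    def test_pool_then_test_equals_test_of_pooled_table(self):
        """Counts, not p-values, are combined across cohorts."""
        cases = [CohortCounts("a", 2, 100), CohortCounts("b", 3, 200)]
        controls = [CohortCounts("x", 1, 400), CohortCounts("y", 2, 300)]
        model = LocusAssociationModel.from_counts({"L": (cases, controls)})
        res = model.fit()["L"]
        direct = ContingencyTable(5, 295, 3, 697)
        assert res.p_value == fisher_exact_two_sided(direct)
        assert res.table == direct


class TestFisherExact:
    def test_zero_margin_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 10, 0, 20)) == 1.0

    def test_small_table_full_enumeration(self):
        t = ContingencyTable(2, 3, 1, 4)
        assert fisher_exact_two_sided(t) == pytest.approx(
            enumerate_fisher_p(2, 3, 1, 4), rel=1e-12)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 31, size=4))
            if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
                continue
            got = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            assert got == pytest.approx(enumerate_fisher_p(a, b, c, d), rel=1e-9)

    def test_transpose_symmetry(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 20, size=4))
            p1 = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            p2 = fisher_exact_two_sided(ContingencyTable(a, c, b, d))
            assert p1 == pytest.approx(p2, rel=1e-9)


class TestOddsRatio:
    def test_symmetric_table(self):
        assert odds_ratio(ContingencyTable(1, 1, 1, 1)) == 1.0

    def test_zero_cell_undefined(self):
        assert odds_ratio(ContingencyTable(0, 10, 5, 5)) is None
        assert woolf_ci(ContingencyTable(0, 10, 5, 5)) is None

    def test_row_swap_reciprocal(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 50, size=4))
            product = odds_ratio(ContingencyTable(a, b, c, d)) * \
                odds_ratio(ContingencyTable(c, d, a, b))
            assert product == pytest.approx(1.0, rel=1e-12)


class TestWoolfCI:
    def test_agrees_with_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 200, size=4))
            lo, hi = woolf_ci(ContingencyTable(a, b, c, d))
            ref_lo, ref_hi = sm.Table2x2(
                [[a, b], [c, d]]).oddsratio_confint(0.05)
            assert lo == pytest.approx(ref_lo, rel=1e-9)
            assert hi == pytest.approx(ref_hi, rel=1e-9)

    def test_symmetric_on_log_scale_at_null(self):
        lo, hi = woolf_ci(ContingencyTable(10, 30, 10, 30))
        assert math.log(lo) + math.log(hi) == pytest.approx(0.0, abs=1e-12)

    def test_ci_brackets_estimate(self, rng):
        for _ in range(50):
            t = ContingencyTable(*(int(x) for x in rng.integers(1, 100, size=4)))
            lo, hi = woolf_ci(t)
            assert lo <= odds_ratio(t) <= hi

    def test_empirical_coverage_near_nominal(self, rng):
        """95% CI covers the true OR ~95% of the time on large-count tables."""
        p1, true_or, n = 0.2, 2.0, 2000
        p2 = case_frequency_from_or(p1, true_or)
        reps, covered = 400, 0
        for _ in range(reps):
            a = rng.binomial(n, p2)
            c = rng.binomial(n, p1)
            lo, hi = woolf_ci(ContingencyTable(a, n - a, c, n - c))
            covered += lo <= true_or <= hi
        se = math.sqrt(0.95 * 0.05 / reps)
        assert abs(covered / reps - 0.95) < 2 * se + 1 / reps


class TestThresholdsAndPower:
    def test_recurrent_region_correction(self):
        assert genomewide_threshold(120, 0.05) == pytest.approx(0.05 / 120)
        assert genomewide_threshold(1, 0.05) == 0.05
        assert genomewide_threshold(20_000, 0.05) == pytest.approx(2.5e-6)
        with pytest.raises(ValueError):
            genomewide_threshold(0)

    def test_null_power_equals_alpha(self):
        p = power_two_proportion(0.01, 1.0, 2591, 8842, alpha=0.05)
        assert p == pytest.approx(0.05, abs=1e-9)

    def test_power_monotone_in_n_and_effect(self):
        grid_n = [power_two_proportion(0.01, 2.0, n, 4 * n) for n in
                  (500, 2000, 8000, 32000)]
        assert grid_n == sorted(grid_n)
        grid_or = [power_two_proportion(0.01, o, 2591, 8842) for o in
                   (1.2, 1.8, 2.6, 4.0)]
        assert grid_or == sorted(grid_or)
        assert power_two_proportion(0.01, 4.0, 10**6, 10**6) > 0.999

    def test_power_matches_fisher_rejection_rate(self, rng):
        """Analytic power tracks the Monte-Carlo Fisher rejection rate."""
        p1, orr, n_case, n_control, alpha = 0.05, 1.35, 2591, 8842, 0.05
        expected = power_two_proportion(p1, orr, n_case, n_control, alpha)
        p2 = case_frequency_from_or(p1, orr)
        reps, rejected = 300, 0
        for _ in range(reps):
            a = rng.binomial(n_case, p2)
            c = rng.binomial(n_control, p1)
            t = ContingencyTable(a, n_case - a, c, n_control - c)
            rejected += fisher_exact_two_sided(t) < alpha
        se = math.sqrt(expected * (1 - expected) / reps)
        assert abs(rejected / reps - expected) < 3 * se


class TestModelInterface:
    def test_fit_from_calls(self, sz_loci):
        roster = [SampleRecord(f"A{i}", "case") for i in range(100)] + \
                 [SampleRecord(f"B{i}", "control") for i in range(300)]
        calls = [CnvCall("A0", "16", 29_640_000, 30_200_000, "dup"),
                 CnvCall("B5", "16", 29_640_000, 30_200_000, "dup")]
        res = LocusAssociationModel(calls, roster, sz_loci).fit()
        r = res["16p11.2 dup"]
        assert (r.table.a, r.table.c) == (1, 1)
        assert "16p11.2 dup" in res.summary()
        assert len(res.to_frame()) == 15

    def test_association_flags_genomewide(self):
        t = ContingencyTable(12, 9117, 19, 63049)
        r = associate(t, "16p11.2 dup")
        assert r.significant_genomewide  # 2.3e-4 < 0.05/120
        r2 = associate(ContingencyTable(1, 9, 1, 9), "null locus")
        assert not r2.significant_genomewide
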
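"""Sample QC, rarity filtering, size strata and intensity validation."""

import numpy as np
import pytest

from rarecnv.cnv_data import CnvCall, SampleRecord
from rarecnv.qc_filtering import (
    LrrMatrix,
    QcConfig,
    exclude_outlier_samples,
    filter_by_frequency,
    filter_by_size,
    median_zscore_validate,
    reciprocal_overlap,
)
from rarecnv.synthetic_data import SimConfig, simulate_cohort, simulate_lrr


def roster_with_metric(values, cohort="c1"):
    return [
        SampleRecord(f"S{i}", "control", cohort,
                     qc_metrics={"lrr_sd": v, "wave_factor": 0.0})
        for i, v in enumerate(values)
    ]


class TestOutlierExclusion:
    def test_identical_metrics_exclude_nobody(self):
        kept, excluded = exclude_outlier_samples(roster_with_metric([0.1] * 10))
        assert len(kept) == 10 and excluded == []

    def test_zero_iqr_flags_any_deviation(self):
        kept, excluded = exclude_outlier_samples(
            roster_with_metric([0.1] * 9 + [0.100001]))
        assert len(excluded) == 1
        assert excluded[0][0].sample_id == "S9"

    def test_extreme_metric_excluded_with_named_reason(self):
        values = [0.1, 0.11, 0.09, 0.1, 0.12, 0.08, 0.1, 0.11, 1.0]
        kept, excluded = exclude_outlier_samples(roster_with_metric(values), k=3)
        (sample, reasons), = excluded
        assert sample.sample_id == "S8" and reasons == ["lrr_sd"]

    def test_exclusion_is_per_cohort(self):
        # the same value is an outlier in one cohort but typical in the other
        a = roster_with_metric([0.1] * 9 + [0.5], cohort="a")
        b = roster_with_metric([0.45, 0.5, 0.55, 0.48, 0.52, 0.5, 0.47, 0.53],
                               cohort="b")
        kept, excluded = exclude_outlier_samples(a + b)
        assert [s.sample_id for s, _ in excluded] == ["S9"]
        assert all(s.cohort == "a" for s, _ in excluded)

    def test_small_cohort_refused(self):
        with pytest.raises(ValueError, match="cohort"):
            exclude_outlier_samples(roster_with_metric([0.1] * 5))

    def test_planted_outliers_recovered_exactly(self):
        cfg = SimConfig(n_cases=80, n_controls=120, background_rate=1.0,
                        n_outliers=4, seed=5)
        cohort = simulate_cohort(cfg)
        _, excluded = exclude_outlier_samples(cohort.roster, k=3.0)
        flagged_for_lrr = {s.sample_id for s, reasons in excluded
                          if "lrr_sd" in reasons}
        assert flagged_for_lrr == cohort.truth.outlier_samples


class TestFrequencyFilter:
    def make_roster(self, n):
        return [SampleRecord(f"S{i}", "control") for i in range(n)]

    def test_common_identical_event_removed(self):
        roster = self.make_roster(100)
        calls = [CnvCall(f"S{i}", "1", 1000, 50_000, "del") for i in range(5)]
        assert filter_by_frequency(calls, roster, threshold=0.01) == []

    def test_singleton_kept(self):
        roster = self.make_roster(10_000)
        calls = [CnvCall("S0", "1", 1000, 50_000, "del")]
        assert filter_by_frequency(calls, roster, threshold=0.01) == calls

    def test_type_specific_grouping(self):
        # same interval, opposite types: each is a singleton
        roster = self.make_roster(100)
        calls = [CnvCall("S0", "1", 1000, 50_000, "del"),
                 CnvCall("S1", "1", 1000, 50_000, "dup")]
        assert filter_by_frequency(calls, roster, threshold=0.02) == calls

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            filter_by_frequency([], [], threshold=0.01)

    @staticmethod
    def brute_force_kept(calls, roster, threshold, frac):
        kept = []
        for c in calls:
            carriers = {c.sample_id}
            for other in calls:
                if reciprocal_overlap(c, other) >= frac and other.cnv_type == c.cnv_type:
                    carriers.add(other.sample_id)
            if len(carriers) / len(roster) < threshold:
                kept.append(c)
        return kept

    def test_matches_all_pairs_oracle(self, rng):
        """Interval-tree grouping equals O(n^2) reciprocal-overlap counting."""
        roster = self.make_roster(60)
        for _ in range(10):
            calls = []
            for _ in range(150):
                s = int(rng.integers(1, 200_000))
                length = int(rng.integers(1_000, 80_000))
                calls.append(CnvCall(
                    f"S{rng.integers(60)}", str(rng.integers(1, 3)),
                    s, s + length, "del" if rng.random() < 0.5 else "dup"))
            fast = filter_by_frequency(calls, roster, 0.05, 0.5)
            slow = self.brute_force_kept(calls, roster, 0.05, 0.5)
            assert fast == slow

    def test_idempotent(self, small_cohort):
        once = filter_by_frequency(small_cohort.calls, small_cohort.roster)
        twice = filter_by_frequency(once, small_cohort.roster)
        assert once == twice


class TestSizeFilter:
    def test_boundaries_strict_lower_inclusive_upper(self):
        at_min = CnvCall("S", "1", 1, 500_000, "del")       # length exactly 500 kb
        inside = CnvCall("S", "1", 1, 600_000, "del")
        at_max = CnvCall("S", "1", 1, 1_000_000, "del")
        above = CnvCall("S", "1", 1, 1_000_001, "del")
        kept = filter_by_size([at_min, inside, at_max, above], 500_000, 1_000_000)
        assert kept == [inside, at_max]

    def test_strata_partition_large_calls(self, rng):
        calls = [CnvCall("S", "1", 1, int(l), "del")
                 for l in rng.integers(400_000, 3_000_000, size=300)]
        large = filter_by_size(calls, 500_000)
        mid = filter_by_size(calls, 500_000, 1_000_000)
        top = filter_by_size(calls, 1_000_000)
        assert sorted(mid + top, key=id) == sorted(large, key=id)
        assert not set(map(id, mid)) & set(map(id, top))

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_by_size([], 1000, 1000)


class TestMedianZscore:
    def constant_matrix(self, n_samples=10, n_probes=5):
        return LrrMatrix(
            chroms=["1"] * n_probes,
            positions=np.arange(1, n_probes + 1) * 1000,
            sample_ids=[f"S{i}" for i in range(n_samples)],
            values=np.zeros((n_probes, n_samples)),
        )

    def test_constant_matrix_rejected(self):
        call = CnvCall("S0", "1", 1, 10_000, "del")
        res = median_zscore_validate(call, self.constant_matrix(), threshold=2)
        assert not res.validated and res.z == 0.0

    def test_no_probe_support(self):
        call = CnvCall("S0", "2", 1, 10_000, "del")
        res = median_zscore_validate(call, self.constant_matrix())
        assert not res.validated and res.reason == "no probe support"

    def test_too_few_samples_rejected(self):
        call = CnvCall("S0", "1", 1, 10_000, "del")
        with pytest.raises(ValueError):
            median_zscore_validate(call, self.constant_matrix(n_samples=5))

    def planted_matrix(self, shift, noise=0.05, seed=3):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, noise, size=(8, 20))
        values[:, 0] += shift
        return LrrMatrix(["1"] * 8, np.arange(1, 9) * 1000,
                         [f"S{i}" for i in range(20)], values)

    def test_planted_deletion_validates(self):
        call = CnvCall("S0", "1", 1, 10_000, "del")
        res = median_zscore_validate(call, self.planted_matrix(-0.5), threshold=2)
        assert res.validated and res.z < -2

    def test_wrong_sign_rejected(self):
        # a duplication whose carrier shows a deletion-like intensity drop
        call = CnvCall("S0", "1", 1, 10_000, "dup")
        res = median_zscore_validate(call, self.planted_matrix(-0.5), threshold=2)
        assert not res.validated

    def test_invariant_under_global_offset(self):
        call = CnvCall("S0", "1", 1, 10_000, "del")
        m = self.planted_matrix(-0.5)
        shifted = LrrMatrix(m.chroms, m.positions, m.sample_ids, m.values + 1.7)
        z0 = median_zscore_validate(call, m).z
        z1 = median_zscore_validate(call, shifted).z
        assert z1 == pytest.approx(z0, abs=1e-10)

    def test_simulated_lrr_carrier_detected_null_not(self):
        cfg = SimConfig(n_cases=10, n_controls=10, lrr_noise_sd=0.05,
                        del_shift=-0.45, seed=9)
        sample_ids = [f"S{i}" for i in range(20)]
        lrr = simulate_lrr(("1", 100_000, 300_000), sample_ids, {"S3": "del"}, cfg)
        carrier = CnvCall("S3", "1", 100_000, 300_000, "del")
        bystander = CnvCall("S7", "1", 100_000, 300_000, "del")
        assert median_zscore_validate(carrier, lrr, 2).validated
        assert not median_zscore_validate(bystander, lrr, 2).validated


class TestQcConfig:
    def test_defaults_valid(self):
        cfg = QcConfig()
        assert cfg.freq_threshold == 0.01 and cfg.autosomes_only

    @pytest.mark.parametrize("kw", [
        {"freq_threshold": 0.0}, {"freq_threshold": 1.5},
        {"overlap_fraction": 0.0}, {"outlier_k": -1}, {"min_probes": -2},
    ])
    def test_bad_thresholds_rejected(self, kw):
        with pytest.raises(ValueError):
            QcConfig(**kw)
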
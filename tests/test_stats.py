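import numpy as np
import pytest
import scipy.stats

from methylcnv import (
    CNVSpec, ValidationError, bonferroni, call_state, merge_significant_bins,
    region_length, students_t,
)
from methylcnv.stats import BinTestResult, Region
from methylcnv.binning import Bin, BinSet

from conftest import run_replicate


class TestStudentsT:
    def test_frozen_small_example(self):
        # pooled t by hand: means 2 vs 5, pooled var 1, se = sqrt(2/3)
        t, df, p, _ = students_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert df == 4
        assert p == pytest.approx(0.0213, abs=2e-4)

    def test_identical_groups_are_null(self):
        assert students_t([1, 2, 3], [1, 2, 3])[:1] == (0.0,)
        assert students_t([1, 2, 3], [1, 2, 3]).p == 1.0

    def test_degenerate_zero_variance(self):
        t_eq = students_t([5, 5], [5, 5])
        assert (t_eq.t, t_eq.p, t_eq.degenerate) == (0.0, 1.0, False)
        t_ne = students_t([5, 5], [7, 7])
        assert t_ne.p == 0.0 and t_ne.degenerate
        assert np.isinf(t_ne.t) and t_ne.t < 0

    def test_group_size_validated(self):
        with pytest.raises(ValidationError):
            students_t([1], [2, 3])

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n_a, n_b = rng.integers(2, 12, size=2)
            x_a = rng.normal(0, 1 + rng.random(), n_a)
            x_b = rng.normal(rng.normal(), 1 + rng.random(), n_b)
            ours = students_t(x_a, x_b)
            ref = scipy.stats.ttest_ind(x_a, x_b, equal_var=True)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert ours.df == n_a + n_b - 2

    def test_label_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(3)
        x_a, x_b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 8)
        fwd, rev = students_t(x_a, x_b), students_t(x_b, x_a)
        assert fwd.t == pytest.approx(-rev.t, abs=1e-12)
        assert fwd.p == pytest.approx(rev.p, abs=1e-12)


class TestBonferroni:
    def test_basic_scaling_and_cap(self):
        assert bonferroni(0.01, 2) == pytest.approx(0.02)
        assert bonferroni(0.5, 3) == 1.0

    def test_published_family_size_round_trip(self):
        # the family of 16,272 bins maps the implied raw p back to 0.045
        raw = 0.045 / 16_272
        assert round(bonferroni(raw, 16_272), 3) == 0.045

    def test_monotonic_in_p_and_family_size(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.random(100))
        adj = bonferroni(p, 50)
        assert (np.diff(adj) >= 0).all()
        for raw in rng.random(20):
            prev = 0.0
            for B in (1, 2, 10, 100, 10_000):
                cur = bonferroni(float(raw), B)
                assert cur >= prev
                prev = cur

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            bonferroni(1.5, 10)
        with pytest.raises(ValidationError):
            bonferroni(0.5, 0)


def _result(chrom, start, end, index, delta, p_adj, significant=True):
    b = Bin(chrom=chrom, start=start, end=end,
            probe_indices=np.arange(15))
    return BinTestResult(bin=b, binset_index=index, mean_a=delta, mean_b=0.0,
                         delta=delta, t=0.0, df=10, p_raw=p_adj / 100,
                         p_adj=p_adj, significant=significant)


def _binset(results):
    import pandas as pd
    return BinSet(bins=[r.bin for r in results],
                  probe_ids=pd.Index([], name="probe_id"))


class TestMergeAndCalls:
    def test_adjacent_same_sign_bins_merge(self):
        results = [
            _result("chr8", 100_000_001, 100_100_000, 0, -0.15, 0.045),
            _result("chr8", 100_100_001, 100_750_000, 1, -0.18, 0.050),
        ]
        regions = merge_significant_bins(results, _binset(results))
        assert len(regions) == 1
        r = regions[0]
        assert (r.chrom, r.start, r.end) == ("chr8", 100_000_001, 100_750_000)
        assert r.length == 750_000
        assert r.adj_p == pytest.approx(0.045)  # min over members
        assert r.log2_ratio == pytest.approx(-0.165)  # mean of deltas
        assert r.bin_indices == (0, 1)

    def test_sign_change_splits_runs(self):
        results = [
            _result("chr1", 1, 50_000, 0, -0.3, 0.01),
            _result("chr1", 50_001, 100_000, 1, +0.3, 0.01),
        ]
        assert len(merge_significant_bins(results, _binset(results))) == 2

    def test_intervening_bin_splits_runs(self):
        results = [
            _result("chr1", 1, 50_000, 0, -0.3, 0.01),
            _result("chr1", 100_001, 150_000, 2, -0.3, 0.01),  # index gap
        ]
        assert len(merge_significant_bins(results, _binset(results))) == 2

    def test_chromosome_change_splits_runs(self):
        results = [
            _result("chr1", 1, 50_000, 0, -0.3, 0.01),
            _result("chr2", 1, 50_000, 1, -0.3, 0.01),
        ]
        assert len(merge_significant_bins(results, _binset(results))) == 2

    def test_isolated_bin_single_region_and_empty_case(self):
        results = [_result("chr1", 1, 50_000, 0, 0.5, 0.01)]
        regions = merge_significant_bins(results, _binset(results))
        assert len(regions) == 1 and regions[0].state == "gain"
        none = [_result("chr1", 1, 50_000, 0, 0.5, 0.9, significant=False)]
        assert merge_significant_bins(none, _binset(none)) == []

    def test_call_state_threshold(self):
        assert call_state(0.25) == "gain"
        assert call_state(-0.25) == "loss"
        assert call_state(0.177) == "neutral"  # below the 0.2 threshold
        assert call_state(-0.165) == "neutral"
        assert call_state(0.3, theta=0.5) == "neutral"
        with pytest.raises(ValidationError):
            call_state(0.1, theta=0.0)

    def test_region_length_conventions(self):
        assert region_length("chr8:100000001-100750000") == 750_000
        assert region_length("chr15:79250001-79350000") == 100_000
        assert region_length(("chr1", 5, 5)) == 1
        reg = Region("chr1", 11, 20, (0,), 0.01, 0.5)
        assert region_length(reg) == 10


class TestCompareGroups:
    def test_null_cohort_typically_clean(self):
        *_, results = run_replicate(101)
        assert sum(r.significant for r in results) == 0

    def test_implanted_shift_detected_with_correct_delta(self):
        spec = CNVSpec("chr1", 2_000_001, 2_200_000, 1, 1.0, "case")
        *_, results = run_replicate(102, noise_sd=0.1, cnvs=(spec,))
        inside = [r for r in results
                  if r.bin.start >= spec.start and r.bin.end <= spec.end]
        assert inside and all(r.significant for r in inside)
        for r in inside:
            assert r.delta == pytest.approx(-1.0, abs=0.1)

    def test_permuted_labels_lose_the_signal(self):
        spec = CNVSpec("chr1", 2_000_001, 2_200_000, 1, 1.0, "case")
        man, cohort, ratios, bins, values, _ = run_replicate(
            103, noise_sd=0.1, cnvs=(spec,))
        from methylcnv import compare_groups
        # alternate labels across the true groups: effect splits evenly
        samples = list(values.values.columns)
        permuted = {s: ("case" if i % 2 == 0 else "ref")
                    for i, s in enumerate(samples)}
        results = compare_groups(values, permuted, order=("case", "ref"))
        inside = [r for r in results
                  if r.bin.start >= spec.start and r.bin.end <= spec.end]
        assert not any(r.significant for r in inside)

    def test_symmetry_under_group_order(self):
        man, cohort, ratios, bins, values, fwd = run_replicate(104)
        from methylcnv import compare_groups
        rev = compare_groups(values, cohort.groups, order=("ref", "case"))
        for a, b in zip(fwd, rev):
            assert a.delta == pytest.approx(-b.delta, abs=1e-12)
            assert a.p_raw == pytest.approx(b.p_raw, abs=1e-12)
            assert a.p_adj == pytest.approx(b.p_adj, abs=1e-12)

    def test_more_than_two_groups_rejected(self):
        from methylcnv import (CohortDesign, aggregate_bins, build_bins,
                               compare_groups, generate_manifest,
                               probe_log2_ratios, simulate_cohort)
        man = generate_manifest(1, 2_000_000, 1e-3, seed=105)
        design = CohortDesign(groups={"a": 3, "b": 3, "c": 2},
                              control_count=10, seed=105)
        cohort = simulate_cohort(man, design)
        ratios = probe_log2_ratios(cohort.intensities)
        values = aggregate_bins(ratios, build_bins(man, mask=ratios.mask))
        with pytest.raises(ValidationError, match="exactly two groups"):
            compare_groups(values, cohort.groups)
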
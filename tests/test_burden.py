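import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from cnvburden import (
    CnvCall,
    SampleRecord,
    SizeBins,
    bin_by_size,
    burden_table,
    find_singletons,
    odds_ratio,
    or_confidence_interval,
    stratified_burden,
    two_proportion_test,
)
from cnvburden.intervals import reciprocal_overlap


def call(sid, length, cnv_type="DEL", chrom=1, start=1_000_000):
    cn = 1 if cnv_type == "DEL" else 3
    return CnvCall(sid, chrom, start, start + length, cnv_type, cn, 10)


def person(sid, phenotype, country="NO"):
    return SampleRecord(sid, phenotype, country, "M", 0.1, 0.001, 0.0)


class TestBins:
    @pytest.mark.parametrize(
        "length, label",
        [
            (50_001, "50-100kb"),
            (100_000, "50-100kb"),
            (100_001, "100-200kb"),
            (1_000_000, "500-1000kb"),
            (1_000_001, ">1000kb"),
        ],
    )
    def test_boundary_convention_lo_exclusive_hi_inclusive(self, length, label):
        assert SizeBins().assign(length) == label

    def test_undersized_call_is_qc_violation(self):
        with pytest.raises(ValueError, match="QC violation"):
            SizeBins().assign(50_000)

    def test_partition_property(self, rng):
        calls = [call(f"S{i}", int(rng.integers(50_001, 3_000_000)))
                 for i in range(200)]
        binned = bin_by_size(calls)
        assert sum(len(v) for v in binned.values()) == len(calls)

    def test_edges_must_increase(self):
        with pytest.raises(ValueError):
            SizeBins(edges=[100, 100])


class TestOddsRatio:
    def test_headline_cell(self):
        assert odds_ratio(13, 1182, 10, 3810) == pytest.approx(4.2258, abs=1e-4)

    def test_overall_del_row(self):
        assert odds_ratio(827, 1182, 2615, 3810) == pytest.approx(1.0646, abs=1e-4)

    def test_equal_proportions_give_unity(self):
        assert odds_ratio(10, 100, 30, 300) == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        for _ in range(200):
            n1, n2 = int(rng.integers(2, 500)), int(rng.integers(2, 500))
            a, b = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            assert odds_ratio(a, n1, b, n2) * odds_ratio(b, n2, a, n1) == pytest.approx(1.0)

    def test_zero_cells_flagged_not_raised(self):
        assert odds_ratio(5, 10, 0, 10) == math.inf
        assert or_confidence_interval(5, 10, 0, 10) == (pytest.approx(math.nan, nan_ok=True),) * 2


class TestConfidenceInterval:
    def test_headline_interval(self):
        lo, hi = or_confidence_interval(13, 1182, 10, 3810)
        assert (round(lo, 2), round(hi, 2)) == (1.85, 9.66)

    def test_overall_del_interval(self):
        lo, hi = or_confidence_interval(827, 1182, 2615, 3810)
        assert (round(lo, 2), round(hi, 2)) == (0.92, 1.23)

    def test_symmetric_on_log_scale_under_null(self):
        lo, hi = or_confidence_interval(10, 100, 10, 100)
        assert math.log(lo) == pytest.approx(-math.log(hi))


class TestTwoProportionTest:
    def test_headline_p(self):
        p = two_proportion_test(13, 1182, 10, 3810)
        assert p == pytest.approx(2.04e-4, rel=0.01)

    def test_equal_proportions_p_one(self):
        assert two_proportion_test(10, 100, 30, 300) == pytest.approx(1.0)

    def test_chi_square_identity(self, rng):
        """Without continuity the test equals Pearson chi-square on the 2x2
        table; with continuity it equals the Yates-corrected chi-square."""
        for _ in range(300):
            n1, n2 = int(rng.integers(10, 500)), int(rng.integers(10, 500))
            a, b = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            table = [[a, n1 - a], [b, n2 - b]]
            for continuity in (False, True):
                expected = chi2_contingency(table, correction=continuity).pvalue
                got = two_proportion_test(a, n1, b, n2, continuity=continuity)
                assert got == pytest.approx(expected, rel=1e-6, abs=1e-12)


class TestBurdenTable:
    def make_cohort(self):
        cases = [person(f"C{i}", "case") for i in range(20)]
        controls = [person(f"K{i}", "control") for i in range(40)]
        calls = [call(f"C{i}", 60_000) for i in range(6)]
        calls += [call(f"K{i}", 60_000) for i in range(4)]
        calls += [call("C0", 1_500_000, start=10_000_000)]
        return cases, controls, calls

    def test_counts_and_frequencies(self):
        cases, controls, calls = self.make_cohort()
        rows = burden_table(cases, controls, calls)
        by_key = {(r.cnv_type, r.bin_label): r for r in rows}
        r = by_key[("DEL", "50-100kb")]
        assert (r.case_count, r.control_count) == (6, 4)
        assert r.case_freq == pytest.approx(6 / 20)
        big = by_key[("DEL", ">1000kb")]
        assert big.case_count == 1

    def test_overall_rows_sum_their_bins(self):
        cases, controls, calls = self.make_cohort()
        rows = burden_table(cases, controls, calls)
        for cnv_type in ("DEL", "DUP"):
            bins = [r for r in rows if r.cnv_type == cnv_type and r.bin_label != "all"]
            (overall,) = [r for r in rows if r.cnv_type == cnv_type and r.bin_label == "all"]
            assert overall.case_count == sum(r.case_count for r in bins)
            assert overall.control_count == sum(r.control_count for r in bins)
            assert overall.bonferroni_significant is None

    def test_empty_call_set_no_crash(self):
        rows = burden_table([person("C0", "case")], [person("K0", "control")], [])
        assert all(r.case_count == 0 for r in rows)
        assert all(math.isnan(r.odds_ratio) for r in rows)

    def test_bonferroni_threshold(self):
        cases = [person(f"C{i}", "case") for i in range(1182)]
        controls = [person(f"K{i}", "control") for i in range(3810)]
        calls = [call(f"C{i}", 1_500_000, start=1_000_000 + 2_000_000 * i)
                 for i in range(13)]
        calls += [call(f"K{i}", 1_500_000, start=1_000_000 + 2_000_000 * i)
                  for i in range(10)]
        rows = burden_table(cases, controls, calls)
        (big,) = [r for r in rows if r.bin_label == ">1000kb" and r.cnv_type == "DEL"]
        assert big.p_value < 0.005 and big.bonferroni_significant


class TestSingletons:
    def test_shared_call_not_singleton(self):
        a = call("S1", 60_000)
        b = call("S2", 60_000)
        assert find_singletons([a, b]) == []

    def test_unique_call_is_singleton(self):
        a = call("S1", 60_000)
        b = call("S2", 60_000, start=5_000_000)
        assert set(c.sample_id for c in find_singletons([a, b])) == {"S1", "S2"}

    def test_same_sample_repeat_still_singleton(self):
        a = call("S1", 60_000)
        b = call("S1", 60_000, start=1_010_000)
        assert len(find_singletons([a, b])) == 2

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(200):
            calls = []
            for i in range(int(rng.integers(2, 20))):
                start = int(rng.integers(0, 80_000))
                calls.append(call(f"S{int(rng.integers(0, 8))}",
                                  int(rng.integers(1_000, 40_000)),
                                  cnv_type=str(rng.choice(["DEL", "DUP"])),
                                  start=start))
            got = {id(c) for c in find_singletons(calls)}
            expected = set()
            for a in calls:
                if not any(
                    b.sample_id != a.sample_id and b.cnv_type == a.cnv_type
                    and b.chrom == a.chrom
                    and reciprocal_overlap(a.interval(), b.interval()) >= 0.5
                    for b in calls
                ):
                    expected.add(id(a))
            assert got == expected


class TestStratified:
    def test_counts_sum_to_pooled(self):
        cases = [person(f"C{i}", "case", "NO" if i % 2 else "SE") for i in range(20)]
        controls = [person(f"K{i}", "control", "NO" if i % 2 else "SE") for i in range(40)]
        calls = [call(f"C{i}", 60_000) for i in range(8)]
        calls += [call(f"K{i}", 60_000) for i in range(12)]
        pooled = burden_table(cases, controls, calls)
        strata = stratified_burden(cases, controls, calls)
        assert set(strata) == {"NO", "SE"}
        for i, row in enumerate(pooled):
            assert row.case_count == sum(t[i].case_count for t in strata.values())
            assert row.control_count == sum(t[i].control_count for t in strata.values())

    def test_single_country_identical_to_pooled(self):
        cases = [person(f"C{i}", "case", "NO") for i in range(10)]
        controls = [person(f"K{i}", "control", "NO") for i in range(10)]
        calls = [call("C0", 60_000)]
        pooled = burden_table(cases, controls, calls)
        strata = stratified_burden(cases, controls, calls)
        assert strata["NO"] == pooled

    def test_empty_stratum_suppressed_with_warning(self):
        cases = [person("C0", "case", "NO")]
        controls = [person("K0", "control", "SE")]
        with pytest.warns(UserWarning, match="lacks"):
            strata = stratified_burden(cases, controls, [])
        assert strata == {}
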
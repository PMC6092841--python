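"""Accounting contracts: dedup, on-target partition, down-sampling, metrics, stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ycapture import synthio
from ycapture.accounting import (
    DuplicateHistogram,
    binomial_ci,
    classify_on_target,
    deduplicate,
    downsample,
    library_metrics,
    min_retained_reads,
    paired_length_test,
    round_half_up,
    summarize_replicates,
)
from ycapture.synthio import TargetRegions

from conftest import make_read


def reads_from_classes(multiplicities):
    """Build reads where class i appears multiplicities[i] times."""
    reads = []
    k = 0
    for i, m in enumerate(multiplicities):
        for _ in range(m):
            reads.append(make_read(start=100 * i, end=100 * i + 50, read_id=f"r{k:04d}"))
            k += 1
    return reads


class TestDeduplicate:
    def test_all_identical(self):
        unique, hist = deduplicate(reads_from_classes([5]))
        assert len(unique) == 1
        assert hist.counts == {5: 1}
        assert unique[0].read_id == "r0000"  # smallest read_id retained

    def test_all_distinct(self):
        unique, hist = deduplicate(reads_from_classes([1] * 7))
        assert len(unique) == 7
        assert hist.counts == {1: 7}

    def test_mixed_classes(self):
        unique, hist = deduplicate(reads_from_classes([2, 3, 1]))
        assert len(unique) == 3
        assert hist.counts == {1: 1, 2: 1, 3: 1}

    def test_strand_distinguishes(self):
        reads = [make_read(strand="+", read_id="a"), make_read(strand="-", read_id="b")]
        unique, _ = deduplicate(reads)
        assert len(unique) == 2

    @given(st.lists(st.integers(1, 5), min_size=0, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_conservation_and_idempotence(self, multiplicities):
        reads = reads_from_classes(multiplicities)
        unique, hist = deduplicate(reads)
        assert hist.total_reads == len(reads)
        assert hist.distinct == len(unique) == len(multiplicities)
        again, hist2 = deduplicate(unique)
        assert again == unique
        assert hist2.counts == ({1: len(unique)} if unique else {})


class TestClassifyOnTarget:
    def test_one_bp_overlap(self):
        regions = TargetRegions("chrY", [(140, 200)])
        part = classify_on_target([make_read(start=100, end=150)], regions)
        assert len(part.on_target) == 1

    def test_half_open_no_overlap(self):
        regions = TargetRegions("chrY", [(150, 200)])
        part = classify_on_target([make_read(start=100, end=150)], regions)
        assert len(part.off_target_same_reference) == 1

    def test_other_reference(self):
        regions = TargetRegions("chrY", [(0, 1000)])
        part = classify_on_target([make_read(ref="chrX", start=10, end=60)], regions)
        assert len(part.other) == 1

    def test_matches_quadratic_scan(self, small_regions):
        rng = np.random.default_rng(42)
        reads = []
        for i in range(1000):
            ref = ["chrY", "chrX"][int(rng.integers(2))]
            start = int(rng.integers(0, 9_900))
            reads.append(make_read(ref=ref, start=start, end=start + 60, read_id=f"r{i}"))
        part = classify_on_target(reads, small_regions)
        # independent oracle: per-read scan over every interval
        on = off = other = 0
        for r in reads:
            if r.reference != small_regions.reference:
                other += 1
            elif any(s < r.end and r.start < e for s, e in small_regions.intervals):
                on += 1
            else:
                off += 1
        assert (len(part.on_target), len(part.off_target_same_reference), len(part.other)) == (
            on, off, other,
        )
        # partition is exhaustive and disjoint
        assert on + off + other == len(reads)

    def test_order_invariance(self, small_regions):
        reads = [make_read(start=s, end=s + 60, read_id=f"r{s}") for s in range(900, 1200, 17)]
        a = classify_on_target(reads, small_regions)
        b = classify_on_target(list(reversed(reads)), small_regions)
        assert {r.read_id for r in a.on_target} == {r.read_id for r in b.on_target}


class TestMinRetainedAndDownsample:
    def test_min_retained(self):
        assert min_retained_reads({"pre": 68_795, "YCC": 1_000_000}) == 68_795
        assert min_retained_reads({"only": 42}) == 42
        assert min_retained_reads({"a": 5, "b": 5}) == 5

    def test_downsample_full_size(self):
        reads = reads_from_classes([1] * 10)
        for rep in downsample(reads, 10, n_replicates=3, base_seed=0):
            assert sorted(r.read_id for r in rep) == sorted(r.read_id for r in reads)

    def test_downsample_zero(self):
        reads = reads_from_classes([1] * 5)
        assert all(rep == [] for rep in downsample(reads, 0, 3, 0))

    def test_downsample_too_large(self):
        with pytest.raises(ValueError):
            downsample(reads_from_classes([1] * 3), 4, 2, 0)

    def test_replicates_reproducible(self):
        reads = reads_from_classes([1] * 100)
        a = downsample(reads, 30, 5, base_seed=7)
        b = downsample(reads, 30, 5, base_seed=7)
        assert [[r.read_id for r in rep] for rep in a] == [[r.read_id for r in rep] for rep in b]
        assert any(a[0] != rep for rep in a[1:])  # replicates differ from each other

    def test_composition_within_hypergeometric_bounds(self):
        # endogenous proportion across replicates brackets the parent proportion
        n_endo, n_exo, n = 300, 700, 200
        reads = [make_read(ref="chrY", start=10 * i, read_id=f"e{i:04d}") for i in range(n_endo)]
        reads += [
            make_read(ref=synthio.EXOGENOUS_REF, start=10 * i, read_id=f"x{i:04d}")
            for i in range(n_exo)
        ]
        lo, hi = stats.hypergeom.ppf([0.005, 0.995], n_endo + n_exo, n_endo, n)
        for rep in downsample(reads, n, n_replicates=10, base_seed=1):
            k = sum(1 for r in rep if r.reference == "chrY")
            assert lo <= k <= hi


class TestLibraryMetrics:
    def test_printed_percentages(self):
        """Published-count reproduction: 16,191 on-target / 16,430 chrY / 68,795 total."""
        regions = TargetRegions("chrY", [(0, 2_000_000)])
        reads = [
            make_read(start=100 + 2 * i, end=160 + 2 * i, read_id=f"on{i:05d}")
            for i in range(16_191)
        ]
        reads += [
            make_read(start=3_000_000 + 2 * i, end=3_000_060 + 2 * i, read_id=f"of{i:05d}")
            for i in range(16_430 - 16_191)
        ]
        m = library_metrics(
            reads, TargetRegions("chrY", [(0, 2_000_000)]), total_reads=68_795
        )
        assert m.chry_unique == 16_430
        assert m.on_target_unique == 16_191
        assert m.display()["pct_sequenced_on_target"] == "23.54%"
        assert m.display()["pct_chry_on_target"] == "99%"

    def test_second_sample_percentage(self):
        # 1,910 of 30,629 sequenced reads on-target -> 6.24%
        assert round_half_up(100 * 1909.8 / 30_629, 2) == 6.24

    def test_zero_denominator_missing(self):
        regions = TargetRegions("chrY", [(0, 100)])
        reads = [make_read(ref="chrX", start=10, read_id="a")]
        m = library_metrics(reads, regions)
        assert m.chry_unique == 0
        assert m.pct_chry_on_target is None
        assert m.display()["pct_chry_on_target"] == "-"

    def test_zero_clonality(self):
        regions = TargetRegions("chrY", [(0, 100_000)])
        reads = [make_read(start=100 * i, read_id=f"r{i}") for i in range(100)]
        m = library_metrics(reads, regions)
        assert m.mapped_reads == 100 and m.unique_mapped == 100
        assert m.clonality_pct == 0.0

    def test_partition_identity(self, small_regions):
        rng = np.random.default_rng(0)
        reads = [
            make_read(start=int(rng.integers(0, 9_900)), read_id=f"r{i}") for i in range(500)
        ]
        m = library_metrics(reads, small_regions)
        assert m.on_target_unique + m.off_target_chry_unique == m.chry_unique
        assert m.unique_mapped <= m.mapped_reads <= m.total_reads

    def test_summary_ci_brackets_mean(self, small_regions):
        rng = np.random.default_rng(3)
        reads = [
            make_read(
                ref=["chrY", synthio.EXOGENOUS_REF][int(rng.integers(2))],
                start=int(rng.integers(0, 9_900)),
                read_id=f"r{i:04d}",
            )
            for i in range(400)
        ]
        reps = downsample(reads, 200, 10, base_seed=0)
        summary = summarize_replicates([library_metrics(r, small_regions) for r in reps])
        assert summary.n_replicates == 10
        for name, bounds in summary.ci.items():
            if bounds is None:
                assert summary.mean[name] is None
                continue
            lo, hi = bounds
            assert lo <= summary.mean[name] <= hi


class TestBinomialCI:
    def test_extremes(self):
        assert binomial_ci(0, 20)[0] == 0.0
        assert binomial_ci(20, 20)[1] == 1.0

    def test_wilson_closed_form(self):
        # independent Wilson computation
        n, k, z = 10, 5, stats.norm.ppf(0.975)
        p = k / n
        center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        lo, hi = binomial_ci(5, 10, 0.95)
        assert lo == pytest.approx(center - half, abs=1e-6)
        assert hi == pytest.approx(center + half, abs=1e-6)

    def test_contains_point_estimate(self):
        for k, n in [(1, 10), (3, 7), (99, 100)]:
            lo, hi = binomial_ci(k, n)
            assert lo <= k / n <= hi


class TestPairedLengthTest:
    def test_identical_lists(self):
        res = paired_length_test([90.0, 92.0, 95.0], [90.0, 92.0, 95.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0 and res.degenerate

    def test_constant_shift_degenerate(self):
        res = paired_length_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and math.isinf(res.statistic) and res.statistic > 0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        a = rng.normal(100, 5, 8)
        b = a - rng.normal(3, 1, 8)
        res = paired_length_test(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert res.statistic == pytest.approx(t)
        assert res.pvalue == pytest.approx(p)
        assert not res.degenerate
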
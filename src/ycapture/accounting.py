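"""Per-library read accounting: deduplication, on-target classification,
down-sampling replicates, and the derived percentage metrics.

Mirrors the bookkeeping of a capture-enrichment evaluation: reads are
PCR duplicates iff they share (reference, start, end, strand); a read is
on-target iff it overlaps a target interval by at least one base; libraries
are compared at matched effort by down-sampling each condition to the
per-individual minimum read count, ten replicates by default; proportions
carry Wilson binomial confidence intervals. Zero-denominator ratios are
reported as missing (``None``), matching the dashes of a results table.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .synthio import EXOGENOUS_REF, ReadRecord, TargetRegions

DEFAULT_N_REPLICATES = 10


# ---------------------------------------------------------------------------
# Display rounding (decimal half-up, as in printed tables)
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up of ``x`` to ``ndigits`` digits."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(x: float | None, ndigits: int) -> str:
    """Render a percentage for display; missing values print as ``-``."""
    if x is None:
        return "-"
    v = round_half_up(x, ndigits)
    return f"{v:.{ndigits}f}%"


# ---------------------------------------------------------------------------
# Duplicate accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplicateHistogram:
    """Counts n_j of distinct templates observed exactly j times.

    The sufficient statistic for library-complexity extrapolation:
    ``total_reads`` = sum j * n_j and ``distinct`` = sum n_j.
    """

    counts: dict[int, int]

    def __post_init__(self) -> None:
        for j, n in self.counts.items():
            if j < 1 or n < 0:
                raise ValueError(f"invalid histogram entry {j}: {n}")

    @property
    def total_reads(self) -> int:
        return sum(j * n for j, n in self.counts.items())

    @property
    def distinct(self) -> int:
        return sum(self.counts.values())

    @property
    def has_duplicates(self) -> bool:
        return any(j >= 2 and n > 0 for j, n in self.counts.items())

    def multiplicities(self) -> np.ndarray:
        """Per-class observation counts, one entry per distinct template."""
        return np.repeat(
            np.fromiter(self.counts.keys(), dtype=int),
            np.fromiter(self.counts.values(), dtype=int),
        )

    @classmethod
    def from_multiplicities(cls, mult: Iterable[int]) -> "DuplicateHistogram":
        return cls(dict(Counter(int(m) for m in mult)))


def deduplicate(reads: Sequence[ReadRecord]) -> tuple[list[ReadRecord], DuplicateHistogram]:
    """Collapse PCR duplicates and return the duplicate-count histogram.

    Reads are duplicates iff they share (reference, start, end, strand).
    One representative per class is retained, deterministically the one with
    the smallest read_id. The histogram satisfies sum j*n_j == len(reads).
    """
    classes: dict[tuple, list[ReadRecord]] = {}
    for r in reads:
        classes.setdefault(r.coordinate_key, []).append(r)
    unique = sorted(
        (min(group, key=lambda r: r.read_id) for group in classes.values()),
        key=lambda r: r.read_id,
    )
    hist = DuplicateHistogram.from_multiplicities(len(g) for g in classes.values())
    return unique, hist


class TargetPartition(NamedTuple):
    on_target: list[ReadRecord]
    off_target_same_reference: list[ReadRecord]
    other: list[ReadRecord]


def classify_on_target(
    reads: Sequence[ReadRecord], regions: TargetRegions
) -> TargetPartition:
    """Partition reads into on-target / off-target-same-reference / other.

    On-target means >= 1 bp overlap with any target interval (half-open
    coordinates, so a read ending where a region starts does not overlap).
    """
    tree = IntervalTree.from_tuples(regions.intervals) if regions.intervals else IntervalTree()
    on, off, other = [], [], []
    for r in reads:
        if r.reference != regions.reference:
            other.append(r)
        elif tree.overlap(r.start, r.end):
            on.append(r)
        else:
            off.append(r)
    return TargetPartition(on, off, other)


def min_retained_reads(read_counts_by_condition: Mapping[str, int]) -> int:
    """Per-individual minimum read count across conditions (down-sampling size)."""
    if not read_counts_by_condition:
        raise ValueError("empty condition map")
    return min(read_counts_by_condition.values())


def downsample(
    reads: Sequence[ReadRecord],
    n: int,
    n_replicates: int = DEFAULT_N_REPLICATES,
    base_seed: int = 0,
) -> list[list[ReadRecord]]:
    """Draw seeded uniform without-replacement subsets of size ``n``.

    Replicate ``r`` uses seed ``base_seed + r``, so individual replicates
    are reproducible in isolation.
    """
    if n > len(reads):
        raise ValueError(f"cannot down-sample {len(reads)} reads to {n}")
    if n < 0 or n_replicates < 1:
        raise ValueError("need n >= 0 and n_replicates >= 1")
    replicates = []
    for r in range(n_replicates):
        rng = np.random.default_rng(base_seed + r)
        idx = rng.choice(len(reads), size=n, replace=False)
        replicates.append([reads[i] for i in sorted(idx)])
    return replicates


# ---------------------------------------------------------------------------
# Library metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryMetrics:
    """Per-library accounting of one (possibly down-sampled) read set.

    Percentages are full precision; ``None`` marks a zero-denominator
    (missing) value. Display rounding is applied only when formatting.
    """

    total_reads: int
    mapped_reads: int
    unique_mapped: int
    chry_unique: int
    on_target_unique: int
    off_target_chry_unique: int
    endogenous_pct: float | None
    clonality_pct: float | None
    pct_sequenced_on_target: float | None
    pct_chry_on_target: float | None
    mean_length: float | None

    def display(self) -> dict[str, str]:
        """Table-style rendering: 2 decimals for % of sequenced, whole % for % of chrY."""
        return {
            "pct_sequenced_on_target": format_pct(self.pct_sequenced_on_target, 2),
            "pct_chry_on_target": format_pct(self.pct_chry_on_target, 0),
            "clonality_pct": format_pct(self.clonality_pct, 1),
            "endogenous_pct": format_pct(self.endogenous_pct, 2),
        }


def library_metrics(
    reads: Sequence[ReadRecord],
    regions: TargetRegions,
    chry_name: str = "chrY",
    exogenous_ref: str = EXOGENOUS_REF,
    total_reads: int | None = None,
) -> LibraryMetrics:
    """Compute the full per-library metric set from raw reads.

    ``total_reads`` defaults to the input size (the down-sampled count);
    mapped reads are those not on the exogenous pseudo-reference.
    Percentage conventions: % of sequenced on-target uses total reads as
    denominator; % of chrY on-target uses unique chrY reads (missing when
    zero); clonality is the percentage of mapped reads that are duplicates.
    """
    total = len(reads) if total_reads is None else total_reads
    mapped = [r for r in reads if r.reference != exogenous_ref]
    unique, _ = deduplicate(mapped)
    chry_unique = [r for r in unique if r.reference == chry_name]
    part = classify_on_target(unique, regions)
    on_t = len(part.on_target)
    off_t_chry = sum(1 for r in part.off_target_same_reference if r.reference == chry_name)

    def pct(num: float, den: float) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return LibraryMetrics(
        total_reads=total,
        mapped_reads=len(mapped),
        unique_mapped=len(unique),
        chry_unique=len(chry_unique),
        on_target_unique=on_t,
        off_target_chry_unique=off_t_chry,
        endogenous_pct=pct(len(unique), total),
        clonality_pct=pct(len(mapped) - len(unique), len(mapped)),
        pct_sequenced_on_target=pct(on_t, total),
        pct_chry_on_target=pct(on_t, len(chry_unique)),
        mean_length=float(np.mean([r.length for r in unique])) if unique else None,
    )


_PROPORTION_FIELDS = {
    # metric -> (numerator field, denominator field), on the 0-100 scale
    "endogenous_pct": ("unique_mapped", "total_reads"),
    "clonality_pct": ("_n_duplicates", "mapped_reads"),
    "pct_sequenced_on_target": ("on_target_unique", "total_reads"),
    "pct_chry_on_target": ("on_target_unique", "chry_unique"),
}

_COUNT_FIELDS = (
    "total_reads",
    "mapped_reads",
    "unique_mapped",
    "chry_unique",
    "on_target_unique",
    "off_target_chry_unique",
)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean metrics across down-sampling replicates, with binomial CIs.

    Proportion means are pooled (summed numerators over summed denominators
    across replicates — identical to the simple mean when replicate sizes
    are equal, which down-sampling guarantees for total-read denominators),
    so each Wilson CI is guaranteed to bracket its mean.
    """

    n_replicates: int
    replicates: tuple[LibraryMetrics, ...]
    mean: dict[str, float | None]
    ci: dict[str, tuple[float, float] | None]


def _field_value(m: LibraryMetrics, name: str) -> float:
    if name == "_n_duplicates":
        return m.mapped_reads - m.unique_mapped
    return getattr(m, name)


def summarize_replicates(
    metrics: Sequence[LibraryMetrics], level: float = 0.95
) -> ReplicateSummary:
    """Aggregate replicate metrics: count means, pooled proportions, Wilson CIs."""
    if not metrics:
        raise ValueError("no replicates")
    mean: dict[str, float | None] = {}
    ci: dict[str, tuple[float, float] | None] = {}
    for name in _COUNT_FIELDS:
        mean[name] = float(np.mean([getattr(m, name) for m in metrics]))
    lengths = [m.mean_length for m in metrics if m.mean_length is not None]
    mean["mean_length"] = float(np.mean(lengths)) if lengths else None
    for name, (num_f, den_f) in _PROPORTION_FIELDS.items():
        num = sum(_field_value(m, num_f) for m in metrics)
        den = sum(_field_value(m, den_f) for m in metrics)
        if den == 0:
            mean[name] = None
            ci[name] = None
            continue
        mean[name] = 100.0 * num / den
        lo, hi = binomial_ci(int(round(num)), int(round(den)), level)
        ci[name] = (100.0 * lo, 100.0 * hi)
    return ReplicateSummary(len(metrics), tuple(metrics), mean, ci)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def binomial_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, on [0, 1]."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    lo, hi = proportion_confint(successes, trials, alpha=1.0 - level, method="wilson")
    lo = 0.0 if successes == 0 else max(0.0, float(lo))
    hi = 1.0 if successes == trials else min(1.0, float(hi))
    return lo, hi


class PairedTestResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool


def paired_length_test(
    mean_lengths_a: Sequence[float], mean_lengths_b: Sequence[float]
) -> PairedTestResult:
    """Two-sided paired t-test on per-library mean read lengths.

    The typical use is testing the fragment-length shift after capture
    (paired by sample across conditions). When the paired differences have
    zero variance the t statistic is undefined and the result is flagged
    degenerate (statistic 0 / p 1 for identical lists, signed infinity / p 0
    for a constant nonzero shift).
    """
    a = np.asarray(mean_lengths_a, dtype=float)
    b = np.asarray(mean_lengths_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired 1-d samples with n >= 2")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return PairedTestResult(0.0, 1.0, True)
        return PairedTestResult(math.copysign(math.inf, d[0]), 0.0, True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(float(t), float(p), False)
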
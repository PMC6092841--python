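"""Truth-labeled synthetic ancient-DNA capture experiments.

The simulator emulates the statistical structure of shotgun and
capture-enriched aDNA sequencing libraries without touching raw bases or
alignment: a finite pool of template molecules (endogenous chrY, endogenous
non-Y, and exogenous/environmental) is drawn once per library, hybridization
capture thins that pool with class- and length-dependent retention, and
sequencing samples templates with replacement so PCR-duplicate structure
arises from pool size alone. Fragment lengths follow a truncated normal;
capture carries a logistic length bias centered at the probe length
(105 bp), reproducing the fragment-length shift seen after enrichment.

All coordinates are 0-based half-open; all operations are deterministic for
a fixed seed.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .ychrom import VALID_BASES, HaplogroupTree, SnpDef

#: Name of the pseudo-reference carrying exogenous (environmental) templates.
#: Reads on this reference count as sequenced but not as mapped/endogenous.
EXOGENOUS_REF = "exogenous"

#: Wildcard reference for whole-genome capture targets: matches every
#: mapped (non-exogenous) reference.
WHOLE_GENOME_REF = "*"

ORIGIN_ENDOGENOUS_Y = "endogenous_Y"
ORIGIN_ENDOGENOUS_OTHER = "endogenous_other"
ORIGIN_EXOGENOUS = "exogenous"

#: Probe length of the capture design; default midpoint of the length bias.
DEFAULT_PROBE_LENGTH = 105


@dataclass(frozen=True)
class LibraryProfile:
    """Composition of a sequencing library before any enrichment.

    Parameters
    ----------
    pool_size : int
        Number of distinct template molecules (library complexity).
    endogenous_fraction : float
        Proportion of templates of host origin, in [0, 1]. The study
        conditions emulated here span 0.0001-0.0154.
    y_fraction_of_endogenous : float
        Proportion of endogenous templates from chrY, in [0, 1].
    fragment_length_mean, fragment_length_sd : float
        Truncated-normal fragment length parameters in bp (observed
        pre-capture means span 63-108 bp).
    min_length : int
        Truncation point / shortest mappable fragment in bp.
    reference_lengths : dict
        Mapped reference name -> length in bp. Must contain the chrY
        reference the target regions live on.
    """

    pool_size: int
    endogenous_fraction: float
    y_fraction_of_endogenous: float
    fragment_length_mean: float
    fragment_length_sd: float
    min_length: int
    reference_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        for name in ("endogenous_fraction", "y_fraction_of_endogenous"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.fragment_length_mean > self.min_length > 0:
            raise ValueError("need fragment_length_mean > min_length > 0")
        if self.fragment_length_sd < 0:
            raise ValueError("fragment_length_sd must be >= 0")
        if not self.reference_lengths:
            raise ValueError("reference_lengths must be non-empty")


@dataclass(frozen=True)
class CaptureProfile:
    """Retention probabilities of one hybridization-capture round.

    Templates overlapping a target region are retained with ``p_on_target``,
    chrY templates outside the targets with ``p_off_target_y``, and all
    other templates with ``p_background``. A logistic length bias
    (midpoint at the probe length, 105 bp by default) multiplies the class
    probability; ``length_bias_scale`` of 0 disables the bias.
    """

    p_on_target: float
    p_off_target_y: float
    p_background: float
    length_bias_midpoint: float = DEFAULT_PROBE_LENGTH
    length_bias_scale: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_background <= self.p_off_target_y <= self.p_on_target <= 1.0:
            raise ValueError(
                "need 0 <= p_background <= p_off_target_y <= p_on_target <= 1"
            )
        if self.length_bias_scale < 0:
            raise ValueError("length_bias_scale must be >= 0")

    def length_multiplier(self, length: float | np.ndarray) -> float | np.ndarray:
        """Monotone non-decreasing retention multiplier in (0, 1]."""
        if self.length_bias_scale == 0:
            return np.ones_like(np.asarray(length, dtype=float)) if np.ndim(length) else 1.0
        z = (np.asarray(length, dtype=float) - self.length_bias_midpoint) / self.length_bias_scale
        out = 1.0 / (1.0 + np.exp(-z))
        return out if np.ndim(length) else float(out)


@dataclass(frozen=True)
class Template:
    """One distinct library molecule."""

    template_id: str
    reference: str
    start: int
    end: int
    strand: str
    origin: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MoleculePool:
    """Finite pool of distinct templates; the unit capture acts on."""

    templates: tuple[Template, ...]

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def origin_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.templates:
            counts[t.origin] = counts.get(t.origin, 0) + 1
        return counts


@dataclass(frozen=True)
class ReadRecord:
    """One mapped sequencing read; duplicates share all coordinates."""

    read_id: str
    template_id: str
    reference: str
    start: int
    end: int
    strand: str
    mapping_quality: int = 37

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def coordinate_key(self) -> tuple[str, int, int, str]:
        return (self.reference, self.start, self.end, self.strand)


class TargetRegions:
    """Sorted, disjoint half-open intervals on one named reference."""

    def __init__(self, reference: str, intervals: Iterable[tuple[int, int]]) -> None:
        self.reference = reference
        ivs = sorted((int(s), int(e)) for s, e in intervals)
        for s, e in ivs:
            if s < 0 or e <= s:
                raise ValueError(f"invalid interval [{s}, {e})")
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping intervals [{s0},{e0}) and [{s1},{e1})")
        self.intervals: tuple[tuple[int, int], ...] = tuple(ivs)
        self.total_bp: int = sum(e - s for s, e in ivs)
        self._starts = [s for s, _ in ivs]

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps(self, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any target interval by >= 1 bp."""
        if self.reference == WHOLE_GENOME_REF:
            return True
        i = bisect_right(self._starts, end - 1) - 1
        for j in (i, i - 1):
            if 0 <= j < len(self.intervals):
                s, e = self.intervals[j]
                if s < end and start < e:
                    return True
        return False

    # BED (0-based half-open), matching the on-disk target-region format
    @classmethod
    def from_bed(cls, path: str | Path, reference: str | None = None) -> "TargetRegions":
        ivs = []
        ref = reference
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                if ref is None:
                    ref = chrom
                if chrom != ref:
                    continue
                ivs.append((int(start), int(end)))
        if ref is None:
            raise ValueError(f"no intervals in {path}")
        return cls(ref, ivs)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, e in self.intervals:
                fh.write(f"{self.reference}\t{s}\t{e}\n")


def whole_genome_regions() -> TargetRegions:
    """Pseudo-target covering every mapped reference (whole-genome capture)."""
    return TargetRegions(WHOLE_GENOME_REF, [(0, 2**62)])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def make_target_regions(
    reference_length: int, n_regions: int, total_target_bp: int, seed: int
) -> TargetRegions:
    """Draw a random on-target design: disjoint intervals of fixed total size.

    A miniature stand-in for a real probe design (the emulated study used
    17,934 regions totalling ~7.4 Mb on chrY). Interval lengths are a random
    composition of ``total_target_bp`` into ``n_regions`` positive parts;
    gaps distribute the leftover reference uniformly.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if total_target_bp > reference_length:
        raise ValueError(
            f"cannot pack {total_target_bp} target bp into a {reference_length} bp reference"
        )
    if n_regions > total_target_bp:
        raise ValueError("n_regions exceeds total_target_bp (regions must be >= 1 bp)")
    rng = np.random.default_rng(seed)
    if n_regions == 1:
        lengths = np.array([total_target_bp])
    else:
        cuts = np.sort(rng.choice(total_target_bp - 1, size=n_regions - 1, replace=False) + 1)
        lengths = np.diff(np.concatenate(([0], cuts, [total_target_bp])))
    slack = reference_length - total_target_bp
    gaps = rng.multinomial(slack, np.full(n_regions + 1, 1.0 / (n_regions + 1)))
    intervals = []
    pos = 0
    for gap, length in zip(gaps, lengths):
        pos += int(gap)
        intervals.append((pos, pos + int(length)))
        pos += int(length)
    return TargetRegions("chrY", intervals)


def simulate_molecule_pool(
    profile: LibraryProfile, regions: TargetRegions, seed: int
) -> MoleculePool:
    """Draw the finite template pool of one library.

    Origins follow the profile proportions (chrY endogenous / other
    endogenous / exogenous); fragment lengths are truncated-normal above
    ``min_length``; coordinates are uniform over the labeled reference.
    Exogenous templates are placed on a dedicated pseudo-reference so they
    never count as mapped.
    """
    if regions.reference not in profile.reference_lengths:
        raise ValueError(
            f"target reference {regions.reference!r} absent from profile.reference_lengths"
        )
    rng = np.random.default_rng(seed)
    n = profile.pool_size
    p_y = profile.endogenous_fraction * profile.y_fraction_of_endogenous
    p_other = profile.endogenous_fraction * (1.0 - profile.y_fraction_of_endogenous)
    p_exo = 1.0 - profile.endogenous_fraction
    origins = rng.choice(
        [ORIGIN_ENDOGENOUS_Y, ORIGIN_ENDOGENOUS_OTHER, ORIGIN_EXOGENOUS],
        size=n,
        p=[p_y, p_other, p_exo],
    )

    if profile.fragment_length_sd > 0:
        a = (profile.min_length - profile.fragment_length_mean) / profile.fragment_length_sd
        lengths = stats.truncnorm.rvs(
            a,
            np.inf,
            loc=profile.fragment_length_mean,
            scale=profile.fragment_length_sd,
            size=n,
            random_state=rng,
        )
        lengths = np.maximum(np.rint(lengths).astype(int), profile.min_length)
    else:
        lengths = np.full(n, int(round(profile.fragment_length_mean)))

    chry = regions.reference
    other_refs = [r for r in profile.reference_lengths if r != chry]
    other_len = np.array([profile.reference_lengths[r] for r in other_refs], dtype=float)
    exo_length = 10 * sum(profile.reference_lengths.values())
    strands = rng.choice(["+", "-"], size=n)

    templates = []
    for i in range(n):
        origin = origins[i]
        if origin == ORIGIN_ENDOGENOUS_Y:
            ref = chry
        elif origin == ORIGIN_ENDOGENOUS_OTHER:
            if not other_refs:
                ref = chry  # single-reference profile: everything endogenous is chrY
            else:
                ref = other_refs[int(rng.choice(len(other_refs), p=other_len / other_len.sum()))]
        else:
            ref = EXOGENOUS_REF
        ref_len = exo_length if ref == EXOGENOUS_REF else profile.reference_lengths[ref]
        length = int(min(lengths[i], ref_len))
        start = int(rng.integers(0, ref_len - length + 1))
        templates.append(
            Template(f"t{i:07d}", ref, start, start + length, strands[i], origin)
        )
    return MoleculePool(tuple(templates))


def amplify_and_sequence(pool: MoleculePool, n_reads: int, seed: int) -> list[ReadRecord]:
    """Sequence ``n_reads`` reads by sampling templates with replacement.

    Amplification is unbiased (uniform template weights), so the expected
    number of distinct templates observed follows the occupancy formula
    P * (1 - (1 - 1/P)**n) for pool size P; duplicate structure and hence
    clonality arise from the finite pool alone.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads == 0:
        return []
    if len(pool) == 0:
        raise ValueError("cannot sequence from an empty pool")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pool), size=n_reads)
    reads = []
    for k, i in enumerate(idx):
        t = pool.templates[int(i)]
        reads.append(
            ReadRecord(f"r{k:08d}", t.template_id, t.reference, t.start, t.end, t.strand)
        )
    return reads


def simulate_capture(
    pool: MoleculePool, regions: TargetRegions, capture: CaptureProfile, seed: int
) -> MoleculePool:
    """Thin a pool by one round of hybridization capture.

    Each template is retained independently with probability
    class-probability x length-bias multiplier. Applying the operation twice
    models a capture-after-capture experiment (e.g. whole-genome capture
    followed by chrY capture) with its attendant complexity loss: the output
    pool is always a subset of the input pool.
    """
    rng = np.random.default_rng(seed)
    u = rng.random(len(pool))
    kept = []
    for i, t in enumerate(pool.templates):
        if regions.reference == WHOLE_GENOME_REF:
            on_target = t.reference != EXOGENOUS_REF
        else:
            on_target = t.reference == regions.reference and regions.overlaps(t.start, t.end)
        if on_target:
            p = capture.p_on_target
        elif t.reference == regions.reference:
            p = capture.p_off_target_y
        else:
            p = capture.p_background
        p *= capture.length_multiplier(t.length)
        if u[i] < p:
            kept.append(t)
    return MoleculePool(tuple(kept))


# ---------------------------------------------------------------------------
# Genotype / pileup simulation for the haplogroup caller
# ---------------------------------------------------------------------------

#: Pileup: position -> list of (base, Phred base quality) observations.
Pileup = dict[int, list[tuple[str, int]]]


def simulate_genotypes(
    tree: HaplogroupTree,
    true_haplogroup: str,
    mean_depth: float,
    error_rate: float,
    seed: int,
    q_high: tuple[int, int] = (20, 41),
    q_low: tuple[int, int] = (2, 13),
    p_low_quality: float = 0.15,
) -> Pileup:
    """Simulate a pileup over the tree's SNP sites for a known haplogroup.

    Sites on the root-to-``true_haplogroup`` path carry the derived allele,
    all other sites the ancestral one. Per-site read depth is
    Poisson(``mean_depth``); each observed base is flipped to a random other
    base with probability ``error_rate``. Base qualities straddle the
    calling quality floor: a fraction ``p_low_quality`` falls in ``q_low``
    (below the default floor of 13), the rest in ``q_high``.
    """
    if true_haplogroup not in tree:
        raise KeyError(f"unknown haplogroup {true_haplogroup!r}")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    path = set(tree.root_path(true_haplogroup))
    bases = sorted(VALID_BASES)
    pileup: Pileup = {}
    for snp in tree.all_snps():
        truth = snp.derived if snp.haplogroup in path else snp.ancestral
        depth = int(rng.poisson(mean_depth))
        if depth == 0:
            continue
        column = []
        for _ in range(depth):
            base = truth
            if error_rate > 0 and rng.random() < error_rate:
                base = bases[int(rng.choice([i for i in range(4) if bases[i] != truth]))]
            if rng.random() < p_low_quality:
                qual = int(rng.integers(*q_low))
            else:
                qual = int(rng.integers(*q_high))
            column.append((base, qual))
        pileup[snp.position] = column
    return pileup


def make_random_tree(
    n_nodes: int,
    seed: int,
    snps_per_branch: tuple[int, int] = (2, 4),
) -> HaplogroupTree:
    """Generate a random rooted haplogroup tree for simulation studies.

    Node ``H0`` is the root (no defining SNPs); each later node attaches to
    a uniformly chosen earlier node and carries 2-4 defining SNPs at unique
    positions with random distinct ancestral/derived alleles.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    parents: dict[str, str | None] = {"H0": None}
    branch_snps: dict[str, list[SnpDef]] = {}
    bases = sorted(VALID_BASES)
    pos = 0
    for i in range(1, n_nodes):
        name = f"H{i}"
        parents[name] = f"H{int(rng.integers(i))}"
        k = int(rng.integers(snps_per_branch[0], snps_per_branch[1] + 1))
        snps = []
        for _ in range(k):
            pos += int(rng.integers(50, 500))
            anc, der = rng.choice(4, size=2, replace=False)
            snps.append(SnpDef(f"M{pos}", pos, bases[int(anc)], bases[int(der)], name))
        branch_snps[name] = snps
    return HaplogroupTree(parents, branch_snps)


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

_READ_COLUMNS = ("read_id", "template_id", "reference", "start", "end", "strand", "mapping_quality")
_TEMPLATE_COLUMNS = ("template_id", "reference", "start", "end", "strand", "origin")


def write_reads_tsv(reads: Sequence[ReadRecord], path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"#seed={seed}\n")
        fh.write("\t".join(_READ_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.template_id}\t{r.reference}\t{r.start}\t{r.end}\t"
                f"{r.strand}\t{r.mapping_quality}\n"
            )


def read_reads_tsv(path: str | Path) -> list[ReadRecord]:
    reads = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("read_id"):
                continue
            rid, tid, ref, start, end, strand, mq = line.rstrip("\n").split("\t")
            reads.append(ReadRecord(rid, tid, ref, int(start), int(end), strand, int(mq)))
    return reads


def write_pool_tsv(pool: MoleculePool, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"#seed={seed}\n")
        fh.write("\t".join(_TEMPLATE_COLUMNS) + "\n")
        for t in pool.templates:
            fh.write(f"{t.template_id}\t{t.reference}\t{t.start}\t{t.end}\t{t.strand}\t{t.origin}\n")


def read_pool_tsv(path: str | Path) -> MoleculePool:
    templates = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("template_id"):
                continue
            tid, ref, start, end, strand, origin = line.rstrip("\n").split("\t")
            templates.append(Template(tid, ref, int(start), int(end), strand, origin))
    return MoleculePool(tuple(templates))
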
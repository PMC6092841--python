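"""Genetic sex determination and Y-chromosome haplogroup assignment.

Two procedures commonly applied to low-coverage ancient-DNA data:

* the Ry statistic — the fraction of sex-chromosome reads mapping to chrY,
  with a normal-approximation confidence interval and a decision threshold
  (default 0.075) above which a library is consistent with an XY karyotype;
* most-derived-SNP haplogroup assignment — haploid genotypes are sampled
  (one random base per site, base quality >= 13) and matched against a
  rooted Y-SNP phylogeny; the call is the deepest haplogroup whose own
  defining branch carries at least one derived allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Default base-quality floor for haploid genotype sampling (Phred scale).
DEFAULT_MIN_BASE_QUALITY = 13

#: Default Ry threshold above which a library is consistent with XY.
DEFAULT_RY_THRESHOLD = 0.075


@dataclass(frozen=True)
class SnpDef:
    """A phylogenetically informative Y-SNP.

    Attributes
    ----------
    snp_id : str
        Marker name (e.g. ``M343``).
    position : int
        0-based position on the Y chromosome.
    ancestral, derived : str
        Pre- and post-mutation alleles; distinct single bases in ACGT.
    haplogroup : str
        Name of the haplogroup whose defining branch carries this SNP.
    """

    snp_id: str
    position: int
    ancestral: str
    derived: str
    haplogroup: str

    def __post_init__(self) -> None:
        if self.ancestral not in VALID_BASES or self.derived not in VALID_BASES:
            raise ValueError(
                f"SNP {self.snp_id}: alleles must be in ACGT, got "
                f"{self.ancestral!r}/{self.derived!r}"
            )
        if self.ancestral == self.derived:
            raise ValueError(f"SNP {self.snp_id}: ancestral == derived ({self.ancestral})")
        if self.position < 0:
            raise ValueError(f"SNP {self.snp_id}: negative position")


class HaplogroupTree:
    """Rooted haplogroup phylogeny with SNPs attached to branches.

    Each non-root node has exactly one parent; the SNPs on the branch
    leading into a node define that node's haplogroup. SNP positions are
    unique across the whole tree.
    """

    def __init__(
        self,
        parents: Mapping[str, str | None],
        branch_snps: Mapping[str, Sequence[SnpDef]],
    ) -> None:
        self.parents: dict[str, str | None] = dict(parents)
        self.branch_snps: dict[str, tuple[SnpDef, ...]] = {
            name: tuple(branch_snps.get(name, ())) for name in self.parents
        }
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}: {roots}")
        self.root: str = roots[0]
        for name, parent in self.parents.items():
            if parent is not None and parent not in self.parents:
                raise ValueError(f"node {name!r} references unknown parent {parent!r}")
        for name, snps in self.branch_snps.items():
            for snp in snps:
                if snp.haplogroup != name:
                    raise ValueError(
                        f"SNP {snp.snp_id} labeled {snp.haplogroup!r} attached to branch {name!r}"
                    )
        # root-path precomputation doubles as the cycle check
        self._root_paths: dict[str, tuple[str, ...]] = {}
        for name in self.parents:
            path: list[str] = []
            node: str | None = name
            seen: set[str] = set()
            while node is not None:
                if node in seen:
                    raise ValueError(f"cycle detected at node {node!r}")
                seen.add(node)
                path.append(node)
                node = self.parents[node]
            self._root_paths[name] = tuple(reversed(path))
        self.snp_by_position: dict[int, SnpDef] = {}
        for snps in self.branch_snps.values():
            for snp in snps:
                if snp.position in self.snp_by_position:
                    raise ValueError(f"duplicate SNP position {snp.position}")
                self.snp_by_position[snp.position] = snp

    # -- queries ---------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.parents)

    def root_path(self, name: str) -> tuple[str, ...]:
        """Path of node names from the root down to (and including) ``name``."""
        try:
            return self._root_paths[name]
        except KeyError:
            raise KeyError(f"unknown haplogroup {name!r}") from None

    def depth(self, name: str) -> int:
        return len(self.root_path(name)) - 1

    def all_snps(self) -> tuple[SnpDef, ...]:
        return tuple(self.snp_by_position[p] for p in sorted(self.snp_by_position))

    def __contains__(self, name: str) -> bool:
        return name in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    # -- construction / serialization ------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str | None, str | None, int | None, str | None, str | None]]
    ) -> "HaplogroupTree":
        """Build a tree from (haplogroup, parent, snp_id, position, ancestral, derived) rows.

        Multiple rows per haplogroup attach multiple SNPs to its branch; rows
        with snp_id ``None`` declare a branch without SNPs (typically the root).
        """
        parents: dict[str, str | None] = {}
        snps: dict[str, list[SnpDef]] = {}
        for hg, parent, snp_id, pos, anc, der in records:
            if hg in parents and parents[hg] != parent:
                raise ValueError(f"conflicting parents for {hg!r}: {parents[hg]!r} vs {parent!r}")
            parents[hg] = parent
            if snp_id is not None:
                if pos is None or anc is None or der is None:
                    raise ValueError(f"incomplete SNP row for {snp_id!r}")
                snps.setdefault(hg, []).append(SnpDef(snp_id, int(pos), anc, der, hg))
        return cls(parents, snps)


_NULL_FIELD = {"-", "", ".", "NA"}


def load_haplogroup_tree(path: str | Path) -> HaplogroupTree:
    """Read a haplogroup tree from 6-column TSV.

    Columns: haplogroup, parent, snp_id, position (0-based), ancestral,
    derived. ``-`` marks a missing parent (the root) or a branch without a
    SNP. Lines starting with ``#`` and a header line are skipped. Row order
    is irrelevant.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated columns")
            hg, parent, snp_id, pos, anc, der = fields
            if lineno == 1 and not pos.lstrip("-").isdigit() and pos not in _NULL_FIELD:
                continue  # header
            records.append(
                (
                    hg,
                    None if parent in _NULL_FIELD else parent,
                    None if snp_id in _NULL_FIELD else snp_id,
                    None if pos in _NULL_FIELD else int(pos),
                    None if anc in _NULL_FIELD else anc,
                    None if der in _NULL_FIELD else der,
                )
            )
    return HaplogroupTree.from_records(records)


def write_haplogroup_tree(tree: HaplogroupTree, path: str | Path) -> None:
    """Write a tree in the 6-column TSV layout read by :func:`load_haplogroup_tree`."""
    with open(path, "w") as fh:
        fh.write("haplogroup\tparent\tsnp_id\tposition\tancestral\tderived\n")
        for name in tree.nodes:
            parent = tree.parents[name] or "-"
            snps = tree.branch_snps[name]
            if not snps:
                fh.write(f"{name}\t{parent}\t-\t-\t-\t-\n")
            for snp in snps:
                fh.write(
                    f"{name}\t{parent}\t{snp.snp_id}\t{snp.position}\t"
                    f"{snp.ancestral}\t{snp.derived}\n"
                )


# ---------------------------------------------------------------------------
# Sex determination
# ---------------------------------------------------------------------------

CONSISTENT_XY = "consistent-with-XY"
NOT_CONSISTENT_XY = "not-consistent-with-XY"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class SexResult:
    """Outcome of the read-count sex test."""

    n_chrx: int
    n_chry: int
    ry: float
    ci: tuple[float, float]
    assignment: str
    threshold: float


def ry_statistic(
    n_chrx: int, n_chry: int, threshold: float = DEFAULT_RY_THRESHOLD
) -> SexResult:
    """Sex determination from sex-chromosome read counts.

    Ry = n_chrY / (n_chrX + n_chrY) with a 95% normal-approximation CI
    (Ry +/- 1.96 * sqrt(Ry (1-Ry) / n), clipped to [0, 1]). The library is
    called consistent with XY only when the whole CI lies above the
    threshold, and not consistent only when it lies entirely below;
    otherwise the result is indeterminate.
    """
    if n_chrx < 0 or n_chry < 0:
        raise ValueError("read counts must be non-negative")
    total = n_chrx + n_chry
    if total < 1:
        raise ValueError("need at least one sex-chromosome read")
    ry = n_chry / total
    half = 1.96 * np.sqrt(ry * (1.0 - ry) / total)
    lo = max(0.0, ry - half)
    hi = min(1.0, ry + half)
    if lo > threshold:
        assignment = CONSISTENT_XY
    elif hi < threshold:
        assignment = NOT_CONSISTENT_XY
    else:
        assignment = INDETERMINATE
    return SexResult(n_chrx, n_chry, ry, (lo, hi), assignment, threshold)


# ---------------------------------------------------------------------------
# Haploid genotype sampling
# ---------------------------------------------------------------------------


def call_haploid_genotypes(
    pileup: Mapping[int, Sequence[tuple[str, int]]],
    min_quality: int = DEFAULT_MIN_BASE_QUALITY,
    seed: int = 0,
) -> list[tuple[int, str]]:
    """Sample one random base per site after a base-quality filter.

    Bases below ``min_quality`` (inclusive floor: quality == min_quality
    survives) are discarded; among survivors one base is drawn uniformly.
    Sites with no surviving base are omitted. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    calls: list[tuple[int, str]] = []
    for pos in sorted(pileup):
        survivors = [base for base, qual in pileup[pos] if qual >= min_quality]
        if not survivors:
            continue
        calls.append((pos, survivors[int(rng.integers(len(survivors)))]))
    return calls


# ---------------------------------------------------------------------------
# Haplogroup assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplogroupCall:
    """Result of the most-derived-SNP tree search.

    ``haplogroup`` is ``None`` when no derived allele was observed anywhere
    in the tree, or when conflicting data leave two equally deep, equally
    supported candidates (listed in ``candidates``).
    """

    haplogroup: str | None
    most_derived_snp: str | None
    n_derived_support: int
    n_ancestral_support: int
    conflicts: tuple[str, ...]
    candidates: tuple[str, ...] = ()
    n_ignored_positions: int = 0

    @property
    def resolved(self) -> bool:
        return self.haplogroup is not None


def assign_haplogroup(
    calls: Sequence[tuple[int, str]], tree: HaplogroupTree
) -> HaplogroupCall:
    """Assign the deepest haplogroup supported by a derived allele.

    Every call is matched against the tree's SNPs and scored derived,
    ancestral or other. The assignment is the deepest node whose own branch
    carries at least one derived call; among equally deep candidates the one
    with more derived calls along its root path wins, and a remaining tie is
    reported unresolved with both candidates listed. Derived calls on
    branches off the chosen root path are returned as conflicts rather than
    silently dropped. Calls at positions absent from the tree are counted
    and ignored.
    """
    derived_by_node: dict[str, list[SnpDef]] = {}
    ignored = 0
    for pos, base in calls:
        snp = tree.snp_by_position.get(pos)
        if snp is None:
            ignored += 1
            continue
        if base == snp.derived:
            derived_by_node.setdefault(snp.haplogroup, []).append(snp)
    if ignored:
        logger.info("assign_haplogroup: ignored %d calls at positions absent from tree", ignored)
    if not derived_by_node:
        return HaplogroupCall(None, None, 0, 0, (), (), ignored)

    def path_derived_count(node: str) -> int:
        return sum(len(derived_by_node.get(n, ())) for n in tree.root_path(node))

    best_depth = max(tree.depth(n) for n in derived_by_node)
    deepest = [n for n in derived_by_node if tree.depth(n) == best_depth]
    best_support = max(path_derived_count(n) for n in deepest)
    winners = sorted(n for n in deepest if path_derived_count(n) == best_support)
    if len(winners) > 1:
        return HaplogroupCall(
            None, None, 0, 0, (), tuple(winners), ignored
        )
    chosen = winners[0]
    path = set(tree.root_path(chosen))
    # score calls against SNPs on the chosen root path
    n_derived = n_ancestral = 0
    for pos, base in calls:
        snp = tree.snp_by_position.get(pos)
        if snp is None or snp.haplogroup not in path:
            continue
        if base == snp.derived:
            n_derived += 1
        elif base == snp.ancestral:
            n_ancestral += 1
    conflicts = tuple(
        sorted(
            snp.snp_id
            for node, snps in derived_by_node.items()
            if node not in path
            for snp in snps
        )
    )
    most_derived = min(s.snp_id for s in derived_by_node[chosen])
    return HaplogroupCall(
        chosen, most_derived, n_derived, n_ancestral, conflicts, (), ignored
    )
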
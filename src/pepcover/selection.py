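"""Family-unique peptides, greedy minimum cover, coverage curves and
EC/taxonomy groupings.

A tryptic peptide is "unique" to a family when it occurs in at least one
target-family protein and nowhere in the background peptidome.  The greedy
cover repeatedly takes the peptide covering the most still-uncovered
proteins, removes those proteins from every other peptide's set, and stops
when every coverable protein is claimed; covered sets are therefore pairwise
disjoint and their sizes non-increasing with rank.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .errors import InstanceTooLargeError, PepcoverError
from .peptides import Peptidome

__all__ = [
    "SelectionGroup",
    "SelectionResult",
    "CoverageCurve",
    "unique_target_peptides",
    "greedy_min_cover",
    "brute_force_min_cover",
    "coverage_curve",
    "group_by_ec",
    "group_by_phylum",
    "peptides_to_cover_taxon",
]

DEFAULT_CUTOFFS = (10, 50, 100, 200)


@dataclass(frozen=True)
class SelectionGroup:
    rank: int
    peptide: str
    covered: frozenset[str]


@dataclass
class SelectionResult:
    """Ordered greedy cover of a family's proteins by unique peptides.

    ``residual`` lists target proteins left uncovered — proteins with no
    family-unique peptide at all.
    """

    family: str
    total_target_proteins: int
    groups: list[SelectionGroup]
    residual: frozenset[str] = frozenset()

    @property
    def covered_proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= g.covered
        return frozenset(out)

    @property
    def n_covered(self) -> int:
        return sum(len(g.covered) for g in self.groups)


@dataclass
class CoverageCurve:
    """Percent of target proteins covered by the top-k ranked peptides."""

    points: list[tuple[int, float]]  # (cutoff, percent_covered)


def unique_target_peptides(target: Peptidome, background: Peptidome) -> Peptidome:
    """Drop every target peptide whose exact sequence occurs in the background.

    Uniqueness is a peptide-string comparison: only an identical tryptic
    peptide in the background removes a candidate.  Membership sets are
    unchanged.  An empty result is allowed.
    """
    kept = {
        pep: ids
        for pep, ids in target.peptides.items()
        if pep not in background.peptides
    }
    return Peptidome(peptides=kept, provenance="target", filtered=target.filtered)


def greedy_min_cover(
    unique: Peptidome,
    *,
    family: str = "",
    total_target_proteins: int | None = None,
) -> SelectionResult:
    """Greedy minimum set cover over the unique peptidome.

    Each round selects the peptide whose current protein set is largest
    (ties: lexicographically smallest peptide string), removes the covered
    proteins from every remaining peptide's set, and drops peptides whose
    sets become empty.  Terminates when every protein carrying at least one
    unique peptide is covered.

    ``total_target_proteins`` sets the denominator for coverage curves; it
    defaults to the number of proteins appearing in the unique peptidome.
    """
    if not unique.peptides:
        raise PepcoverError("greedy_min_cover requires a non-empty peptidome")
    working: dict[str, set[str]] = {
        pep: set(ids) for pep, ids in unique.peptides.items()
    }
    coverable = unique.protein_ids
    if total_target_proteins is None:
        total_target_proteins = len(coverable)

    groups: list[SelectionGroup] = []
    rank = 0
    while working:
        # largest current set; ties go to the lexicographically smallest peptide
        peptide = min(working, key=lambda p: (-len(working[p]), p))
        covered = frozenset(working[peptide])
        rank += 1
        groups.append(SelectionGroup(rank, peptide, covered))
        del working[peptide]
        for pep in list(working):
            working[pep] -= covered
            if not working[pep]:
                del working[pep]

    covered_all: set[str] = set()
    for g in groups:
        covered_all |= g.covered
    residual = frozenset(coverable - covered_all)  # empty by construction
    return SelectionResult(
        family=family,
        total_target_proteins=total_target_proteins,
        groups=groups,
        residual=residual,
    )


def brute_force_min_cover(unique: Peptidome, max_peptides: int = 15) -> int:
    """Exact minimum number of peptides covering every coverable protein.

    Exhaustive subset search; refuses instances with more than
    ``max_peptides`` peptides.  Test oracle for greedy quality.
    """
    n = len(unique.peptides)
    if n > max_peptides:
        raise InstanceTooLargeError(
            f"{n} peptides exceeds the exhaustive-search bound of {max_peptides}"
        )
    if n == 0:
        raise PepcoverError("brute_force_min_cover requires a non-empty peptidome")
    proteins = sorted(unique.protein_ids)
    index = {p: i for i, p in enumerate(proteins)}
    universe = (1 << len(proteins)) - 1
    masks = []
    for ids in unique.peptides.values():
        m = 0
        for p in ids:
            m |= 1 << index[p]
        masks.append(m)
    for k in range(1, n + 1):
        for combo in combinations(masks, k):
            acc = 0
            for m in combo:
                acc |= m
            if acc == universe:
                return k
    raise AssertionError("unreachable: all peptides together cover the universe")


def coverage_curve(
    result: SelectionResult, cutoffs: Sequence[int] = DEFAULT_CUTOFFS
) -> CoverageCurve:
    """Percent of target proteins covered by the top-k ranked peptides.

    Percent at cutoff k = (sum of covered-set sizes of the first k groups)
    / total_target_proteins x 100.  An empty selection yields 0 everywhere.
    """
    points: list[tuple[int, float]] = []
    sizes = [len(g.covered) for g in result.groups]
    for k in cutoffs:
        if k <= 0:
            raise ValueError(f"cutoff must be positive, got {k}")
        if result.total_target_proteins == 0:
            points.append((k, 0.0))
            continue
        covered = sum(sizes[:k])
        points.append((k, 100.0 * covered / result.total_target_proteins))
    return CoverageCurve(points=points)


def group_by_ec(
    result: SelectionResult,
    ec_table: Mapping[str, Sequence[str]] | None = None,
) -> dict[frozenset[str], tuple[int, int]]:
    """Group selected peptides by the EC-number set of the proteins they cover.

    Each peptide is keyed by the set of distinct EC annotations across its
    covered proteins (proteins without annotation contribute "N/A").  The
    value is (peptide count, distinct protein count) per key, reproducing
    composite substrate-specificity categories.
    """
    peptide_count: Counter[frozenset[str]] = Counter()
    proteins_by_key: dict[frozenset[str], set[str]] = {}
    for g in result.groups:
        ecs: set[str] = set()
        for pid in g.covered:
            annotated = tuple(ec_table.get(pid, ())) if ec_table else ()
            ecs.update(annotated if annotated else ("N/A",))
        key = frozenset(ecs)
        peptide_count[key] += 1
        proteins_by_key.setdefault(key, set()).update(g.covered)
    return {
        key: (peptide_count[key], len(proteins_by_key[key]))
        for key in peptide_count
    }


def group_by_phylum(
    result: SelectionResult,
    taxonomy: Mapping[str, str],
    mag_by_protein: Mapping[str, str],
) -> list[dict]:
    """Phylum composition of the proteins each selected peptide covers.

    Returns one entry per group with the per-phylum protein counts and a
    ``taxon_specific`` flag set when a single phylum accounts for the whole
    covered set.  MAGs absent from the taxonomy fall into the "NA" bucket.
    """
    out: list[dict] = []
    for g in result.groups:
        comp: Counter[str] = Counter()
        for pid in g.covered:
            comp[taxonomy.get(mag_by_protein.get(pid, ""), "NA")] += 1
        out.append(
            {
                "rank": g.rank,
                "peptide": g.peptide,
                "composition": dict(comp),
                "taxon_specific": len(comp) == 1,
            }
        )
    return out


def peptides_to_cover_taxon(
    result: SelectionResult,
    taxonomy: Mapping[str, str],
    mag_by_protein: Mapping[str, str],
    phylum: str,
    *,
    mode: str = "prefix",
) -> int:
    """Number of selected peptides needed to cover a phylum's target proteins.

    ``mode="prefix"`` (default): the smallest k such that the first k ranked
    groups of the family-wide selection contain every covered target protein
    of the phylum.  Because the selection is taxa-agnostic, these counts
    include peptides shared across phyla.

    ``mode="greedy-subset"``: re-runs the greedy choice over the selected
    groups restricted to the phylum's proteins, giving the smaller count a
    phylum-focused assay would need.

    A phylum with zero covered target proteins yields 0.
    """
    wanted = {
        pid
        for g in result.groups
        for pid in g.covered
        if taxonomy.get(mag_by_protein.get(pid, ""), "NA") == phylum
    }
    if not wanted:
        return 0
    if mode == "prefix":
        remaining = set(wanted)
        for g in result.groups:
            remaining -= g.covered
            if not remaining:
                return g.rank
        raise AssertionError("unreachable: wanted is drawn from covered sets")
    if mode == "greedy-subset":
        sets = [
            set(g.covered & frozenset(wanted))
            for g in result.groups
            if g.covered & frozenset(wanted)
        ]
        remaining = set(wanted)
        count = 0
        while remaining:
            best = max(sets, key=lambda s: len(s & remaining))
            remaining -= best
            count += 1
        return count
    raise ValueError(f"unknown mode {mode!r}")
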
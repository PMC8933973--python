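"""Multi-tool consensus CAZyme assignment, community census and
target/background partitioning.

dbCAN2 runs three independent searches (HMMER against dbCAN HMMs, DIAMOND
against CAZy, Hotpep peptide-pattern matching).  A protein counts as a
CAZyme only when at least two tools annotate it; HMMER labels take priority,
and when HMMER is silent the DIAMOND/Hotpep label intersection is used —
an empty intersection discards the protein.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyTargetError, PepcoverError
from .io import ProteinRecord, ToolAnnotationRow

__all__ = [
    "FamilyAssignment",
    "CensusReport",
    "collapse_family",
    "family_class",
    "consensus_families",
    "partition_consensus",
    "cazyme_census",
    "split_target_background",
    "CAZYME_CLASSES",
]

logger = logging.getLogger(__name__)

EVIDENCE_HMMER = "hmmer-priority"
EVIDENCE_AGREEMENT = "diamond-hotpep-agreement"

# Display order for class-proportion vectors; structural domains pooled.
CAZYME_CLASSES = ("AA", "CBM", "CE", "GH", "GT", "PL", "cohesin/SLH")


@dataclass(frozen=True)
class FamilyAssignment:
    """Consensus family label set for one protein, with the rule that fired."""

    protein_id: str
    families: frozenset[str]
    evidence: str

    def __post_init__(self):
        if not self.families:
            raise PepcoverError(
                f"FamilyAssignment for {self.protein_id!r} has no families"
            )


@dataclass
class CensusReport:
    """Per-MAG CAZyme fractions and per-phylum class composition."""

    per_mag: pd.DataFrame  # mag_id, phylum, n_proteins, n_cazymes, pct_cazymes
    per_phylum: pd.DataFrame | None  # phylum, n_mags, median_pct, one column per class


def collapse_family(label: str) -> str:
    """Collapse a subfamily label to its family: "GH13_20" -> "GH13"."""
    return label.split("_", 1)[0]


def family_class(label: str) -> str:
    """Map a family label to its CAZyme class; cohesin and SLH are pooled."""
    if label.startswith("cohesin") or label.startswith("SLH"):
        return "cohesin/SLH"
    prefix = "".join(ch for ch in label if ch.isalpha())
    return prefix


def partition_consensus(
    rows: Iterable[ToolAnnotationRow],
) -> tuple[list[FamilyAssignment], list[tuple[str, str]]]:
    """Apply the consensus rule, returning (assignments, discarded).

    Discarded entries carry a reason: "single-tool" (fewer than two tools
    annotated the protein) or "no-agreement" (HMMER silent and the
    DIAMOND/Hotpep intersection empty).  Output is sorted by protein_id so
    the result is independent of input row order.
    """
    kept: list[FamilyAssignment] = []
    discarded: list[tuple[str, str]] = []
    for row in sorted(rows, key=lambda r: r.protein_id):
        if row.n_tools < 2:
            discarded.append((row.protein_id, "single-tool"))
            continue
        if row.hmmer:
            kept.append(FamilyAssignment(row.protein_id, row.hmmer, EVIDENCE_HMMER))
            continue
        agreement = row.diamond & row.hotpep
        if agreement:
            kept.append(
                FamilyAssignment(row.protein_id, agreement, EVIDENCE_AGREEMENT)
            )
        else:
            discarded.append((row.protein_id, "no-agreement"))
    return kept, discarded


def consensus_families(rows: Iterable[ToolAnnotationRow]) -> list[FamilyAssignment]:
    """Consensus CAZyme assignments (discards logged, not raised)."""
    kept, discarded = partition_consensus(rows)
    if discarded:
        logger.info(
            "consensus discarded %d of %d annotated proteins",
            len(discarded),
            len(discarded) + len(kept),
        )
    return kept


def cazyme_census(
    assignments: Sequence[FamilyAssignment],
    proteome_sizes: Mapping[str, int],
    mag_by_protein: Mapping[str, str],
    taxonomy: Mapping[str, str] | None = None,
) -> CensusReport:
    """Census of CAZyme content per MAG and, when taxonomy is given, per phylum.

    Percent CAZymes per MAG = assigned proteins / proteome size x 100.
    Class proportions count each protein once per distinct class it carries
    (a GH13+CBM48 protein contributes to both GH and CBM) and sum to 1
    within each phylum that has at least one CAZyme.

    MAGs with a recorded proteome size of zero are excluded with a warning.
    """
    for a in assignments:
        if a.protein_id not in mag_by_protein:
            raise PepcoverError(
                f"assigned protein {a.protein_id!r} belongs to no known MAG"
            )

    cazymes_per_mag: Counter[str] = Counter()
    class_by_mag: dict[str, Counter[str]] = {}
    for a in assignments:
        mag = mag_by_protein[a.protein_id]
        cazymes_per_mag[mag] += 1
        classes = {family_class(f) for f in a.families}
        class_by_mag.setdefault(mag, Counter()).update(classes)

    mag_rows = []
    for mag, size in sorted(proteome_sizes.items()):
        if size == 0:
            warnings.warn(f"MAG {mag!r} has zero proteins; excluded from census")
            continue
        n_caz = cazymes_per_mag.get(mag, 0)
        mag_rows.append(
            {
                "mag_id": mag,
                "phylum": (taxonomy or {}).get(mag, "NA"),
                "n_proteins": size,
                "n_cazymes": n_caz,
                "pct_cazymes": 100.0 * n_caz / size,
            }
        )
    per_mag = pd.DataFrame(
        mag_rows,
        columns=["mag_id", "phylum", "n_proteins", "n_cazymes", "pct_cazymes"],
    )

    per_phylum = None
    if taxonomy is not None and not per_mag.empty:
        phylum_rows = []
        for phylum, sub in per_mag.groupby("phylum"):
            class_counts: Counter[str] = Counter()
            for mag in sub["mag_id"]:
                class_counts.update(class_by_mag.get(mag, {}))
            total = sum(class_counts.values())
            row = {
                "phylum": phylum,
                "n_mags": len(sub),
                "median_pct": float(sub["pct_cazymes"].median()),
            }
            for cls in CAZYME_CLASSES:
                row[cls] = class_counts.get(cls, 0) / total if total else 0.0
            phylum_rows.append(row)
        per_phylum = pd.DataFrame(phylum_rows).sort_values("phylum", ignore_index=True)

    return CensusReport(per_mag=per_mag, per_phylum=per_phylum)


def split_target_background(
    records: Sequence[ProteinRecord],
    assignments: Sequence[FamilyAssignment],
    family: str,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition a community into target-family proteins and everything else.

    Subfamily suffixes collapse to the family (GH13_20 targets as GH13).
    The background keeps unannotated proteins and members of every other
    family, so peptide uniqueness is judged against the full community.

    Raises
    ------
    EmptyTargetError
        If no protein carries the requested family.
    """
    family = collapse_family(family)
    target_ids = {
        a.protein_id
        for a in assignments
        if family in {collapse_family(f) for f in a.families}
    }
    targets = [r for r in records if r.protein_id in target_ids]
    background = [r for r in records if r.protein_id not in target_ids]
    if not targets:
        raise EmptyTargetError(f"family {family!r} has no annotated proteins")
    return targets, background
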
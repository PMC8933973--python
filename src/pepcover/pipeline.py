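"""End-to-end per-family peptide selection: the composition the CLI and
examples run.

For one target family: partition the community into targets and background,
cluster targets at 100% identity, trim, digest and filter the target side,
digest the background untouched, keep the family-unique peptides, and rank
them by greedy cover.  Stage counts are retained because they are the
numbers a practitioner sanity-checks first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .annotation import FamilyAssignment, split_target_background
from .errors import EmptyPeptidomeError
from .io import ProteinRecord
from .peptides import (
    DEFAULT_EXCLUDED,
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_LEN,
    DEFAULT_TRIM,
    Peptidome,
    background_peptidome,
    dedup_100,
    target_peptidome,
)
from .selection import SelectionResult, greedy_min_cover, unique_target_peptides

__all__ = ["FamilySelection", "select_family"]

logger = logging.getLogger(__name__)


@dataclass
class FamilySelection:
    """Selection result plus the stage counts that produced it."""

    family: str
    result: SelectionResult
    unique: Peptidome
    n_targets: int
    n_seeds: int  # after 100% clustering
    n_filtered_peptides: int
    n_background_peptides: int
    n_unique_peptides: int


def select_family(
    records: Sequence[ProteinRecord],
    assignments: Sequence[FamilyAssignment],
    family: str,
    *,
    trim: int = DEFAULT_TRIM,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    excluded_residues: frozenset[str] = DEFAULT_EXCLUDED,
    il_equivalent: bool = False,
) -> FamilySelection:
    """Run the whole selection for one family.

    The returned result's ``total_target_proteins`` is the seed count (the
    clustered target proteins), so coverage percentages are relative to the
    non-redundant family population.  Raises EmptyPeptidomeError when no
    target peptide survives trimming and filtering; an empty *unique* set is
    not an error — the result simply has no groups and every seed in the
    residual list.
    """
    targets, background = split_target_background(records, assignments, family)
    seeds = dedup_100(targets)
    logger.info(
        "%s: %d target proteins, %d seeds after 100%% clustering, "
        "%d background proteins",
        family,
        len(targets),
        len(seeds),
        len(background),
    )
    target_pep = target_peptidome(
        seeds,
        trim=trim,
        il_equivalent=il_equivalent,
        min_len=min_len,
        max_len=max_len,
        excluded_residues=excluded_residues,
    )
    background_pep = background_peptidome(background, il_equivalent=il_equivalent)
    unique = unique_target_peptides(target_pep, background_pep)
    logger.info(
        "%s: %d filtered target peptides, %d unique after background comparison",
        family,
        len(target_pep),
        len(unique),
    )
    if unique.peptides:
        result = greedy_min_cover(
            unique, family=family, total_target_proteins=len(seeds)
        )
        # seeds whose every peptide was masked by the background
        covered = result.covered_proteins
        result.residual = frozenset(
            s.protein_id for s in seeds if s.protein_id not in covered
        )
    else:
        result = SelectionResult(
            family=family,
            total_target_proteins=len(seeds),
            groups=[],
            residual=frozenset(s.protein_id for s in seeds),
        )
    logger.info(
        "%s: %d peptide groups selected, %d seeds uncovered",
        family,
        len(result.groups),
        len(result.residual),
    )
    return FamilySelection(
        family=family,
        result=result,
        unique=unique,
        n_targets=len(targets),
        n_seeds=len(seeds),
        n_filtered_peptides=len(target_pep),
        n_background_peptides=len(background_pep),
        n_unique_peptides=len(unique),
    )
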
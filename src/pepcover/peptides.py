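"""From protein sequences to filtered tryptic peptidomes.

The target side of the pipeline is: cluster at 100% identity (drop exact
duplicates and contained fragments, as CD-HIT -c 1.0 does), remove the first
24 N-terminal residues as a surrogate for signal-peptide cleavage, digest
with trypsin in silico, and keep peptides of 6-25 residues free of Met and
Cys.  The background is digested as-is — untrimmed and unfiltered — which
makes peptide uniqueness strictly harder to achieve and is therefore the
conservative comparison.

Digestion follows prot2pept semantics: cleave C-terminal to every K or R
that is not immediately followed by P, with zero missed cleavages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import EmptyPeptidomeError, PepcoverError
from .io import ProteinRecord

__all__ = [
    "Peptidome",
    "CANONICAL_RESIDUES",
    "dedup_100",
    "trim_n_terminus",
    "tryptic_digest",
    "filter_peptides",
    "build_peptidome",
    "target_peptidome",
    "background_peptidome",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_TRIM = 24
DEFAULT_MIN_LEN = 6
DEFAULT_MAX_LEN = 25
DEFAULT_EXCLUDED = frozenset("MC")


@dataclass
class Peptidome:
    """Mapping of peptide sequence to the protein ids containing it."""

    peptides: dict[str, frozenset[str]]
    provenance: str = "target"  # "target" | "background"
    filtered: bool = False

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def protein_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for ids in self.peptides.values():
            out |= ids
        return frozenset(out)


def dedup_100(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Remove exact duplicates and contained-fragment sequences.

    A sequence is dropped when it is a contiguous substring of a longer
    retained sequence; the longest member (ties broken by lexicographically
    smallest protein_id) represents each cluster.  This reproduces 100%
    identity clustering as used to discard partial gene calls.
    """
    if not records:
        raise PepcoverError("dedup_100 requires at least one record")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.protein_id))
    retained: list[ProteinRecord] = []
    # "\x00" separators prevent matches spanning two retained sequences.
    blob_parts: list[str] = []
    blob = ""
    for rec in ordered:
        if rec.sequence in blob:
            continue
        retained.append(rec)
        blob_parts.append(rec.sequence)
        blob = "\x00".join(blob_parts)
    retained.sort(key=lambda r: r.protein_id)
    return retained


def trim_n_terminus(seq: str, n: int = DEFAULT_TRIM) -> str:
    """Drop the first ``n`` residues (signal-peptide surrogate).

    Sequences of length <= n return "" and contribute no peptides.
    """
    if n < 0:
        raise ValueError("trim length must be non-negative")
    return seq[n:]


def tryptic_digest(seq: str) -> list[str]:
    """Cleave after every K or R not followed by P; no missed cleavages.

    The concatenation of the output equals the input.
    """
    peptides: list[str] = []
    start = 0
    for i, ch in enumerate(seq):
        if ch in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            peptides.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        peptides.append(seq[start:])
    return peptides


def filter_peptides(
    peptides: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    excluded_residues: frozenset[str] = DEFAULT_EXCLUDED,
) -> list[str]:
    """Keep peptides suitable for targeted MS measurement.

    Retains peptides of min_len..max_len residues built solely from the 20
    canonical amino acids and free of the excluded residues (Met and Cys by
    default, which are prone to artifactual modification).  Peptides with
    ambiguity codes (X/B/Z/U) or stop characters are dropped.
    """
    if min_len <= 0 or max_len < min_len:
        raise ValueError("require 0 < min_len <= max_len")
    allowed = CANONICAL_RESIDUES - excluded_residues
    return [
        p
        for p in peptides
        if min_len <= len(p) <= max_len and set(p) <= allowed
    ]


def _canonical(peptide: str, il_equivalent: bool) -> str:
    # MS cannot distinguish Leu from Ile; the optional equivalence mode
    # folds both onto I so isobaric peptides compare equal.
    return peptide.replace("L", "I") if il_equivalent else peptide


def build_peptidome(
    records: Sequence[ProteinRecord],
    *,
    trim: int | None = None,
    apply_filter: bool = False,
    dedup: bool = False,
    il_equivalent: bool = False,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    excluded_residues: frozenset[str] = DEFAULT_EXCLUDED,
    provenance: str = "target",
) -> Peptidome:
    """Digest every record and union peptide-to-protein memberships.

    Raises
    ------
    EmptyPeptidomeError
        If no peptide survives (e.g. every protein shorter than the trim).
    """
    if not records:
        raise PepcoverError("build_peptidome requires at least one record")
    if dedup:
        records = dedup_100(records)
    mapping: dict[str, set[str]] = {}
    for rec in records:
        seq = trim_n_terminus(rec.sequence, trim) if trim is not None else rec.sequence
        if not seq:
            continue
        peps = tryptic_digest(seq)
        if apply_filter:
            peps = filter_peptides(peps, min_len, max_len, excluded_residues)
        for pep in peps:
            mapping.setdefault(_canonical(pep, il_equivalent), set()).add(
                rec.protein_id
            )
    if not mapping:
        raise EmptyPeptidomeError(
            f"no peptides produced from {len(records)} {provenance} proteins"
        )
    return Peptidome(
        peptides={p: frozenset(ids) for p, ids in mapping.items()},
        provenance=provenance,
        filtered=apply_filter,
    )


def target_peptidome(
    records: Sequence[ProteinRecord],
    *,
    trim: int = DEFAULT_TRIM,
    il_equivalent: bool = False,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    excluded_residues: frozenset[str] = DEFAULT_EXCLUDED,
) -> Peptidome:
    """Target-side build: 100% clustering, N-terminal trim, digest, filter."""
    return build_peptidome(
        records,
        trim=trim,
        apply_filter=True,
        dedup=True,
        il_equivalent=il_equivalent,
        min_len=min_len,
        max_len=max_len,
        excluded_residues=excluded_residues,
        provenance="target",
    )


def background_peptidome(
    records: Sequence[ProteinRecord], *, il_equivalent: bool = False
) -> Peptidome:
    """Background build: digestion only — no clustering, trim or filter."""
    return build_peptidome(
        records,
        il_equivalent=il_equivalent,
        provenance="background",
    )
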
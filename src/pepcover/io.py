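"""Readers and writers for the external files the pipeline touches.

Inputs are per-MAG protein FASTA files (Prodigal-style headers), a dbCAN2
"overview"-style multi-tool CAZyme annotation TSV, a GhostKOALA-style EC
table and a MAG-to-phylum taxonomy table.  Output is the ranked selection
table (one row per selected peptide group).

All TSVs are tab-separated UTF-8 with "\\n" line endings and no quoting.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DuplicateIdError, FastaParseError, PepcoverError, SchemaError

__all__ = [
    "ProteinRecord",
    "ToolAnnotationRow",
    "read_fasta",
    "write_fasta",
    "read_fasta_dir",
    "read_tool_annotations",
    "read_taxonomy",
    "read_ec_table",
    "write_selection_table",
    "read_selection_table",
    "FAMILY_RE",
    "EC_RE",
]

# CAZy naming grammar: class prefix + optional number + optional subfamily.
FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM|SLH|cohesin)\d*(_\d+)?$")

# EC numbers, dash wildcards allowed in any position after the first.
EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence tied to its MAG of origin."""

    protein_id: str
    mag_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise PepcoverError(f"empty sequence for protein {self.protein_id!r}")


@dataclass(frozen=True)
class ToolAnnotationRow:
    """Per-protein family labels from the three dbCAN2 search tools.

    Empty frozensets mean "no annotation from that tool".
    """

    protein_id: str
    hmmer: frozenset[str]
    diamond: frozenset[str]
    hotpep: frozenset[str]

    @property
    def n_tools(self) -> int:
        return sum(bool(s) for s in (self.hmmer, self.diamond, self.hotpep))


def _clean_sequence(raw: str, protein_id: str) -> str:
    # Prodigal emits a trailing "*"; strip stop characters from the ends.
    seq = raw.upper().strip("*")
    if not seq:
        raise FastaParseError(f"protein {protein_id!r} has an empty sequence")
    return seq


def read_fasta(path: str | Path, mag_id: str) -> list[ProteinRecord]:
    """Parse one per-MAG protein FASTA file.

    The protein_id is the first whitespace-delimited header token; the rest
    of the header (Prodigal coordinates etc.) is discarded.  Sequences are
    uppercased and terminal "*" stop characters removed.

    Raises
    ------
    FastaParseError
        If sequence data precedes the first header (the line number is
        reported) or an entry is empty.
    DuplicateIdError
        If two entries share a protein_id.
    """
    path = Path(path)
    # Light grammar pre-check so the error can name a line number; Biopython's
    # parser is lenient about leading junk.
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    "sequence data before first FASTA header", line=lineno
                )
            break

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id  # first whitespace-delimited token
        if pid in seen:
            raise DuplicateIdError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        records.append(
            ProteinRecord(pid, mag_id, _clean_sequence(str(entry.seq), pid))
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as protein FASTA (60-column wrapping)."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="")
        for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(entries, fh, "fasta")


def read_fasta_dir(directory: str | Path, suffix: str = ".faa") -> list[ProteinRecord]:
    """Load every per-MAG FASTA in a directory; the file stem is the MAG id.

    Protein ids must be unique across the whole community.
    """
    directory = Path(directory)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for path in sorted(directory.glob(f"*{suffix}")):
        for rec in read_fasta(path, mag_id=path.stem):
            if rec.protein_id in seen:
                raise DuplicateIdError(
                    f"protein id {rec.protein_id!r} appears in more than one MAG"
                )
            seen.add(rec.protein_id)
            records.append(rec)
    return records


_NO_ANNOTATION = {"", "-", "N", "N/A"}


def _parse_family_cell(cell: str, column: str) -> frozenset[str]:
    """Split a dbCAN2 tool cell into family labels.

    Multi-domain hits are "+"-joined; HMMER appends "(start-end)" coordinate
    suffixes which are stripped.  "-" and empty both mean no annotation.
    """
    cell = cell.strip()
    if cell in _NO_ANNOTATION:
        return frozenset()
    labels = set()
    for token in cell.split("+"):
        token = re.sub(r"\(.*\)$", "", token.strip())
        if not token or token == "-":
            continue
        if not FAMILY_RE.match(token):
            raise SchemaError(
                f"family label {token!r} in column {column!r} does not match "
                "the CAZy naming grammar"
            )
        labels.add(token)
    return frozenset(labels)


def read_tool_annotations(path: str | Path) -> list[ToolAnnotationRow]:
    """Parse a dbCAN2 overview-style TSV.

    The header must contain (case-insensitively) one column per tool —
    HMMER, DIAMOND and Hotpep — with the protein id in the first column.
    """
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"annotation table {path} is empty") from None
        lower = [h.strip().lower() for h in header]
        cols: dict[str, int] = {}
        for tool in ("hmmer", "diamond", "hotpep"):
            hits = [i for i, h in enumerate(lower) if tool in h]
            if not hits:
                raise SchemaError(
                    f"annotation table {path} lacks a {tool.upper()} column"
                )
            cols[tool] = hits[0]
        rows: list[ToolAnnotationRow] = []
        for fields in reader:
            if not fields or not fields[0].strip():
                continue
            rows.append(
                ToolAnnotationRow(
                    protein_id=fields[0].strip(),
                    hmmer=_parse_family_cell(fields[cols["hmmer"]], "HMMER"),
                    diamond=_parse_family_cell(fields[cols["diamond"]], "DIAMOND"),
                    hotpep=_parse_family_cell(fields[cols["hotpep"]], "Hotpep"),
                )
            )
    return rows


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a MAG-to-phylum TSV (columns: mag_id, phylum). "NA" = unassigned."""
    taxonomy: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise SchemaError(f"taxonomy table {path} needs mag_id and phylum columns")
        for fields in reader:
            if not fields or not fields[0].strip():
                continue
            mag = fields[0].strip()
            if mag in taxonomy:
                raise SchemaError(f"duplicate mag_id {mag!r} in taxonomy table")
            phylum = fields[1].strip() or "NA"
            taxonomy[mag] = phylum
    return taxonomy


def read_ec_table(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a GhostKOALA-style EC table (columns: protein_id, EC numbers).

    EC numbers may be ";" or ","-separated; "N/A", "-" or an empty cell mean
    no annotation (stored as an empty tuple).
    """
    table: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise SchemaError(f"EC table {path} is empty")
        for fields in reader:
            if not fields or not fields[0].strip():
                continue
            pid = fields[0].strip()
            cell = fields[1].strip() if len(fields) > 1 else ""
            if cell in _NO_ANNOTATION:
                table[pid] = ()
                continue
            ecs = []
            for token in re.split(r"[;,]", cell):
                token = token.strip()
                if not token:
                    continue
                if not EC_RE.match(token):
                    raise SchemaError(f"malformed EC number {token!r} for {pid!r}")
                ecs.append(token)
            table[pid] = tuple(sorted(set(ecs)))
    return table


_SELECTION_COLUMNS = ["rank", "peptide", "n_proteins", "protein_ids", "ec_set", "phylum_set"]


def write_selection_table(
    result,
    path: str | Path,
    *,
    ec_table: Mapping[str, Sequence[str]] | None = None,
    taxonomy: Mapping[str, str] | None = None,
    mag_by_protein: Mapping[str, str] | None = None,
) -> None:
    """Write a ranked selection as a TSV.

    Columns: rank, peptide, n_proteins, protein_ids (semicolon-joined,
    sorted), ec_set, phylum_set.  Proteins lacking an EC annotation (or when
    no EC table is supplied) contribute "N/A"; MAGs absent from the taxonomy
    contribute "NA".
    """
    if not result.groups:
        raise PepcoverError("refusing to write an empty selection table")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_SELECTION_COLUMNS) + "\n")
        for group in result.groups:
            ids = sorted(group.covered)
            ecs: set[str] = set()
            phyla: set[str] = set()
            for pid in ids:
                annotated = tuple(ec_table.get(pid, ())) if ec_table else ()
                ecs.update(annotated if annotated else ("N/A",))
                if mag_by_protein is not None and taxonomy is not None:
                    phyla.add(taxonomy.get(mag_by_protein.get(pid, ""), "NA"))
                else:
                    phyla.add("NA")
            fh.write(
                "\t".join(
                    [
                        str(group.rank),
                        group.peptide,
                        str(len(ids)),
                        ";".join(ids),
                        ";".join(sorted(ecs)),
                        ";".join(sorted(phyla)),
                    ]
                )
                + "\n"
            )


def read_selection_table(path: str | Path) -> list[dict]:
    """Read back a selection table written by :func:`write_selection_table`."""
    rows: list[dict] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _SELECTION_COLUMNS:
            raise SchemaError(f"unexpected selection-table header in {path}")
        for row in reader:
            rows.append(
                {
                    "rank": int(row["rank"]),
                    "peptide": row["peptide"],
                    "n_proteins": int(row["n_proteins"]),
                    "protein_ids": frozenset(row["protein_ids"].split(";")),
                    "ec_set": frozenset(row["ec_set"].split(";")),
                    "phylum_set": frozenset(row["phylum_set"].split(";")),
                }
            )
    return rows
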
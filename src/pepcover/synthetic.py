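"""Parameterized mock MAG community with planted family-shared peptides.

The generator emulates the structure the pipeline exploits in real data:
members of an enzyme family share conserved sequence blocks — hence shared
tryptic peptides — against a background of unrelated proteins.  Each family
gets one or more planted blocks constructed so that trypsin releases them
intact (flanked by cleavage-compatible residues) and so that they pass the
6-25 residue / no-Met/Cys filter.  Blocks are inserted, never substituted,
at positions beyond residue 24, so the N-terminal trim cannot delete them.
A ``decoy_rate`` optionally copies planted blocks into background proteins,
destroying their family uniqueness in a controlled way.

Everything is reproducible from the spec's seed; the on-disk output uses
exactly the formats the io module reads.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import SpecValidationError
from .io import ProteinRecord, ToolAnnotationRow, write_fasta
from .selection import SelectionResult

__all__ = [
    "FamilySpec",
    "CommunitySpec",
    "TruthManifest",
    "SyntheticCommunity",
    "simulate_community",
    "verify_recovery",
    "RecoveryReport",
    "DEFAULT_RESIDUE_FREQS",
]

# Approximate natural amino-acid abundances; K+R ~ 11% gives a mean tryptic
# peptide length of about 9 residues, as in real proteomes.
DEFAULT_RESIDUE_FREQS: dict[str, float] = {
    "A": 0.083, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.014,
    "Q": 0.039, "E": 0.068, "G": 0.071, "H": 0.023, "I": 0.060,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.069,
}

# Residues allowed inside a planted block body: no K/R (would be cleaved),
# no P (could suppress flanking cleavage), no M/C (filter would drop it).
_BLOCK_BODY = "ADEFGHILNQSTVWY"


@dataclass(frozen=True)
class FamilySpec:
    """One planted enzyme family.

    ``n_members`` places that many member proteins on randomly chosen MAGs;
    alternatively ``members_per_mag`` draws a uniform count per MAG.
    Exactly one of the two must be given.
    """

    family: str
    n_members: int | None = 20
    members_per_mag: tuple[int, int] | None = None
    n_planted_blocks: int = 1
    ec_numbers: tuple[str, ...] = ()


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a simulated MAG community."""

    n_mags: int = 50
    phyla: tuple[tuple[str, float], ...] = (
        ("Firmicutes", 0.5),
        ("Bacteroidetes", 0.3),
        ("Proteobacteria", 0.2),
    )
    families: tuple[FamilySpec, ...] = (
        FamilySpec("GH13", ec_numbers=("3.2.1.1",)),
        FamilySpec("GH3", ec_numbers=("3.2.1.21",)),
        FamilySpec("GH2", ec_numbers=("3.2.1.23",)),
    )
    background_proteins_per_mag: tuple[int, int] = (30, 60)
    protein_length: tuple[int, int] = (120, 400)
    residue_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_FREQS)
    )
    block_length: tuple[int, int] = (8, 14)
    # With several planted blocks per family, each member carries each block
    # with this probability (always at least one), so coverage is partial
    # and the greedy cover has non-trivial structure.
    block_share: float = 0.6
    decoy_rate: float = 0.0
    # Fraction of family members annotated by one tool only, which the
    # consensus rule must discard.
    single_tool_fraction: float = 0.0
    # Fraction of background proteins given a non-target CAZyme annotation.
    background_cazyme_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_mags <= 0:
            raise SpecValidationError("must be positive", field="n_mags")
        if abs(sum(p for _, p in self.phyla) - 1.0) > 1e-9:
            raise SpecValidationError("proportions must sum to 1", field="phyla")
        if self.protein_length[0] <= 0 or self.protein_length[0] > self.protein_length[1]:
            raise SpecValidationError("invalid range", field="protein_length")
        if self.block_length[0] < 6 or self.block_length[1] > 25:
            raise SpecValidationError(
                "planted blocks must satisfy the 6-25 residue filter",
                field="block_length",
            )
        # +2 for the flanking guard residues added at insertion time
        if self.block_length[1] + 2 > self.protein_length[0]:
            raise SpecValidationError(
                "block longer than the shortest protein", field="block_length"
            )
        if self.protein_length[0] < 26:
            raise SpecValidationError(
                "proteins must be long enough to carry a block beyond the "
                "24-residue trim",
                field="protein_length",
            )
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise SpecValidationError("must be in [0, 1]", field="decoy_rate")
        if not 0.0 <= self.block_share <= 1.0:
            raise SpecValidationError("must be in [0, 1]", field="block_share")
        if not 0.0 <= self.single_tool_fraction <= 1.0:
            raise SpecValidationError("must be in [0, 1]", field="single_tool_fraction")
        for fam in self.families:
            if (fam.n_members is None) == (fam.members_per_mag is None):
                raise SpecValidationError(
                    f"family {fam.family}: give exactly one of n_members / "
                    "members_per_mag",
                    field="families",
                )
            if fam.n_planted_blocks <= 0:
                raise SpecValidationError(
                    f"family {fam.family}: n_planted_blocks must be positive",
                    field="families",
                )


@dataclass
class TruthManifest:
    """Ground truth of a simulated community.

    ``planted`` maps each planted peptide to its intended family and member
    protein ids; ``decoys`` lists (peptide, background protein id) placements
    that break a peptide's uniqueness.
    """

    planted: dict[str, tuple[str, frozenset[str]]]
    decoys: list[tuple[str, str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": {
                    pep: {"family": fam, "members": sorted(ids)}
                    for pep, (fam, ids) in sorted(self.planted.items())
                },
                "decoys": sorted(self.decoys),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        data = json.loads(text)
        return cls(
            planted={
                pep: (entry["family"], frozenset(entry["members"]))
                for pep, entry in data["planted"].items()
            },
            decoys=[tuple(d) for d in data["decoys"]],
        )


@dataclass
class SyntheticCommunity:
    spec: CommunitySpec
    records: list[ProteinRecord]
    annotation_rows: list[ToolAnnotationRow]
    taxonomy: dict[str, str]
    ec_table: dict[str, tuple[str, ...]]
    manifest: TruthManifest

    @property
    def mag_by_protein(self) -> dict[str, str]:
        return {r.protein_id: r.mag_id for r in self.records}

    @property
    def proteome_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for r in self.records:
            sizes[r.mag_id] = sizes.get(r.mag_id, 0) + 1
        return sizes


def _random_sequence(rng: random.Random, length: int, residues: str, weights: list[float]) -> str:
    return "".join(rng.choices(residues, weights=weights, k=length))


def _make_block(rng: random.Random, lo: int, hi: int, taken: set[str]) -> str:
    """A tryptic-release-ready conserved block: body of safe residues ending
    in K or R; unique among already-drawn blocks."""
    while True:
        length = rng.randint(lo, hi)
        body = "".join(rng.choice(_BLOCK_BODY) for _ in range(length - 1))
        block = body + rng.choice("KR")
        if block not in taken:
            taken.add(block)
            return block


def _insert_block(rng: random.Random, seq: str, block: str, min_pos: int) -> str:
    """Insert "R" + block + "A" at a random position past ``min_pos``.

    The guard R guarantees cleavage immediately before the block (the block
    never starts with P) and the trailing A guarantees cleavage right after
    its terminal K/R, so digestion releases the block intact.
    """
    pos = rng.randint(min_pos, len(seq))
    return seq[:pos] + "R" + block + "A" + seq[pos:]


def simulate_community(
    spec: CommunitySpec, out_dir: str | Path | None = None
) -> SyntheticCommunity:
    """Generate a community; optionally write it to disk.

    When ``out_dir`` is given the layout is::

        out_dir/proteomes/<mag_id>.faa
        out_dir/annotations.tsv     (dbCAN2 overview style)
        out_dir/taxonomy.tsv
        out_dir/ec.tsv
        out_dir/truth_manifest.json

    Identical specs (same seed) produce byte-identical trees.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    residues = "".join(sorted(spec.residue_freqs))
    weights = [spec.residue_freqs[r] for r in residues]

    mags = [f"MAG{i:04d}" for i in range(1, spec.n_mags + 1)]
    # Deterministic phylum allocation: largest-remainder on the proportions.
    taxonomy: dict[str, str] = {}
    counts = []
    for name, prop in spec.phyla:
        counts.append([name, int(prop * spec.n_mags), prop * spec.n_mags])
    while sum(c[1] for c in counts) < spec.n_mags:
        counts.sort(key=lambda c: c[2] - c[1], reverse=True)
        counts[0][1] += 1
    pool = [name for name, n, _ in counts for _ in range(n)]
    rng.shuffle(pool)
    for mag, phylum in zip(mags, pool):
        taxonomy[mag] = phylum

    records: list[ProteinRecord] = []
    annotation_rows: list[ToolAnnotationRow] = []
    ec_table: dict[str, tuple[str, ...]] = {}
    planted: dict[str, tuple[str, set[str]]] = {}
    decoys: list[tuple[str, str]] = []
    taken_blocks: set[str] = set()
    serial = 0

    def next_id(mag: str) -> str:
        nonlocal serial
        serial += 1
        return f"{mag}_p{serial:06d}"

    # --- family members -------------------------------------------------
    for fam in spec.families:
        blocks = [
            _make_block(rng, *spec.block_length, taken_blocks)
            for _ in range(fam.n_planted_blocks)
        ]
        for b in blocks:
            planted[b] = (fam.family, set())
        member_mags: list[str] = []
        if fam.n_members is not None:
            member_mags = [rng.choice(mags) for _ in range(fam.n_members)]
        else:
            lo, hi = fam.members_per_mag  # type: ignore[misc]
            for mag in mags:
                member_mags.extend([mag] * rng.randint(lo, hi))
        for mag in member_mags:
            pid = next_id(mag)
            seq = _random_sequence(
                rng, rng.randint(*spec.protein_length), residues, weights
            )
            if len(blocks) == 1:
                carried = blocks
            else:
                carried = [b for b in blocks if rng.random() < spec.block_share]
                if not carried:
                    carried = [rng.choice(blocks)]
            for b in carried:
                seq = _insert_block(rng, seq, b, min_pos=25)
                planted[b][1].add(pid)
            records.append(ProteinRecord(pid, mag, seq))
            if rng.random() < spec.single_tool_fraction:
                annotation_rows.append(
                    ToolAnnotationRow(pid, frozenset({fam.family}), frozenset(), frozenset())
                )
            else:
                annotation_rows.append(
                    ToolAnnotationRow(
                        pid,
                        frozenset({fam.family}),
                        frozenset({fam.family}),
                        frozenset(),
                    )
                )
            if fam.ec_numbers:
                ec_table[pid] = tuple(sorted(fam.ec_numbers))

    # --- background -----------------------------------------------------
    other_families = ("GT2", "GT4", "CE1", "CBM48", "PL1", "AA3")
    background_ids: list[str] = []
    for mag in mags:
        for _ in range(rng.randint(*spec.background_proteins_per_mag)):
            pid = next_id(mag)
            seq = _random_sequence(
                rng, rng.randint(*spec.protein_length), residues, weights
            )
            records.append(ProteinRecord(pid, mag, seq))
            background_ids.append(pid)
            if rng.random() < spec.background_cazyme_rate:
                fam_label = rng.choice(other_families)
                annotation_rows.append(
                    ToolAnnotationRow(
                        pid,
                        frozenset({fam_label}),
                        frozenset({fam_label}),
                        frozenset(),
                    )
                )

    # --- decoys ---------------------------------------------------------
    index_by_id = {r.protein_id: i for i, r in enumerate(records)}
    for block in sorted(planted):
        if rng.random() < spec.decoy_rate:
            pid = rng.choice(background_ids)
            i = index_by_id[pid]
            host = records[i]
            new_seq = _insert_block(rng, host.sequence, block, min_pos=1)
            records[i] = ProteinRecord(pid, host.mag_id, new_seq)
            decoys.append((block, pid))

    manifest = TruthManifest(
        planted={b: (fam, frozenset(ids)) for b, (fam, ids) in planted.items()},
        decoys=decoys,
    )
    community = SyntheticCommunity(
        spec=spec,
        records=records,
        annotation_rows=annotation_rows,
        taxonomy=taxonomy,
        ec_table=ec_table,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_community(community, Path(out_dir))
    return community


def _write_community(community: SyntheticCommunity, out_dir: Path) -> None:
    proteome_dir = out_dir / "proteomes"
    proteome_dir.mkdir(parents=True, exist_ok=True)
    by_mag: dict[str, list[ProteinRecord]] = {}
    for rec in community.records:
        by_mag.setdefault(rec.mag_id, []).append(rec)
    for mag in sorted(by_mag):
        write_fasta(by_mag[mag], proteome_dir / f"{mag}.faa")
    with open(out_dir / "annotations.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("Gene ID\tHMMER\tDIAMOND\tHotpep\n")
        for row in sorted(community.annotation_rows, key=lambda r: r.protein_id):
            cells = [
                "+".join(sorted(s)) if s else "-"
                for s in (row.hmmer, row.diamond, row.hotpep)
            ]
            fh.write("\t".join([row.protein_id, *cells]) + "\n")
    with open(out_dir / "taxonomy.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mag_id\tphylum\n")
        for mag in sorted(community.taxonomy):
            fh.write(f"{mag}\t{community.taxonomy[mag]}\n")
    with open(out_dir / "ec.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\tec_numbers\n")
        for pid in sorted(community.ec_table):
            ecs = community.ec_table[pid]
            fh.write(f"{pid}\t{';'.join(ecs) if ecs else 'N/A'}\n")
    with open(out_dir / "truth_manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(community.manifest.to_json() + "\n")


@dataclass
class RecoveryReport:
    """How well a selection recovered the planted ground truth."""

    recall: float  # planted-and-selected / planted-and-unique
    precision: float  # selected-and-planted / selected
    per_family: dict[str, dict]
    uncovered_planted_members: frozenset[str]


def verify_recovery(
    manifest: TruthManifest,
    results: Mapping[str, SelectionResult],
) -> RecoveryReport:
    """Score selections from a simulated community against its ground truth.

    A planted peptide counts as expected ("planted-and-unique") when no
    decoy placement destroyed its uniqueness.  Per-family coverage is the
    fraction of intended members appearing in some covered set.
    """
    decoyed = {pep for pep, _ in manifest.decoys}
    selected_by_family: dict[str, set[str]] = {
        fam: {g.peptide for g in res.groups} for fam, res in results.items()
    }
    all_selected = set().union(*selected_by_family.values()) if selected_by_family else set()

    expected = {
        pep
        for pep, (fam, _) in manifest.planted.items()
        if pep not in decoyed and fam in results
    }
    recovered = {pep for pep in expected if pep in all_selected}
    recall = len(recovered) / len(expected) if expected else 1.0
    precision = (
        len(all_selected & set(manifest.planted)) / len(all_selected)
        if all_selected
        else 1.0
    )

    per_family: dict[str, dict] = {}
    uncovered: set[str] = set()
    for fam, res in results.items():
        fam_planted = {
            pep: ids for pep, (f, ids) in manifest.planted.items() if f == fam
        }
        members = set().union(*fam_planted.values()) if fam_planted else set()
        covered = set(res.covered_proteins)
        missing = members - covered
        uncovered |= missing
        fam_expected = {p for p in fam_planted if p not in decoyed}
        per_family[fam] = {
            "n_selected": len(res.groups),
            "planted_expected": len(fam_expected),
            "planted_recovered": len(fam_expected & selected_by_family[fam]),
            "member_coverage": (
                len(members & covered) / len(members) if members else 1.0
            ),
            "uncovered_members": frozenset(missing),
        }
    return RecoveryReport(
        recall=recall,
        precision=precision,
        per_family=per_family,
        uncovered_planted_members=frozenset(uncovered),
    )
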
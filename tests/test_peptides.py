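import re

import pytest
from hypothesis import given, strategies as st

from pepcover import (
    EmptyPeptidomeError,
    ProteinRecord,
    background_peptidome,
    build_peptidome,
    dedup_100,
    filter_peptides,
    target_peptidome,
    trim_n_terminus,
    tryptic_digest,
)

AMINO = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AMINO, min_size=1, max_size=200)


def rec(pid, seq):
    return ProteinRecord(pid, "m1", seq)


class TestDedup100:
    def test_exact_duplicates_collapse_to_one(self):
        out = dedup_100([rec("p1", "ABCDEF"), rec("p2", "ABCDEF")])
        assert [r.protein_id for r in out] == ["p1"]  # smallest id represents

    def test_contained_fragment_removed(self):
        # frozen expected value cross-checked once against CD-HIT -c 1.0
        out = dedup_100([rec("p1", "ABCDEFGH"), rec("p2", "CDEF")])
        assert [r.protein_id for r in out] == ["p1"]

    def test_unrelated_sequences_both_retained(self):
        out = dedup_100([rec("p1", "AAAA"), rec("p2", "TTTT")])
        assert {r.protein_id for r in out} == {"p1", "p2"}

    @given(st.lists(st.text(alphabet="ACDG", min_size=1, max_size=12), min_size=1, max_size=8))
    def test_removed_sequences_are_substrings_of_retained(self, seqs):
        records = [rec(f"p{i}", s) for i, s in enumerate(seqs)]
        retained = dedup_100(records)
        kept_seqs = [r.sequence for r in retained]
        for r in records:
            if r.protein_id not in {k.protein_id for k in retained}:
                assert any(r.sequence in k for k in kept_seqs)


class TestTrim:
    def test_default_removes_first_24(self):
        seq = "M" * 24 + "TAILSS"
        assert trim_n_terminus(seq) == "TAILSS"

    def test_zero_is_identity(self):
        assert trim_n_terminus("PEPTIDE", 0) == "PEPTIDE"

    def test_short_sequence_becomes_empty(self):
        assert trim_n_terminus("A" * 10, 24) == ""


class TestDigest:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AAAKGGGRTTT", ["AAAK", "GGGR", "TTT"]),
            ("AAAKPGGG", ["AAAKPGGG"]),  # proline suppresses cleavage
            ("R", ["R"]),
            ("KRK", ["K", "R", "K"]),
            ("", []),
        ],
    )
    def test_examples(self, seq, expected):
        assert tryptic_digest(seq) == expected

    @given(sequences)
    def test_concatenation_reproduces_input(self, seq):
        assert "".join(tryptic_digest(seq)) == seq

    @given(sequences)
    def test_idempotent_on_emitted_peptides(self, seq):
        for pep in tryptic_digest(seq):
            assert tryptic_digest(pep) == [pep]

    @given(sequences)
    def test_matches_regex_oracle(self, seq):
        oracle = [p for p in re.split(r"(?<=[KR])(?!P)", seq) if p]
        assert tryptic_digest(seq) == oracle


class TestFilter:
    def test_each_rule_fires(self):
        peps = ["AAAK", "GGGGGR", "MAAAAK", "A" * 26]
        assert filter_peptides(peps) == ["GGGGGR"]

    def test_ambiguous_residues_dropped(self):
        assert filter_peptides(["AAXAAK"]) == []

    def test_empty_input(self):
        assert filter_peptides([]) == []

    @given(st.lists(st.text(alphabet=AMINO + "XBZU", min_size=1, max_size=30), max_size=30))
    def test_filtered_is_subset(self, peps):
        assert set(filter_peptides(peps)) <= set(peps)

    def test_bad_bounds_raise(self):
        with pytest.raises(ValueError):
            filter_peptides(["AAAAAA"], min_len=10, max_len=5)


class TestBuildPeptidome:
    def test_trim_and_filter_composition(self):
        records = [rec("p1", "A" * 24 + "GGGGGGK")]
        pep = build_peptidome(records, trim=24, apply_filter=True)
        assert pep.peptides == {"GGGGGGK": frozenset({"p1"})}

    def test_shared_block_maps_to_both_proteins(self):
        records = [
            rec("p1", "AAAK" + "GGPEPTIDEGGK" + "GGG"),
            rec("p2", "TTTR" + "GGPEPTIDEGGK" + "WWW"),
        ]
        pep = build_peptidome(records)
        assert pep.peptides["GGPEPTIDEGGK"] == frozenset({"p1", "p2"})

    def test_background_build_keeps_short_and_modified_peptides(self):
        records = [rec("p1", "MKCR")]  # 2-residue peptides with Met/Cys
        pep = background_peptidome(records)
        assert "MK" in pep.peptides and "CR" in pep.peptides
        assert pep.filtered is False

    def test_all_proteins_shorter_than_trim_raises(self):
        with pytest.raises(EmptyPeptidomeError):
            build_peptidome([rec("p1", "A" * 10)], trim=24)

    def test_target_build_filters(self):
        records = [rec("p1", "A" * 24 + "GGGGGGK" + "MAAAAK")]
        pep = target_peptidome(records)
        assert set(pep.peptides) == {"GGGGGGK"}
        assert pep.filtered is True

    def test_il_equivalence_folds_leucine(self):
        records = [rec("p1", "LLLGGGK"), rec("p2", "ILLGGGK")]
        pep = build_peptidome(records, il_equivalent=True)
        assert pep.peptides == {"IIIGGGK": frozenset({"p1", "p2"})}

    @given(st.lists(sequences, min_size=1, max_size=6))
    def test_filtered_peptidome_subset_of_raw(self, seqs):
        records = [rec(f"p{i}", s) for i, s in enumerate(seqs)]
        raw = build_peptidome(records)
        try:
            filtered = build_peptidome(records, apply_filter=True)
        except EmptyPeptidomeError:
            return
        assert set(filtered.peptides) <= set(raw.peptides)
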
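import random

import pytest
from hypothesis import given, strategies as st

from pepcover import (
    InstanceTooLargeError,
    Peptidome,
    brute_force_min_cover,
    coverage_curve,
    greedy_min_cover,
    group_by_ec,
    group_by_phylum,
    peptides_to_cover_taxon,
    unique_target_peptides,
)


def peptidome(mapping, **kw):
    return Peptidome({p: frozenset(ids) for p, ids in mapping.items()}, **kw)


class TestUnique:
    def test_background_occurrence_removes_peptide(self):
        target = peptidome({"PEPTIDER": {"p1", "p2"}}, filtered=True)
        background = peptidome({"PEPTIDER": {"b1"}}, provenance="background")
        assert unique_target_peptides(target, background).peptides == {}

    def test_disjoint_peptidomes_unchanged(self):
        target = peptidome({"AAAAGGK": {"p1"}}, filtered=True)
        background = peptidome({"TTTTGGK": {"b1"}}, provenance="background")
        assert unique_target_peptides(target, background).peptides == target.peptides

    def test_only_exact_peptide_match_removes(self):
        # the background protein contains the same residues in a different
        # tryptic context, so its peptides differ and uniqueness survives
        target = peptidome({"AAAGGGK": {"p1"}}, filtered=True)
        background = peptidome({"AAAGGGKTTTR": {"b1"}}, provenance="background")
        kept = unique_target_peptides(target, background)
        assert "AAAGGGK" in kept.peptides


class TestGreedyWorkedExample:
    def test_selection_order_and_sizes(self, worked_example):
        result = greedy_min_cover(worked_example)
        assert [g.peptide for g in result.groups] == ["PEP1", "PEP5", "PEP3"]
        assert [len(g.covered) for g in result.groups] == [4, 2, 1]
        assert result.groups[0].covered == frozenset("ADEF")
        assert result.groups[1].covered == frozenset("CG")
        assert result.groups[2].covered == frozenset("B")
        assert result.covered_proteins == frozenset("ABCDEFG")

    def test_brute_force_optimum_is_three(self, worked_example):
        assert brute_force_min_cover(worked_example) == 3

    def test_single_peptide_covering_everything(self):
        result = greedy_min_cover(peptidome({"AAAAGGK": {"p1", "p2", "p3"}}))
        assert len(result.groups) == 1

    def test_one_peptide_per_protein_needs_n(self):
        unique = peptidome({f"PEP{i}": {f"p{i}"} for i in range(5)})
        assert brute_force_min_cover(unique) == 5
        assert len(greedy_min_cover(unique).groups) == 5

    def test_brute_force_refuses_large_instances(self):
        unique = peptidome({f"PEP{i:02d}": {f"p{i}"} for i in range(20)})
        with pytest.raises(InstanceTooLargeError):
            brute_force_min_cover(unique)


def random_instance(rng, max_peptides=12, max_proteins=15):
    n_pep = rng.randint(1, max_peptides)
    n_prot = rng.randint(1, max_proteins)
    proteins = [f"p{i}" for i in range(n_prot)]
    mapping = {}
    for i in range(n_pep):
        k = rng.randint(1, n_prot)
        mapping[f"PEP{i:02d}"] = frozenset(rng.sample(proteins, k))
    return Peptidome(mapping)


class TestGreedyProperties:
    N_INSTANCES = 60

    def test_invariants_and_per_step_oracle(self):
        rng = random.Random(42)
        for _ in range(self.N_INSTANCES):
            inst = random_instance(rng)
            result = greedy_min_cover(inst)
            sizes = [len(g.covered) for g in result.groups]
            assert sizes == sorted(sizes, reverse=True)
            seen = set()
            remaining = {p: set(ids) for p, ids in inst.peptides.items()}
            for g in result.groups:
                assert not (g.covered & seen)  # disjoint
                # per-step oracle: no remaining peptide covers more
                best = max(len(ids - seen) for ids in remaining.values())
                assert len(g.covered) == best
                seen |= g.covered
            assert seen == inst.protein_ids  # completeness

    def test_greedy_never_beats_exhaustive_optimum(self):
        rng = random.Random(43)
        for _ in range(self.N_INSTANCES):
            inst = random_instance(rng)
            assert len(greedy_min_cover(inst).groups) >= brute_force_min_cover(inst)

    def test_order_invariance(self):
        rng = random.Random(44)
        inst = random_instance(rng)
        result = greedy_min_cover(inst)
        items = list(inst.peptides.items())
        rng.shuffle(items)
        shuffled = Peptidome(dict(items))
        assert greedy_min_cover(shuffled).groups == result.groups


class TestCoverageCurve:
    def test_worked_example_arithmetic(self, worked_example):
        result = greedy_min_cover(worked_example)
        curve = coverage_curve(result, cutoffs=[1, 2, 3])
        assert curve.points[0] == (1, pytest.approx(100 * 4 / 7))
        assert curve.points[0][1] == pytest.approx(57.14, abs=0.01)
        assert curve.points[2] == (3, pytest.approx(100.0))

    def test_cutoff_beyond_groups_equals_final_coverage(self, worked_example):
        result = greedy_min_cover(worked_example)
        curve = coverage_curve(result, cutoffs=[200])
        assert curve.points[0][1] == pytest.approx(100.0)

    def test_empty_selection_is_zero_everywhere(self):
        from pepcover import SelectionResult

        empty = SelectionResult(family="GH13", total_target_proteins=0, groups=[])
        assert all(pct == 0.0 for _, pct in coverage_curve(empty).points)

    def test_nonpositive_cutoff_rejected(self, worked_example):
        result = greedy_min_cover(worked_example)
        with pytest.raises(ValueError):
            coverage_curve(result, cutoffs=[0])


class TestGroupings:
    @pytest.fixture
    def result(self):
        unique = peptidome(
            {
                "AAAAGGK": {"p1", "p2"},
                "DDDDGGK": {"p3", "p4"},
                "EEEEGGK": {"p5"},
            }
        )
        return greedy_min_cover(unique)

    def test_ec_single_activity_key(self, result):
        ec = {pid: ("3.2.1.23",) for pid in ("p1", "p2", "p3", "p4", "p5")}
        groups = group_by_ec(result, ec)
        assert groups == {frozenset({"3.2.1.23"}): (3, 5)}

    def test_ec_composite_key(self, result):
        ec = {"p1": ("3.2.1.54",), "p2": ("3.2.1.135",)}
        groups = group_by_ec(result, ec)
        assert frozenset({"3.2.1.54", "3.2.1.135"}) in groups
        assert groups[frozenset({"N/A"})] == (2, 3)  # p3..p5 unannotated

    def test_no_ec_table_single_na_key(self, result):
        assert set(group_by_ec(result, None)) == {frozenset({"N/A"})}

    def test_phylum_composition_and_specific_flag(self, result):
        mag_by_protein = {f"p{i}": f"m{i}" for i in range(1, 6)}
        taxonomy = {
            "m1": "Firmicutes",
            "m2": "Firmicutes",
            "m3": "Firmicutes",
            "m4": "Bacteroidetes",
            # m5 unannotated -> NA bucket
        }
        comp = group_by_phylum(result, taxonomy, mag_by_protein)
        by_pep = {c["peptide"]: c for c in comp}
        assert by_pep["AAAAGGK"]["composition"] == {"Firmicutes": 2}
        assert by_pep["AAAAGGK"]["taxon_specific"]
        assert by_pep["DDDDGGK"]["composition"] == {
            "Firmicutes": 1,
            "Bacteroidetes": 1,
        }
        assert not by_pep["DDDDGGK"]["taxon_specific"]
        assert by_pep["EEEEGGK"]["composition"] == {"NA": 1}


class TestPeptidesToCoverTaxon:
    @pytest.fixture
    def setup(self):
        unique = peptidome(
            {
                "AAAAGGK": {"p1", "p2", "p3"},
                "DDDDGGK": {"p4", "p5"},
                "EEEEGGK": {"p6"},
            }
        )
        result = greedy_min_cover(unique)
        mag_by_protein = {f"p{i}": f"m{i}" for i in range(1, 7)}
        return result, mag_by_protein

    def test_all_in_first_group(self, setup):
        result, mag_by_protein = setup
        taxonomy = {"m1": "Firmicutes", "m2": "Firmicutes", "m3": "Firmicutes"}
        assert (
            peptides_to_cover_taxon(result, taxonomy, mag_by_protein, "Firmicutes")
            == 1
        )

    def test_spread_over_groups_one_and_three(self, setup):
        result, mag_by_protein = setup
        taxonomy = {"m1": "Firmicutes", "m6": "Firmicutes"}
        assert (
            peptides_to_cover_taxon(result, taxonomy, mag_by_protein, "Firmicutes")
            == 3
        )

    def test_absent_phylum_is_zero(self, setup):
        result, mag_by_protein = setup
        assert peptides_to_cover_taxon(result, {}, mag_by_protein, "Thermotogae") == 0

    def test_greedy_subset_mode_never_needs_more(self, setup):
        result, mag_by_protein = setup
        taxonomy = {"m1": "Firmicutes", "m6": "Firmicutes"}
        prefix = peptides_to_cover_taxon(
            result, taxonomy, mag_by_protein, "Firmicutes"
        )
        subset = peptides_to_cover_taxon(
            result, taxonomy, mag_by_protein, "Firmicutes", mode="greedy-subset"
        )
        assert subset <= prefix
        assert subset == 2
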
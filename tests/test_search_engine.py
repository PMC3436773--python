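"""Constraint matching and the backtracking search."""

import numpy as np
import pytest

from motif3d.fixtures import (
    FixtureRecipe,
    PlantedMotif,
    brute_force_search,
    make_chain,
    random_search_case,
    triad_template,
    write_pdb,
)
from motif3d.motif_spec import (
    DistanceConstraint,
    GroupConstraint,
    MotifSpec,
    SeparationConstraint,
    parse_motif,
)
from motif3d.search_engine import (
    count_candidate_subsets,
    find_matches,
    match_satisfies,
    search_many,
)
from motif3d.structure_io import AtomRecord, ResidueView, StructureModel


def _two_residue_model(distance, types="AG"):
    residues = []
    for i, pos in enumerate([(0.0, 0.0, 0.0), (distance, 0.0, 0.0)]):
        atoms = {"CA": AtomRecord("CA", "C", np.asarray(pos))}
        if types[i] != "G":
            atoms["CB"] = AtomRecord("CB", "C", np.asarray(pos) + [0.0, 1.5, 0.0])
        residues.append(
            ResidueView(chain_id="A", seq_number=i + 1, insertion_code="",
                        res_type=types[i], res_name="ALA", ordinal=i, atoms=atoms)
        )
    return StructureModel("pair", chains={"A": residues})


def _pair_spec(d_min, d_max, types=("A", "G"), atom_b="CA"):
    return MotifSpec(
        groups=[
            GroupConstraint(1, frozenset(types[0]), frozenset("hsc")),
            GroupConstraint(2, frozenset(types[1]), frozenset("hsc")),
        ],
        distances=[DistanceConstraint(1, "CA", 2, atom_b,
                                      d_min, (d_min + d_max) / 2, d_max)],
    )


class TestMatchSatisfies:
    def test_planted_motif_matches_its_own_spec(self, triad_fixture):
        spec = triad_fixture.planted_spec()
        assert match_satisfies(spec, triad_fixture.model, triad_fixture.ground_truth[0])

    def test_bounds_are_inclusive(self):
        model = _two_residue_model(6.0)
        assignment = {1: ("A", 1, ""), 2: ("A", 2, "")}
        assert match_satisfies(_pair_spec(5.0, 6.0), model, assignment)
        assert match_satisfies(_pair_spec(6.0, 7.0), model, assignment)

    def test_just_outside_bounds_fails(self):
        model = _two_residue_model(6.0)
        assignment = {1: ("A", 1, ""), 2: ("A", 2, "")}
        assert not match_satisfies(_pair_spec(5.0, 5.99), model, assignment)

    def test_missing_atom_is_failure_not_error(self):
        model = _two_residue_model(6.0)  # residue 2 is GLY: no CB
        assignment = {1: ("A", 1, ""), 2: ("A", 2, "")}
        assert not match_satisfies(
            _pair_spec(0.0, 100.0, atom_b="CB"), model, assignment)

    def test_repeated_residue_fails_injectivity(self):
        model = _two_residue_model(6.0, types="AA")
        spec = _pair_spec(0.0, 100.0, types=("A", "A"))
        assert not match_satisfies(spec, model, {1: ("A", 1, ""), 2: ("A", 1, "")})

    def test_cross_chain_delta_fails(self):
        model = _two_residue_model(6.0, types="AA")
        other = ResidueView(chain_id="B", seq_number=1, insertion_code="",
                            res_type="A", res_name="ALA", ordinal=0,
                            atoms={"CA": AtomRecord("CA", "C", np.zeros(3))})
        model.chains["B"] = [other]
        spec = _pair_spec(0.0, 100.0, types=("A", "A"))
        spec.separations.append(SeparationConstraint(1, 2, -1000, 1000))
        assert not match_satisfies(spec, model, {1: ("A", 1, ""), 2: ("B", 1, "")})


class TestFindMatches:
    def test_single_planted_motif_found_once(self, triad_fixture):
        hits = find_matches(triad_fixture.model, triad_fixture.planted_spec())
        assert [m.assignment for m in hits] == triad_fixture.ground_truth

    def test_impossible_types_yield_nothing(self, triad_fixture):
        spec = triad_fixture.planted_spec()
        spec.groups = [GroupConstraint(g.label, frozenset("W"), g.allowed_ss)
                       for g in spec.groups]
        assert find_matches(triad_fixture.model, spec) == []

    def test_two_copies_found_and_agree_with_brute_force(self, two_copy_fixture):
        spec = two_copy_fixture.planted_spec()
        hits = find_matches(two_copy_fixture.model, spec)
        assert len(hits) == 2
        assert {frozenset(m.assignment.values()) for m in hits} == {
            frozenset(gt.values()) for gt in two_copy_fixture.ground_truth
        }
        oracle = brute_force_search(two_copy_fixture.model, spec)
        assert [m.assignment for m in hits] == [m.assignment for m in oracle]

    def test_measured_values_lie_within_bounds(self, triad_fixture):
        spec = triad_fixture.planted_spec()
        for m in find_matches(triad_fixture.model, spec):
            for idx, value in m.measured.items():
                c = spec.distances[idx]
                assert c.d_min <= value <= c.d_max
            for idx, value in m.separations.items():
                s = spec.separations[idx]
                assert s.sep_min <= value <= s.sep_max

    def test_pruning_never_removes_matches(self):
        for seed in range(8):
            fixture, spec = random_search_case(seed)
            pruned = find_matches(fixture.model, spec, prune=True)
            unpruned = find_matches(fixture.model, spec, prune=False)
            assert [m.assignment for m in pruned] == [m.assignment for m in unpruned]

    def test_symmetric_groups_permute_unless_deduped(self):
        model = _two_residue_model(6.0, types="AA")
        spec = _pair_spec(5.0, 7.0, types=("A", "A"))
        hits = find_matches(model, spec)
        assert len(hits) == 2  # both assignments of the same residue pair
        deduped = find_matches(model, spec, dedupe_sets=True)
        assert len(deduped) == 1
        assert deduped[0].residue_set() == hits[0].residue_set()

    def test_signed_versus_absolute_separation(self):
        model = _two_residue_model(6.0, types="AA")
        spec = _pair_spec(5.0, 7.0, types=("A", "A"))
        # group 1 on the later residue: signed separation is -1
        spec.separations.append(SeparationConstraint(1, 2, 1, 1))
        signed = find_matches(model, spec)
        assert [tuple(m.assignment[g] for g in (1, 2)) for m in signed] == [
            (("A", 1, ""), ("A", 2, ""))
        ]
        unsigned = find_matches(model, spec, abs_delta=True)
        assert len(unsigned) == 2

    def test_deterministic_order_and_bytes(self, two_copy_fixture):
        spec = two_copy_fixture.planted_spec()
        lines1 = [m.format_line() for m in find_matches(two_copy_fixture.model, spec)]
        lines2 = [m.format_line() for m in find_matches(two_copy_fixture.model, spec)]
        assert lines1 == lines2
        assert lines1 == sorted(lines1)


class TestCountCandidateSubsets:
    @pytest.mark.parametrize("m, k, expected", [
        (10, 3, 120),
        (7, 0, 1),
        (5, 5, 1),
        (3, 5, 0),
    ])
    def test_known_values(self, m, k, expected):
        assert count_candidate_subsets(m, k) == expected

    def test_large_value_matches_product_formula(self):
        m, k = 250, 4
        product = m * (m - 1) * (m - 2) * (m - 3) // 24
        assert count_candidate_subsets(m, k) == product == 158_882_750


class TestSearchMany:
    def test_report_counts(self, tmp_path, triad_fixture):
        plain = make_chain(FixtureRecipe(n_residues=40, seed=5, structure_id="plain"))
        paths = [
            write_pdb(triad_fixture.model, tmp_path / "hit.pdb"),
            write_pdb(plain.model, tmp_path / "miss1.pdb"),
            write_pdb(plain.model, tmp_path / "miss2.pdb"),
        ]
        report = search_many(paths, triad_fixture.planted_spec())
        assert report.structures_searched == 3
        assert report.structures_with_hits == 1
        assert len(report.matches) == 1

    def test_empty_input_collection(self, triad_fixture):
        report = search_many([], triad_fixture.planted_spec())
        assert report.structures_searched == 0
        assert report.matches == []

    def test_unreadable_file_skipped_not_fatal(self, tmp_path, triad_fixture):
        bad = tmp_path / "garbage.pdb"
        bad.write_text("this is not a structure\n")
        good = write_pdb(triad_fixture.model, tmp_path / "good.pdb")
        report = search_many([bad, good], triad_fixture.planted_spec())
        assert report.structures_searched == 2
        assert report.structures_with_hits == 1

    def test_directory_of_fixtures_matches_ground_truth(self, tmp_path):
        template = triad_template()
        spec = None
        expected = 0
        paths = []
        for i in range(6):
            copies = 1 + i % 2
            fixture = make_chain(FixtureRecipe(
                n_residues=70, seed=100 + i, structure_id=f"fx{i}",
                planted=(PlantedMotif(template, copies=copies),),
            ))
            if spec is None:
                spec = fixture.planted_spec(delta_policy="none")
            expected += copies
            paths.append(write_pdb(fixture.model, tmp_path / f"fx{i}.pdb"))
        report = search_many(paths, spec)
        assert len(report.matches) >= expected
        assert report.structures_with_hits == 6
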
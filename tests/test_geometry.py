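"""Superposition, rmsd and distance-matrix similarity."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from motif3d.geometry import (
    backbone_rmsd,
    distance_matrix,
    dm_similarity,
    rmsd,
    superpose,
)
from motif3d.fixtures import FixtureRecipe, make_chain
from motif3d.structure_io import StructureModel


def _random_points(rng, n=6):
    return rng.normal(size=(n, 3)) * 5.0


def _random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return rot, rng.normal(size=3) * 10.0


class TestRmsd:
    def test_identical_sets_zero(self, rng):
        a = _random_points(rng)
        assert rmsd(a, a) == 0.0

    def test_unit_displacements(self):
        a = np.zeros((2, 3))
        b = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        assert rmsd(a, b) == pytest.approx(1.0)

    def test_matches_direct_sum_of_squares(self, rng):
        a, b = _random_points(rng, 5), _random_points(rng, 5)
        direct = np.sqrt(sum(np.dot(ai - bi, ai - bi) for ai, bi in zip(a, b)) / 5)
        assert rmsd(a, b) == pytest.approx(direct)

    def test_symmetry(self, rng):
        a, b = _random_points(rng), _random_points(rng)
        assert rmsd(a, b) == pytest.approx(rmsd(b, a))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestSuperpose:
    def test_pure_translation(self, rng):
        a = _random_points(rng)
        result = superpose(a, a + np.array([1.0, 2.0, 3.0]))
        assert result.rmsd < 1e-9
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(result.translation, [1, 2, 3], atol=1e-9)

    def test_rotation_recovered(self, rng):
        a = _random_points(rng)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        result = superpose(a, a @ rot.T)
        assert result.rmsd < 1e-9
        np.testing.assert_allclose(result.rotation, rot, atol=1e-9)

    def test_rigid_motion_recovered(self, rng):
        for _ in range(20):
            a = _random_points(rng)
            rot, t = _random_rigid(rng)
            result = superpose(a, a @ rot.T + t)
            assert result.rmsd < 1e-6
            assert np.linalg.det(result.rotation) == pytest.approx(1.0)

    def test_mirror_image_of_chiral_set_keeps_positive_rmsd(self, rng):
        # a chiral 4-point set; its mirror cannot be superposed by a proper
        # rotation, so the optimum stays > 0
        a = np.array([[0, 0, 0], [3, 0, 0], [0, 2, 0], [0, 0, 4.0]])
        mirrored = a * np.array([1, 1, -1.0])
        result = superpose(a, mirrored)
        assert result.rmsd > 0.1
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)
        # brute-force oracle: no sampled proper rotation does better
        sampled = Rotation.random(3000, random_state=7).as_matrix()
        centred_a = a - a.mean(axis=0)
        centred_b = mirrored - mirrored.mean(axis=0)
        best = min(rmsd(centred_a @ r.T, centred_b) for r in sampled)
        assert result.rmsd <= best + 1e-9

    def test_fit_beats_random_rigid_transforms(self, rng):
        a, b = _random_points(rng, 8), _random_points(rng, 8)
        fitted = superpose(a, b).rmsd
        for _ in range(1000):
            rot, t = _random_rigid(rng)
            assert fitted <= rmsd(a @ rot.T + t, b) + 1e-9

    def test_agrees_with_scipy_align_vectors(self, rng):
        a, b = _random_points(rng, 7), _random_points(rng, 7)
        result = superpose(a, b)
        rot_scipy, _ = Rotation.align_vectors(b - b.mean(axis=0), a - a.mean(axis=0))
        np.testing.assert_allclose(result.rotation, rot_scipy.as_matrix(), atol=1e-8)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


@pytest.fixture(scope="module")
def chain_model():
    return make_chain(FixtureRecipe(n_residues=20, seed=9)).model


class TestBackboneRmsd:
    def _keys(self, model, idx):
        chain = model.chains["A"]
        return [chain[i].key for i in idx]

    def test_motif_against_itself(self, chain_model):
        keys = self._keys(chain_model, [2, 5, 9, 14])
        assert backbone_rmsd(chain_model, keys, chain_model, keys) < 1e-9

    def test_motif_against_rigidly_moved_copy(self, chain_model, rng):
        rot, t = _random_rigid(rng)
        moved = StructureModel("moved", chains={"A": []})
        import copy
        moved.chains["A"] = copy.deepcopy(chain_model.chains["A"])
        for res in moved.chains["A"]:
            for atom in res.atoms.values():
                atom.coords = rot @ atom.coords + t
        keys = self._keys(chain_model, [2, 5, 9, 14])
        assert backbone_rmsd(chain_model, keys, moved, keys) < 1e-6

    def test_missing_atoms_are_dropped(self, chain_model):
        import copy
        partial = StructureModel("partial",
                                 chains={"A": copy.deepcopy(chain_model.chains["A"])})
        keys = self._keys(chain_model, [2, 5, 9])
        del partial.chains["A"][2].atoms["O"]
        value = backbone_rmsd(chain_model, keys, partial, keys)
        assert value < 1e-9  # remaining 11 pairs still superpose exactly

    def test_too_few_usable_pairs(self, chain_model):
        keys = self._keys(chain_model, [2])
        import copy
        bare = StructureModel("bare", chains={"A": copy.deepcopy(chain_model.chains["A"])})
        bare.chains["A"][2].atoms = {
            "N": bare.chains["A"][2].atoms["N"], "CA": bare.chains["A"][2].atoms["CA"]}
        with pytest.raises(ValueError, match="usable atom pairs"):
            backbone_rmsd(chain_model, keys, bare, keys)

    def test_length_mismatch(self, chain_model):
        with pytest.raises(ValueError, match="length"):
            backbone_rmsd(chain_model, self._keys(chain_model, [1, 2]),
                          chain_model, self._keys(chain_model, [1]))


class TestDistanceMatrixSimilarity:
    def test_identical_matrices(self, rng):
        dm = distance_matrix(_random_points(rng))
        assert dm_similarity(dm, dm) == 0.0

    def test_single_offdiagonal_difference_counts_twice(self):
        a = np.array([[0.0, 2.0], [2.0, 0.0]])
        b = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert dm_similarity(a, b) == pytest.approx(2.0)

    def test_matches_elementwise_oracle(self, rng):
        a = distance_matrix(_random_points(rng))
        b = distance_matrix(_random_points(rng))
        oracle = sum(abs(a[i, j] - b[i, j]) for i in range(len(a)) for j in range(len(a)))
        assert dm_similarity(a, b) == pytest.approx(oracle)

    def test_pseudometric_properties(self, rng):
        a = distance_matrix(_random_points(rng))
        b = distance_matrix(_random_points(rng))
        assert dm_similarity(a, b) >= 0
        assert dm_similarity(a, b) == pytest.approx(dm_similarity(b, a))

    def test_invariant_under_rigid_motion(self, rng):
        pts = _random_points(rng)
        rot, t = _random_rigid(rng)
        assert dm_similarity(distance_matrix(pts),
                             distance_matrix(pts @ rot.T + t)) == pytest.approx(0, abs=1e-9)

    def test_matrix_properties(self, rng):
        dm = distance_matrix(_random_points(rng))
        np.testing.assert_allclose(dm, dm.T)
        assert np.all(np.diag(dm) == 0)
        # triangle inequality on a sampled triple
        i, j, k = 0, 2, 4
        assert dm[i, k] <= dm[i, j] + dm[j, k] + 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            dm_similarity(np.zeros((2, 2)), np.zeros((3, 3)))
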
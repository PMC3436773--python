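"""Rigid superposition, rmsd and distance-matrix similarity.

Superposition uses the SVD solution to the orthogonal Procrustes problem
restricted to proper rotations (the determinant of the optimal orthogonal
matrix is sign-corrected so mirror images are never matched by reflection).
rmsd is the plain root-mean-square deviation over positionally corresponded
points; it does not fit — callers superpose first when a fitted value is
wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

from .structure_io import ResidueKey, StructureModel

__all__ = [
    "SuperpositionResult",
    "superpose",
    "rmsd",
    "backbone_rmsd",
    "distance_matrix",
    "dm_similarity",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid fit: b ≈ rotation @ a + translation, with the residual rmsd."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _as_points(coords: Iterable, name: str) -> np.ndarray:
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array, got shape {arr.shape}")
    return arr


def rmsd(coords_a: Iterable, coords_b: Iterable) -> float:
    """Root mean square deviation of positionally paired points, in Å.

    No superposition is performed.
    """
    a = _as_points(coords_a, "coords_a")
    b = _as_points(coords_b, "coords_b")
    if a.shape != b.shape:
        raise ValueError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    if len(a) == 0:
        raise ValueError("rmsd of empty point sets is undefined")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(coords_a: Iterable, coords_b: Iterable) -> SuperpositionResult:
    """Least-squares rigid fit of ``coords_a`` onto ``coords_b``.

    Returns the proper rotation and translation minimising the rmsd between
    the transformed first set and the second; reflections are excluded.
    Correspondence is positional; at least 3 points are required.
    """
    a = _as_points(coords_a, "coords_a")
    b = _as_points(coords_b, "coords_b")
    if a.shape != b.shape:
        raise ValueError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("superposition needs at least 3 point pairs")

    centroid_a = a.mean(axis=0)
    centroid_b = b.mean(axis=0)
    a0, b0 = a - centroid_a, b - centroid_b

    # Kabsch: H = a0^T b0; R = V diag(1,1,det) U^T with H = U S V^T.
    u, _, vt = np.linalg.svd(a0.T @ b0)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign if sign != 0 else 1.0])
    rotation = vt.T @ d @ u.T
    translation = centroid_b - rotation @ centroid_a
    fitted = a @ rotation.T + translation
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd(fitted, b))


def backbone_rmsd(
    model_a: StructureModel,
    residues_a: Sequence[ResidueKey],
    model_b: StructureModel,
    residues_b: Sequence[ResidueKey],
    atoms: Tuple[str, ...] = BACKBONE_ATOMS,
) -> float:
    """Fitted rmsd over backbone atoms of paired residues, in Å.

    Residues are paired in the given order; atom pairs where either residue
    lacks the atom are dropped.  Raises when fewer than 3 usable atom pairs
    remain.
    """
    if len(residues_a) != len(residues_b):
        raise ValueError(
            f"residue selections differ in length: {len(residues_a)} vs {len(residues_b)}"
        )
    pa, pb = [], []
    dropped = 0
    for key_a, key_b in zip(residues_a, residues_b):
        res_a = model_a.residue(key_a)
        res_b = model_b.residue(key_b)
        for atom in atoms:
            ca, cb = res_a.get_atom(atom), res_b.get_atom(atom)
            if ca is None or cb is None:
                dropped += 1
                continue
            pa.append(ca)
            pb.append(cb)
    if len(pa) < 3:
        raise ValueError(
            f"only {len(pa)} usable atom pairs ({dropped} dropped); need at least 3"
        )
    return superpose(np.array(pa), np.array(pb)).rmsd


def distance_matrix(coords: Iterable) -> np.ndarray:
    """All internal pairwise distances of one point set, as an n×n matrix."""
    arr = _as_points(coords, "coords")
    diff = arr[:, None, :] - arr[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def dm_similarity(dm_a: np.ndarray, dm_b: np.ndarray) -> float:
    """Sum of absolute entry-wise differences of two distance matrices.

    Zero iff the matrices are identical; a pseudometric on configurations
    (blind to rigid motion and mirror inversion).
    """
    a = np.asarray(dm_a, dtype=float)
    b = np.asarray(dm_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"distance matrices differ in shape: {a.shape} vs {b.shape}")
    return float(np.sum(np.abs(a - b)))
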
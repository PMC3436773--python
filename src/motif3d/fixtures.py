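"""Synthetic PDB-format structures with planted motifs, and a brute-force oracle.

The generator builds single-chain polypeptides from ideal internal
coordinates (bond lengths/angles of the peptide unit, per-residue phi/psi
drawn from helix, strand or coil windows), then *plants* copies of a motif
template by overwriting the residue types and coordinates of chosen chain
positions with a rigidly transformed (optionally noise-perturbed) copy of
the template geometry.  Every planted copy is recorded as ground truth, so
tests can reason analytically about which hits a search must return.

The chains are geometrically idealized test articles, not physically
plausible proteins: side chains stop at C-beta, and planted residues float
free of the backbone trace.  That is exactly enough to exercise residue
typing, secondary structure, distance and separation constraints.

``brute_force_search`` is the reference oracle: it enumerates every
injective assignment of structure residues to motif groups and filters with
the same public match predicate, with no candidate prefiltering, ordering
heuristic, or early rejection.  A size guard refuses structures where the
enumeration would exceed ten million assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .motif_build import ToleranceRule, build_motif
from .motif_spec import GroupConstraint, MotifSpec
from .search_engine import MotifMatch, count_candidate_subsets, match_satisfies
from .structure_io import (
    ONE_TO_THREE,
    AtomRecord,
    ResidueKey,
    ResidueView,
    StructureModel,
    assign_secondary_structure,
    write_pdb,
)

__all__ = [
    "MotifTemplate",
    "PlantedMotif",
    "FixtureRecipe",
    "Fixture",
    "make_chain",
    "ideal_chain",
    "brute_force_search",
    "triad_template",
    "extract_template",
    "random_template",
    "random_search_case",
    "write_pdb",
    "RecipeError",
]

BRUTE_FORCE_GUARD = 10_000_000

# Ideal peptide internal coordinates (Å, degrees).
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_BOND_CA_CB = 1.521
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.5
_ANGLE_C_CA_CB = 109.5
_DIHEDRAL_N_C_CA_CB = 122.68
_OMEGA = 180.0

PHI_PSI = {"h": (-57.0, -47.0), "s": (-120.0, 120.0)}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class RecipeError(ValueError):
    """Raised when a fixture recipe cannot be realised."""


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d bonded to c with angle b-c-d and dihedral a-b-c-d (degrees)."""
    ang, dih = math.radians(angle), math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class MotifTemplate:
    """Residue types, atom coordinates and chain-ordinal gaps of a motif.

    ``gaps[i]`` is the ordinal offset of residue i from residue 0 in the
    source chain; planted copies reproduce these gaps so sequence-separation
    constraints derived from one copy hold for all of them.
    """

    res_types: Tuple[str, ...]
    atom_sets: Tuple[Dict[str, np.ndarray], ...]
    gaps: Tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.res_types) == len(self.atom_sets) == len(self.gaps)):
            raise ValueError("template fields must have equal length")
        if list(self.gaps) != sorted(set(self.gaps)) or self.gaps[0] != 0:
            raise ValueError("gaps must be strictly increasing and start at 0")

    @property
    def size(self) -> int:
        return len(self.res_types)

    @property
    def span(self) -> int:
        return self.gaps[-1] + 1


@dataclass(frozen=True)
class PlantedMotif:
    template: MotifTemplate
    copies: int = 1
    noise_sigma: float = 0.0


@dataclass(frozen=True)
class FixtureRecipe:
    """Reproducible description of one synthetic structure."""

    n_residues: int = 80
    planted: Tuple[PlantedMotif, ...] = ()
    decoy_types: str = _AA20
    seed: int = 0
    chain_id: str = "A"
    structure_id: str = "fixture"


@dataclass
class Fixture:
    """A generated structure plus the ground truth of its planted motifs."""

    model: StructureModel
    ground_truth: List[Dict[int, ResidueKey]] = field(default_factory=list)
    recipe: Optional[FixtureRecipe] = None

    def planted_spec(
        self,
        copy_index: int = 0,
        tol: ToleranceRule = ToleranceRule(1.0, "A"),
        ss_policy: str = "wildcard",
        delta_policy: str = "strict",
        **kwargs,
    ) -> MotifSpec:
        """Build a motif spec from one planted copy (self-recovery input)."""
        assignment = self.ground_truth[copy_index]
        residues = [assignment[label] for label in sorted(assignment)]
        return build_motif(
            self.model, residues, tol=tol, ss_policy=ss_policy,
            delta_policy=delta_policy, **kwargs,
        )


def _build_backbone(phi_psi: List[Tuple[float, float]]) -> List[Dict[str, np.ndarray]]:
    """Backbone + O atoms for a chain with the given per-residue (phi, psi)."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANGLE_N_CA_C)
    c = ca + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    atoms = [{"N": n, "CA": ca, "C": c}]
    for i in range(1, len(phi_psi)):
        prev = atoms[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = _nerf(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANGLE_CA_C_N, psi_prev)
        ca_i = _nerf(prev["CA"], prev["C"], n_i, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        c_i = _nerf(prev["C"], n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi_psi[i][0])
        atoms.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(atoms):
        # Carbonyl O in the peptide plane: dihedral N-CA-C-O = psi + 180.
        res["O"] = _nerf(res["N"], res["CA"], res["C"], _BOND_C_O, _ANGLE_CA_C_O,
                         phi_psi[i][1] + 180.0)
    return atoms


def _add_cb(res_type: str, atoms: Dict[str, np.ndarray]) -> None:
    if res_type == "G":
        return
    atoms["CB"] = _nerf(
        atoms["N"], atoms["C"], atoms["CA"], _BOND_CA_CB, _ANGLE_C_CA_CB,
        _DIHEDRAL_N_C_CA_CB,
    )


def _segment_plan(n: int, rng: np.random.Generator) -> List[Tuple[float, float]]:
    """Per-residue (phi, psi): alternating helix/strand/coil segments."""
    out: List[Tuple[float, float]] = []
    while len(out) < n:
        kind = rng.choice(["h", "s", "c"])
        length = int(rng.integers(4, 13))
        for _ in range(min(length, n - len(out))):
            if kind == "c":
                out.append((float(rng.uniform(-180, -30)), float(rng.uniform(0, 90))))
            else:
                out.append(PHI_PSI[kind])
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_chain(recipe: FixtureRecipe) -> Fixture:
    """Generate a synthetic single-chain structure per the recipe.

    Deterministic: the same recipe (including seed) yields byte-identical
    PDB output.  Planted copies are placed at non-overlapping ordinal slots
    with the template's ordinal gaps, each rigidly moved to its own region
    of space (copies are spaced 120 Å apart so planted geometry never
    collides with the decoy trace), with isotropic Gaussian coordinate
    noise of the requested sigma.
    """
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_residues

    total_span = sum(p.template.span * p.copies for p in recipe.planted)
    if total_span > n:
        raise RecipeError(
            f"planted motifs span {total_span} residues but the chain has only {n}"
        )

    phi_psi = _segment_plan(n, rng)
    backbone = _build_backbone(phi_psi)
    types = [recipe.decoy_types[i] for i in rng.integers(0, len(recipe.decoy_types), n)]

    # Reserve ordinal slots for each planted copy, left to right with random
    # spacing, so copies never overlap.
    slots: List[Tuple[PlantedMotif, int]] = []  # (motif, start ordinal)
    cursor = 0
    remaining = total_span
    for planted in recipe.planted:
        for _ in range(planted.copies):
            free = n - cursor - remaining
            offset = int(rng.integers(0, free + 1)) if free > 0 else 0
            start = cursor + offset
            slots.append((planted, start))
            cursor = start + planted.template.span
            remaining -= planted.template.span

    residues: List[ResidueView] = []
    for i in range(n):
        atoms = dict(backbone[i])
        _add_cb(types[i], atoms)
        residues.append(
            ResidueView(
                chain_id=recipe.chain_id,
                seq_number=i + 1,
                insertion_code="",
                res_type=types[i],
                res_name=ONE_TO_THREE[types[i]],
                atoms={
                    name: AtomRecord(name=name, element=name[0], coords=np.round(pos, 3))
                    for name, pos in atoms.items()
                },
                ordinal=i,
            )
        )

    ground_truth: List[Dict[int, ResidueKey]] = []
    for copy_idx, (planted, start) in enumerate(slots):
        template = planted.template
        rotation = _random_rotation(rng)
        translation = np.array([150.0 + 120.0 * copy_idx, 0.0, 0.0])
        assignment: Dict[int, ResidueKey] = {}
        for g, (res_type, atom_set, gap) in enumerate(
            zip(template.res_types, template.atom_sets, template.gaps)
        ):
            ordinal = start + gap
            res = residues[ordinal]
            res.res_type = res_type
            res.res_name = ONE_TO_THREE[res_type]
            new_atoms: Dict[str, AtomRecord] = {}
            for name, pos in atom_set.items():
                moved = rotation @ np.asarray(pos, dtype=float) + translation
                if planted.noise_sigma > 0:
                    moved = moved + rng.normal(0.0, planted.noise_sigma, 3)
                new_atoms[name] = AtomRecord(
                    name=name, element=name[0], coords=np.round(moved, 3)
                )
            res.atoms = new_atoms
            assignment[g + 1] = res.key
        ground_truth.append(assignment)

    model = StructureModel(
        structure_id=recipe.structure_id,
        chains={recipe.chain_id: residues},
        source=f"recipe(seed={recipe.seed})",
    )
    assign_secondary_structure(model)
    return Fixture(model=model, ground_truth=ground_truth, recipe=recipe)


def ideal_chain(
    phi_psi: Sequence[Tuple[float, float]],
    types: Optional[str] = None,
    chain_id: str = "A",
    structure_id: str = "ideal",
) -> StructureModel:
    """Build a chain with exactly the given per-residue (phi, psi) angles.

    Used to construct reference geometry (ideal helices, strands, dipeptides)
    whose torsions are known by construction rather than sampled.
    """
    n = len(phi_psi)
    if n == 0:
        raise ValueError("need at least one residue")
    types = types or "A" * n
    if len(types) != n:
        raise ValueError("types must match phi_psi in length")
    backbone = _build_backbone(list(phi_psi))
    residues: List[ResidueView] = []
    for i in range(n):
        atoms = dict(backbone[i])
        _add_cb(types[i], atoms)
        residues.append(
            ResidueView(
                chain_id=chain_id,
                seq_number=i + 1,
                insertion_code="",
                res_type=types[i],
                res_name=ONE_TO_THREE[types[i]],
                atoms={
                    name: AtomRecord(name=name, element=name[0], coords=np.round(pos, 3))
                    for name, pos in atoms.items()
                },
                ordinal=i,
            )
        )
    model = StructureModel(structure_id=structure_id, chains={chain_id: residues})
    return assign_secondary_structure(model)


def random_template(size: int, seed: int, max_gap: int = 6) -> MotifTemplate:
    """A motif template of ``size`` residues cut from a random donor chain."""
    rng = np.random.default_rng(seed)
    gaps = [0]
    for _ in range(size - 1):
        gaps.append(gaps[-1] + int(rng.integers(1, max_gap + 1)))
    donor = make_chain(
        FixtureRecipe(n_residues=gaps[-1] + 4, seed=int(rng.integers(2**31)),
                      structure_id="donor")
    )
    chain = donor.model.chains["A"]
    start = int(rng.integers(0, len(chain) - gaps[-1]))
    keys = [chain[start + g].key for g in gaps]
    template = extract_template(donor.model, keys)
    # Randomize residue identities so type filters vary between templates.
    new_types = tuple(_AA20[i] for i in rng.integers(0, len(_AA20), size))
    sets = []
    for res_type, atom_set in zip(new_types, template.atom_sets):
        atoms = dict(atom_set)
        if res_type == "G":
            atoms.pop("CB", None)
        sets.append(atoms)
    return MotifTemplate(res_types=new_types, atom_sets=tuple(sets), gaps=template.gaps)


def extract_template(model: StructureModel, residues: Sequence[ResidueKey]) -> MotifTemplate:
    """Capture the types, coordinates and ordinal gaps of existing residues."""
    views = [model.residue(key) for key in residues]
    if any(v.chain_id != views[0].chain_id for v in views):
        raise ValueError("template residues must share one chain")
    base = views[0].ordinal
    return MotifTemplate(
        res_types=tuple(v.res_type for v in views),
        atom_sets=tuple(
            {name: rec.coords.copy() for name, rec in v.atoms.items()} for v in views
        ),
        gaps=tuple(v.ordinal - base for v in views),
    )


def triad_template() -> MotifTemplate:
    """A His/Asp/Ser arrangement with serine-protease-like Cα spacing.

    Geometry is synthetic: three residues cut from an ideal chain and rigidly
    rearranged so the Cα-Cα distances approximate a catalytic triad
    (His-Asp 7.0 Å, His-Ser 6.5 Å, Asp-Ser ~9.6 Å).
    """
    donor = make_chain(FixtureRecipe(n_residues=30, seed=7, structure_id="donor"))
    keys = [("A", 5, ""), ("A", 12, ""), ("A", 20, "")]
    base = extract_template(donor.model, keys)
    # Re-centre each residue's atoms on its CA, then place the CAs at
    # triad-like positions, preserving local geometry.
    targets = [
        np.array([0.0, 0.0, 0.0]),
        np.array([7.0, 0.0, 0.0]),
        np.array([0.0, 6.5, 0.0]),
    ]
    new_types = ("H", "D", "S")
    new_sets = []
    for atom_set, target in zip(base.atom_sets, targets):
        ca = atom_set["CA"]
        new_sets.append({name: pos - ca + target for name, pos in atom_set.items()})
    return MotifTemplate(res_types=new_types, atom_sets=tuple(new_sets), gaps=base.gaps)


def random_search_case(seed: int) -> Tuple[Fixture, MotifSpec]:
    """One randomized (fixture, motif spec) pair for oracle comparisons.

    Sizes are drawn so exhaustive enumeration stays within the brute-force
    guard: 3-group motifs in chains of up to ~45 residues, 4- and 5-group
    motifs in proportionally shorter chains.  The spec is generated from the
    first planted copy and then randomly perturbed (wider residue-type sets,
    varying tolerance, secondary-structure and separation policies) so the
    search problem is not always a pure self-recovery.
    """
    rng = np.random.default_rng(seed)
    k = int(rng.choice([3, 3, 3, 4, 5]))
    n = {3: int(rng.integers(24, 46)), 4: int(rng.integers(16, 23)),
         5: int(rng.integers(13, 16))}[k]
    max_gap = max(1, (n - 4) // (2 * k))
    template = random_template(k, seed=int(rng.integers(2**31)), max_gap=max_gap)
    copies = 2 if (template.span * 2 <= n and rng.random() < 0.4) else 1
    noise = float(rng.choice([0.0, 0.1, 0.3]))
    # Bias decoy residue types toward the template's so type filters alone
    # do not trivialise the search.
    decoys = _AA20 + "".join(template.res_types) * 3
    fixture = make_chain(
        FixtureRecipe(
            n_residues=n,
            planted=(PlantedMotif(template, copies=copies, noise_sigma=noise),),
            decoy_types=decoys,
            seed=int(rng.integers(2**31)),
            structure_id=f"case{seed}",
        )
    )
    tol = ToleranceRule(float(rng.uniform(0.5, 2.0)), "A")
    ss_policy = "wildcard" if rng.random() < 0.7 else "observed"
    delta_policy = str(rng.choice(["strict", "slack", "none"]))
    spec = fixture.planted_spec(
        tol=tol, ss_policy=ss_policy, delta_policy=delta_policy,
        delta_slack=int(rng.integers(1, 6)),
    )
    if rng.random() < 0.4:
        # Loosen type filters: each group also tolerates one random extra type.
        spec.groups = [
            GroupConstraint(
                g.label,
                g.allowed_types | {_AA20[int(rng.integers(0, len(_AA20)))]},
                g.allowed_ss,
            )
            for g in spec.groups
        ]
    return fixture, spec


def brute_force_search(model: StructureModel, spec: MotifSpec, abs_delta: bool = False) -> List[MotifMatch]:
    """Exhaustively enumerate every injective group assignment and filter.

    The reference oracle for :func:`motif3d.search_engine.find_matches`:
    no candidate prefiltering, no ordering heuristic, no early rejection —
    just the public match predicate applied to every permutation of k
    residues drawn from the structure.
    """
    k = len(spec.groups)
    m = len(model)
    work = count_candidate_subsets(m, k) * math.factorial(k)
    if work > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"brute force refused: {m} residues / {k} groups implies {work:,} "
            f"assignments (guard is {BRUTE_FORCE_GUARD:,})"
        )
    labels = sorted(g.label for g in spec.groups)
    all_res = list(model.residues())
    matches: List[MotifMatch] = []
    for combo in permutations(all_res, k):
        assignment = {label: res.key for label, res in zip(labels, combo)}
        if match_satisfies(spec, model, assignment, abs_delta=abs_delta):
            match = MotifMatch(structure_id=model.structure_id, assignment=assignment)
            for idx, c in enumerate(spec.distances):
                ra = model.residue(assignment[c.group_a])
                rb = model.residue(assignment[c.group_b])
                match.measured[idx] = float(
                    np.linalg.norm(ra.get_atom(c.atom_a) - rb.get_atom(c.atom_b))
                )
            for idx, c in enumerate(spec.separations):
                ra = model.residue(assignment[c.group_a])
                rb = model.residue(assignment[c.group_b])
                sep = rb.ordinal - ra.ordinal
                match.separations[idx] = abs(sep) if abs_delta else sep
            matches.append(match)
    matches.sort(key=MotifMatch.sort_key)
    return matches
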
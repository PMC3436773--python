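"""Generate motif specifications from existing structures.

Because a spec is always derived from measured geometry, at least one
structure satisfying it — the source — is guaranteed to exist, and the
search engine is guaranteed to recover it (the self-recovery property the
test suite enforces).

Distances are stored on a milli-Å grid so that written specs re-parse to
identical values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np

from .motif_spec import (
    MAX_DISTANCES,
    MAX_DISTANCES_PER_PAIR,
    DistanceConstraint,
    GroupConstraint,
    MotifSpec,
    SeparationConstraint,
)
from .structure_io import ResidueKey, StructureModel

__all__ = [
    "ToleranceRule",
    "AtomPairSelection",
    "measure_distance",
    "build_motif",
    "widen_spec",
    "BuildError",
]

ExplicitPair = Tuple[ResidueKey, str, ResidueKey, str]


class BuildError(ValueError):
    """Raised when a motif cannot be generated from the requested selection."""


@dataclass(frozen=True)
class ToleranceRule:
    """Distance tolerance: bounds are measured ± value Å, or ± value percent."""

    value: float
    unit: Literal["A", "percent"] = "A"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("tolerance must be non-negative")
        if self.unit not in ("A", "percent"):
            raise ValueError(f"unknown tolerance unit {self.unit!r}")

    def bounds(self, measured: float) -> Tuple[float, float]:
        delta = self.value if self.unit == "A" else measured * self.value / 100.0
        return max(0.0, measured - delta), measured + delta


@dataclass
class AtomPairSelection:
    """Which atom pairs receive distance constraints.

    ``ca_only`` constrains every unordered residue pair between Cα atoms;
    ``explicit`` constrains exactly the listed (residue, atom) pairs.
    """

    mode: Literal["ca_only", "explicit"] = "ca_only"
    explicit_pairs: List[ExplicitPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode == "explicit" and not self.explicit_pairs:
            raise ValueError("explicit mode requires a non-empty pair list")
        if self.mode == "ca_only" and self.explicit_pairs:
            raise ValueError("ca_only mode takes no explicit pairs")


def measure_distance(
    model: StructureModel,
    res_a: ResidueKey,
    atom_a: str,
    res_b: ResidueKey,
    atom_b: str,
) -> float:
    """Euclidean distance in Å between two named atoms."""
    coords = []
    for key, atom in ((res_a, atom_a), (res_b, atom_b)):
        residue = model.residue(key)  # KeyError names the residue key
        pos = residue.get_atom(atom)
        if pos is None:
            raise KeyError(f"residue {key!r} has no atom {atom!r}")
        coords.append(pos)
    return float(np.linalg.norm(coords[0] - coords[1]))


def _round3(value: float) -> float:
    return round(value, 3)


def build_motif(
    model: StructureModel,
    residues: Sequence[ResidueKey],
    pairs: Optional[AtomPairSelection] = None,
    tol: ToleranceRule = ToleranceRule(1.0, "A"),
    ss_policy: Literal["observed", "wildcard"] = "observed",
    delta_policy: Literal["strict", "slack", "none"] = "strict",
    delta_slack: int = 25,
) -> MotifSpec:
    """Create a MotifSpec from a structure and an ordered residue selection.

    One GROUP is emitted per residue, labelled 1..k in the supplied order,
    restricted to the observed residue type and (per ``ss_policy``) the
    observed secondary structure.  Distance constraints follow ``pairs``
    with bounds measured ± ``tol``.  Sequence-separation constraints chain
    consecutive groups: ``strict`` pins each signed ordinal separation to
    its observed value, ``slack`` widens both bounds by ± ``delta_slack``,
    ``none`` emits no DELTA lines.
    """
    if not 2 <= len(residues) <= 32:
        raise BuildError(f"selection must contain 2..32 residues, got {len(residues)}")
    if len(set(residues)) != len(residues):
        raise BuildError("duplicate residue in selection")
    pairs = pairs or AtomPairSelection()

    views = [model.residue(key) for key in residues]
    label_of = {key: i + 1 for i, key in enumerate(residues)}

    spec = MotifSpec()
    spec.provenance.append(
        f"# motif generated from {model.structure_id}: "
        + " ".join(f"{r.chain_id}{r.seq_number}{r.insertion_code}" for r in views)
    )
    for i, res in enumerate(views):
        ss = frozenset("hsc") if ss_policy == "wildcard" else frozenset(res.ss_label)
        spec.groups.append(GroupConstraint(i + 1, frozenset(res.res_type), ss))

    if pairs.mode == "ca_only":
        pair_list: List[ExplicitPair] = [
            (a, "CA", b, "CA") for a, b in combinations(residues, 2)
        ]
    else:
        pair_list = list(pairs.explicit_pairs)

    pair_counts: dict = {}
    for res_a, atom_a, res_b, atom_b in pair_list:
        if res_a not in label_of or res_b not in label_of:
            raise BuildError(f"explicit pair references residue outside the selection")
        measured = _round3(measure_distance(model, res_a, atom_a, res_b, atom_b))
        lo, hi = tol.bounds(measured)
        spec.distances.append(
            DistanceConstraint(
                group_a=label_of[res_a],
                atom_a=atom_a.upper(),
                group_b=label_of[res_b],
                atom_b=atom_b.upper(),
                d_min=_round3(lo),
                d_measured=measured,
                d_max=_round3(hi),
            )
        )
        key = frozenset((label_of[res_a], label_of[res_b]))
        pair_counts[key] = pair_counts.get(key, 0) + 1
        if pair_counts[key] > MAX_DISTANCES_PER_PAIR:
            raise BuildError(
                f"more than {MAX_DISTANCES_PER_PAIR} distance constraints between "
                f"groups {sorted(key)}; reduce the explicit pair list"
            )
    if len(spec.distances) > MAX_DISTANCES:
        raise BuildError(
            f"{len(spec.distances)} distance constraints exceed the limit of "
            f"{MAX_DISTANCES}; use ca_only mode or fewer pairs"
        )

    if delta_policy != "none":
        for earlier, later in zip(views, views[1:]):
            if earlier.chain_id != later.chain_id:
                raise BuildError(
                    f"residues {earlier.key!r} and {later.key!r} are on different "
                    "chains; sequence separation is undefined (use delta_policy='none')"
                )
            sep = later.ordinal - earlier.ordinal
            slack = delta_slack if delta_policy == "slack" else 0
            spec.separations.append(
                SeparationConstraint(
                    group_a=label_of[earlier.key],
                    group_b=label_of[later.key],
                    sep_min=sep - slack,
                    sep_max=sep + slack,
                )
            )
    return spec


def widen_spec(spec: MotifSpec, extra: ToleranceRule) -> MotifSpec:
    """Relax every distance constraint by an extra tolerance, flooring at 0 Å.

    Groups and separation constraints are untouched; widening can only grow
    the match set.
    """
    widened = MotifSpec(
        groups=list(spec.groups),
        separations=list(spec.separations),
        provenance=list(spec.provenance),
    )
    for d in spec.distances:
        delta = extra.value if extra.unit == "A" else d.d_measured * extra.value / 100.0
        widened.distances.append(
            DistanceConstraint(
                group_a=d.group_a,
                atom_a=d.atom_a,
                group_b=d.group_b,
                atom_b=d.atom_b,
                d_min=_round3(max(0.0, d.d_min - delta)),
                d_measured=d.d_measured,
                d_max=_round3(d.d_max + delta),
            )
        )
    return widened
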
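"""Constraint-satisfaction search for motif instances in structures.

Matching is exact constraint satisfaction, not similarity scoring: an
assignment of structure residues to motif groups is a match iff every
residue passes its group's type and secondary-structure filters, every
distance constraint holds inclusively at both bounds, and every sequence-
separation constraint holds on the signed chain-ordinal separation.

The search is a backtracking expansion over per-group candidate lists
(prefiltered by type and secondary structure), ordered most-constrained
group first, with partial assignments rejected at the first violated
constraint whose endpoints are both assigned.  Because a typical motif
constrains only a handful of distances on chemically restricted residue
types, this prunes the combinatorial space of C(m, k) * k! candidate
assignments down to a few survivors almost immediately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .motif_spec import DistanceConstraint, MotifSpec, SeparationConstraint
from .structure_io import PDBParseError, ResidueKey, ResidueView, StructureModel, read_pdb

__all__ = [
    "MotifMatch",
    "SearchReport",
    "match_satisfies",
    "find_matches",
    "search_many",
    "count_candidate_subsets",
]

logger = logging.getLogger(__name__)


@dataclass
class MotifMatch:
    """One satisfying assignment of structure residues to motif groups."""

    structure_id: str
    assignment: Dict[int, ResidueKey]
    measured: Dict[int, float] = field(default_factory=dict)
    separations: Dict[int, int] = field(default_factory=dict)

    def residue_set(self) -> frozenset:
        return frozenset(self.assignment.values())

    def sort_key(self) -> Tuple:
        return tuple(self.assignment[label] for label in sorted(self.assignment))

    def format_line(self, model: Optional[StructureModel] = None) -> str:
        parts = [self.structure_id]
        for label in sorted(self.assignment):
            chain, num, icode = self.assignment[label]
            res_type = ""
            if model is not None:
                res_type = f":{model.residue(self.assignment[label]).res_type}"
            parts.append(f"{chain}:{num}{icode}{res_type}")
        return " ".join(parts)


@dataclass
class SearchReport:
    """Aggregate result of searching one or more structures."""

    spec_provenance: str = ""
    matches: List[MotifMatch] = field(default_factory=list)
    structures_searched: int = 0
    structures_with_hits: int = 0

    def to_lines(self) -> List[str]:
        return [m.format_line() for m in self.matches]


def count_candidate_subsets(m: int, k: int) -> int:
    """Number of k-residue subsets of an m-residue structure, C(m, k).

    This is the combinatorial space a naive superposition-based search
    would have to score; returns 0 when k > m.
    """
    if m < 0 or k < 0:
        raise ValueError("residue counts must be non-negative")
    if k > m:
        return 0
    return math.comb(m, k)


def _signed_separation(res_a: ResidueView, res_b: ResidueView) -> Optional[int]:
    if res_a.chain_id != res_b.chain_id:
        return None
    return res_b.ordinal - res_a.ordinal


def _distance(res_a: ResidueView, atom_a: str, res_b: ResidueView, atom_b: str) -> Optional[float]:
    pa, pb = res_a.get_atom(atom_a), res_b.get_atom(atom_b)
    if pa is None or pb is None:
        return None
    return float(np.linalg.norm(pa - pb))


def _check_distance(c: DistanceConstraint, res_a: ResidueView, res_b: ResidueView) -> Optional[float]:
    """Measured distance when the constraint holds, else None (missing atom fails)."""
    d = _distance(res_a, c.atom_a, res_b, c.atom_b)
    if d is None or not (c.d_min <= d <= c.d_max):
        return None
    return d


def _check_separation(
    c: SeparationConstraint, res_a: ResidueView, res_b: ResidueView, abs_delta: bool
) -> Optional[int]:
    sep = _signed_separation(res_a, res_b)
    if sep is None:
        return None  # cross-chain: any finite DELTA fails
    value = abs(sep) if abs_delta else sep
    if not (c.sep_min <= value <= c.sep_max):
        return None
    return value


def match_satisfies(
    spec: MotifSpec,
    model: StructureModel,
    assignment: Dict[int, ResidueKey],
    abs_delta: bool = False,
) -> bool:
    """True iff a complete group→residue assignment satisfies every constraint.

    Missing named atoms make the affected distance constraint fail rather
    than raising, so structures with truncated side chains are simply
    non-matches.
    """
    if set(assignment) != set(spec.labels):
        raise ValueError("assignment must cover every group label exactly")
    if len(set(assignment.values())) != len(assignment):
        return False
    views: Dict[int, ResidueView] = {}
    for label, key in assignment.items():
        res = model.residue(key)
        if not spec.group(label).accepts(res.res_type, res.ss_label):
            return False
        views[label] = res
    for c in spec.distances:
        if _check_distance(c, views[c.group_a], views[c.group_b]) is None:
            return False
    for c in spec.separations:
        if _check_separation(c, views[c.group_a], views[c.group_b], abs_delta) is None:
            return False
    return True


def _expansion_order(spec: MotifSpec, candidates: Dict[int, List[ResidueView]]) -> List[int]:
    incident: Dict[int, int] = {label: 0 for label in spec.labels}
    for c in spec.distances:
        incident[c.group_a] += 1
        incident[c.group_b] += 1
    for c in spec.separations:
        incident[c.group_a] += 1
        incident[c.group_b] += 1
    # Most-constrained-variable heuristic: fewest candidates first, then
    # most incident constraints; label as the deterministic tie-break.
    return sorted(spec.labels, key=lambda g: (len(candidates[g]), -incident[g], g))


def find_matches(
    model: StructureModel,
    spec: MotifSpec,
    abs_delta: bool = False,
    dedupe_sets: bool = False,
    prune: bool = True,
) -> List[MotifMatch]:
    """All assignments of ``model`` residues to ``spec`` groups that match.

    Results are deterministic: sorted by the assigned residue keys in group-
    label order.  With ``dedupe_sets``, permuted assignments of one residue
    set (possible when groups share constraints) collapse to the first in
    sort order.  ``prune=False`` disables early rejection of partial
    assignments (used to test pruning soundness); the match set is identical
    either way.
    """
    candidates: Dict[int, List[ResidueView]] = {
        label: [
            res
            for res in model.residues()
            if spec.group(label).accepts(res.res_type, res.ss_label)
        ]
        for label in spec.labels
    }
    order = _expansion_order(spec, candidates)
    position = {label: i for i, label in enumerate(order)}

    # Constraints become checkable as soon as both endpoint groups are
    # assigned; index them by the later of the two expansion positions.
    dist_at: List[List[Tuple[int, DistanceConstraint]]] = [[] for _ in order]
    sep_at: List[List[Tuple[int, SeparationConstraint]]] = [[] for _ in order]
    for idx, c in enumerate(spec.distances):
        dist_at[max(position[c.group_a], position[c.group_b])].append((idx, c))
    for idx, c in enumerate(spec.separations):
        sep_at[max(position[c.group_a], position[c.group_b])].append((idx, c))

    matches: List[MotifMatch] = []
    assigned: Dict[int, ResidueView] = {}
    used: set = set()

    def extend(depth: int, measured: Dict[int, float], seps: Dict[int, int]) -> None:
        if depth == len(order):
            matches.append(
                MotifMatch(
                    structure_id=model.structure_id,
                    assignment={g: r.key for g, r in assigned.items()},
                    measured=dict(measured),
                    separations=dict(seps),
                )
            )
            return
        label = order[depth]
        last = depth + 1 == len(order)
        if prune:
            check_depths = [depth]
        else:
            # Without pruning, constraints are evaluated only on complete
            # assignments — the exhaustive-rejection baseline.
            check_depths = list(range(len(order))) if last else []
        for res in candidates[label]:
            if res.key in used:
                continue
            assigned[label] = res
            used.add(res.key)
            ok = True
            new_measured: Dict[int, float] = {}
            new_seps: Dict[int, int] = {}
            for d in check_depths:
                for idx, c in dist_at[d]:
                    value = _check_distance(c, assigned[c.group_a], assigned[c.group_b])
                    if value is None:
                        ok = False
                        break
                    new_measured[idx] = value
                if not ok:
                    break
                for idx, c in sep_at[d]:
                    value = _check_separation(
                        c, assigned[c.group_a], assigned[c.group_b], abs_delta
                    )
                    if value is None:
                        ok = False
                        break
                    new_seps[idx] = value
                if not ok:
                    break
            if ok:
                measured.update(new_measured)
                seps.update(new_seps)
                extend(depth + 1, measured, seps)
            del assigned[label]
            used.discard(res.key)

    extend(0, {}, {})
    matches.sort(key=MotifMatch.sort_key)
    if dedupe_sets:
        seen: set = set()
        unique: List[MotifMatch] = []
        for m in matches:
            rset = m.residue_set()
            if rset not in seen:
                seen.add(rset)
                unique.append(m)
        matches = unique
    return matches


def search_many(
    models_or_paths: Iterable[Union[StructureModel, str, Path]],
    spec: MotifSpec,
    abs_delta: bool = False,
    dedupe_sets: bool = False,
) -> SearchReport:
    """Search a collection of structures (models or PDB file paths).

    Unreadable files are logged and skipped; they still count as searched.
    """
    report = SearchReport(spec_provenance="\n".join(spec.provenance))
    for item in models_or_paths:
        report.structures_searched += 1
        if isinstance(item, StructureModel):
            model = item
        else:
            try:
                model = read_pdb(Path(item))
            except (PDBParseError, OSError) as exc:
                logger.warning("skipping unreadable structure %s: %s", item, exc)
                continue
        hits = find_matches(model, spec, abs_delta=abs_delta, dedupe_sets=dedupe_sets)
        if hits:
            report.structures_with_hits += 1
            report.matches.extend(hits)
    return report
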
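"""Data model, parser, writer and validator for motif specifications.

A motif specification is a plain-text file with three blocks:

* ``GROUP <label> <types> <ss>`` — one line per motif residue.  ``types`` is
  a string of one-letter amino-acid codes read as a disjunction (``DN`` means
  Asp or Asn); ``ss`` is a combination of ``h``/``s``/``c`` or ``*`` for no
  restriction.
* ``DIST <ga> <atom_a> <gb> <atom_b> <min> <measured> <max>`` — an
  inter-atomic distance constraint in Å between named atoms of two groups;
  a candidate satisfies it when min <= d <= max (inclusive bounds).
* ``DELTA <ga> <gb> <sep_min> <sep_max>`` — bounds on the signed sequence
  separation (chain-ordinal difference) between two groups.

Lines starting with any other token are retained verbatim as provenance.
Hard limits: at most 32 groups, 150 distance constraints in total, and 31
distance constraints per group pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, List, Tuple

__all__ = [
    "GroupConstraint",
    "DistanceConstraint",
    "SeparationConstraint",
    "MotifSpec",
    "MotifFormatError",
    "parse_motif",
    "write_motif",
    "validate",
    "MAX_GROUPS",
    "MAX_DISTANCES",
    "MAX_DISTANCES_PER_PAIR",
]

MAX_GROUPS = 32
MAX_DISTANCES = 150
MAX_DISTANCES_PER_PAIR = 31

VALID_RES_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
VALID_SS_LETTERS = frozenset("hsc")


class MotifFormatError(ValueError):
    """Raised by the parser/writer for malformed or invalid specifications."""


@dataclass(frozen=True)
class GroupConstraint:
    """A motif residue: numeric label plus type and secondary-structure filters."""

    label: int
    allowed_types: FrozenSet[str]
    allowed_ss: FrozenSet[str]

    def accepts(self, res_type: str, ss_label: str) -> bool:
        return res_type in self.allowed_types and ss_label in self.allowed_ss


@dataclass(frozen=True)
class DistanceConstraint:
    """Bounds on one inter-atomic distance: d_min <= d <= d_max, in Å."""

    group_a: int
    atom_a: str
    group_b: int
    atom_b: str
    d_min: float
    d_measured: float
    d_max: float


@dataclass(frozen=True)
class SeparationConstraint:
    """Bounds on the signed chain-ordinal separation between two groups."""

    group_a: int
    group_b: int
    sep_min: int
    sep_max: int


@dataclass
class MotifSpec:
    groups: List[GroupConstraint] = field(default_factory=list)
    distances: List[DistanceConstraint] = field(default_factory=list)
    separations: List[SeparationConstraint] = field(default_factory=list)
    provenance: List[str] = field(default_factory=list)

    @property
    def labels(self) -> List[int]:
        return [g.label for g in self.groups]

    def group(self, label: int) -> GroupConstraint:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(f"no group with label {label}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifSpec):
            return NotImplemented
        return (
            self.groups == other.groups
            and self.distances == other.distances
            and self.separations == other.separations
            and self.provenance == other.provenance
        )


def validate(spec: MotifSpec) -> List[str]:
    """Return a list of human-readable issues; empty iff the spec is valid."""
    issues: List[str] = []
    seen = set()
    for i, g in enumerate(spec.groups):
        if g.label in seen:
            issues.append(f"group {i}: duplicate label {g.label}")
        seen.add(g.label)
        if g.label <= 0:
            issues.append(f"group {i}: label must be a positive integer")
        if not g.allowed_types:
            issues.append(f"group {i}: empty residue-type set")
        bad = set(g.allowed_types) - VALID_RES_LETTERS
        if bad:
            issues.append(f"group {i}: unknown residue letters {sorted(bad)}")
        if not g.allowed_ss or not set(g.allowed_ss) <= VALID_SS_LETTERS:
            issues.append(f"group {i}: secondary-structure set must be a non-empty subset of h/s/c")
    if len(spec.groups) > MAX_GROUPS:
        issues.append(f"{len(spec.groups)} groups exceeds the maximum of {MAX_GROUPS}")

    labels = {g.label for g in spec.groups}
    pair_counts: dict = {}
    for i, d in enumerate(spec.distances):
        for lab in (d.group_a, d.group_b):
            if lab not in labels:
                issues.append(f"distance {i}: undeclared group label {lab}")
        if d.group_a == d.group_b and d.atom_a == d.atom_b:
            issues.append(f"distance {i}: constrains an atom against itself")
        if d.d_min < 0:
            issues.append(f"distance {i}: negative lower bound {d.d_min}")
        if d.d_min > d.d_max:
            issues.append(f"distance {i}: d_min {d.d_min} exceeds d_max {d.d_max}")
        elif not (d.d_min <= d.d_measured <= d.d_max):
            issues.append(
                f"distance {i}: measured {d.d_measured} outside [{d.d_min}, {d.d_max}]"
            )
        pair = frozenset((d.group_a, d.group_b))
        pair_counts[pair] = pair_counts.get(pair, 0) + 1
    if len(spec.distances) > MAX_DISTANCES:
        issues.append(
            f"{len(spec.distances)} distance constraints exceeds the maximum of {MAX_DISTANCES}"
        )
    for pair, count in pair_counts.items():
        if count > MAX_DISTANCES_PER_PAIR:
            issues.append(
                f"group pair {sorted(pair)}: {count} distance constraints exceeds "
                f"the per-pair maximum of {MAX_DISTANCES_PER_PAIR}"
            )

    for i, s in enumerate(spec.separations):
        for lab in (s.group_a, s.group_b):
            if lab not in labels:
                issues.append(f"separation {i}: undeclared group label {lab}")
        if s.sep_min > s.sep_max:
            issues.append(f"separation {i}: sep_min {s.sep_min} exceeds sep_max {s.sep_max}")
    return issues


def _parse_float(token: str, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise MotifFormatError(f"line {lineno}: non-numeric {what} {token!r}") from None


def _parse_int(token: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise MotifFormatError(f"line {lineno}: non-integer {what} {token!r}") from None


def parse_motif(text: str) -> MotifSpec:
    """Parse motif-format text, raising MotifFormatError on any invalid input.

    Keywords are case-insensitive; any line not starting with GROUP/DIST/DELTA
    is kept as provenance.  The returned spec always satisfies every type
    invariant (the parser rejects exactly the inputs :func:`validate` flags).
    """
    spec = MotifSpec()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        keyword = tokens[0].upper()
        if keyword == "GROUP":
            if len(tokens) != 4:
                raise MotifFormatError(
                    f"line {lineno}: GROUP needs label, residue types and secondary structure"
                )
            label = _parse_int(tokens[1], lineno, "group label")
            types = frozenset(tokens[2].upper())
            ss_token = tokens[3].lower()
            ss = frozenset("hsc") if ss_token == "*" else frozenset(ss_token)
            spec.groups.append(GroupConstraint(label, types, ss))
        elif keyword == "DIST":
            if len(tokens) != 8:
                raise MotifFormatError(
                    f"line {lineno}: DIST needs two (group, atom) pairs and min/measured/max"
                )
            spec.distances.append(
                DistanceConstraint(
                    group_a=_parse_int(tokens[1], lineno, "group label"),
                    atom_a=tokens[2].upper(),
                    group_b=_parse_int(tokens[3], lineno, "group label"),
                    atom_b=tokens[4].upper(),
                    d_min=_parse_float(tokens[5], lineno, "minimum distance"),
                    d_measured=_parse_float(tokens[6], lineno, "measured distance"),
                    d_max=_parse_float(tokens[7], lineno, "maximum distance"),
                )
            )
        elif keyword == "DELTA":
            if len(tokens) != 5:
                raise MotifFormatError(
                    f"line {lineno}: DELTA needs two group labels and min/max separation"
                )
            spec.separations.append(
                SeparationConstraint(
                    group_a=_parse_int(tokens[1], lineno, "group label"),
                    group_b=_parse_int(tokens[2], lineno, "group label"),
                    sep_min=_parse_int(tokens[3], lineno, "minimum separation"),
                    sep_max=_parse_int(tokens[4], lineno, "maximum separation"),
                )
            )
        else:
            spec.provenance.append(raw.rstrip("\r"))

    issues = validate(spec)
    if issues:
        raise MotifFormatError("; ".join(issues))
    return spec


def _fmt(value: float) -> str:
    # Fixed 3-decimal rendering: distances are stored on a milli-Å grid so
    # write -> parse round-trips exactly.
    return f"{value:.3f}"


def write_motif(spec: MotifSpec) -> str:
    """Render a spec as motif-format text (GROUP, DIST, then DELTA block).

    The output re-parses to a field-for-field identical spec.
    """
    issues = validate(spec)
    if issues:
        raise MotifFormatError("; ".join(issues))
    lines = list(spec.provenance)
    for g in spec.groups:
        ss = "*" if g.allowed_ss == frozenset("hsc") else "".join(sorted(g.allowed_ss))
        lines.append(f"GROUP {g.label} {''.join(sorted(g.allowed_types))} {ss}")
    for d in spec.distances:
        lines.append(
            f"DIST {d.group_a} {d.atom_a} {d.group_b} {d.atom_b} "
            f"{_fmt(d.d_min)} {_fmt(d.d_measured)} {_fmt(d.d_max)}"
        )
    for s in spec.separations:
        lines.append(f"DELTA {s.group_a} {s.group_b} {s.sep_min} {s.sep_max}")
    return "\n".join(lines) + "\n"
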
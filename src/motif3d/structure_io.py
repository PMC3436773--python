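"""Read and write PDB coordinate files into a lightweight residue/atom model.

The in-memory model deliberately flattens the PDB hierarchy to what motif
searching needs: chains of residues in file order, each residue carrying its
heavy atoms (one coordinate per atom name after alternate-location
resolution), a one-letter residue type, and a secondary-structure label in
{h, s, c}.  Parsing is delegated to :mod:`gemmi`; this module applies the
normalisation policy on top of it:

* first model only (multi-model entries are typically NMR ensembles),
* alternate locations resolved to the highest-occupancy conformer
  (ties broken by file order),
* HETATM records skipped except selenomethionine (MSE, typed ``M``),
* waters and hydrogens dropped.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple, Union

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueView",
    "StructureModel",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "write_pdb_string",
    "assign_secondary_structure",
    "get_atom",
    "backbone_torsions",
]

# Residue key: (chain id, PDB residue number, insertion code or "")
ResidueKey = Tuple[str, int, str]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}

# Torsion-angle windows (degrees) for secondary-structure assignment, plus
# the minimum run length for a label to stick.  Exposed at module level so a
# different backend or window set can be swapped in.
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -40.0)
STRAND_PSI = ((90.0, 180.0), (-180.0, -170.0))
HELIX_MIN_RUN = 4
STRAND_MIN_RUN = 3

# C(i-1)-N(i) beyond this distance is treated as a chain break.
PEPTIDE_BOND_MAX = 2.0


class PDBParseError(ValueError):
    """Raised for unreadable or malformed PDB input."""


@dataclass
class AtomRecord:
    """One atom: PDB atom name, element symbol, coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name or len(self.name) > 4:
            raise ValueError(f"invalid atom name {self.name!r}")


@dataclass
class ResidueView:
    """One residue with its atoms keyed by atom name.

    ``ordinal`` is the residue's 0-based position within its chain after
    parsing; sequence-separation constraints are evaluated on ordinals so
    that author-assigned numbering gaps do not distort separations.
    """

    chain_id: str
    seq_number: int
    insertion_code: str
    res_type: str
    res_name: str
    atoms: Dict[str, AtomRecord] = field(default_factory=dict)
    ss_label: str = "c"
    ordinal: int = -1

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def get_atom(self, atom_name: str) -> Optional[np.ndarray]:
        rec = self.atoms.get(atom_name)
        return None if rec is None else rec.coords


@dataclass
class StructureModel:
    """A parsed structure: chains of residues in file order."""

    structure_id: str
    chains: Dict[str, List[ResidueView]] = field(default_factory=dict)
    source: str = ""

    def residues(self) -> Iterator[ResidueView]:
        for chain in self.chains.values():
            yield from chain

    def residue(self, key: ResidueKey) -> ResidueView:
        index = self.__dict__.get("_index")
        if index is None or len(index) != len(self):
            index = {res.key: res for res in self.residues()}
            self.__dict__["_index"] = index
        try:
            return index[key]
        except KeyError:
            raise KeyError(
                f"residue {key!r} not in structure {self.structure_id!r}"
            ) from None

    def __len__(self) -> int:
        return sum(len(c) for c in self.chains.values())


def get_atom(residue: ResidueView, atom_name: str) -> Optional[np.ndarray]:
    """Coordinates of ``atom_name`` in ``residue``, or None when absent."""
    return residue.get_atom(atom_name)


def _validate_coordinate_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fragment = line[lo:hi]
            try:
                float(fragment)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field {fragment.strip()!r}"
                ) from None


def _looks_like_content(text: str) -> bool:
    if "\n" in text:
        return True
    return text.startswith(("ATOM", "HETATM", "HEADER", "MODEL", "REMARK"))


def _resolve_altlocs(atoms: List[AtomRecord]) -> Dict[str, AtomRecord]:
    """Keep one atom per name: highest occupancy, ties to the first seen."""
    best: Dict[str, AtomRecord] = {}
    for atom in atoms:
        held = best.get(atom.name)
        if held is None or atom.occupancy > held.occupancy:
            best[atom.name] = atom
    return best


def read_pdb(text_or_path: Union[str, Path]) -> StructureModel:
    """Parse PDB-format content (a path or the raw text) into a model.

    Only the first model is read.  Every residue receives a secondary-
    structure label before the model is returned.
    """
    if isinstance(text_or_path, Path):
        source, text = str(text_or_path), text_or_path.read_text()
    elif isinstance(text_or_path, str) and not _looks_like_content(text_or_path):
        if not os.path.exists(text_or_path):
            raise PDBParseError(f"no such file: {text_or_path}")
        source, text = text_or_path, Path(text_or_path).read_text()
    else:
        source, text = "<string>", str(text_or_path)

    _validate_coordinate_lines(text)
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(str(exc)) from exc

    gemmi_name = structure.name.strip().lower()
    if gemmi_name in ("", "string"):  # gemmi's placeholder for header-less text
        gemmi_name = ""
    stem = "" if source == "<string>" else Path(source).stem
    structure_id = gemmi_name or stem or "structure"

    model = StructureModel(structure_id=structure_id, source=source)
    if len(structure) == 0:
        raise PDBParseError("no ATOM records found")

    first_model = structure[0]
    for gchain in first_model:
        for gres in gchain:
            name = gres.name.strip().upper()
            if name in _WATER_NAMES:
                continue
            if gres.het_flag == "H" and name != "MSE":
                continue
            kept: List[AtomRecord] = []
            for gatom in gres:
                is_h = gatom.element.is_hydrogen
                if is_h() if callable(is_h) else is_h:  # method pre-gemmi-0.7
                    continue
                kept.append(
                    AtomRecord(
                        name=gatom.name.strip(),
                        element=gatom.element.name,
                        coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=gatom.occ,
                        altloc=gatom.altloc.replace("\x00", ""),
                    )
                )
            if not kept:
                continue
            icode = gres.seqid.icode.strip()
            residue = ResidueView(
                chain_id=gchain.name,
                seq_number=gres.seqid.num,
                insertion_code=icode,
                res_type=THREE_TO_ONE.get(name, "X"),
                res_name=name,
                atoms=_resolve_altlocs(kept),
            )
            chain = model.chains.setdefault(gchain.name, [])
            if any(r.key == residue.key for r in chain):
                raise PDBParseError(f"duplicate residue key {residue.key!r}")
            chain.append(residue)

    if len(model) == 0:
        raise PDBParseError("no ATOM records found")

    for chain in model.chains.values():
        for i, res in enumerate(chain):
            res.ordinal = i

    return assign_secondary_structure(model)


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return math.degrees(math.atan2(y, x))


def backbone_torsions(chain: List[ResidueView]) -> List[Tuple[Optional[float], Optional[float]]]:
    """Per-residue (phi, psi) for a chain; None where not computable.

    A torsion is computable only when the flanking peptide bond is intact
    (C-N within :data:`PEPTIDE_BOND_MAX`), so chain breaks never contribute
    spurious angles.
    """
    out: List[Tuple[Optional[float], Optional[float]]] = []
    for i, res in enumerate(chain):
        n, ca, c = res.get_atom("N"), res.get_atom("CA"), res.get_atom("C")
        phi = psi = None
        if n is not None and ca is not None and c is not None:
            if i > 0:
                c_prev = chain[i - 1].get_atom("C")
                if c_prev is not None and np.linalg.norm(n - c_prev) <= PEPTIDE_BOND_MAX:
                    phi = _dihedral(c_prev, n, ca, c)
            if i + 1 < len(chain):
                n_next = chain[i + 1].get_atom("N")
                if n_next is not None and np.linalg.norm(n_next - c) <= PEPTIDE_BOND_MAX:
                    psi = _dihedral(n, ca, c, n_next)
        out.append((phi, psi))
    return out


def _in_window(value: float, window: Tuple[float, float]) -> bool:
    return window[0] <= value <= window[1]


def assign_secondary_structure(model: StructureModel) -> StructureModel:
    """Label every residue h/s/c from backbone torsion windows.

    A residue is a helix candidate when both phi and psi fall in the helical
    window, a strand candidate in the extended window; candidates become h/s
    only in consecutive runs of at least HELIX_MIN_RUN / STRAND_MIN_RUN
    residues.  Anything else — including residues whose torsions cannot be
    computed — is coil.
    """
    for chain in model.chains.values():
        torsions = backbone_torsions(chain)
        raw: List[str] = []
        for phi, psi in torsions:
            if phi is None or psi is None:
                raw.append("c")
            elif _in_window(phi, HELIX_PHI) and _in_window(psi, HELIX_PSI):
                raw.append("h")
            elif _in_window(phi, STRAND_PHI) and any(
                _in_window(psi, w) for w in STRAND_PSI
            ):
                raw.append("s")
            else:
                raw.append("c")
        labels = ["c"] * len(raw)
        i = 0
        while i < len(raw):
            j = i
            while j < len(raw) and raw[j] == raw[i]:
                j += 1
            run, length = raw[i], j - i
            if (run == "h" and length >= HELIX_MIN_RUN) or (
                run == "s" and length >= STRAND_MIN_RUN
            ):
                for k in range(i, j):
                    labels[k] = run
            i = j
        for res, label in zip(chain, labels):
            res.ss_label = label
    return model


def _format_atom_name(name: str) -> str:
    # Names of <4 chars conventionally start in column 14 for C/N/O/S atoms.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3}"


def write_pdb_string(model: StructureModel) -> str:
    """Render a model as minimal, re-readable PDB v3 text."""
    if len(model) == 0:
        raise ValueError("refusing to write a structure with no residues")
    lines: List[str] = []
    serial = 0
    for chain_id, chain in model.chains.items():
        for res in chain:
            record = "HETATM" if res.res_name == "MSE" else "ATOM  "
            for atom in res.atoms.values():
                serial += 1
                lines.append(
                    f"{record}{serial:>5} {_format_atom_name(atom.name)} "
                    f"{res.res_name:>3} {chain_id[:1]}{res.seq_number:>4}"
                    f"{res.insertion_code or ' ':1}   "
                    f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2}"
                )
        lines.append(f"TER   {serial + 1:>5}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(model: StructureModel, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(write_pdb_string(model))
    return path
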
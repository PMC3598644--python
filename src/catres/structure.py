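"""Typed model of a single protein chain read from PDB ATOM records.

The chain model keeps only heavy atoms of standard amino-acid residues;
it is the substrate for the contact graph, the general-center-of-mass
geometry and the solvent-accessibility calculation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Standard atomic weights (daltons) for elements common in protein heavy atoms.
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}

#: Three-letter to one-letter codes of the 20 standard amino acids.
AA_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA_1TO3: dict[str, str] = {v: k for k, v in AA_3TO1.items()}

#: Common non-standard residues with an unambiguous standard parent.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine -> closest standard type
    "HYP": "PRO",
    "MLY": "LYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "CSO": "CYS",
    "PCA": "GLU",
}

_HYDROGEN = {"H", "D"}  # deuterium treated as hydrogen


class ChainNotFoundError(ValueError):
    """Requested chain identifier has no ATOM records."""


class EmptyChainError(ValueError):
    """Chain has no standard amino-acid residues."""


class PDBParseError(ValueError):
    """A malformed record; the message names the offending line."""


@dataclass
class Atom:
    """A heavy atom: element, standard atomic mass (Da), position (Å)."""

    name: str
    element: str
    mass: float
    coord: np.ndarray  # shape (3,)
    residue_index: int

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.mass <= 0:
            raise ValueError("atomic mass must be positive")


@dataclass
class Residue:
    """One standard amino-acid residue with its heavy atoms."""

    chain_id: str
    number: int
    icode: str
    aa: str  # one-letter type
    atoms: list[Atom] = field(default_factory=list)
    ca: np.ndarray | None = None  # Cα coordinates, absent in some models

    @property
    def label(self) -> str:
        """Author residue number plus insertion code, e.g. ``'52'`` or ``'52A'``."""
        return f"{self.number}{self.icode}".strip()

    @property
    def has_ca(self) -> bool:
        return self.ca is not None


@dataclass
class ProteinChain:
    """Ordered residues of one PDB chain."""

    residues: list[Residue]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def atoms(self) -> list[Atom]:
        """All heavy atoms of the chain in residue order."""
        return [a for r in self.residues for a in r.atoms]


def _element_of(line: str, atom_name: str) -> str:
    elem = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not elem:
        # Fall back on the atom-name convention: first alphabetic character
        # of the justified name field, two-letter elements right-justified.
        stripped = atom_name.strip()
        elem = "".join(c for c in stripped if c.isalpha())[:1].upper()
        if stripped[:2].upper() in ("SE", "CL", "BR"):
            elem = stripped[:2].upper()
    return elem


def _mass_of(element: str) -> float:
    if element in ATOMIC_MASSES:
        return ATOMIC_MASSES[element]
    logger.warning("unknown element %r: using carbon mass", element)
    return ATOMIC_MASSES["C"]


def parse_pdb_chain(pdb_text: str, chain_id: str) -> ProteinChain:
    """Parse the ATOM records of one chain into a :class:`ProteinChain`.

    Hydrogens, waters, HETATM ligands and alternate-location duplicates are
    excluded; of several altLocs for one atom the highest occupancy wins
    (ties: first seen).  Non-standard residues with a standard parent
    (e.g. MSE) are mapped to that parent; others are skipped with a warning.
    Only the first model of a multi-model file is read.

    Raises
    ------
    ChainNotFoundError
        if no ATOM/HETATM record carries *chain_id*.
    EmptyChainError
        if the chain yields no standard residue.
    PDBParseError
        on a malformed coordinate field, naming the line.
    """
    chain_seen = False
    # residue key -> dict(atom name -> (occupancy, order, Atom fields))
    residues: dict[tuple[int, str], dict] = {}
    order = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[0:6].strip()
        if rec == "ENDMDL":
            break  # first model only
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM record: {line!r}")
        if line[21] != chain_id:
            continue
        chain_seen = True
        resname = line[17:20].strip().upper()
        if resname == "HOH":
            continue
        if resname in NONSTANDARD_PARENT:
            resname = NONSTANDARD_PARENT[resname]
        elif resname not in AA_3TO1:
            if rec == "ATOM":
                logger.warning(
                    "skipping non-standard residue %s with no standard parent", resname
                )
            continue
        elif rec == "HETATM":
            continue  # free amino-acid ligand, not part of the polymer
        atom_name = line[12:16]
        element = _element_of(line, atom_name)
        if element in _HYDROGEN:
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(
                f"line {lineno}: malformed coordinate field: {line!r}"
            ) from exc
        try:
            occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
        except ValueError:
            occupancy = 1.0
        try:
            resnum = int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(
                f"line {lineno}: malformed residue number: {line!r}"
            ) from exc
        icode = line[26].strip()
        key = (resnum, icode)
        entry = residues.setdefault(key, {"aa": AA_3TO1[resname], "atoms": {}, "order": order})
        order += 1
        name_key = atom_name.strip()
        prev = entry["atoms"].get(name_key)
        if prev is None or occupancy > prev[0]:
            entry["atoms"][name_key] = (
                occupancy,
                order,
                (atom_name.strip(), element, np.array([x, y, z])),
            )

    if not chain_seen:
        raise ChainNotFoundError(f"chain not found: {chain_id!r}")
    if not residues:
        raise EmptyChainError(f"empty chain: no standard residues in chain {chain_id!r}")

    ordered = sorted(residues.items(), key=lambda kv: kv[1]["order"])
    out: list[Residue] = []
    for idx, ((resnum, icode), entry) in enumerate(ordered):
        atoms: list[Atom] = []
        ca = None
        for _occ, _ord, (name, element, coord) in sorted(
            entry["atoms"].values(), key=lambda t: t[1]
        ):
            atoms.append(Atom(name, element, _mass_of(element), coord, idx))
            if name == "CA" and element == "C":
                ca = coord
        if ca is None:
            logger.warning("residue %s%s has no Cα record", resnum, icode)
        out.append(Residue("", resnum, icode, entry["aa"], atoms, ca))
    for r in out:
        r.chain_id = chain_id
    return ProteinChain(out, source_id=f"?{chain_id}")


def chain_sequence(chain: ProteinChain) -> str:
    """One-letter sequence of the chain in residue order."""
    if len(chain) == 0:
        raise EmptyChainError("empty chain")
    return chain.sequence


def write_pdb_chain(chain: ProteinChain) -> str:
    """Serialize the chain as minimal fixed-column ATOM records (round-trip subset)."""
    lines = []
    serial = 1
    for res in chain.residues:
        res3 = AA_1TO3[res.aa]
        for atom in res.atoms:
            name = atom.name
            # PDB atom-name justification: 1-char elements start in column 14
            field_name = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {field_name[:4]} {res3} {res.chain_id}"
                f"{res.number:4d}{res.icode or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
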
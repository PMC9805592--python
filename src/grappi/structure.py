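"""Typed protein structure hierarchy and PDB coordinate file I/O.

A :class:`Structure` holds exactly two protein chains as ordered lists of
residues, each residue an ordered list of heavy atoms.  Hydrogens, waters
and heteroatom records are removed at parse time, so every distance
computed downstream is a heavy-atom distance by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

from .errors import ChainNotFoundError, ParseError

#: The 20 canonical amino acids, 3-letter codes, alphabetical order.
CANONICAL_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    """A heavy atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")


@dataclass
class Residue:
    """A residue identified by (chain_id, number, insertion_code)."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def is_canonical(self) -> bool:
        return self.name in CANONICAL_RESIDUES

    def coords(self) -> np.ndarray:
        """Heavy-atom coordinates, shape (n_atoms, 3)."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def atom_coord(self, name: str) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == name:
                return a.coord
        return None


@dataclass
class Structure:
    """A two-chain protein complex restricted to heavy atoms.

    ``chains`` maps chain id to the ordered residue list; the mapping
    preserves the order in which chains were requested from the parser.
    """

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    @property
    def chain_ids(self) -> tuple[str, ...]:
        return tuple(self.chains)

    def residues(self) -> list[Residue]:
        return [r for res_list in self.chains.values() for r in res_list]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def residue(self, key: tuple[str, int, str]) -> Residue | None:
        for r in self.chains.get(key[0], []):
            if r.key == key:
                return r
        return None

    def copy(self) -> "Structure":
        new = Structure(id=self.id)
        for cid, residues in self.chains.items():
            new.chains[cid] = [
                Residue(r.chain_id, r.number, r.insertion_code, r.name,
                        [Atom(a.name, a.element, a.coord.copy(), a.altloc) for a in r.atoms])
                for r in residues
            ]
        return new

    def transform(self, rotation: np.ndarray, translation: np.ndarray,
                  chain_id: str | None = None) -> "Structure":
        """Return a copy with ``x -> R x + t`` applied to one chain or all."""
        new = self.copy()
        targets = [chain_id] if chain_id is not None else list(new.chains)
        for cid in targets:
            for r in new.chains[cid]:
                for a in r.atoms:
                    a.coord = rotation @ a.coord + translation
        return new


def _pick_altloc(bio_residue, atom_name):
    """Highest-occupancy conformer; ties broken by file order."""
    atom = bio_residue[atom_name]
    if not atom.is_disordered():
        return atom
    best = None
    for child in atom.disordered_get_list():
        if best is None or (child.get_occupancy() or 0.0) > (best.get_occupancy() or 0.0):
            best = child
    return best


def read_structure(path: str | Path, chains: tuple[str, str]) -> Structure:
    """Read a two-chain protein complex from a PDB coordinate file.

    Only ``ATOM`` records of the two requested chains are kept; hydrogens,
    waters and HETATM-derived residues (including MSE) are dropped.  For
    alternate locations the highest-occupancy conformer is retained, ties
    resolved by file order.  Models beyond the first are ignored with a
    warning.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ChainNotFoundError
        If a requested chain is absent or has no protein residues.
    ParseError
        If the file contains no parsable ATOM records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        model_obj = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Biopython reports the offending line itself
        raise ParseError(f"{path}: {exc}") from exc
    models = list(model_obj)
    if not models:
        raise ParseError(f"{path}: no coordinate model found")
    if len(models) > 1:
        warnings.warn(f"{path}: {len(models)} models present, using the first")
    model = models[0]

    structure = Structure(id=path.stem)
    present = {c.id for c in model}
    for cid in chains:
        if cid not in present:
            raise ChainNotFoundError(f"{path}: chain not found: {cid!r}")
        residues: list[Residue] = []
        for bio_res in model[cid]:
            hetflag, resseq, icode = bio_res.get_id()
            if hetflag.strip():
                continue  # HETATM-derived (waters, MSE, ligands)
            if not is_aa(bio_res, standard=False) and not _looks_proteinaceous(bio_res):
                continue
            atoms = []
            for bio_atom in bio_res:
                chosen = _pick_altloc(bio_res, bio_atom.get_id())
                element = (chosen.element or "").strip().upper()
                if element == "H" or (not element and chosen.get_name().lstrip("0123456789").startswith("H")):
                    continue
                atoms.append(Atom(
                    name=chosen.get_name(),
                    element=element or chosen.get_name()[0],
                    coord=np.asarray(chosen.get_coord(), dtype=float),
                    altloc=chosen.get_altloc().strip(),
                ))
            if not atoms:
                continue
            name = bio_res.get_resname().strip()
            if name not in CANONICAL_RESIDUES:
                warnings.warn(f"{path}: nonstandard residue {name} {cid}{resseq} retained")
            residues.append(Residue(cid, resseq, icode.strip(), name, atoms))
        if not residues:
            raise ChainNotFoundError(f"{path}: chain {cid!r} has no protein residues")
        structure.chains[cid] = residues
    return structure


def _looks_proteinaceous(bio_res) -> bool:
    """ATOM-record residues with backbone atoms count as protein even if
    their name is nonstandard (kept but flagged)."""
    names = {a.get_name() for a in bio_res}
    return {"N", "CA", "C"} <= names


_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-column PDB ATOM records (wwPDB v3.3).

    Coordinates are written to 3 decimals; a read/write round trip
    preserves residue keys and coordinates to 1e-3 A.
    """
    residues = structure.residues()
    if not residues:
        raise ValueError("cannot write an empty Structure")
    path = Path(path)
    serial = 0
    with open(path, "w") as fh:
        prev_chain = None
        for res in residues:
            if prev_chain is not None and res.chain_id != prev_chain:
                fh.write("TER\n")
            prev_chain = res.chain_id
            for atom in res.atoms:
                serial += 1
                # wwPDB: 1-3 char atom names start in column 14
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(_ATOM_FMT.format(
                    serial=serial, name=name, altloc=atom.altloc or " ",
                    resname=res.name, chain=res.chain_id, resseq=res.number,
                    icode=res.insertion_code or " ",
                    x=atom.coord[0], y=atom.coord[1], z=atom.coord[2],
                    occ=1.0, b=0.0, element=atom.element[:2],
                ))
        fh.write("TER\nEND\n")
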
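"""Reading and writing predicted-structure files and their pLDDT conventions.

Structure predictors write their per-residue confidence (pLDDT, 0-100) into
the B-factor column.  Conventions differ: AF2-style files repeat one value on
every atom of a residue, AF3-style files carry genuinely atomic values that
must be averaged per residue, and RFAA writes the whole scale as 0-1.  This
module reads PDB/mmCIF into a light in-memory model and normalises those
dialects.

Residue numbering is 1-based author numbering end to end; list indices are
0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

Dialect = Literal["residue_bfactor", "atomic_bfactor"]

#: 1-letter -> 3-letter residue codes for the 20 standard amino acids.
ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


@dataclass
class Atom:
    """A single atom: name, element symbol, position in Å, B-factor."""

    name: str
    element: str
    position: np.ndarray
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    """One residue: author seqid (1-based), 1-letter code, atoms."""

    seqid: int
    code: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def sidechain_atoms(self) -> list[Atom]:
        """Atoms beyond the backbone (N, CA, C, O)."""
        return [a for a in self.atoms if a.name not in ("N", "CA", "C", "O")]


@dataclass
class StructureModel:
    """An ordered single-chain structure with optional per-residue pLDDT."""

    chain_id: str = "A"
    residues: list[Residue] = field(default_factory=list)
    source: str = ""
    dialect: Dialect = "residue_bfactor"
    _plddt: np.ndarray | None = None

    def __post_init__(self) -> None:
        seqids = [r.seqid for r in self.residues]
        if any(b <= a for a, b in zip(seqids, seqids[1:])):
            raise ValueError("residue seqids must be strictly increasing")
        if any(not r.atoms for r in self.residues):
            raise ValueError("every residue must have at least one atom")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of CA positions; first atom stands in if CA absent."""
        rows = []
        for r in self.residues:
            a = r.ca or r.atoms[0]
            rows.append(a.position)
        return np.array(rows)

    def all_atoms(self) -> list[tuple[int, Atom]]:
        """Flat list of (residue index, atom) pairs, in order."""
        return [(i, a) for i, r in enumerate(self.residues) for a in r.atoms]


def residue_plddt(model: StructureModel, dialect: Dialect | None = None) -> np.ndarray:
    """Per-residue pLDDT from B-factors.

    ``residue_bfactor`` (AF2 style) reads the CA atom; if a residue lacks a
    CA the mean over its atoms is used with a logged warning.
    ``atomic_bfactor`` (AF3 style) averages, unweighted, over all atoms of
    the residue.
    """
    if model._plddt is not None and dialect is None:
        return model._plddt.copy()
    dialect = dialect or model.dialect
    values = np.empty(len(model))
    for i, res in enumerate(model.residues):
        if dialect == "residue_bfactor":
            ca = res.ca
            if ca is not None:
                values[i] = ca.bfactor
            else:
                logger.warning(
                    "residue %s%d has no CA; falling back to atom-mean B-factor",
                    res.code, res.seqid,
                )
                values[i] = float(np.mean([a.bfactor for a in res.atoms]))
        elif dialect == "atomic_bfactor":
            values[i] = float(np.mean([a.bfactor for a in res.atoms]))
        else:
            raise ValueError(f"unknown pLDDT dialect: {dialect!r}")
    return normalize_plddt_scale(values)


def normalize_plddt_scale(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Bring pLDDT values onto the 0-100 scale.

    RFAA writes pLDDT on 0-1; if every value is <= 1 the whole vector is
    multiplied by 100, otherwise it is returned unchanged.  Idempotent.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError(f"negative pLDDT value: {arr.min()}")
    if arr.size and arr.max() <= 1.0:
        return arr * 100.0
    return arr.copy()


def mean_plddt(model: StructureModel) -> float:
    """Mean per-residue pLDDT (after dialect extraction and scaling)."""
    return float(np.mean(residue_plddt(model)))


# ---------------------------------------------------------------------------
# gemmi-backed file I/O

def _from_gemmi(structure: gemmi.Structure, chain: str | None, source: str) -> StructureModel:
    structure.setup_entities()
    if not len(structure):
        raise ValueError(f"{source}: no models in file")
    gmodel = structure[0]
    picked = None
    for ch in gmodel:
        poly = ch.get_polymer()
        if chain is not None and ch.name != chain:
            continue
        if len(poly) or chain is not None:
            picked = ch
            break
    if picked is None:
        raise ValueError(f"{source}: no polymer chain found"
                         + (f" with id {chain!r}" if chain else ""))
    residues: list[Residue] = []
    for gres in picked:
        if gres.is_water():
            continue
        code = THREE_TO_ONE.get(gres.name.upper())
        if code is None:
            continue  # heteroatoms / non-standard residues are not audited
        atoms = [
            Atom(
                name=ga.name,
                element=ga.element.name.upper(),
                position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                bfactor=ga.b_iso,
            )
            for ga in gres
        ]
        residues.append(Residue(seqid=gres.seqid.num, code=code, atoms=atoms,
                                icode=(gres.seqid.icode or "").strip()))
    if not residues:
        raise ValueError(f"{source}: chain {picked.name!r} has no standard residues")
    return StructureModel(chain_id=picked.name, residues=residues, source=source)


def read_structure(path: str | Path, format: str = "auto",
                   chain: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file (optionally gzipped) into a StructureModel.

    Takes model 1 and the first polymer chain unless ``chain`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = {"pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        structure = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    return _from_gemmi(structure, chain, str(path))


def _to_gemmi(model: StructureModel, name: str = "model") -> gemmi.Structure:
    structure = gemmi.Structure()
    structure.name = name
    gmodel = gemmi.Model("1")
    chain = gemmi.Chain(model.chain_id)
    for res in model.residues:
        gres = gemmi.Residue()
        gres.name = ONE_TO_THREE[res.code]
        gres.seqid = gemmi.SeqId(res.seqid, res.icode or " ")
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.position)
            ga.b_iso = a.bfactor
            ga.occ = 1.0
            gres.add_atom(ga)
        chain.add_residue(gres)
    gmodel.add_chain(chain)
    structure.add_model(gmodel)
    structure.setup_entities()
    return structure


def write_structure(model: StructureModel, path: str | Path,
                    format: str = "auto") -> Path:
    """Write a StructureModel as PDB or mmCIF (chosen by extension if auto)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    structure = _to_gemmi(model, path.stem)
    if format == "pdb":
        structure.write_pdb(str(path))
    elif format == "mmcif":
        structure.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
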
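"""Structural I/O and the in-memory complex representation.

Proteins are read from PDB/mmCIF via gemmi and flattened into an ordered
heavy-atom table grouped by ``(chain_id, residue_index)``; ligands are read
from SDF V2000 via RDKit and carried as molecular graphs with a single
heavy-atom conformer.  All downstream metrics operate on heavy atoms only;
hydrogens are stripped at the door.

Residue indices are renumbered 1..n per chain in file order; the author's
numbering is kept as metadata (``author_seq_id``) and never used by metrics.
Alternate locations resolve to the highest-occupancy conformer (ties broken
by altloc label), waters are dropped by default.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from rdkit import Chem

from ._chem import THREE_TO_ONE, WATER_NAMES
from .errors import FormatError, GraphMismatchError, MissingPrimaryError

__all__ = [
    "Atom",
    "ProteinStructure",
    "LigandMol",
    "ComplexPose",
    "read_protein",
    "write_protein",
    "read_ligands",
    "write_ligands",
    "extract_primary",
]


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a protein structure."""

    element: str
    name: str
    coords: tuple[float, float, float]
    residue_index: int            # 1-based, sequential within its chain
    residue_name: str
    chain_id: str
    is_hetero: bool = False
    author_seq_id: int | None = None

    def __post_init__(self):
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")


class ProteinStructure:
    """Ordered heavy-atom collection grouped by (chain, residue)."""

    def __init__(self, atoms: Sequence[Atom]):
        if not atoms:
            raise ValueError("empty structure")
        self.atoms: list[Atom] = list(atoms)
        self._index()

    def _index(self) -> None:
        self._chains: dict[str, dict[int, list[int]]] = {}
        for i, a in enumerate(self.atoms):
            self._chains.setdefault(a.chain_id, {}).setdefault(
                a.residue_index, []).append(i)

    # -- accessors ---------------------------------------------------------

    @property
    def chain_ids(self) -> list[str]:
        return list(self._chains)

    def residues(self, chain_id: str) -> list[int]:
        return sorted(self._chains[chain_id])

    def residue_atoms(self, chain_id: str, residue_index: int) -> list[Atom]:
        return [self.atoms[i] for i in self._chains[chain_id][residue_index]]

    def residue_name(self, chain_id: str, residue_index: int) -> str:
        return self.residue_atoms(chain_id, residue_index)[0].residue_name

    def sequence(self, chain_id: str) -> str:
        return "".join(
            THREE_TO_ONE.get(self.residue_name(chain_id, r), "X")
            for r in self.residues(chain_id)
        )

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def ca_coord(self, chain_id: str, residue_index: int) -> np.ndarray | None:
        for a in self.residue_atoms(chain_id, residue_index):
            if a.name == "CA":
                return np.asarray(a.coords, dtype=float)
        return None

    def n_residues(self) -> int:
        return sum(len(r) for r in self._chains.values())

    # -- geometry ----------------------------------------------------------

    def with_coords(self, coords: np.ndarray) -> "ProteinStructure":
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.element, a.name, tuple(float(x) for x in c),
                 a.residue_index, a.residue_name, a.chain_id,
                 a.is_hetero, a.author_seq_id)
            for a, c in zip(self.atoms, coords)
        ]
        return ProteinStructure(atoms)

    def transformed(self, transform) -> "ProteinStructure":
        return self.with_coords(transform.apply(self.coords()))

    def __len__(self) -> int:
        return len(self.atoms)


class LigandMol:
    """Small-molecule graph plus one heavy-atom conformer.

    Wraps an RDKit ``Mol`` (hydrogens removed, single 3D conformer).  The
    canonical graph key is the canonical SMILES of the element/bond/charge
    graph with stereochemistry erased: predictions that flip a stereocentre
    must still be matched and scored, so stereo lives in validity checks,
    not in identity.
    """

    def __init__(self, mol: Chem.Mol, ligand_code: str = "LIG"):
        mol = Chem.Mol(mol)
        if any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
            mol = Chem.RemoveHs(mol)
        if mol.GetNumAtoms() < 1:
            raise ValueError("ligand must have at least one heavy atom")
        if mol.GetNumConformers() != 1:
            raise ValueError("ligand must carry exactly one conformer")
        self._mol = mol
        self.ligand_code = ligand_code

    @property
    def mol(self) -> Chem.Mol:
        return self._mol

    @property
    def n_atoms(self) -> int:
        return self._mol.GetNumAtoms()

    @property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self._mol.GetAtoms()]

    @property
    def formal_charges(self) -> list[int]:
        return [a.GetFormalCharge() for a in self._mol.GetAtoms()]

    @property
    def bonds(self) -> list[tuple[int, int, str]]:
        out = []
        for b in self._mol.GetBonds():
            order = ("aromatic" if b.GetIsAromatic()
                     else {1.0: "1", 2.0: "2", 3.0: "3"}.get(
                         b.GetBondTypeAsDouble(), str(b.GetBondTypeAsDouble())))
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        return out

    def coords(self) -> np.ndarray:
        return np.array(self._mol.GetConformer().GetPositions(), dtype=float)

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    @property
    def identity(self) -> str:
        flat = Chem.Mol(self._mol)
        Chem.RemoveStereochemistry(flat)
        return Chem.MolToSmiles(flat, isomericSmiles=False)

    def with_coords(self, coords: np.ndarray) -> "LigandMol":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        mol = Chem.Mol(self._mol)
        conf = mol.GetConformer()
        for i, xyz in enumerate(coords):
            conf.SetAtomPosition(i, [float(x) for x in xyz])
        return LigandMol(mol, self.ligand_code)

    def transformed(self, transform) -> "LigandMol":
        return self.with_coords(transform.apply(self.coords()))

    def permuted(self, order: Sequence[int]) -> "LigandMol":
        """Renumber atoms so new atom ``i`` is old atom ``order[i]``."""
        mol = Chem.RenumberAtoms(self._mol, list(order))
        return LigandMol(mol, self.ligand_code)


@dataclass
class ComplexPose:
    """Protein plus a role-annotated ligand set in one coordinate frame."""

    protein: ProteinStructure
    ligands: list[LigandMol]
    roles: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.roles:
            self.roles = ["primary"] + ["fragment"] * (len(self.ligands) - 1)
        if len(self.roles) != len(self.ligands):
            raise ValueError("one role per ligand required")
        bad = set(self.roles) - {"primary", "fragment"}
        if bad:
            raise ValueError(f"unknown roles: {bad}")

    @property
    def primary(self) -> LigandMol:
        idx = [i for i, r in enumerate(self.roles) if r == "primary"]
        if len(idx) != 1:
            raise ValueError(
                f"expected exactly one primary ligand, found {len(idx)}")
        return self.ligands[idx[0]]

    def transformed(self, transform) -> "ComplexPose":
        return ComplexPose(
            self.protein.transformed(transform),
            [lig.transformed(transform) for lig in self.ligands],
            list(self.roles),
        )

    def copy(self) -> "ComplexPose":
        return ComplexPose(
            self.protein.with_coords(self.protein.coords()),
            [lig.with_coords(lig.coords()) for lig in self.ligands],
            list(self.roles),
        )


# ---------------------------------------------------------------------------
# protein I/O
# ---------------------------------------------------------------------------

def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties to first altloc label."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif atom.occ > prev.occ or (atom.occ == prev.occ
                                     and atom.altloc < prev.altloc
                                     and prev.altloc != "\x00"):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_protein(path, fmt: str | None = None,
                 keep_waters: bool = False) -> ProteinStructure:
    """Read a PDB or mmCIF file into a heavy-atom :class:`ProteinStructure`.

    ``fmt`` is inferred from the extension when omitted.  Hydrogens and (by
    default) waters are discarded; altlocs collapse to the highest-occupancy
    conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    coor_fmt = {None: gemmi.CoorFormat.Detect,
                "PDB": gemmi.CoorFormat.Pdb,
                "mmCIF": gemmi.CoorFormat.Mmcif}.get(
                    fmt, gemmi.CoorFormat.Detect)
    try:
        st = gemmi.read_structure(str(path), format=coor_fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if not len(st) or not len(st[0]):
        raise FormatError(f"empty structure: {path}")
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        res_counter = 0
        for residue in chain:
            if residue.name in WATER_NAMES and not keep_waters:
                continue
            picked = [a for a in _resolve_altlocs(residue)
                      if a.element.name != "H" and a.element.name != "D"]
            if not picked:
                continue
            res_counter += 1
            hetero = residue.het_flag == "H"
            for a in picked:
                atoms.append(Atom(
                    element=a.element.name,
                    name=a.name,
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    residue_index=res_counter,
                    residue_name=residue.name,
                    chain_id=chain.name,
                    is_hetero=hetero,
                    author_seq_id=residue.seqid.num,
                ))
    if not atoms:
        raise FormatError(f"no heavy atoms found in {path}")
    return ProteinStructure(atoms)


def write_protein(structure: ProteinStructure, path) -> None:
    """Write a structure as PDB (coordinates at the format's 10^-3 Å grid)."""
    st = gemmi.Structure()
    st.name = "poseval"
    model = gemmi.Model("1")
    for chain_id in structure.chain_ids:
        chain = gemmi.Chain(chain_id)
        for ri in structure.residues(chain_id):
            res_atoms = structure.residue_atoms(chain_id, ri)
            res = gemmi.Residue()
            res.name = res_atoms[0].residue_name
            res.seqid = gemmi.SeqId(res_atoms[0].author_seq_id or ri, " ")
            res.het_flag = "H" if res_atoms[0].is_hetero else "A"
            for a in res_atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = 1.0
                res.add_atom(ga)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    st.write_pdb(str(doc_path))


# ---------------------------------------------------------------------------
# ligand I/O
# ---------------------------------------------------------------------------

def _graph_key(mol: Chem.Mol) -> str:
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    return Chem.MolToSmiles(Chem.RemoveHs(flat), isomericSmiles=False)


def read_ligands(sdf_path, smiles: Sequence[str] | None = None,
                 codes: Sequence[str] | None = None) -> list[LigandMol]:
    """Read an SDF (V2000) into a list of :class:`LigandMol`.

    When ``smiles`` is given (one per block, order-matched), each block's
    molecular graph must agree with the corresponding SMILES graph —
    stereochemistry excluded — or a :class:`GraphMismatchError` is raised.
    """
    sdf_path = Path(sdf_path)
    if not sdf_path.exists():
        raise FormatError(f"no such file: {sdf_path}")
    supplier = Chem.SDMolSupplier(str(sdf_path), removeHs=True, sanitize=True)
    ligands: list[LigandMol] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise FormatError(f"unparseable or valence-invalid SDF block {i} "
                              f"in {sdf_path}")
        code = (codes[i] if codes is not None
                else (mol.GetProp("_Name").strip() or f"LIG{i}")
                if mol.HasProp("_Name") and mol.GetProp("_Name").strip()
                else f"LIG{i}")
        if smiles is not None:
            want = Chem.MolFromSmiles(smiles[i])
            if want is None:
                raise FormatError(f"invalid SMILES for block {i}: {smiles[i]}")
            if _graph_key(mol) != _graph_key(want):
                raise GraphMismatchError(
                    f"SDF block {i} graph does not match SMILES {smiles[i]!r}")
        ligands.append(LigandMol(mol, code))
    if not ligands:
        raise FormatError(f"no molecules in {sdf_path}")
    return ligands


def write_ligands(ligands: Iterable[LigandMol], path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for lig in ligands:
        mol = Chem.Mol(lig.mol)
        mol.SetProp("_Name", lig.ligand_code)
        writer.write(mol)
    writer.close()


def extract_primary(pred: ComplexPose, ref_primary: LigandMol) -> LigandMol:
    """Pick the predicted fragment matching the reference primary ligand.

    Matching is by canonical graph key; among several graph-identical
    candidates the one with the nearest heavy-atom centroid wins.  A missing
    match raises :class:`MissingPrimaryError`, which the evaluation driver
    converts into an excluded prediction.
    """
    if not pred.ligands:
        raise MissingPrimaryError("prediction contains no ligands")
    key = ref_primary.identity
    candidates = [lig for lig in pred.ligands if lig.identity == key]
    if not candidates:
        raise MissingPrimaryError(
            f"no predicted fragment matches primary graph {key!r}")
    ref_c = ref_primary.centroid()
    return min(candidates,
               key=lambda lig: float(np.linalg.norm(lig.centroid() - ref_c)))
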
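"""Geometric and chemical pose sanity checks ("PB-Valid" style).

A predicted pose can have an excellent RMSD and still be chemically
nonsensical — stretched bonds, puckered aromatic rings, atoms inside the
protein.  These checks flag such poses with deterministic geometric rules:

* bond lengths within [0.75, 1.25] × a reference length (covalent-radius
  sums scaled by bond order),
* bond angles within [0.75, 1.25] × the ideal hybridization angle,
* non-bonded intramolecular heavy-atom pairs at >= 0.8 × the van der Waals
  radius sum,
* aromatic rings and double-bond frames flat to <= 0.25 Å (max deviation
  from the least-squares plane),
* no protein–ligand or ligand–ligand heavy-atom pair closer than 0.75 × the
  van der Waals radius sum.

The force-field energy-ratio check used by the original suite is
deliberately not part of the verdict: it is recorded as "not evaluated" to
keep the toolkit deterministic and dependency-light.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist

from ._chem import covalent_radius, vdw_radius
from .model_io import ComplexPose, LigandMol

__all__ = [
    "GeometryTolerances",
    "Violation",
    "ValidityReport",
    "check_ligand_geometry",
    "check_intermolecular",
    "check_stereo",
    "pb_valid",
]

# bond-order contraction factors applied to the single-bond covalent sum
_ORDER_FACTOR = {1.0: 1.0, 1.5: 0.93, 2.0: 0.87, 3.0: 0.78}
_IDEAL_ANGLE = {
    Chem.HybridizationType.SP3: 109.47,
    Chem.HybridizationType.SP2: 120.0,
    Chem.HybridizationType.SP: 180.0,
}


@dataclass
class GeometryTolerances:
    bond_length_ratio: tuple = (0.75, 1.25)
    bond_angle_ratio: tuple = (0.75, 1.25)
    intramolecular_vdw_factor: float = 0.8
    intermolecular_vdw_factor: float = 0.75
    flatness_max: float = 0.25


@dataclass(frozen=True)
class Violation:
    check: str
    atoms: tuple
    value: float
    bound: float


@dataclass
class ValidityReport:
    """Per-check flags; ``None`` marks a check that was not evaluated."""

    sanitizable: bool | None = None
    bond_lengths_ok: bool | None = None
    bond_angles_ok: bool | None = None
    internal_clash_free: bool | None = None
    aromatic_rings_flat: bool | None = None
    double_bonds_flat: bool | None = None
    protein_ligand_clash_free: bool | None = None
    inter_ligand_clash_free: bool | None = None
    stereo_preserved: bool | None = None
    energy_ratio_ok: bool | None = None   # always None: not evaluated here
    details: list = field(default_factory=list)

    _FLAGS = ("sanitizable", "bond_lengths_ok", "bond_angles_ok",
              "internal_clash_free", "aromatic_rings_flat",
              "double_bonds_flat", "protein_ligand_clash_free",
              "inter_ligand_clash_free", "stereo_preserved",
              "energy_ratio_ok")

    @property
    def pb_valid(self) -> bool:
        evaluated = [getattr(self, f) for f in self._FLAGS
                     if getattr(self, f) is not None]
        return all(evaluated) if evaluated else False

    def merge(self, other: "ValidityReport") -> "ValidityReport":
        """Conjunction of two reports (None = not evaluated is neutral)."""
        out = ValidityReport(details=self.details + other.details)
        for f in self._FLAGS:
            a, b = getattr(self, f), getattr(other, f)
            setattr(out, f, a if b is None else b if a is None else (a and b))
        return out

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self._FLAGS}
        d["pb_valid"] = self.pb_valid
        d["violations"] = [vars(v) | {"atoms": list(v.atoms)}
                           for v in self.details]
        return d


def _plane_max_residual(points: np.ndarray) -> float:
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return float(np.abs(centred @ vt[2]).max())


def check_ligand_geometry(ligand: LigandMol,
                          tol: GeometryTolerances | None = None
                          ) -> ValidityReport:
    """Run the intramolecular geometry checks on one ligand."""
    tol = tol or GeometryTolerances()
    report = ValidityReport()
    mol = Chem.Mol(ligand.mol)
    try:
        Chem.SanitizeMol(mol)
        report.sanitizable = True
    except (Chem.AtomValenceException, Chem.KekulizeException, ValueError):
        report.sanitizable = False
        return report

    xyz = ligand.coords()
    elements = ligand.elements
    n = ligand.n_atoms

    # bond lengths
    ok = True
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        factor = _ORDER_FACTOR.get(
            1.5 if bond.GetIsAromatic() else bond.GetBondTypeAsDouble(), 1.0)
        ref = (covalent_radius(elements[i]) +
               covalent_radius(elements[j])) * factor
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        lo, hi = tol.bond_length_ratio
        if not lo * ref <= d <= hi * ref:
            ok = False
            report.details.append(Violation("bond_length", (i, j), d, ref))
    report.bond_lengths_ok = ok

    # bond angles
    ok = True
    for atom in mol.GetAtoms():
        nbrs = [a.GetIdx() for a in atom.GetNeighbors()]
        if len(nbrs) < 2:
            continue
        ideal = _IDEAL_ANGLE.get(atom.GetHybridization())
        if atom.GetIsAromatic():
            ideal = 120.0
        if ideal is None:
            continue
        c = xyz[atom.GetIdx()]
        for i, j in combinations(nbrs, 2):
            u, v = xyz[i] - c, xyz[j] - c
            cosv = np.clip(np.dot(u, v) /
                           (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
            ang = float(np.degrees(np.arccos(cosv)))
            lo, hi = tol.bond_angle_ratio
            if not lo * ideal <= ang <= hi * ideal:
                ok = False
                report.details.append(
                    Violation("bond_angle", (i, atom.GetIdx(), j), ang, ideal))
    report.bond_angles_ok = ok

    # intramolecular clashes: non-bonded, non-1-3 heavy pairs
    bonded = {frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
              for b in mol.GetBonds()}
    one_three = set()
    for atom in mol.GetAtoms():
        nbrs = [a.GetIdx() for a in atom.GetNeighbors()]
        for i, j in combinations(nbrs, 2):
            one_three.add(frozenset((i, j)))
    ok = True
    if n > 1:
        d = cdist(xyz, xyz)
        for i in range(n):
            for j in range(i + 1, n):
                pair = frozenset((i, j))
                if pair in bonded or pair in one_three:
                    continue
                limit = tol.intramolecular_vdw_factor * (
                    vdw_radius(elements[i]) + vdw_radius(elements[j]))
                if d[i, j] < limit:
                    ok = False
                    report.details.append(
                        Violation("internal_clash", (i, j),
                                  float(d[i, j]), limit))
    report.internal_clash_free = ok

    # aromatic ring flatness
    ok = True
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            dev = _plane_max_residual(xyz[list(ring)])
            if dev > tol.flatness_max:
                ok = False
                report.details.append(
                    Violation("aromatic_ring_flat", tuple(ring), dev,
                              tol.flatness_max))
    report.aromatic_rings_flat = ok

    # double-bond planarity (sp2 frame: the two atoms plus their neighbours)
    ok = True
    for bond in mol.GetBonds():
        if bond.GetBondTypeAsDouble() != 2.0 or bond.GetIsAromatic():
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        frame = {i, j}
        for idx in (i, j):
            frame |= {a.GetIdx()
                      for a in mol.GetAtomWithIdx(idx).GetNeighbors()}
        if len(frame) < 4:
            continue
        dev = _plane_max_residual(xyz[sorted(frame)])
        if dev > tol.flatness_max:
            ok = False
            report.details.append(
                Violation("double_bond_flat", tuple(sorted(frame)), dev,
                          tol.flatness_max))
    report.double_bonds_flat = ok
    return report


def check_stereo(pred: LigandMol, ref: LigandMol) -> bool:
    """True when 3D-assigned stereochemistry agrees between pred and ref."""
    def iso(lig: LigandMol) -> str:
        mol = Chem.Mol(lig.mol)
        Chem.AssignStereochemistryFrom3D(mol)
        return Chem.MolToSmiles(mol, isomericSmiles=True)
    return iso(pred) == iso(ref)


def check_intermolecular(complex_pose: ComplexPose,
                         tol: GeometryTolerances | None = None
                         ) -> tuple[int, int]:
    """Count steric clashes: (protein↔ligand pairs, ligand↔ligand pairs).

    A clash is a non-bonded heavy-atom pair closer than
    ``intermolecular_vdw_factor`` × the van der Waals radius sum.
    """
    tol = tol or GeometryTolerances()
    f = tol.intermolecular_vdw_factor
    prot_xyz = complex_pose.protein.coords()
    prot_vdw = np.array([vdw_radius(a.element)
                         for a in complex_pose.protein.atoms])
    pl = 0
    lig_data = [(lig.coords(),
                 np.array([vdw_radius(e) for e in lig.elements]))
                for lig in complex_pose.ligands]
    for xyz, radii in lig_data:
        d = cdist(prot_xyz, xyz)
        pl += int((d < f * (prot_vdw[:, None] + radii[None, :])).sum())
    ll = 0
    for (xa, ra), (xb, rb) in combinations(lig_data, 2):
        d = cdist(xa, xb)
        ll += int((d < f * (ra[:, None] + rb[None, :])).sum())
    return pl, ll


def pb_valid(complex_pose: ComplexPose,
             tol: GeometryTolerances | None = None,
             ref_ligands: list | None = None
             ) -> tuple[bool, ValidityReport]:
    """Aggregate pose-validity verdict for a complex.

    Intramolecular checks run per fragment, intermolecular checks once; for
    multi-ligand complexes this yields a single per-complex verdict.  When
    reference ligands are supplied (order-matched to the complex's ligands),
    stereo preservation is checked as well.
    """
    if not complex_pose.ligands:
        raise ValueError("complex has no ligands")
    tol = tol or GeometryTolerances()
    report = ValidityReport()
    for lig in complex_pose.ligands:
        report = report.merge(check_ligand_geometry(lig, tol))
    pl, ll = check_intermolecular(complex_pose, tol)
    report.protein_ligand_clash_free = pl == 0
    report.inter_ligand_clash_free = ll == 0
    if pl:
        report.details.append(Violation("protein_ligand_clash", (), pl, 0))
    if ll:
        report.details.append(Violation("inter_ligand_clash", (), ll, 0))
    if ref_ligands is not None:
        ok = True
        for lig, ref in zip(complex_pose.ligands, ref_ligands):
            if ref is not None and lig.identity == ref.identity:
                ok = ok and check_stereo(lig, ref)
        report.stereo_preserved = ok
    return report.pb_valid, report
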
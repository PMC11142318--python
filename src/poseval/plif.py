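"""Protein–ligand interaction fingerprints (PLIFs) and Wasserstein metrics.

A PLIF is the tuple ⟨ligand code, amino-acid type, interaction type⟩.  For
each complex the detector scans every ligand × residue-instance pair against
a set of purely geometric criteria (distance cutoffs, angle windows) and
emits at most one count per interaction type per pair; counts aggregate over
residue instances into a histogram keyed by the tuple.

PLIF-EMD compares a predicted histogram u against the native histogram v:
the bins of both are unified (union of keys, canonical lexicographic order,
zeros where absent), counts are normalized to probability mass, keys are
embedded at integer positions 0..m−1, and the 1-D Wasserstein distance
between the two discrete distributions is returned.  PLIF-WM min–max
normalizes mean PLIF-EMD across a collection of methods to a 0–1
higher-is-better matching score.

Hydrogen positions needed for hydrogen-bond angles are idealized from
heavy-atom frames (crystal and predicted structures routinely lack H).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable, NamedTuple

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import wasserstein_distance

from ._chem import HALOGENS, METALS
from .errors import EmptyHistogramsError
from .model_io import ComplexPose, LigandMol, ProteinStructure

__all__ = [
    "Interaction",
    "PLIFKey",
    "PLIFHistogram",
    "GeometricCriteria",
    "detect_plifs",
    "unify_support",
    "plif_emd",
    "plif_wm",
]


class Interaction(str, Enum):
    HBOND_DONOR = "HBond-donor"          # ligand donates the H
    HBOND_ACCEPTOR = "HBond-acceptor"    # ligand accepts the H
    HYDROPHOBIC = "Hydrophobic"
    IONIC_CATION = "Ionic-cation"        # ligand carries the + charge
    IONIC_ANION = "Ionic-anion"          # ligand carries the − charge
    PI_STACKING = "PiStacking"
    CATION_PI = "CationPi"               # ligand cation on protein ring
    PI_CATION = "PiCation"               # ligand ring near protein cation
    HALOGEN_BOND = "HalogenBond"
    METAL_COORDINATION = "MetalCoordination"
    VDW_CONTACT = "VdWContact"


class PLIFKey(NamedTuple):
    ligand_code: str
    residue_name: str
    interaction: str


@dataclass
class PLIFHistogram:
    """Counts over ⟨ligand, amino acid, interaction⟩ tuples."""

    counts: dict = field(default_factory=dict)

    def add(self, key: PLIFKey, n: int = 1) -> None:
        self.counts[key] = self.counts.get(key, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def to_json(self) -> str:
        return json.dumps(
            [{"ligand": k.ligand_code, "residue": k.residue_name,
              "interaction": k.interaction, "count": v}
             for k, v in sorted(self.counts.items())])

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["ligand_code", "residue_name", "interaction", "count"])
            for k, v in sorted(self.counts.items()):
                w.writerow([k.ligand_code, k.residue_name, k.interaction, v])


@dataclass
class GeometricCriteria:
    """Distance cutoffs (Å) and angle windows (degrees) per interaction."""

    hbond_dist: float = 3.5
    hbond_angle: float = 130.0           # D–H···A angle, minimum
    hydrophobic_dist: float = 4.5
    ionic_dist: float = 4.5
    pistack_dist: float = 5.5            # ring-centroid separation
    pistack_face_angle: float = 35.0     # inter-plane angle, face-to-face
    pistack_edge_window: tuple = (50.0, 90.0)
    cation_pi_dist: float = 4.5
    halogen_dist: float = 3.5
    halogen_angle: float = 130.0         # C–X···A angle, minimum
    metal_dist: float = 2.8
    vdw_contact: bool = False            # off: swamps histograms
    vdw_tolerance: float = 0.0


# ---------------------------------------------------------------------------
# protein-side feature tables (standard amino acids, heavy-atom names)
# ---------------------------------------------------------------------------

_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"}, "HIS": {"ND1", "NE2"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
_CATION_GROUPS = {
    "LYS": [("NZ",)],
    "ARG": [("CZ", "NE", "NH1", "NH2")],
}
_ANION_GROUPS = {
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
}
_RING_GROUPS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
}
_HYDROPHOBIC_ATOMS = {
    "ALA": {"CB"}, "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"}, "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "PRO": {"CB", "CG", "CD"}, "LYS": {"CB", "CG", "CD"},
    "ARG": {"CB", "CG"}, "GLU": {"CB", "CG"}, "GLN": {"CB", "CG"},
    "ASP": {"CB"}, "ASN": {"CB"}, "HIS": {"CB"}, "THR": {"CG2"},
    "CYS": {"CB"},
}


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else v


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosv = float(np.clip(np.dot(_unit(a), _unit(b)), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosv)))


def _ideal_h_direction(donor: np.ndarray,
                       neighbours: list[np.ndarray]) -> np.ndarray | None:
    """Direction of an idealized H on a donor: opposite the mean bond vector."""
    if not neighbours:
        return None
    s = np.sum([_unit(np.asarray(nb) - donor) for nb in neighbours], axis=0)
    if np.linalg.norm(s) < 1e-6:
        return None
    return -_unit(s)


def _hbond_geometry_ok(donor: np.ndarray, acceptor: np.ndarray,
                       neighbours: list[np.ndarray],
                       min_angle: float) -> bool:
    """D–H···A angle with an idealized H; distance is checked by the caller.

    Donors without heavy neighbours (ions, lone atoms) pass on distance
    alone — there is no frame to idealize an H in.
    """
    u = _ideal_h_direction(donor, neighbours)
    if u is None:
        return True
    h = donor + 1.0 * u
    return _angle_deg(donor - h, acceptor - h) >= min_angle


def _plane_normal(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[2]


# ---------------------------------------------------------------------------
# ligand-side features (from the RDKit graph)
# ---------------------------------------------------------------------------

@dataclass
class _LigandFeatures:
    donors: list            # (atom idx, neighbour idx list)
    acceptors: list         # atom idx
    hydrophobic: list       # atom idx
    cations: list           # atom idx
    anions: list            # atom idx
    rings: list             # list of atom idx tuples (aromatic)
    halogens: list          # (X idx, attached C idx)
    metals: list            # atom idx


def _ligand_features(lig: LigandMol) -> _LigandFeatures:
    mol = lig.mol
    donors, acceptors, hydrophobic = [], [], []
    cations, anions, halogens, metals = [], [], [], []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol().upper()
        idx = atom.GetIdx()
        charge = atom.GetFormalCharge()
        nbrs = [n.GetIdx() for n in atom.GetNeighbors()]
        if sym in METALS:
            metals.append(idx)
            if charge > 0:
                cations.append(idx)
            continue
        if sym in {"N", "O", "S"} and atom.GetTotalNumHs() > 0 and charge >= 0:
            donors.append((idx, nbrs))
        if sym == "O" and charge <= 0:
            acceptors.append(idx)
        elif sym == "N" and charge <= 0:
            pyrrole_like = atom.GetIsAromatic() and atom.GetTotalNumHs() > 0
            if not pyrrole_like and atom.GetTotalValence() <= 3:
                acceptors.append(idx)
        if sym in {"C", "S"} and charge == 0:
            if all(n.GetSymbol().upper() in {"C", "S", "H"}
                   for n in atom.GetNeighbors()):
                hydrophobic.append(idx)
        if charge > 0:
            cations.append(idx)
        elif charge < 0:
            anions.append(idx)
        if sym in HALOGENS and nbrs:
            carbon = [n for n in atom.GetNeighbors()
                      if n.GetSymbol().upper() == "C"]
            if carbon:
                halogens.append((idx, carbon[0].GetIdx()))
    rings = [tuple(r) for r in mol.GetRingInfo().AtomRings()
             if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)]
    return _LigandFeatures(donors, acceptors, hydrophobic,
                           sorted(set(cations)), anions, rings,
                           halogens, metals)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _residue_interactions(lig: LigandMol, feats: _LigandFeatures,
                          lig_xyz: np.ndarray,
                          res_atoms: list, res_name: str,
                          crit: GeometricCriteria) -> set[str]:
    """Interaction types present between one ligand and one residue instance."""
    found: set[str] = set()
    names = [a.name for a in res_atoms]
    xyz = np.array([a.coords for a in res_atoms], dtype=float)
    elements = [a.element.upper() for a in res_atoms]
    pos = dict(zip(names, xyz))

    def covalent_neighbours(i: int) -> list[np.ndarray]:
        d = np.linalg.norm(xyz - xyz[i], axis=1)
        return [xyz[j] for j in range(len(xyz)) if 0 < d[j] <= 1.8]

    # --- hydrogen bonds ---------------------------------------------------
    res_acceptors = [i for i, nm in enumerate(names)
                     if nm in ("O", "OXT")
                     or nm in _SIDECHAIN_ACCEPTORS.get(res_name, ())]
    res_donors = [i for i, nm in enumerate(names)
                  if (nm == "N" and res_name != "PRO")
                  or nm in _SIDECHAIN_DONORS.get(res_name, ())]
    for d_idx, d_nbrs in feats.donors:
        D = lig_xyz[d_idx]
        for a_i in res_acceptors:
            A = xyz[a_i]
            if np.linalg.norm(D - A) <= crit.hbond_dist and \
                    _hbond_geometry_ok(D, A, [lig_xyz[j] for j in d_nbrs],
                                       crit.hbond_angle):
                found.add(Interaction.HBOND_DONOR.value)
    for a_idx in feats.acceptors:
        A = lig_xyz[a_idx]
        for d_i in res_donors:
            D = xyz[d_i]
            if np.linalg.norm(D - A) <= crit.hbond_dist and \
                    _hbond_geometry_ok(D, A, covalent_neighbours(d_i),
                                       crit.hbond_angle):
                found.add(Interaction.HBOND_ACCEPTOR.value)

    # --- hydrophobic ------------------------------------------------------
    res_phobic = [i for i, nm in enumerate(names)
                  if nm in _HYDROPHOBIC_ATOMS.get(res_name, ())]
    if feats.hydrophobic and res_phobic:
        d = cdist(lig_xyz[feats.hydrophobic], xyz[res_phobic])
        if (d <= crit.hydrophobic_dist).any():
            found.add(Interaction.HYDROPHOBIC.value)

    # --- ionic ------------------------------------------------------------
    def group_centres(groups):
        out = []
        for g in groups:
            if all(nm in pos for nm in g):
                out.append(np.mean([pos[nm] for nm in g], axis=0))
        return out

    anion_centres = group_centres(_ANION_GROUPS.get(res_name, []))
    cation_centres = group_centres(_CATION_GROUPS.get(res_name, []))
    for c_idx in feats.cations:
        for centre in anion_centres:
            if np.linalg.norm(lig_xyz[c_idx] - centre) <= crit.ionic_dist:
                found.add(Interaction.IONIC_CATION.value)
    for a_idx in feats.anions:
        for centre in cation_centres:
            if np.linalg.norm(lig_xyz[a_idx] - centre) <= crit.ionic_dist:
                found.add(Interaction.IONIC_ANION.value)

    # --- aromatic ---------------------------------------------------------
    res_rings = []
    for g in _RING_GROUPS.get(res_name, []):
        if all(nm in pos for nm in g):
            pts = np.array([pos[nm] for nm in g])
            res_rings.append((pts.mean(axis=0), _plane_normal(pts)))
    lig_rings = []
    for ring in feats.rings:
        pts = lig_xyz[list(ring)]
        lig_rings.append((pts.mean(axis=0), _plane_normal(pts)))
    for lc, ln in lig_rings:
        for rc, rn in res_rings:
            if np.linalg.norm(lc - rc) <= crit.pistack_dist:
                ang = _angle_deg(ln, rn)
                ang = min(ang, 180.0 - ang)   # plane angle in [0, 90]
                lo, hi = crit.pistack_edge_window
                if ang <= crit.pistack_face_angle or lo <= ang <= hi:
                    found.add(Interaction.PI_STACKING.value)
    for c_idx in feats.cations:
        for rc, _ in res_rings:
            if np.linalg.norm(lig_xyz[c_idx] - rc) <= crit.cation_pi_dist:
                found.add(Interaction.CATION_PI.value)
    for lc, _ in lig_rings:
        for centre in cation_centres:
            if np.linalg.norm(lc - centre) <= crit.cation_pi_dist:
                found.add(Interaction.PI_CATION.value)

    # --- halogen bonds ----------------------------------------------------
    for x_idx, c_idx in feats.halogens:
        X, C = lig_xyz[x_idx], lig_xyz[c_idx]
        for a_i in res_acceptors:
            A = xyz[a_i]
            if np.linalg.norm(X - A) <= crit.halogen_dist and \
                    _angle_deg(C - X, A - X) >= crit.halogen_angle:
                found.add(Interaction.HALOGEN_BOND.value)

    # --- metal coordination -----------------------------------------------
    if feats.metals:
        coord_targets = [i for i, el in enumerate(elements)
                         if el in {"N", "O", "S"}]
        if coord_targets:
            d = cdist(lig_xyz[feats.metals], xyz[coord_targets])
            if (d <= crit.metal_dist).any():
                found.add(Interaction.METAL_COORDINATION.value)

    # --- generic van der Waals contact (off by default) ---------------------
    if crit.vdw_contact:
        from ._chem import vdw_radius
        lv = np.array([vdw_radius(e) for e in lig.elements])
        rv = np.array([vdw_radius(e) for e in elements])
        d = cdist(lig_xyz, xyz)
        if (d <= lv[:, None] + rv[None, :] + crit.vdw_tolerance).any():
            found.add(Interaction.VDW_CONTACT.value)
    return found


def detect_plifs(complex_pose: ComplexPose,
                 criteria: GeometricCriteria | None = None) -> PLIFHistogram:
    """Detect interaction fingerprints for every ligand × residue pair.

    Each residue *instance* contributes at most one count per interaction
    type per ligand; counts aggregate into ⟨ligand code, residue name,
    interaction⟩ tuples.  An empty histogram is a valid result.
    """
    crit = criteria or GeometricCriteria()
    hist = PLIFHistogram()
    protein = complex_pose.protein
    reach = max(crit.hbond_dist, crit.hydrophobic_dist, crit.ionic_dist,
                crit.pistack_dist, crit.cation_pi_dist, crit.halogen_dist,
                crit.metal_dist) + 3.0   # ring-centre / group-centre slack
    for lig in complex_pose.ligands:
        feats = _ligand_features(lig)
        lig_xyz = lig.coords()
        for chain_id in protein.chain_ids:
            for res_idx in protein.residues(chain_id):
                res_atoms = protein.residue_atoms(chain_id, res_idx)
                res_xyz = np.array([a.coords for a in res_atoms])
                if cdist(lig_xyz, res_xyz).min() > reach:
                    continue
                res_name = res_atoms[0].residue_name
                for itype in _residue_interactions(
                        lig, feats, lig_xyz, res_atoms, res_name, crit):
                    hist.add(PLIFKey(lig.ligand_code, res_name, itype))
    return hist


# ---------------------------------------------------------------------------
# Wasserstein metrics
# ---------------------------------------------------------------------------

def unify_support(u: PLIFHistogram, v: PLIFHistogram
                  ) -> tuple[list[PLIFKey], np.ndarray, np.ndarray]:
    """Union of keys in canonical lexicographic order with aligned weights."""
    if len(u) == 0 and len(v) == 0:
        raise EmptyHistogramsError("both histograms are empty")
    support = sorted(set(u.counts) | set(v.counts))
    uw = np.array([u.counts.get(k, 0) for k in support], dtype=float)
    vw = np.array([v.counts.get(k, 0) for k in support], dtype=float)
    return support, uw, vw


def plif_emd(u: PLIFHistogram, v: PLIFHistogram,
             normalize: bool = True,
             empty_fallback: bool = False) -> float:
    """1-D Wasserstein distance between two PLIF histograms.

    Keys are embedded at integer positions 0..m−1 in unified canonical
    order; with ``normalize`` (the default) counts become probability mass
    first, so total-count differences are not penalized.  An empty histogram
    raises :class:`EmptyHistogramsError` unless ``empty_fallback`` assigns it
    the maximum support distance instead.
    """
    support, uw, vw = unify_support(u, v)
    m = len(support)
    if uw.sum() == 0 or vw.sum() == 0:
        if empty_fallback:
            return float(m - 1) if m > 1 else 1.0
        raise EmptyHistogramsError(
            "one histogram is empty; no distribution to compare")
    pos = np.arange(m, dtype=float)
    if normalize:
        if m == 1:
            return 0.0
        return float(wasserstein_distance(pos, pos, uw, vw))
    # raw-count mode: unnormalized CDF difference
    return float(np.abs(np.cumsum(uw) - np.cumsum(vw))[:-1].sum()
                 if m > 1 else abs(uw[0] - vw[0]))


def plif_wm(method_emds: dict) -> dict:
    """Min–max normalized Wasserstein matching score per method.

    ``1 − (EMD_m − EMD_min) / (EMD_max − EMD_min)`` over the supplied
    collection; degenerate collections (all equal, or a single method) score
    1.0 for every member with a warning.
    """
    if not method_emds:
        raise ValueError("empty method collection")
    values = np.array(list(method_emds.values()), dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        warnings.warn("degenerate PLIF-EMD collection (all values equal); "
                      "all matching scores set to 1.0", RuntimeWarning)
        return {m: 1.0 for m in method_emds}
    return {m: float(1.0 - (e - lo) / (hi - lo))
            for m, e in method_emds.items()}
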
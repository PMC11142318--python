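"""Deterministic synthetic complexes with known ground-truth metric values.

The generator builds toy binding pockets — idealized amino-acid residues
placed on a sphere with side chains pointing inward at a small-molecule
ligand at the centre — plus perturbation operators whose effect on each
metric is known in closed form (translation by d gives RMSD exactly d,
rotation about the centroid leaves the centroid fixed, an automorphism
permutation leaves symmetry-aware RMSD at zero, ...).  Every reference
complex is constructed to pass the validity checks, to have a non-empty
10 Å pocket, and to plant at least one detectable protein–ligand
interaction of a type suited to the ligand's chemistry.

These are not physically realistic folds: residues have no peptide bonds,
side-chain rotamers are fixed, and the pocket has no secondary structure.
They exist to give every metric a fixture with an analytically known value.

All randomness flows from a single seed through independent named streams,
so generated files are byte-identical across runs and insensitive to
generation order.
"""

from __future__ import annotations

import math
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .model_io import (Atom, ComplexPose, LigandMol, ProteinStructure,
                       write_ligands, write_protein)

__all__ = [
    "RESIDUE_TEMPLATES",
    "LIGAND_TEMPLATES",
    "make_toy_pocket",
    "make_toy_ligand",
    "make_reference_complex",
    "perturb",
    "make_benchmark",
]


# ---------------------------------------------------------------------------
# residue templates (idealized heavy-atom geometry, local frame: CA at origin)
# ---------------------------------------------------------------------------

def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation mapping unit vector a onto unit vector b."""
    a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        perp = np.array([1.0, 0, 0])
        if abs(a[0]) > 0.9:
            perp = np.array([0, 1.0, 0])
        axis = np.cross(a, perp)
        return _rotation_about(axis, math.pi)
    return _rotation_about(v, math.acos(np.clip(c, -1, 1)))


def _build_templates() -> dict:
    """Heavy-atom templates for the curated residue set.

    Backbone uses standard ideal coordinates; side chains extend from CB
    along a tetrahedral zigzag with literature bond lengths.  Each template
    records a ``tip`` (interaction anchor) for pocket orientation.
    """
    N = np.array([-0.572, 1.337, 0.0])
    CA = np.zeros(3)
    C = np.array([1.517, 0.0, 0.0])
    O = np.array([2.146, 1.042, 0.0])
    CB = np.array([-0.536, -0.777, -1.208])
    backbone = [("N", "N", N), ("CA", "C", CA), ("C", "C", C), ("O", "O", O)]

    w = CB / np.linalg.norm(CB)                     # side-chain axis
    p = np.cross(w, np.array([0.0, 0.0, 1.0]))
    p /= np.linalg.norm(p)
    q = np.cross(w, p)

    def zigzag(start: np.ndarray, lengths: Sequence[float]) -> list:
        """Chain positions with tetrahedral (109.5°) zigzag geometry."""
        pts, cur, flip = [], start.copy(), 1.0
        for L in lengths:
            cur = cur + w * (L * 0.8165) + p * (flip * L * 0.5774)
            pts.append(cur.copy())
            flip = -flip
        return pts

    T: dict[str, dict] = {}
    T["GLY"] = {"atoms": list(backbone), "tip": "CA"}
    T["ALA"] = {"atoms": backbone + [("CB", "C", CB)], "tip": "CB"}

    og, = zigzag(CB, [1.42])
    T["SER"] = {"atoms": backbone + [("CB", "C", CB), ("OG", "O", og)],
                "tip": "OG"}

    cg, = zigzag(CB, [1.52])
    d1 = w * math.cos(math.radians(61.5)) + q * math.sin(math.radians(61.5))
    d2 = w * math.cos(math.radians(61.5)) - q * math.sin(math.radians(61.5))
    T["ASP"] = {"atoms": backbone + [("CB", "C", CB), ("CG", "C", cg),
                                     ("OD1", "O", cg + 1.25 * d1),
                                     ("OD2", "O", cg + 1.25 * d2)],
                "tip": "CG"}

    cg, cd, ne, cz = zigzag(CB, [1.52, 1.52, 1.46, 1.33])
    n1 = w * 0.5 + q * 0.866
    n2 = w * 0.5 - q * 0.866
    T["ARG"] = {"atoms": backbone + [("CB", "C", CB), ("CG", "C", cg),
                                     ("CD", "C", cd), ("NE", "N", ne),
                                     ("CZ", "C", cz),
                                     ("NH1", "N", cz + 1.33 * n1),
                                     ("NH2", "N", cz + 1.33 * n2)],
                "tip": "CZ"}

    cg, = zigzag(CB, [1.50])
    centre = cg + 1.39 * w
    ring_names = [("CG", 180.0), ("CD1", 120.0), ("CD2", 240.0),
                  ("CE1", 60.0), ("CE2", 300.0), ("CZ", 0.0)]
    phe_ring = [(nm, "C", centre + 1.39 * (math.cos(math.radians(a)) * w
                                           + math.sin(math.radians(a)) * q))
                for nm, a in ring_names[1:]]
    T["PHE"] = {"atoms": backbone + [("CB", "C", CB), ("CG", "C", cg)]
                + phe_ring, "tip": "CZ"}

    cg, = zigzag(CB, [1.50])
    centre = cg + 1.17 * w
    his_ring = [("ND1", "N", 108.0), ("CD2", "C", 252.0),
                ("CE1", "C", 36.0), ("NE2", "N", 324.0)]
    his_atoms = [(nm, el, centre + 1.17 * (math.cos(math.radians(a)) * w
                                           + math.sin(math.radians(a)) * q))
                 for nm, el, a in his_ring]
    T["HIS"] = {"atoms": backbone + [("CB", "C", CB), ("CG", "C", cg)]
                + his_atoms, "tip": "NE2"}
    return T


RESIDUE_TEMPLATES = _build_templates()


# ---------------------------------------------------------------------------
# ligand templates
# ---------------------------------------------------------------------------

def _mol_from_spec(atoms, bonds, charges=None, explicit_hs=None) -> Chem.Mol:
    """atoms: [(symbol, (x,y,z))]; bonds: [(i, j, order_str)]."""
    rw = Chem.RWMol()
    for sym, _ in atoms:
        rw.AddAtom(Chem.Atom(sym))
    if explicit_hs:
        for i, h in explicit_hs.items():
            rw.GetAtomWithIdx(i).SetNumExplicitHs(h)
    order_map = {"1": Chem.BondType.SINGLE, "2": Chem.BondType.DOUBLE,
                 "3": Chem.BondType.TRIPLE, "ar": Chem.BondType.AROMATIC}
    for i, j, o in bonds:
        rw.AddBond(i, j, order_map[o])
    if charges:
        for i, c in charges.items():
            rw.GetAtomWithIdx(i).SetFormalCharge(c)
    mol = rw.GetMol()
    conf = Chem.Conformer(len(atoms))
    for i, (_, xyz) in enumerate(atoms):
        conf.SetAtomPosition(i, Point3D(*[float(x) for x in xyz]))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol)
    return mol


def _hexagon(r: float):
    return [(r * math.cos(math.radians(a)), r * math.sin(math.radians(a)), 0.0)
            for a in range(0, 360, 60)]


def _ligand_specs() -> dict:
    specs = {}
    hexa = _hexagon(1.39)
    specs["benzene"] = (
        [("C", xyz) for xyz in hexa],
        [(i, (i + 1) % 6, "ar") for i in range(6)], None)
    c0, c1 = (0.0, 0.0, 0.0), (1.52, 0.0, 0.0)
    o = (1.52 + 1.43 * math.cos(math.radians(70.5)),
         1.43 * math.sin(math.radians(70.5)), 0.0)
    specs["ethanol"] = ([("C", c0), ("C", c1), ("O", o)],
                        [(0, 1, "1"), (1, 2, "1")], None)
    o1 = (1.52 + 1.25 * math.cos(math.radians(60)),
          1.25 * math.sin(math.radians(60)), 0.0)
    o2 = (1.52 + 1.25 * math.cos(math.radians(60)),
          -1.25 * math.sin(math.radians(60)), 0.0)
    specs["acetate"] = ([("C", c0), ("C", c1), ("O", o1), ("O", o2)],
                        [(0, 1, "1"), (1, 2, "2"), (1, 3, "1")], {3: -1})
    specs["methylammonium"] = ([("C", (0.0, 0.0, 0.0)),
                                ("N", (1.50, 0.0, 0.0))],
                               [(0, 1, "1")], {1: 1})
    r5 = 1.17
    penta = [(r5 * math.cos(math.radians(a)), r5 * math.sin(math.radians(a)),
              0.0) for a in (90, 162, 234, 306, 18)]
    # imidazole: N1(H)-C2-N3-C4-C5
    specs["imidazole"] = (
        [("N", penta[0]), ("C", penta[1]), ("N", penta[2]),
         ("C", penta[3]), ("C", penta[4])],
        [(0, 1, "ar"), (1, 2, "ar"), (2, 3, "ar"), (3, 4, "ar"),
         (4, 0, "ar")], None, {0: 1})
    specs["ion"] = ([("Mg", (0.0, 0.0, 0.0))], [], {0: 2})
    return specs


LIGAND_TEMPLATES = tuple(sorted(_ligand_specs()))


def make_toy_ligand(template: str, code: str | None = None) -> LigandMol:
    """Idealized conformer of a named small-molecule template."""
    specs = _ligand_specs()
    if template not in specs:
        raise ValueError(f"unknown ligand template {template!r}; "
                         f"choose from {LIGAND_TEMPLATES}")
    atoms, bonds, charges, *rest = specs[template]
    hs = rest[0] if rest else None
    return LigandMol(_mol_from_spec(atoms, bonds, charges, hs),
                     code or template[:3].upper())


# ---------------------------------------------------------------------------
# toy pockets
# ---------------------------------------------------------------------------

_DEFAULT_CYCLE = ("SER", "ALA", "ASP", "PHE", "ARG", "HIS", "GLY", "ALA")


def _fibonacci_sphere(n: int) -> np.ndarray:
    golden = math.pi * (3.0 - math.sqrt(5.0))
    pts = []
    for i in range(n):
        z = 1.0 - 2.0 * (i + 0.5) / n
        r = math.sqrt(max(0.0, 1.0 - z * z))
        th = golden * i
        pts.append((r * math.cos(th), r * math.sin(th), z))
    return np.array(pts)


def make_toy_pocket(seed: int, n_residues: int = 8, radius: float = 12.0,
                    n_chains: int = 1,
                    residue_cycle: Sequence[str] = _DEFAULT_CYCLE
                    ) -> ProteinStructure:
    """Residues on a sphere around the origin, side chains pointing inward.

    Placement directions follow a Fibonacci sphere (even coverage); the roll
    of each residue about its inward axis is drawn from the seeded stream.
    Raises when residues would clash internally (radius too small).
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues for a pocket")
    rng = np.random.default_rng([seed, 101])
    dirs = _fibonacci_sphere(n_residues)
    atoms: list[Atom] = []
    placed_coords: list[np.ndarray] = []
    per_chain = math.ceil(n_residues / n_chains)
    for i in range(n_residues):
        res_name = residue_cycle[i % len(residue_cycle)]
        tmpl = RESIDUE_TEMPLATES[res_name]
        names = [a[0] for a in tmpl["atoms"]]
        local = np.array([a[2] for a in tmpl["atoms"]])
        elements = [a[1] for a in tmpl["atoms"]]
        tip = local[names.index(tmpl["tip"])]
        inward = tip - 0.0 if np.linalg.norm(tip) > 1e-6 else np.array(
            [0.0, 0.0, -1.0])
        u = dirs[i]
        R0 = _align_rotation(inward, -u)
        roll = _rotation_about(-u, float(rng.uniform(0, 2 * math.pi)))
        R = roll @ R0
        world = local @ R.T + radius * u
        dmin_ok = all(
            np.min(np.linalg.norm(world[:, None, :] - prev[None, :, :],
                                  axis=2)) >= 2.2
            for prev in placed_coords)
        if not dmin_ok:
            raise ValueError(
                f"radius {radius} Å too small: residue {i} clashes")
        placed_coords.append(world)
        chain_id = chr(ord("A") + i // per_chain)
        res_idx = (i % per_chain) + 1
        for nm, el, xyz in zip(names, elements, world):
            atoms.append(Atom(el, nm, tuple(float(x) for x in xyz),
                              res_idx, res_name, chain_id))
    return ProteinStructure(atoms)


# planted-contact recipe per ligand chemistry:
#   (contact residue, its tip atom group, ligand anchor picker, distance Å)
_CONTACT_PLAN = {
    "ethanol": ("SER", ("OG",), "O", 3.0),
    "imidazole": ("SER", ("OG",), "Nacc", 3.0),
    "benzene": ("ALA", ("CB",), "C", 4.0),
    "acetate": ("ARG", ("CZ", "NE", "NH1", "NH2"), "O-", 3.5),
    "methylammonium": ("ASP", ("OD1", "OD2"), "N+", 3.5),
    "ion": ("ASP", ("OD1",), "metal", 2.6),
}


def _anchor_index(lig: LigandMol, kind: str) -> int:
    mol = lig.mol
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        ch = atom.GetFormalCharge()
        if kind == "O-" and sym == "O" and ch < 0:
            return atom.GetIdx()
        if kind == "N+" and sym == "N" and ch > 0:
            return atom.GetIdx()
        if kind == "metal" and ch > 0:
            return atom.GetIdx()
        if kind == "Nacc" and sym == "N" and atom.GetTotalNumHs() == 0:
            return atom.GetIdx()
        if kind == sym and ch == 0:
            return atom.GetIdx()
    return 0


def make_reference_complex(seed: int, ligand_template: str = "ethanol",
                           n_residues: int = 8, radius: float = 12.0,
                           n_chains: int = 1,
                           extra_fragments: Sequence[str] = ()
                           ) -> ComplexPose:
    """A toy holo complex with a guaranteed detectable interaction.

    The ligand sits at the pocket centre; one residue of a chemistry-matched
    type is pulled inward so its interaction group sits at ideal geometry
    from the ligand's anchor atom (hydrogen-bond, salt-bridge, hydrophobic
    or metal-coordination distance depending on the ligand template).
    Extra fragments are placed on displaced sites around the primary.
    """
    res_type, tip_group, anchor_kind, dist = _CONTACT_PLAN[ligand_template]
    cycle = (res_type,) + tuple(r for r in _DEFAULT_CYCLE)[:-1]
    protein = make_toy_pocket(seed, n_residues, radius, n_chains,
                              residue_cycle=cycle)
    lig = make_toy_ligand(ligand_template)
    lig = lig.with_coords(lig.coords() - lig.centroid())  # centre at origin

    ligands = [lig]
    roles = ["primary"]

    # pull contact residues to interaction geometry: the chemistry-matched
    # residue at ideal distance, plus secondary polar and hydrophobic shell
    # contacts so the fingerprint histogram has several entries and degrades
    # gradually under pose error
    lig_xyz = lig.coords()
    elements = lig.elements
    contacts = [(1, tip_group, lig_xyz[_anchor_index(lig, anchor_kind)],
                 dist)]
    acceptor_like = [a.GetIdx() for a in lig.mol.GetAtoms()
                     if (a.GetSymbol() == "O" and a.GetFormalCharge() <= 0)
                     or (a.GetSymbol() == "N" and a.GetTotalNumHs() == 0
                         and a.GetFormalCharge() <= 0)]
    apolar = [i for i, e in enumerate(elements) if e in ("C", "S")]
    # residue 2 is always SER (polar shell), residue 3 always ALA
    # (hydrophobic shell) in the construction cycle
    primary_anchor = _anchor_index(lig, anchor_kind)
    secondary = [i for i in acceptor_like if i != primary_anchor]
    if secondary:
        contacts.append((2, ("OG",), lig_xyz[secondary[0]], 3.1))
    if apolar:
        contacts.append((3, ("CB",), lig_xyz[apolar[-1]], 4.0))

    coords = protein.coords()
    chain0 = protein.chain_ids[0]
    for res_i, group_names, anchor, target_d in contacts:
        res_atoms = protein.residue_atoms(chain0, res_i)
        if not all(any(a.name == nm for a in res_atoms)
                   for nm in group_names):
            continue
        group = np.mean([a.coords for a in res_atoms
                         if a.name in group_names], axis=0)
        shift_dir = anchor - group
        norm = np.linalg.norm(shift_dir)
        shift = shift_dir / norm * (norm - target_d)
        idx = [i for i, a in enumerate(protein.atoms)
               if a.chain_id == chain0 and a.residue_index == res_i]
        coords[idx] += shift
    protein = protein.with_coords(coords)

    # place extra fragments clash-free: deterministic search over candidate
    # directions and radii for >= 3 Å clearance to protein and other ligands
    from scipy.spatial.distance import cdist
    for k, frag in enumerate(extra_fragments):
        fl = make_toy_ligand(frag, code=f"FR{k}")
        centred = fl.coords() - fl.centroid()
        placed = None
        for r in (4.0, 5.0, 6.0, 7.0):
            for u in _fibonacci_sphere(26):
                cand = centred + r * u
                if cdist(cand, protein.coords()).min() < 3.0:
                    continue
                if any(cdist(cand, other.coords()).min() < 3.0
                       for other in ligands):
                    continue
                placed = cand
                break
            if placed is not None:
                break
        if placed is None:
            raise ValueError(f"cannot place fragment {frag!r} clash-free")
        ligands.append(fl.with_coords(placed))
        roles.append("fragment")
    return ComplexPose(protein, ligands, roles)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

PERTURB_MODES = ("translate", "rotate_about_centroid", "jitter",
                 "automorphism_permute", "eject")


def perturb(pose: ComplexPose, mode: str, magnitude: float = 0.0,
            seed: int = 0) -> ComplexPose:
    """Apply a ground-truth-known perturbation to every ligand of a pose.

    translate: rigid shift by exactly ``magnitude`` Å (RMSD and centroid
    distance both equal ``magnitude``); rotate_about_centroid: rotation by
    ``magnitude`` degrees about each ligand's centroid (centroid distance
    0); jitter: i.i.d. Gaussian noise with σ = ``magnitude``;
    automorphism_permute: relabel atoms by a non-identity graph automorphism
    (symmetry-aware RMSD 0); eject: move ligands > ``magnitude`` (min 12) Å
    away from every protein atom.
    """
    if mode not in PERTURB_MODES:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    rng = np.random.default_rng([seed, 202])
    new_ligands = []
    for lig in pose.ligands:
        xyz = lig.coords()
        if mode == "translate":
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * magnitude
            new_ligands.append(lig.with_coords(xyz + v))
        elif mode == "rotate_about_centroid":
            axis = rng.normal(size=3)
            R = _rotation_about(axis, math.radians(magnitude))
            c = xyz.mean(axis=0)
            new_ligands.append(lig.with_coords((xyz - c) @ R.T + c))
        elif mode == "jitter":
            new_ligands.append(lig.with_coords(
                xyz + rng.normal(scale=magnitude, size=xyz.shape)))
        elif mode == "automorphism_permute":
            matches = lig.mol.GetSubstructMatches(lig.mol, uniquify=False,
                                                  maxMatches=1000)
            nontrivial = [m for m in matches
                          if tuple(m) != tuple(range(lig.n_atoms))]
            order = list(nontrivial[0]) if nontrivial else list(
                range(lig.n_atoms))
            new_ligands.append(lig.permuted(order))
        elif mode == "eject":
            target = max(magnitude, 12.0)
            prot = pose.protein.coords()
            centre = prot.mean(axis=0)
            d = xyz.mean(axis=0) - centre
            d = d / np.linalg.norm(d) if np.linalg.norm(d) > 1e-9 else \
                np.array([1.0, 0.0, 0.0])
            moved = xyz.copy()
            for _ in range(100):
                from scipy.spatial.distance import cdist
                if cdist(moved, prot).min() > target:
                    break
                moved = moved + d * 5.0
            new_ligands.append(lig.with_coords(moved))
    return ComplexPose(pose.protein.with_coords(pose.protein.coords()),
                       new_ligands, list(pose.roles))


# ---------------------------------------------------------------------------
# benchmark generator
# ---------------------------------------------------------------------------

def make_benchmark(seed: int, n_targets: int, method_profiles: Sequence[dict],
                   out_dir, n_runs: int = 1) -> "pandas.DataFrame":
    """Write a synthetic benchmark with planted success fractions.

    Per method profile ``{"name", "success_fraction", "noise"}`` and run,
    exactly ``round(success_fraction × n_targets)`` targets receive a pose
    translated by well under the 2 Å success threshold; the rest are
    translated by > 4 Å.  Lower ``noise`` keeps successful poses closer to
    the reference, preserving more native contacts.  Returns (and writes)
    the evaluation manifest.
    """
    import pandas as pd
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    templates = [t for t in LIGAND_TEMPLATES if t != "ion"]
    rows = []
    refs = []
    for t in range(n_targets):
        tmpl = templates[t % len(templates)]
        ref = make_reference_complex(seed * 1000 + t, ligand_template=tmpl)
        ref_protein = out_dir / f"target{t:03d}_ref_protein.pdb"
        ref_lig = out_dir / f"target{t:03d}_ref_ligands.sdf"
        write_protein(ref.protein, ref_protein)
        write_ligands(ref.ligands, ref_lig)
        refs.append((ref, ref_protein, ref_lig))
    for profile in method_profiles:
        name = profile["name"]
        frac = float(profile["success_fraction"])
        noise = float(profile.get("noise", 0.1))
        n_success = round(frac * n_targets)
        for run in range(1, n_runs + 1):
            name_key = zlib.crc32(name.encode()) % (2 ** 31)
            rng = np.random.default_rng([seed, 303, name_key, run])
            success = set(rng.permutation(n_targets)[:n_success].tolist())
            for t, (ref, ref_protein, ref_lig) in enumerate(refs):
                mag = (min(0.2 + 0.9 * noise, 1.9) if t in success
                       else 4.0 + noise)
                pred = perturb(ref, "translate", mag,
                               seed=seed * 7919 + t * 31 + run)
                pred_lig = out_dir / f"{name}_run{run}_target{t:03d}.sdf"
                write_ligands(pred.ligands, pred_lig)
                rows.append({
                    "target_id": f"target{t:03d}",
                    "method": name,
                    "run": run,
                    "pred_protein": str(ref_protein),
                    "pred_ligands": str(pred_lig),
                    "ref_protein": str(ref_protein),
                    "ref_ligands": str(ref_lig),
                    "primary_ligand_code": ref.ligands[0].ligand_code,
                })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
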
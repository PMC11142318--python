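"""Local Distance Difference Test and its protein–ligand interface variant.

lDDT scores how well a prediction preserves the reference's local
inter-atomic distance pattern, without any superposition: for every
reference heavy atom i, its neighbours N_i are the atoms within an
inclusion radius Ro (15 Å by default) excluding atoms of the same residue,
and the score averages — over atoms, then over the four tolerance
thresholds Δk ∈ {0.5, 1, 2, 4} Å — the fraction of neighbour distances
reproduced to within Δk (strict ``<``).

lDDT-PLI restricts the same statistic to protein–ligand cross pairs: i runs
over ligand heavy atoms, N_i contains only protein heavy atoms within a
contact radius (6 Å default) in the reference.  Ligand graph automorphisms
are resolved by taking, per fragment, the atom mapping that maximizes the
score — consistent with symmetry-corrected RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .alignment import ChainMapping, pair_residues
from .errors import UndefinedScoreError
from .ligand_metrics import FragmentAssignment, automorphism_maps
from .model_io import ComplexPose, ProteinStructure

__all__ = ["LddtParams", "lddt", "lddt_pli"]


@dataclass
class LddtParams:
    inclusion_radius: float = 15.0
    thresholds: tuple = (0.5, 1.0, 2.0, 4.0)
    exclude_same_residue: bool = True
    cross_only: bool = False
    pli_radius: float = 6.0

    def __post_init__(self):
        th = tuple(self.thresholds)
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.inclusion_radius <= max(th):
            raise ValueError("inclusion radius must exceed max threshold")


def lddt(pred_coords: np.ndarray, ref_coords: np.ndarray,
         residue_tags: Sequence | None = None,
         params: LddtParams | None = None) -> float:
    """Plain lDDT over a one-to-one atom correspondence.

    ``residue_tags`` gives a hashable residue label per atom; same-residue
    pairs are excluded from neighbour sets when configured (the default).
    Atoms with empty neighbour sets are skipped from the outer average.
    """
    params = params or LddtParams()
    P = np.asarray(pred_coords, dtype=float)
    Q = np.asarray(ref_coords, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("pred/ref coordinate shapes differ")
    n = P.shape[0]
    dref = cdist(Q, Q)
    dpred = cdist(P, P)
    mask = (dref <= params.inclusion_radius)
    np.fill_diagonal(mask, False)
    if params.exclude_same_residue and residue_tags is not None:
        tags = np.array([hash(t) for t in residue_tags])
        mask &= tags[:, None] != tags[None, :]
    dev = np.abs(dpred - dref)
    per_atom = np.zeros(n)
    valid = mask.any(axis=1)
    if not valid.any():
        raise UndefinedScoreError("no atom has a non-empty neighbour set")
    counts = mask.sum(axis=1)
    for delta in params.thresholds:
        hits = ((dev < delta) & mask).sum(axis=1)
        per_atom[valid] += hits[valid] / counts[valid]
    per_atom /= len(params.thresholds)
    return float(per_atom[valid].mean())


# ---------------------------------------------------------------------------
# lDDT-PLI
# ---------------------------------------------------------------------------

def _protein_atom_correspondence(pred: ProteinStructure,
                                 ref: ProteinStructure,
                                 mapping: ChainMapping
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Matched (pred_coords, ref_coords) for protein heavy atoms, paired by
    chain mapping, sequence alignment and atom name."""
    pred_pts, ref_pts = [], []
    for ref_chain, pred_chain in mapping.inverse().items():
        pairs = pair_residues(ref.sequence(ref_chain),
                              pred.sequence(pred_chain))
        ref_res = ref.residues(ref_chain)
        pred_res = pred.residues(pred_chain)
        for i, j in pairs:
            ra = {a.name: a for a in ref.residue_atoms(ref_chain,
                                                       ref_res[i - 1])}
            pa = {a.name: a for a in pred.residue_atoms(pred_chain,
                                                        pred_res[j - 1])}
            for name, atom in ra.items():
                if name in pa:
                    ref_pts.append(atom.coords)
                    pred_pts.append(pa[name].coords)
    return (np.array(pred_pts, dtype=float).reshape(-1, 3),
            np.array(ref_pts, dtype=float).reshape(-1, 3))


def lddt_pli(pred: ComplexPose, ref: ComplexPose,
             params: LddtParams | None = None,
             chain_mapping: ChainMapping | None = None,
             fragment_assignment: FragmentAssignment | None = None) -> float:
    """Interface lDDT over protein–ligand cross distances.

    Uses the reference to define contacts (protein heavy atoms within
    ``params.pli_radius`` of each ligand heavy atom) and scores how well the
    prediction reproduces those cross distances at the four thresholds.
    Raises :class:`UndefinedScoreError` when the reference has no
    protein–ligand contact within the radius.
    """
    params = params or LddtParams(cross_only=True)
    if chain_mapping is None:
        chain_mapping = ChainMapping(
            pairs={c: c for c in pred.protein.chain_ids
                   if c in ref.protein.chain_ids})
    if fragment_assignment is None:
        from .ligand_metrics import assign_fragments
        fragment_assignment = assign_fragments(pred.ligands, ref.ligands)

    prot_pred, prot_ref = _protein_atom_correspondence(
        pred.protein, ref.protein, chain_mapping)
    if len(prot_ref) == 0:
        raise UndefinedScoreError("no matched protein atoms")

    scores: list[float] = []  # per ligand atom with non-empty contact set
    for p_idx, r_idx in fragment_assignment.pairs.items():
        plig, rlig = pred.ligands[p_idx], ref.ligands[r_idx]
        ref_xyz = rlig.coords()
        dref = cdist(ref_xyz, prot_ref)              # (n_lig, n_prot)
        contact = dref <= params.pli_radius
        valid = contact.any(axis=1)
        if not valid.any():
            continue
        maps = automorphism_maps(plig, rlig)
        pred_xyz_all = plig.coords()
        best_atom_scores, best_total = None, -1.0
        for m in maps:
            dpred = cdist(pred_xyz_all[m], prot_pred)
            dev = np.abs(dpred - dref)
            frac = np.zeros(ref_xyz.shape[0])
            counts = contact.sum(axis=1)
            for delta in params.thresholds:
                hits = ((dev < delta) & contact).sum(axis=1)
                frac[valid] += hits[valid] / counts[valid]
            frac /= len(params.thresholds)
            total = frac[valid].sum()
            if total > best_total:
                best_total = total
                best_atom_scores = frac[valid]
        scores.extend(best_atom_scores.tolist())
    if not scores:
        raise UndefinedScoreError(
            f"no protein–ligand contact within {params.pli_radius} Å "
            f"in the reference")
    return float(np.mean(scores))
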
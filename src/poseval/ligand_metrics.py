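"""Ligand pose accuracy metrics.

Heavy-atom RMSD is computed in the pocket-aligned frame with no ligand
re-superposition, so it measures placement error, not just conformer error.
With symmetry correction on (the default) the RMSD is minimized over the
molecular-graph automorphisms, so chemically indistinguishable atom
orderings (e.g. a benzene ring rotated by 60°) do not inflate the score.

``centroid_rmsd`` — the pocket-identification proxy usually written cRMSD —
is simply the distance between unweighted heavy-atom centroids; despite the
name it involves no per-atom deviations, and the two graphs need not match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import GraphMismatchError
from .model_io import LigandMol

__all__ = [
    "heavy_atom_rmsd",
    "centroid_rmsd",
    "assign_fragments",
    "FragmentAssignment",
    "automorphism_maps",
]

DEFAULT_AUTOMORPHISM_CAP = 10_000


def automorphism_maps(pred: LigandMol, ref: LigandMol,
                      cap: int = DEFAULT_AUTOMORPHISM_CAP) -> np.ndarray:
    """Graph matchings ref→pred as an (n_maps, n_atoms) index array.

    Row ``m`` maps reference atom ``i`` to predicted atom ``maps[m, i]``.
    Stereochemistry is ignored (poses with flipped stereocentres must still
    be scored).  Enumeration is capped; at the cap the result is the set
    found so far (element/bond-environment constrained matching), which
    always contains at least one valid map.
    """
    if pred.identity != ref.identity:
        raise GraphMismatchError(
            f"graphs differ: {pred.identity!r} vs {ref.identity!r}")
    matches = pred.mol.GetSubstructMatches(
        ref.mol, uniquify=False, useChirality=False, maxMatches=cap)
    if not matches:
        raise GraphMismatchError(
            "graph keys match but no atom mapping found (inconsistent input)")
    if len(matches) >= cap:
        warnings.warn(
            f"automorphism enumeration capped at {cap}; RMSD is an upper "
            f"bound over the enumerated maps", RuntimeWarning)
    return np.array(matches, dtype=int)


def heavy_atom_rmsd(pred: LigandMol, ref: LigandMol, symmetry: bool = True,
                    cap: int = DEFAULT_AUTOMORPHISM_CAP) -> float:
    """Heavy-atom RMSD in the current frame (no re-superposition).

    With ``symmetry`` on: min over graph automorphisms σ of
    sqrt((1/n) Σ_i ||x̂_σ(i) − x_i||²).  Off: input atom order is used
    directly (atom counts must agree).
    """
    ref_xyz = ref.coords()
    pred_xyz = pred.coords()
    if not symmetry:
        if pred.n_atoms != ref.n_atoms:
            raise GraphMismatchError(
                f"atom counts differ: {pred.n_atoms} vs {ref.n_atoms}")
        diff = pred_xyz - ref_xyz
        return float(np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff))))
    maps = automorphism_maps(pred, ref, cap=cap)
    diffs = pred_xyz[maps] - ref_xyz[None, :, :]     # (m, n, 3)
    msd = np.mean(np.einsum("mij,mij->mi", diffs, diffs), axis=1)
    return float(np.sqrt(msd.min()))


def centroid_rmsd(pred: LigandMol, ref: LigandMol) -> float:
    """Distance between unweighted heavy-atom centroids (Å)."""
    if pred.n_atoms == 0 or ref.n_atoms == 0:
        raise ValueError("empty molecule")
    return float(np.linalg.norm(pred.centroid() - ref.centroid()))


@dataclass
class FragmentAssignment:
    """Optimal matching of predicted to reference fragments.

    ``pairs`` maps predicted-list index → reference-list index.  Fragments
    are matched only within identical-graph classes, minimizing the summed
    symmetry-aware RMSD (Hungarian assignment per class).
    """

    pairs: dict = field(default_factory=dict)       # pred idx -> ref idx
    rmsd: dict = field(default_factory=dict)        # pred idx -> Å
    unmatched_pred: list = field(default_factory=list)
    unmatched_ref: list = field(default_factory=list)

    @property
    def total_rmsd(self) -> float:
        return float(sum(self.rmsd.values()))


def assign_fragments(pred_ligands: Sequence[LigandMol],
                     ref_ligands: Sequence[LigandMol],
                     symmetry: bool = True) -> FragmentAssignment:
    """Assign predicted fragments to reference fragments.

    Within each graph-identity class the assignment minimizes the summed
    (symmetry-aware) RMSD; across classes no matches are possible.  Surplus
    fragments on either side are reported, not errors.
    """
    out = FragmentAssignment()
    classes: dict[str, tuple[list[int], list[int]]] = {}
    for i, lig in enumerate(pred_ligands):
        classes.setdefault(lig.identity, ([], []))[0].append(i)
    for j, lig in enumerate(ref_ligands):
        classes.setdefault(lig.identity, ([], []))[1].append(j)
    for key, (p_idx, r_idx) in classes.items():
        if not p_idx or not r_idx:
            out.unmatched_pred.extend(p_idx)
            out.unmatched_ref.extend(r_idx)
            continue
        cost = np.array([[heavy_atom_rmsd(pred_ligands[i], ref_ligands[j],
                                          symmetry=symmetry)
                          for j in r_idx] for i in p_idx])
        rows, cols = linear_sum_assignment(cost)
        matched_p, matched_r = set(), set()
        for r, c in zip(rows, cols):
            out.pairs[p_idx[r]] = r_idx[c]
            out.rmsd[p_idx[r]] = float(cost[r, c])
            matched_p.add(p_idx[r])
            matched_r.add(r_idx[c])
        out.unmatched_pred.extend(i for i in p_idx if i not in matched_p)
        out.unmatched_ref.extend(j for j in r_idx if j not in matched_r)
    out.unmatched_pred.sort()
    out.unmatched_ref.sort()
    return out
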
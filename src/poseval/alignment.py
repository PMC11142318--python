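"""Rigid superposition and binding-pocket machinery.

The docking evaluation convention implemented here is apo→holo: predicted
protein structures are superposed onto the reference complex using only the
Cα atoms of the binding pocket — all residues with any heavy atom within a
cutoff (default 10 Å) of any reference ligand heavy atom — and the resulting
rigid transform is applied to the whole prediction, ligands included.
Ligand metrics are then computed in that frame with no re-superposition, so
pocket-placement error is preserved.

Residue correspondence between predicted and reference chains comes from a
global sequence alignment with affine gap penalties; only aligned, identical
residues contribute Cα pairs.  Chain mapping searches sequence-compatible
bijections for the one minimizing the pocket fit RMSD (exhaustive up to six
interchangeable chains per sequence class, greedy beyond).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from scipy.spatial.distance import cdist

from .errors import (ChainMappingError, DegenerateAlignmentError,
                     MissingPocketResiduesError)
from .model_io import LigandMol, ProteinStructure

__all__ = [
    "RigidTransform",
    "BindingPocket",
    "ChainMapping",
    "kabsch",
    "define_pocket",
    "align_to_pocket",
    "map_chains",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R x + t (rotation row-major, Å translation)."""

    rotation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    translation: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        R = self.R
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is improper (det < 0)")

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.R.T + self.t

    @classmethod
    def from_arrays(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        return cls(tuple(tuple(float(x) for x in row) for row in R),
                   tuple(float(x) for x in t))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def to_json(self) -> str:
        return json.dumps({"rotation": [list(r) for r in self.rotation],
                           "translation": list(self.translation)})

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        d = json.loads(s)
        return cls.from_arrays(np.array(d["rotation"]),
                               np.array(d["translation"]))


@dataclass(frozen=True)
class BindingPocket:
    """Residues with a heavy atom within ``cutoff`` of any ligand heavy atom."""

    members: frozenset  # of (chain_id, residue_index)
    cutoff: float

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ChainMapping:
    """One-to-one map from predicted chain ids to reference chain ids."""

    pairs: dict = field(default_factory=dict)   # pred chain -> ref chain
    score: float = 0.0                          # pocket fit RMSD used to pick it

    def inverse(self) -> dict:
        return {v: k for k, v in self.pairs.items()}


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------

def kabsch(mobile_coords: np.ndarray, ref_coords: np.ndarray,
           weights: np.ndarray | None = None
           ) -> tuple[RigidTransform, float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``ref``.

    Classic SVD solution of the weighted orthogonal Procrustes problem with
    the determinant correction that forbids reflections.  Returns the
    transform and the post-fit (weighted) RMSD in Å.
    """
    P = np.asarray(mobile_coords, dtype=float)
    Q = np.asarray(ref_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise DegenerateAlignmentError(f"need >= 3 points, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    cm = w @ P
    cr = w @ Q
    P0 = P - cm
    Q0 = Q - cr
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or \
            np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise DegenerateAlignmentError("collinear or coincident point set")
    H = (w[:, None] * P0).T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    transform = RigidTransform.from_arrays(R, t)
    diff = transform.apply(P) - Q
    fit_rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return transform, fit_rmsd


# ---------------------------------------------------------------------------
# pocket
# ---------------------------------------------------------------------------

def define_pocket(ref_protein: ProteinStructure,
                  ref_ligands: Sequence[LigandMol],
                  cutoff: float = 10.0) -> BindingPocket:
    """Binding pocket: residues with >= 1 heavy atom within ``cutoff`` Å of
    >= 1 ligand heavy atom, over all ligands and cofactors."""
    members: set[tuple[str, int]] = set()
    if ref_ligands and cutoff > 0:
        lig_coords = np.vstack([lig.coords() for lig in ref_ligands])
        prot_coords = ref_protein.coords()
        dmin = cdist(prot_coords, lig_coords).min(axis=1)
        for atom, d in zip(ref_protein.atoms, dmin):
            if d <= cutoff:
                members.add((atom.chain_id, atom.residue_index))
    return BindingPocket(frozenset(members), float(cutoff))


# ---------------------------------------------------------------------------
# sequence-based residue correspondence
# ---------------------------------------------------------------------------

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -10.0
_aligner.extend_gap_score = -0.5


def pair_residues(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Aligned identical residue pairs as 1-based (pos_in_a, pos_in_b)."""
    if not seq_a or not seq_b:
        return []
    aln = _aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            ia, ib = a0 + off, b0 + off
            if seq_a[ia] == seq_b[ib]:
                pairs.append((ia + 1, ib + 1))
    return pairs


def sequence_identity(seq_a: str, seq_b: str) -> float:
    pairs = pair_residues(seq_a, seq_b)
    denom = min(len(seq_a), len(seq_b))
    return len(pairs) / denom if denom else 0.0


# ---------------------------------------------------------------------------
# pocket-focused alignment
# ---------------------------------------------------------------------------

def _pocket_ca_pairs(mobile: ProteinStructure, ref: ProteinStructure,
                     pocket: BindingPocket, mapping: ChainMapping
                     ) -> tuple[np.ndarray, np.ndarray, list]:
    ref_to_pred = mapping.inverse()
    mob_pts, ref_pts, missing = [], [], []
    # residue correspondence per mapped chain pair, computed once
    chain_pairs: dict[str, dict[int, int]] = {}
    for ref_chain, pred_chain in ref_to_pred.items():
        pairs = pair_residues(ref.sequence(ref_chain),
                              mobile.sequence(pred_chain))
        ref_res = ref.residues(ref_chain)
        mob_res = mobile.residues(pred_chain)
        chain_pairs[ref_chain] = {ref_res[i - 1]: mob_res[j - 1]
                                  for i, j in pairs}
    for chain_id, res_idx in sorted(pocket.members):
        cmap = chain_pairs.get(chain_id)
        mob_chain = ref_to_pred.get(chain_id)
        mob_res = None if cmap is None else cmap.get(res_idx)
        ref_ca = ref.ca_coord(chain_id, res_idx)
        if ref_ca is None:
            continue  # pocket residue without Cα (non-standard); skip
        mob_ca = (mobile.ca_coord(mob_chain, mob_res)
                  if mob_res is not None else None)
        if mob_ca is None:
            missing.append((chain_id, res_idx))
            continue
        mob_pts.append(mob_ca)
        ref_pts.append(ref_ca)
    return (np.array(mob_pts, dtype=float).reshape(-1, 3),
            np.array(ref_pts, dtype=float).reshape(-1, 3), missing)


def align_to_pocket(mobile_protein: ProteinStructure,
                    ref_protein: ProteinStructure,
                    pocket: BindingPocket,
                    chain_mapping: ChainMapping,
                    trim: bool = False,
                    trim_fraction: float = 0.1,
                    trim_cycles: int = 5,
                    ) -> tuple[ProteinStructure, RigidTransform, float]:
    """Kabsch fit on pocket-residue Cα atoms; transform the whole structure.

    ``trim`` enables iterative outlier rejection (drop the worst
    ``trim_fraction`` of pairs, up to ``trim_cycles`` cycles), mimicking the
    rejection step of common alignment tools; off by default.
    """
    mob, ref, missing = _pocket_ca_pairs(mobile_protein, ref_protein,
                                         pocket, chain_mapping)
    if missing:
        raise MissingPocketResiduesError(missing)
    if len(mob) < 3:
        raise DegenerateAlignmentError(
            f"only {len(mob)} resolvable pocket Cα pairs (need >= 3)")
    transform, fit = kabsch(mob, ref)
    if trim:
        for _ in range(trim_cycles):
            dev = np.linalg.norm(transform.apply(mob) - ref, axis=1)
            keep = dev <= np.quantile(dev, 1.0 - trim_fraction)
            if keep.sum() < 3 or keep.all():
                break
            mob, ref = mob[keep], ref[keep]
            transform, fit = kabsch(mob, ref)
    return mobile_protein.transformed(transform), transform, fit


# ---------------------------------------------------------------------------
# chain mapping
# ---------------------------------------------------------------------------

def map_chains(pred_protein: ProteinStructure,
               ref_protein: ProteinStructure,
               ref_pocket: BindingPocket,
               min_identity: float = 0.95,
               max_exhaustive: int = 6) -> ChainMapping:
    """Optimal chain bijection by pocket-Cα fit RMSD.

    Chains are grouped into sequence classes (pairwise identity >=
    ``min_identity``); within each class all bijections are tried when the
    class holds at most ``max_exhaustive`` interchangeable chains, greedily
    (file order) beyond that.
    """
    ref_chains = ref_protein.chain_ids
    pred_chains = pred_protein.chain_ids
    compat = {rc: [pc for pc in pred_chains
                   if sequence_identity(ref_protein.sequence(rc),
                                        pred_protein.sequence(pc))
                   >= min_identity]
              for rc in ref_chains}
    unmatchable = [rc for rc, pcs in compat.items() if not pcs]
    if len(unmatchable) == len(ref_chains):
        raise ChainMappingError(
            f"no sequence-compatible partner for any reference chain "
            f"{ref_chains}")

    # group ref chains into classes of interchangeable candidates
    classes: dict[frozenset, list[str]] = {}
    for rc in ref_chains:
        if compat[rc]:
            classes.setdefault(frozenset(compat[rc]), []).append(rc)

    def candidate_mappings():
        per_class = []
        for cand_set, rcs in classes.items():
            cands = sorted(cand_set)
            if len(cands) <= max_exhaustive:
                opts = [perm for perm in itertools.permutations(cands,
                                                                len(rcs))]
            else:
                opts = [tuple(cands[:len(rcs)])]  # greedy: file order
            per_class.append((rcs, opts))
        for combo in itertools.product(*[opts for _, opts in per_class]):
            used: set[str] = set()
            pairs: dict[str, str] = {}
            ok = True
            for (rcs, _), perm in zip(per_class, combo):
                if used & set(perm):
                    ok = False
                    break
                used |= set(perm)
                for rc, pc in zip(rcs, perm):
                    pairs[pc] = rc
            if ok and pairs:
                yield pairs

    best: ChainMapping | None = None
    for pairs in candidate_mappings():
        mapping = ChainMapping(pairs=pairs)
        pocket_chains = {c for c, _ in ref_pocket.members}
        if pocket_chains and not pocket_chains & set(pairs.values()):
            continue
        try:
            mob, ref, missing = _pocket_ca_pairs(
                pred_protein, ref_protein, ref_pocket, mapping)
            if len(mob) >= 3:
                _, fit = kabsch(mob, ref)
            else:
                fit = float("inf")
        except DegenerateAlignmentError:
            fit = float("inf")
        mapping.score = fit
        if best is None or fit < best.score:
            best = mapping
    if best is None:
        raise ChainMappingError("no valid chain bijection found")
    return best
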
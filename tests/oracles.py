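"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately avoids the code path it validates: loop-based
enumeration instead of vectorization, generic graph isomorphism instead of
substructure matching, a linear program instead of the CDF formula.
"""

import itertools

import networkx as nx
import numpy as np
from scipy.optimize import linprog


def lddt_brute_force(pred, ref, residue_tags, radius=15.0,
                     thresholds=(0.5, 1.0, 2.0, 4.0)):
    """Plain-loop lDDT over all ordered atom pairs."""
    n = len(ref)
    per_atom = []
    for i in range(n):
        neigh = [j for j in range(n)
                 if j != i
                 and residue_tags[j] != residue_tags[i]
                 and np.linalg.norm(ref[j] - ref[i]) <= radius]
        if not neigh:
            continue
        frac = 0.0
        for delta in thresholds:
            hits = 0
            for j in neigh:
                dref = np.linalg.norm(ref[j] - ref[i])
                dpred = np.linalg.norm(pred[j] - pred[i])
                if abs(dpred - dref) < delta:
                    hits += 1
            frac += hits / len(neigh)
        per_atom.append(frac / len(thresholds))
    if not per_atom:
        raise ValueError("no atom with neighbours")
    return float(np.mean(per_atom))


def pocket_brute_force(protein, ligands, cutoff):
    """All-pairs residue membership scan."""
    members = set()
    for atom in protein.atoms:
        for lig in ligands:
            for xyz in lig.coords():
                if np.linalg.norm(np.array(atom.coords) - xyz) <= cutoff:
                    members.add((atom.chain_id, atom.residue_index))
    return members


def graph_automorphisms(ligand):
    """All automorphisms of the ligand graph via generic VF2 matching.

    Nodes are typed by (element, formal charge); edges by bond order.
    Returns mappings as index arrays: sigma[i] = image of atom i.
    """
    g = nx.Graph()
    for i, (el, ch) in enumerate(zip(ligand.elements,
                                     ligand.formal_charges)):
        g.add_node(i, kind=(el, ch))
    for i, j, order in ligand.bonds:
        g.add_edge(i, j, order=order)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda a, b: a["kind"] == b["kind"],
        edge_match=lambda a, b: a["order"] == b["order"])
    return [np.array([m[i] for i in range(ligand.n_atoms)])
            for m in matcher.isomorphisms_iter()]


def rmsd_by_automorphism_enumeration(pred, ref):
    """min over graph automorphisms of the plain coordinate RMSD."""
    P, R = pred.coords(), ref.coords()
    best = np.inf
    for sigma in graph_automorphisms(ref):
        d = P[sigma] - R
        best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
    return best


def assignment_brute_force(pred_ligands, ref_ligands, rmsd_fn):
    """Exhaustive minimum-cost matching within graph-identity classes."""
    classes = {}
    for i, lig in enumerate(pred_ligands):
        classes.setdefault(lig.identity, ([], []))[0].append(i)
    for j, lig in enumerate(ref_ligands):
        classes.setdefault(lig.identity, ([], []))[1].append(j)
    total = 0.0
    pairs = {}
    for key, (p_idx, r_idx) in classes.items():
        if not p_idx or not r_idx:
            continue
        k = min(len(p_idx), len(r_idx))
        best_cost, best_pairs = np.inf, None
        for p_sub in itertools.permutations(p_idx, k):
            for r_sub in itertools.combinations(r_idx, k):
                cost = sum(rmsd_fn(pred_ligands[p], ref_ligands[r])
                           for p, r in zip(p_sub, r_sub))
                if cost < best_cost:
                    best_cost = cost
                    best_pairs = dict(zip(p_sub, r_sub))
        total += best_cost
        pairs.update(best_pairs)
    return pairs, total


def emd_linear_program(u_weights, v_weights):
    """1-D optimal transport via LP on the unified integer support."""
    u = np.asarray(u_weights, float)
    v = np.asarray(v_weights, float)
    u = u / u.sum()
    v = v / v.sum()
    m = len(u)
    cost = np.abs(np.subtract.outer(np.arange(m), np.arange(m))).ravel()
    A_eq = []
    b_eq = []
    for i in range(m):          # row marginals
        row = np.zeros((m, m))
        row[i, :] = 1
        A_eq.append(row.ravel())
        b_eq.append(u[i])
    for j in range(m):          # column marginals
        col = np.zeros((m, m))
        col[:, j] = 1
        A_eq.append(col.ravel())
        b_eq.append(v[j])
    res = linprog(cost, A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)


def clash_count_brute_force(coords_a, radii_a, coords_b, radii_b, factor):
    count = 0
    for i in range(len(coords_a)):
        for j in range(len(coords_b)):
            if np.linalg.norm(coords_a[i] - coords_b[j]) < \
                    factor * (radii_a[i] + radii_b[j]):
                count += 1
    return count
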
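import numpy as np
import pytest

import poseval as pv
from poseval import fixtures as fx
from poseval.alignment import pair_residues
from poseval.errors import (ChainMappingError, DegenerateAlignmentError,
                            MissingPocketResiduesError)
from conftest import random_rigid
from oracles import pocket_brute_force


class TestKabsch:
    def test_identical_sets_give_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        tr, fit = pv.kabsch(pts, pts)
        assert np.allclose(tr.R, np.eye(3), atol=1e-9)
        assert np.allclose(tr.t, 0, atol=1e-9)
        assert fit < 1e-9

    def test_recovers_known_rigid_motion(self, rng):
        pts = rng.normal(size=(25, 3))
        Q, t = random_rigid(rng)
        moved = pts @ Q.T + t
        tr, fit = pv.kabsch(moved, pts)
        assert fit < 1e-8
        assert np.allclose(tr.apply(moved), pts, atol=1e-8)
        # recovered rotation inverts the applied one
        assert np.allclose(tr.R @ Q, np.eye(3), atol=1e-8)

    def test_reflection_is_rejected(self, rng):
        pts = rng.normal(size=(12, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        tr, fit = pv.kabsch(mirrored, pts)
        assert np.linalg.det(tr.R) == pytest.approx(1.0, abs=1e-9)
        assert fit > 0.1

    def test_degenerate_inputs_raise(self, rng):
        with pytest.raises(DegenerateAlignmentError):
            pv.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(DegenerateAlignmentError):
            pv.kabsch(line, line)


class TestPocket:
    def test_far_ligand_gives_empty_pocket(self, ethanol_complex):
        lig = ethanol_complex.ligands[0]
        far = lig.with_coords(lig.coords() + 200.0)
        pocket = pv.define_pocket(ethanol_complex.protein, [far], 10.0)
        assert len(pocket) == 0

    def test_zero_cutoff_gives_empty_pocket(self, ethanol_complex):
        pocket = pv.define_pocket(ethanol_complex.protein,
                                  ethanol_complex.ligands, 0.0)
        assert len(pocket) == 0

    def test_matches_all_pairs_oracle(self, all_reference_complexes):
        for pose in all_reference_complexes.values():
            got = pv.define_pocket(pose.protein, pose.ligands, 10.0)
            want = pocket_brute_force(pose.protein, pose.ligands, 10.0)
            assert got.members == want

    def test_invariant_to_ligand_order_and_rigid_motion(
            self, acetate_complex, rng):
        pose = fx.make_reference_complex(5, "acetate",
                                         extra_fragments=("benzene",))
        a = pv.define_pocket(pose.protein, pose.ligands, 10.0)
        b = pv.define_pocket(pose.protein, pose.ligands[::-1], 10.0)
        assert a.members == b.members
        Q, t = random_rigid(rng)
        tr = pv.RigidTransform.from_arrays(Q, t)
        moved = pose.transformed(tr)
        c = pv.define_pocket(moved.protein, moved.ligands, 10.0)
        assert c.members == a.members


class TestAlignToPocket:
    def test_recovers_rigid_motion_exactly(self, ethanol_complex, rng):
        pose = ethanol_complex
        pocket = pv.define_pocket(pose.protein, pose.ligands, 10.0)
        Q, t = random_rigid(rng)
        moved = pose.protein.transformed(pv.RigidTransform.from_arrays(Q, t))
        mapping = pv.map_chains(moved, pose.protein, pocket)
        aligned, tr, fit = pv.align_to_pocket(moved, pose.protein,
                                              pocket, mapping)
        assert fit < 1e-8
        assert np.abs(aligned.coords() - pose.protein.coords()).max() < 1e-7

    def test_self_alignment_is_identity(self, all_reference_complexes):
        for pose in all_reference_complexes.values():
            pocket = pv.define_pocket(pose.protein, pose.ligands, 10.0)
            mapping = pv.map_chains(pose.protein, pose.protein, pocket)
            _, tr, fit = pv.align_to_pocket(pose.protein, pose.protein,
                                            pocket, mapping)
            assert fit < 1e-9
            assert np.allclose(tr.R, np.eye(3), atol=1e-7)

    def test_pocket_fit_ignores_displaced_distal_domain(self):
        # two-chain pocket fixture; displace the whole far chain by 20 Å
        pose = fx.make_reference_complex(9, "ethanol", n_residues=12,
                                         n_chains=2)
        pocket = pv.define_pocket(pose.protein, pose.ligands, 6.0)
        pocket_chains = {c for c, _ in pocket.members}
        other = [c for c in pose.protein.chain_ids
                 if c not in pocket_chains]
        if not other:      # all chains touch the pocket: shrink it
            pocket = pv.define_pocket(pose.protein, pose.ligands, 4.0)
            pocket_chains = {c for c, _ in pocket.members}
            other = [c for c in pose.protein.chain_ids
                     if c not in pocket_chains]
        assert other, "fixture must have a distal chain"
        coords = pose.protein.coords()
        idx = [i for i, a in enumerate(pose.protein.atoms)
               if a.chain_id in other]
        coords[idx] += np.array([20.0, 0.0, 0.0])
        mobile = pose.protein.with_coords(coords)
        mapping = pv.ChainMapping(
            pairs={c: c for c in pose.protein.chain_ids})
        _, _, pocket_fit = pv.align_to_pocket(mobile, pose.protein,
                                              pocket, mapping)
        _, global_fit = pv.kabsch(mobile.coords(), pose.protein.coords())
        assert pocket_fit < 1e-8
        assert global_fit > 5.0

    def test_missing_pocket_residues_named(self, ethanol_complex):
        pose = ethanol_complex
        pocket = pv.define_pocket(pose.protein, pose.ligands, 10.0)
        # mobile lacking residue 1 entirely
        kept = [a for a in pose.protein.atoms if a.residue_index != 1]
        renum = pv.ProteinStructure(kept)
        mapping = pv.ChainMapping(pairs={"A": "A"})
        with pytest.raises(MissingPocketResiduesError):
            pv.align_to_pocket(renum, pose.protein, pocket, mapping)


class TestMapChains:
    def test_single_chain_identity(self, ethanol_complex):
        pose = ethanol_complex
        pocket = pv.define_pocket(pose.protein, pose.ligands, 10.0)
        mapping = pv.map_chains(pose.protein, pose.protein, pocket)
        assert mapping.pairs == {"A": "A"}

    def test_homodimer_swap_matches_exhaustive_search(self):
        pose = fx.make_reference_complex(13, "ethanol", n_residues=8,
                                         n_chains=2)
        protein = pose.protein
        pocket = pv.define_pocket(protein, pose.ligands, 10.0)
        # relabel chains A<->B in the prediction
        swapped_atoms = [
            pv.Atom(a.element, a.name, a.coords, a.residue_index,
                    a.residue_name, {"A": "B", "B": "A"}[a.chain_id])
            for a in protein.atoms]
        swapped = pv.ProteinStructure(swapped_atoms)
        mapping = pv.map_chains(swapped, protein, pocket)
        # exhaustive 2-permutation oracle
        best = None
        for pairs in ({"A": "A", "B": "B"}, {"A": "B", "B": "A"}):
            m = pv.ChainMapping(pairs=pairs)
            try:
                _, _, fit = pv.align_to_pocket(swapped, protein, pocket, m)
            except Exception:
                continue
            if best is None or fit < best[1]:
                best = (pairs, fit)
        assert mapping.pairs == best[0]
        assert mapping.score == pytest.approx(best[1], abs=1e-9)

    def test_incompatible_sequences_raise(self, ethanol_complex):
        pose = ethanol_complex
        # a protein with a completely different residue composition
        other = fx.make_toy_pocket(2, 8, 12.0,
                                   residue_cycle=("GLY",) * 8)
        pocket = pv.define_pocket(pose.protein, pose.ligands, 10.0)
        with pytest.raises(ChainMappingError):
            pv.map_chains(other, pose.protein, pocket)


def test_residue_pairing_handles_gaps():
    pairs = pair_residues("ACDEFG", "ACEFG")   # D deleted in second
    assert (1, 1) in pairs and (2, 2) in pairs
    assert (4, 3) in pairs and (6, 5) in pairs
    assert all(a != 3 for a, _ in pairs) or (3, 3) not in pairs
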
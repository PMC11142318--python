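import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poseval as pv
from poseval import fixtures as fx
from poseval.errors import EmptyHistogramsError
from poseval.plif import Interaction, PLIFKey
from conftest import random_rigid
from oracles import emd_linear_program


def _key(lig, res, itype):
    return PLIFKey(lig, res, itype)


class TestDetection:
    def test_distant_ligand_gives_empty_histogram(self, ethanol_complex):
        pose = ethanol_complex
        far = pose.ligands[0].with_coords(pose.ligands[0].coords() + 100.0)
        hist = pv.detect_plifs(
            pv.ComplexPose(pose.protein, [far], ["primary"]))
        assert len(hist) == 0
        assert hist.total == 0

    def test_planted_serine_hydrogen_bond(self, ethanol_complex):
        hist = pv.detect_plifs(ethanol_complex)
        lig_code = ethanol_complex.ligands[0].ligand_code
        assert _key(lig_code, "SER",
                    Interaction.HBOND_ACCEPTOR.value) in hist.counts

    def test_planted_arginine_salt_bridge(self, acetate_complex):
        hist = pv.detect_plifs(acetate_complex)
        lig_code = acetate_complex.ligands[0].ligand_code
        assert _key(lig_code, "ARG",
                    Interaction.IONIC_ANION.value) in hist.counts

    def test_planted_interactions_per_chemistry(self,
                                                all_reference_complexes):
        expected = {
            "methylammonium": ("ASP", Interaction.IONIC_CATION.value),
            "ion": ("ASP", Interaction.METAL_COORDINATION.value),
            "benzene": ("ALA", Interaction.HYDROPHOBIC.value),
            "imidazole": ("SER", Interaction.HBOND_ACCEPTOR.value),
        }
        for template, (res, itype) in expected.items():
            pose = all_reference_complexes[template]
            hist = pv.detect_plifs(pose)
            key = _key(pose.ligands[0].ligand_code, res, itype)
            assert key in hist.counts, (template, dict(hist.counts))

    def test_invariant_under_rigid_motion_of_complex(
            self, acetate_complex, rng):
        base = pv.detect_plifs(acetate_complex).counts
        Q, t = random_rigid(rng)
        moved = acetate_complex.transformed(
            pv.RigidTransform.from_arrays(Q, t))
        assert pv.detect_plifs(moved).counts == base


class TestUnifySupport:
    def test_identical_single_key(self):
        k = _key("LIG", "SER", "Hydrophobic")
        u = pv.PLIFHistogram({k: 3})
        support, uw, vw = pv.unify_support(u, u)
        assert support == [k]
        assert uw.tolist() == [3.0] and vw.tolist() == [3.0]

    def test_disjoint_keys_zero_filled(self):
        a = _key("LIG", "ALA", "Hydrophobic")
        b = _key("LIG", "SER", "HBond-donor")
        support, uw, vw = pv.unify_support(pv.PLIFHistogram({a: 1}),
                                           pv.PLIFHistogram({b: 2}))
        assert support == sorted([a, b])
        assert uw.tolist() == [1.0, 0.0]
        assert vw.tolist() == [0.0, 2.0]

    def test_overlapping_keys_match_set_union(self):
        keys = [_key("L", r, "Hydrophobic") for r in ("ALA", "SER", "PHE")]
        u = pv.PLIFHistogram({keys[0]: 1, keys[1]: 2})
        v = pv.PLIFHistogram({keys[1]: 1, keys[2]: 4})
        support, uw, vw = pv.unify_support(u, v)
        assert set(support) == set(u.counts) | set(v.counts)
        assert support == sorted(support)

    def test_both_empty_raise(self):
        with pytest.raises(EmptyHistogramsError):
            pv.unify_support(pv.PLIFHistogram(), pv.PLIFHistogram())


def _random_histogram(rng, n_keys=5, allow_empty=False):
    residues = ("ALA", "SER", "ASP", "ARG", "PHE")
    types = ("Hydrophobic", "HBond-donor", "Ionic-anion", "PiStacking",
             "HBond-acceptor")
    keys = [_key("L", residues[i], types[i]) for i in range(n_keys)]
    counts = rng.integers(0 if allow_empty else 1, 8, size=n_keys)
    return pv.PLIFHistogram(
        {k: int(c) for k, c in zip(keys, counts) if c > 0})


class TestEmd:
    def test_identical_histograms_are_zero(self, rng):
        for _ in range(10):
            h = _random_histogram(rng)
            assert pv.plif_emd(h, h) == pytest.approx(0.0, abs=1e-12)

    def test_point_masses_closed_form(self):
        keys = [_key("L", r, "Hydrophobic") for r in ("ALA", "PHE", "SER")]
        u = pv.PLIFHistogram({k: (5 if k == keys[0] else 0)
                              for k in keys})
        v = pv.PLIFHistogram({k: (2 if k == keys[2] else 0)
                              for k in keys})
        # all mass moves from position 0 to position 2
        assert pv.plif_emd(u, v) == pytest.approx(2.0, abs=1e-12)

    def test_matches_linear_program_oracle(self, rng):
        for _ in range(200):
            u = _random_histogram(rng)
            v = _random_histogram(rng)
            support, uw, vw = pv.unify_support(u, v)
            got = pv.plif_emd(u, v)
            want = emd_linear_program(uw, vw)
            assert got == pytest.approx(want, abs=1e-9)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(200):
            a, b, c = (_random_histogram(rng) for _ in range(3))
            dab = pv.plif_emd(a, b)
            dba = pv.plif_emd(b, a)
            assert dab >= 0
            assert dab == pytest.approx(dba, abs=1e-12)
            # identity of indiscernibles on normalized distributions
            _, uw, vw = pv.unify_support(a, b)
            if np.allclose(uw / uw.sum(), vw / vw.sum()):
                assert dab == pytest.approx(0.0, abs=1e-12)
            else:
                assert dab > 0
            assert pv.plif_emd(a, c) <= dab + pv.plif_emd(b, c) + 1e-9

    def test_empty_histogram_raises_unless_fallback(self):
        k = _key("L", "ALA", "Hydrophobic")
        u = pv.PLIFHistogram({k: 2})
        with pytest.raises(EmptyHistogramsError):
            pv.plif_emd(pv.PLIFHistogram(), u)
        assert pv.plif_emd(pv.PLIFHistogram(), u,
                           empty_fallback=True) >= 0.0


_RESIDUES = ("ALA", "SER", "ASP", "ARG", "PHE", "HIS")


@settings(max_examples=100, derandomize=True, deadline=None)
@given(counts=st.lists(st.tuples(st.sampled_from(_RESIDUES),
                                 st.integers(0, 10)),
                       min_size=1, max_size=6, unique_by=lambda t: t[0]))
def test_emd_self_distance_zero_and_scale_invariance(counts):
    """EMD of a histogram with itself is 0, and scaling all counts by a
    constant leaves the normalized distance to any other histogram fixed."""
    h = pv.PLIFHistogram({_key("L", r, "Hydrophobic"): c
                          for r, c in counts if c > 0})
    if len(h) == 0:
        return
    assert pv.plif_emd(h, h) == pytest.approx(0.0, abs=1e-12)
    doubled = pv.PLIFHistogram({k: 2 * v for k, v in h.counts.items()})
    other = pv.PLIFHistogram({_key("L", "GLY", "HBond-donor"): 3})
    assert pv.plif_emd(doubled, other) == pytest.approx(
        pv.plif_emd(h, other), abs=1e-12)


class TestWassersteinMatching:
    def test_direct_arithmetic(self):
        scores = pv.plif_wm({"A": 0.2, "B": 0.5, "C": 0.8})
        assert scores == pytest.approx({"A": 1.0, "B": 0.5, "C": 0.0})

    def test_endpoints_in_random_collections(self, rng):
        for _ in range(20):
            emds = {f"m{i}": float(v) for i, v in
                    enumerate(rng.uniform(0, 3, size=5))}
            if len(set(emds.values())) < 2:
                continue
            scores = pv.plif_wm(emds)
            best = min(emds, key=emds.get)
            worst = max(emds, key=emds.get)
            assert scores[best] == pytest.approx(1.0)
            assert scores[worst] == pytest.approx(0.0)
            assert all(0.0 <= s <= 1.0 for s in scores.values())

    def test_degenerate_collection_scores_one_with_warning(self):
        with pytest.warns(RuntimeWarning):
            scores = pv.plif_wm({"A": 0.4, "B": 0.4})
        assert scores == {"A": 1.0, "B": 1.0}
        with pytest.warns(RuntimeWarning):
            assert pv.plif_wm({"only": 1.23}) == {"only": 1.0}
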
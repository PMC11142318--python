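import json
import warnings

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import poseval as pv
from poseval import fixtures as fx
from poseval.cli import main as cli_main


class TestEvaluatePrimary:
    def test_self_evaluation_identities(self, all_reference_complexes):
        for template, pose in all_reference_complexes.items():
            res = pv.evaluate_primary(pose, pose)
            assert res.status == "scored", (template, res.reason)
            assert res.rmsd == pytest.approx(0.0, abs=1e-9)
            assert res.crmsd == pytest.approx(0.0, abs=1e-9)
            assert res.pb_valid is True
            assert res.plif_emd == pytest.approx(0.0, abs=1e-12)

    def test_missing_primary_excluded(self, ethanol_complex):
        pose = ethanol_complex
        wrong = pv.ComplexPose(pose.protein,
                               [fx.make_toy_ligand("benzene")], ["primary"])
        res = pv.evaluate_primary(wrong, pose)
        assert res.status == "excluded"
        assert "MissingPrimary" in res.reason
        assert res.rmsd is None

    def test_translated_ligand_counts_unsuccessful(self, ethanol_complex):
        cfg = pv.EvalConfig()
        pred = fx.perturb(ethanol_complex, "translate", 3.0, seed=2)
        res = pv.evaluate_primary(pred, ethanol_complex, cfg)
        assert res.rmsd == pytest.approx(3.0, abs=1e-9)
        assert not res.success_rmsd(cfg)
        small = fx.perturb(ethanol_complex, "translate", 1.5, seed=2)
        assert pv.evaluate_primary(small, ethanol_complex,
                                   cfg).success_rmsd(cfg)

    def test_prediction_in_shifted_frame_scored_after_pocket_alignment(
            self, acetate_complex, rng):
        from conftest import random_rigid
        Q, t = random_rigid(rng)
        moved = acetate_complex.transformed(
            pv.RigidTransform.from_arrays(Q, t))
        res = pv.evaluate_primary(moved, acetate_complex)
        assert res.status == "scored"
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)


class TestEvaluateMulti:
    def test_three_fragments_all_recovered(self):
        ref = fx.make_reference_complex(5, "acetate",
                                        extra_fragments=("benzene", "ion"))
        res = pv.evaluate_multi(ref, ref)
        assert res.status == "scored"
        assert len(res.fragment_results) == 3
        for frag in res.fragment_results:
            assert frag.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.pb_valid is True
        assert res.inter_ligand_clashes == 0

    def test_one_displaced_fragment_gives_two_thirds(self):
        cfg = pv.EvalConfig()
        ref = fx.make_reference_complex(5, "acetate",
                                        extra_fragments=("benzene", "ion"))
        pred = ref.copy()
        lig = pred.ligands[1]
        pred.ligands[1] = lig.with_coords(lig.coords()
                                          + np.array([5.0, 0.0, 0.0]))
        res = pv.evaluate_multi(pred, ref, cfg)
        fails = [f for f in res.fragment_results if not f.success_rmsd(cfg)]
        assert len(fails) == 1
        assert res.fraction_correct(cfg) == pytest.approx(2.0 / 3.0)

    def test_swapped_identical_ions_score_zero(self):
        ref = fx.make_reference_complex(8, "ethanol",
                                        extra_fragments=("ion", "ion"))
        pred = ref.copy()
        a, b = pred.ligands[1], pred.ligands[2]
        pred.ligands[1] = a.with_coords(b.coords())
        pred.ligands[2] = b.with_coords(a.coords())
        res = pv.evaluate_multi(pred, ref)
        for frag in res.fragment_results:
            assert frag.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_missing_fragment_recorded_not_raised(self):
        ref = fx.make_reference_complex(5, "acetate",
                                        extra_fragments=("benzene",))
        pred = pv.ComplexPose(ref.protein, [ref.ligands[0]], ["primary"])
        res = pv.evaluate_multi(pred, ref)
        assert res.status == "scored"
        assert res.unmatched_ref == 1
        assert len(res.fragment_results) == 1


class TestAggregate:
    def _result(self, method, run, rmsd, pb=True, emd=0.1, status="scored"):
        return pv.ComplexResult(target_id="t", method=method, run=run,
                                status=status, rmsd=rmsd, crmsd=rmsd,
                                pb_valid=pb, plif_emd=emd)

    def test_denominator_counts_excluded_as_unsuccessful(self):
        cfg = pv.EvalConfig()
        results = ([self._result("m", 1, 1.0) for _ in range(4)]
                   + [self._result("m", 1, 5.0) for _ in range(5)]
                   + [pv.ComplexResult(method="m", run=1,
                                       status="excluded",
                                       reason="MissingPrimary")])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = pv.aggregate(results, cfg)[0]
        assert summary.rate_rmsd == pytest.approx(40.0)

    def test_three_runs_mean_and_sample_sd(self):
        cfg = pv.EvalConfig()
        results = []
        for run, n_good in ((1, 4), (2, 5), (3, 6)):
            results += [self._result("m", run, 1.0)
                        for _ in range(n_good)]
            results += [self._result("m", run, 9.0)
                        for _ in range(10 - n_good)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = pv.aggregate(results, cfg)[0]
        assert summary.rate_rmsd == pytest.approx(50.0)
        assert summary.rate_rmsd_sd == pytest.approx(10.0)

    def test_pb_valid_rate_never_exceeds_rmsd_rate(self, rng):
        cfg = pv.EvalConfig()
        results = [self._result("m", 1, float(r), pb=bool(p))
                   for r, p in zip(rng.uniform(0, 4, 30),
                                   rng.integers(0, 2, 30))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = pv.aggregate(results, cfg)[0]
        assert s.rate_rmsd_pb_valid <= s.rate_rmsd

    def test_wasserstein_matching_filled_across_methods(self):
        cfg = pv.EvalConfig()
        results = []
        for method, emd in (("a", 0.2), ("b", 0.5), ("c", 0.8)):
            results += [self._result(method, 1, 1.0, emd=emd)
                        for _ in range(3)]
        summaries = {s.method: s for s in pv.aggregate(results, cfg)}
        assert summaries["a"].plif_wm == pytest.approx(1.0)
        assert summaries["b"].plif_wm == pytest.approx(0.5)
        assert summaries["c"].plif_wm == pytest.approx(0.0)

    def test_single_method_degenerate_warning(self):
        cfg = pv.EvalConfig()
        results = [self._result("only", 1, 1.0)]
        with pytest.warns(RuntimeWarning):
            s = pv.aggregate(results, cfg)[0]
        assert s.plif_wm == 1.0

    def test_empty_results_raise(self):
        with pytest.raises(ValueError):
            pv.aggregate([])


class TestCli:
    def test_score_smoke(self, tmp_path, ethanol_complex):
        pv.write_protein(ethanol_complex.protein, tmp_path / "ref.pdb")
        pv.write_ligands(ethanol_complex.ligands, tmp_path / "ref.sdf")
        runner = CliRunner()
        out = runner.invoke(cli_main, [
            "score", "--pred", str(tmp_path / "ref.pdb"),
            "--pred-ligands", str(tmp_path / "ref.sdf"),
            "--ref", str(tmp_path / "ref.pdb"),
            "--ref-ligands", str(tmp_path / "ref.sdf")])
        assert out.exit_code == 0, out.output
        payload = json.loads(out.output[:out.output.rfind("}") + 1])
        assert payload["status"] == "scored"
        assert payload["rmsd"] < 1e-3

    def test_fixtures_then_batch_pipeline(self, tmp_path):
        runner = CliRunner()
        out = runner.invoke(cli_main, [
            "fixtures", "--seed", "7", "--n", "5",
            "--out-dir", str(tmp_path / "fx")])
        assert out.exit_code == 0, out.output
        out = runner.invoke(cli_main, [
            "batch", "--manifest", str(tmp_path / "fx" / "manifest.csv"),
            "--out", str(tmp_path / "results.csv")])
        assert out.exit_code == 0, out.output
        table = pd.read_csv(tmp_path / "results.csv")
        assert len(table) == 5
        assert (table.status == "scored").all()

    def test_aggregate_three_runs_arithmetic(self, tmp_path):
        rows = []
        for run, n_good in ((1, 4), (2, 5), (3, 6)):
            for i in range(10):
                rows.append({"target_id": f"t{i}", "method": "m",
                             "run": run, "status": "scored",
                             "rmsd": 1.0 if i < n_good else 9.0,
                             "crmsd": 0.5, "pb_valid": True,
                             "plif_emd": 0.1})
        path = tmp_path / "r.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        runner = CliRunner()
        out = runner.invoke(cli_main, [
            "aggregate", "--results", str(path),
            "--out", str(tmp_path / "summary.csv")])
        assert out.exit_code == 0, out.output
        summary = pd.read_csv(tmp_path / "summary.csv").iloc[0]
        assert summary.rate_rmsd == pytest.approx(50.0)
        assert summary.rate_rmsd_sd == pytest.approx(10.0)
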
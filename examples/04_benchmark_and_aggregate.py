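"""Run a full synthetic benchmark: generate, score, aggregate, rank.

Three synthetic 'methods' are planted with success fractions 0.2/0.5/0.9;
evaluation recovers those rates exactly and ranks the methods by the
Wasserstein matching score of their interaction fingerprints.
"""

import tempfile
import warnings

import poseval as pv
from poseval import fixtures as fx
from poseval.cli import _load_pose

profiles = [
    {"name": "weak", "success_fraction": 0.2, "noise": 1.2},
    {"name": "fair", "success_fraction": 0.5, "noise": 0.5},
    {"name": "strong", "success_fraction": 0.9, "noise": 0.1},
]

cfg = pv.EvalConfig()
with tempfile.TemporaryDirectory() as tmp:
    manifest = fx.make_benchmark(seed=11, n_targets=10,
                                 method_profiles=profiles, out_dir=tmp)
    results = []
    for _, row in manifest.iterrows():
        pred = _load_pose(row.pred_protein, row.pred_ligands,
                          row.primary_ligand_code)
        ref = _load_pose(row.ref_protein, row.ref_ligands,
                         row.primary_ligand_code)
        results.append(pv.evaluate_primary(
            pred, ref, cfg, target_id=row.target_id,
            method=row.method, run=row.run))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    summaries = pv.aggregate(results, cfg)

print(f"{'method':8s} {'RMSD<=2Å %':>10s} {'cRMSD<=1Å %':>11s} "
      f"{'mean EMD':>9s} {'PLIF-WM':>8s}")
for s in sorted(summaries, key=lambda s: -s.rate_rmsd):
    emd = "n/a" if s.mean_plif_emd is None else f"{s.mean_plif_emd:.3f}"
    wm = "n/a" if s.plif_wm is None else f"{s.plif_wm:.2f}"
    print(f"{s.method:8s} {s.rate_rmsd:10.1f} {s.rate_centroid:11.1f} "
          f"{emd:>9s} {wm:>8s}")
# Success rates equal the planted fractions; PLIF-WM = 1 marks the method
# whose fingerprint histograms sit closest to native, 0 the farthest.
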
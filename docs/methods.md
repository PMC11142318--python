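# Methods

This note documents what `poseval` computes, the choices behind the
defaults, and what the synthetic fixtures do and do not demonstrate.

## Scoring frame: pocket-focused apo→holo alignment

Docking and co-folding methods emit complexes in arbitrary frames, often
built on predicted (apo) protein structures. Before any ligand metric is
computed, the predicted protein is rigidly superposed onto the reference
using a Kabsch fit restricted to the **Cα atoms of the binding pocket** —
all residues with at least one heavy atom within `pocket_cutoff` (default
10 Å) of any reference ligand heavy atom, cofactors included. The
resulting transform is applied to the whole prediction, ligands included,
and ligand metrics are computed in that frame with **no re-superposition
of the ligand itself**: re-fitting the ligand would erase exactly the
placement error the benchmark is supposed to measure.

Cα-only fitting makes the alignment robust to side-chain repacking in
predicted structures (glycine needs no special case since Cα always
exists). An optional iterative trimming mode (drop the worst 10 % of
pairs, ≤ 5 cycles) mimics the outlier rejection of interactive alignment
tools; it is off by default because plain pocket-Cα Kabsch is fully
deterministic and reproducible. Both pocket-heavy-atom and Cα fitting
interpretations are defensible; Cα is the default and the atoms used are
recorded in the transform's provenance.

Residue correspondence between predicted and reference chains comes from
a global sequence alignment with affine gap penalties (match +1, mismatch
−1, open −10, extend −0.5); only aligned, *identical* residues contribute
Cα pairs. Chain mapping searches sequence-compatible bijections (pairwise
identity ≥ 95 %, configurable) for the one minimizing the pocket fit
RMSD — exhaustively for up to 6 interchangeable chains per sequence class,
greedily in file order beyond that.

## Ligand identity and symmetry

Ligands are matched to references by a canonical graph key: the canonical
SMILES of the element/bond/charge graph with stereochemistry erased. A
prediction that inverts a stereocentre must still be matched and scored —
stereo errors are a *validity* finding, not an identity mismatch. With
several graph-identical candidates, the one nearest the reference centroid
is taken. A prediction containing no graph match for the reference primary
ligand cannot be scored and is excluded (counted as unsuccessful in
rates).

Heavy-atom RMSD minimizes over the graph automorphisms enumerated by
substructure matching, capped at 10⁴ maps; past the cap the result is the
minimum over the enumerated element/bond-environment-constrained maps and
a warning is raised. `cRMSD` follows the field's naming convention: it is
a centroid *distance*, not a per-atom deviation, and deliberately ignores
graph identity (it asks only "is the ligand in the right pocket?").

Multi-ligand complexes are scored after an optimal fragment assignment:
within each graph-identity class, the Hungarian algorithm minimizes summed
symmetry-aware RMSD. Surplus fragments on either side are reported, and
unmatched reference fragments count as unsuccessful.

## lDDT and lDDT-PLI

lDDT uses the inclusion radius R₀ = 15 Å, thresholds {0.5, 1, 2, 4} Å,
strict `<` comparison, and same-residue exclusion. Atoms whose neighbour
set is empty are skipped from the outer average; a structure with no
scoring atom at all raises an undefined-score error rather than reporting
a fake 0 or 1.

For the protein–ligand interface variant the generic 15 Å radius is far
too permissive; the toolkit defaults to a 6 Å contact radius (the common
interface-scoring choice) and exposes it as `LddtParams.pli_radius`.
Contacts are defined in the *reference*; the score asks how well the
prediction reproduces those reference cross distances. Ligand
automorphisms are resolved by taking, per fragment, the atom mapping that
maximizes the score — consistent with symmetry-corrected RMSD. Restricting
the statistic to protein–ligand cross pairs is our reading of
interface-specific lDDT; the per-fragment mapping and the contact radius
are both configurable.

## Interaction fingerprints

A fingerprint is the tuple ⟨ligand code, residue type, interaction type⟩.
Detection is purely geometric, with every threshold held in
`GeometricCriteria`:

| interaction | criterion (defaults) |
| --- | --- |
| hydrogen bond | donor–acceptor heavy distance ≤ 3.5 Å, D–H···A ≥ 130° with an idealized H |
| hydrophobic | apolar C/S ··· apolar C/S ≤ 4.5 Å |
| ionic (salt bridge) | opposite formal-charge group centres ≤ 4.5 Å |
| π-stacking | ring centroids ≤ 5.5 Å, plane angle ≤ 35° (face) or 50–90° (edge) |
| cation–π / π–cation | charge to ring centroid ≤ 4.5 Å |
| halogen bond | X···acceptor ≤ 3.5 Å, C–X···A ≥ 130° (X = Cl, Br, I) |
| metal coordination | metal ··· N/O/S ≤ 2.8 Å |

Hydrogen positions are idealized from heavy-atom frames (anti to the mean
bond vector of the donor's heavy neighbours), since crystal structures and
predictions routinely lack hydrogens; donors with no heavy neighbour
(isolated ions) pass on distance alone. Protein-side features come from
atom-name tables over the 20 standard residues; ligand-side features from
the RDKit graph. Each residue *instance* contributes at most one count per
interaction type per ligand, so histograms count interacting residues, not
atom pairs. A generic van-der-Waals-contact type exists but is off by
default — it swamps the histograms with uninformative counts.

**PLIF-EMD.** The two histograms' bins are unified (union of keys), keys
are ordered canonically — lexicographic in (ligand code, residue name,
interaction) — and embedded at integer positions 0..m−1. Counts are
normalized to probability mass (total-count differences are therefore not
penalized; a raw-count mode exists behind a flag) and compared by the 1-D
Wasserstein distance via its CDF characterization (SciPy's
implementation). Because a 1-D embedding of categorical bins makes the
distance depend on bin order, the canonical order is fixed and documented:
results are reproducible, and the distance remains a true metric on the
embedded distributions (verified by property tests including the triangle
inequality and a linear-program optimal-transport oracle).

An empty histogram (a pose with zero detected interactions) has no
distribution to compare; the toolkit raises and the complex is dropped
from mean PLIF-EMD (a configurable maximum-distance fallback exists, off
by default). **PLIF-WM** is the min–max rescaling of mean PLIF-EMD over a
method collection: best 1, worst 0; degenerate collections (all equal, or
a single method) score 1.0 for every member with an explicit warning.
Normalization is applied to per-method dataset means by default; a
per-complex option exists.

## Pose validity

The verdict conjoins: graph sanitizability; bond lengths within
[0.75, 1.25] × reference (covalent-radius sums scaled by bond order:
single 1.0, aromatic 0.93, double 0.87, triple 0.78); bond angles within
[0.75, 1.25] × the ideal hybridization angle; non-bonded intramolecular
pairs (1-2 and 1-3 excluded) ≥ 0.8 × vdW sum; aromatic rings and
double-bond frames flat to ≤ 0.25 Å; and no protein–ligand or
ligand–ligand pair < 0.75 × vdW sum. The vdW table is Bondi's, the
covalent radii Cordero's, both frozen in `_chem.py`. Stereochemistry
preservation is checked against the reference when one is supplied, via
3D-assigned stereo descriptors.

The force-field energy-ratio inspection that full validity suites run is
deliberately not part of the verdict: it would make the result depend on a
force field and its parameterization. The flag is recorded as "not
evaluated" so downstream consumers can see it was never computed. Clash
*counts* (protein↔ligand and ligand↔ligand separately) are reported
alongside the boolean verdict for multi-ligand analyses.

## Aggregation

Success rates — RMSD ≤ 2 Å, cRMSD ≤ 1 Å, and RMSD ≤ 2 Å ∧ PB-Valid — use
the full per-run target count as denominator: a prediction that could not
be scored is unsuccessful, not invisible. Excluded targets are dropped
only from mean-metric computations (mean PLIF-EMD, lDDT-PLI
distributions). Rates from repeated runs are averaged per run first and
reported as mean ± sample standard deviation (ddof = 1; a single run
reports sd 0). This keeps denominators fixed while still reporting
failures honestly; both conventions appear in the literature, and this one
is stated prominently because it changes numbers.

## Synthetic fixtures

The generator builds toy pockets: idealized heavy-atom residue templates
(GLY, ALA, SER, ASP, PHE, ARG, HIS — enough chemistry to plant every
interaction type) placed on a Fibonacci sphere of configurable radius
(default 12 Å, 8 residues) with side chains pointing inward, and idealized
small-molecule conformers (benzene, ethanol, acetate, methylammonium,
imidazole, a Mg²⁺ ion) built from literature bond lengths and angles.
Each reference complex pulls a chemistry-matched residue to ideal
interaction geometry from the ligand's anchor atom (3.0 Å hydrogen bond,
3.5 Å salt bridge, 4.0 Å hydrophobic contact, 2.6 Å metal coordination)
plus secondary polar and hydrophobic shell contacts, so every reference
passes validity, has a non-empty 10 Å pocket, and carries several
detectable fingerprints that degrade gradually under pose error.

Perturbation operators have closed-form metric effects: translation by d
gives RMSD = cRMSD = d exactly; rotation about the ligand centroid leaves
the centroid fixed; an automorphism relabelling is invisible to
symmetry-aware RMSD; ejection empties the fingerprint histogram. The
benchmark generator plants exact success counts — exactly
round(f × n_targets) targets per method receive sub-2 Å poses (translation
0.2 + 0.9·noise, capped at 1.9 Å), the rest > 4 Å — so recovered rates
have known true values, and lower-noise profiles keep more native contacts
and thus earn lower mean PLIF-EMD. All randomness flows from one seed
through named independent streams; regenerated files are byte-identical.

**What the fixtures do not show.** Toy pockets are not folded proteins: no
peptide bonds, no secondary structure, no rotamer variability, no
crystallographic artifacts (altloc disorder beyond parser tests, missing
atoms, non-standard residues). Passing tests demonstrate that the metrics
compute their definitions correctly and respond to controlled
perturbations as the closed forms require — not that any particular
docking method performs well, nor that the detection criteria reproduce
any specific fingerprinting tool on real crystal structures. Problem sizes
in the tests and the acceptance script (8-residue pockets, ≤ 20-target
benchmarks, ≤ 200-atom lDDT fixtures, 100–200 random oracle comparisons)
were chosen as the smallest sizes at which every code path — multi-chain
mapping, fragment assignment, automorphism handling, empty-histogram
handling — is exercised.

## Numerical choices and degenerate inputs

- Kabsch refuses < 3 points or rank-deficient (collinear) configurations;
  the proper-rotation constraint (det R = +1) is always enforced.
- Altloc resolution: highest occupancy, ties broken by altloc label —
  deterministic parsing over any file ordering.
- lDDT uses strict `<` at every threshold.
- Ties in fragment assignment resolve by the Hungarian algorithm's
  deterministic solution of the cost matrix.
- Empty pockets are legal (flagged, not fatal); an empty pocket simply
  yields no alignment constraint and chain mapping falls back to sequence
  compatibility alone.
- Warnings (`RuntimeWarning`) mark soft degeneracies: automorphism cap
  reached, degenerate PLIF-WM collections.

## Known limitations

- Covalent ligands, nucleic-acid chains, and water-mediated interactions
  are out of scope.
- Protein-side fingerprint features rely on standard residue and atom
  names; heavily non-standard nomenclature degrades detection to
  element-based rules only.
- The validity check set corresponds to the geometric ("dock-style")
  subset of common pose-sanity suites; energy-based checks are not
  implemented.
- lDDT-PLI's contact radius and cross-pair restriction are an
  interpretation of interface-specific lDDT; both are configurable and
  documented above.
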
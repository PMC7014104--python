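# Methods

This note records the models, parameter choices and numerical conventions
behind each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Scope

The package covers the *analysis* layer of an allosteric-site
characterization campaign. The engines that produce the raw data — the MD
package for pure-water/cosolvent/restrained simulations, the hydration-site
thermodynamics estimator, the docking program and decoy generator, and the
MSA program — are upstream: their outputs (PDB structures and multi-model
snapshot files, aligned FASTA, score tables, per-site ΔH/−TΔS tables) are
consumed, never recomputed. Protein preparation, loop modelling, crystal-mate
detection and halogen-bond geometry analysis are likewise out of scope.

## Structure and map I/O

PDB is the interchange format throughout, including multi-model PDB as the
lowest-common-denominator trajectory container (binary trajectory formats are
deliberately out of the core). Parsing is delegated to gemmi with a
pre-validation pass that reports malformed ATOM/HETATM records by line
number. Conventions:

* **Alternate locations** — the highest-occupancy conformer is kept; ties
  break to the alphabetically first alt-loc id. Crystallographic practice
  varies and the choice is rarely material, but it must be deterministic.
* **Residue identity** — author numbering plus insertion code
  (`chain:resnum[icode]`), since site residues are conventionally cited in
  author numbering (e.g. K720 in the AR).
* **Waters** — HETATM residues named HOH/WAT, represented by the oxygen
  atom only (hydrogens are usually absent in crystal structures).
* **Element inference** — when the element column is blank, the element is
  inferred from the atom name (first alphabetic character, with a short
  two-letter list for hetero atoms; CA/NA are read as carbon/nitrogen since
  ions normally carry explicit element fields).
* **Maps** — OpenDX and CNS scalar-map writers/readers round-trip origin,
  spacing and dims exactly and values to the format's precision (CNS's fixed
  `E12.5` fields carry 6 significant digits; its indexing also requires the
  origin to lie on the grid lattice, which the writer enforces). Grids store
  dimensionless multiples of bulk density.
* No periodic re-imaging is applied on input; trajectories are assumed
  wrapped.

## Conservation scoring

Site residues are selected as the ligand contact shell: any protein residue
with a heavy atom within *r* of any ligand heavy atom (default *r* = 5 Å).
This is the standard reading of a "5 Å zone"; a single sphere about the
ligand centroid would over-select for elongated ligands. Hydrogens are
ignored in distance tests.

Each site residue is assigned its alignment column through the reference
receptor's aligned row; the pairwise score per column is 1.0 for identity,
0.5 for a same-group pair, 0 otherwise, and **any gap scores 0**. The
percentage divides by the site residue count — not the gap-free pair count —
so the value is a percentage of the maximally achievable score and gapped
columns dilute it. The diagonal of the receptor matrix is fixed at 100 by
definition.

The default residue grouping is hydrophobic {A,V,L,I,M}, aromatic {F,W,Y},
polar {S,T,N,Q,C,G,P}, positive {K,R,H}, negative {D,E}. Published analyses
differ in where these lines are drawn, so the scheme is fully configurable
(`ResidueGroupScheme.from_config`); exact reproduction of a particular
published matrix requires that study's grouping table.

## Cosolvent density and hotspots

The density grid is a per-frame average of probe-position counts per voxel,
normalized by voxel volume times bulk number density, so 1.0 means
bulk-like. By default every heavy atom of a probe molecule contributes a
position (matching atom-density maps viewed at an isovalue); a
center-of-geometry mode is available. Bulk density defaults to probe count /
box volume averaged over frames. The mass-conservation identity
`Σ ρ_v · V_voxel · ρ_bulk = ⟨in-grid count⟩` holds to floating point and is
asserted in tests.

Hotspots are face-connected (6-neighbor) components of voxels at or above
the isovalue (default 12× bulk), with value-weighted centroids, sorted by
peak value (ties by centroid lexicographic order). The library default grid
spacing is 0.5 Å. For the sparse synthetic benchmark (200 probes in a 40 Å
box, 500 frames) the analyses use 1.0 Å voxels and a 4-voxel minimum
component size: at that sampling a voxel collects ~1.6 counts on average, so
1 Å voxels keep per-voxel Poisson noise far below the isovalue
(P(ρ_v ≥ 12) ~ 10⁻¹⁵ under bulk) while single-voxel shot-noise excursions
near a blob's rim are suppressed by the 4 Å³ volume floor. Map overlap is
reported as the Jaccard index of supra-isovalue voxel sets on congruent
grids plus nearest-centroid pairings.

## Hydration sites

DBSCAN with ε = 0.9 Å and min_pts = 2 clusters water-oxygen positions; the
neighbor count includes the query point, so min_pts = 2 means "at least one
other water within ε". Border points join the first core cluster that
reaches them in input order — the classic DBSCAN order dependence — and
inputs are processed in deterministic order. Cluster centroids are
unweighted means; occupancy counts *distinct* sources (frames or
structures), never raw members, so repeated waters from one structure cannot
inflate conservation.

The minimal-occupancy criterion is a step schedule on source count,
defaulting to ≥ 0.5 below 10 sources, ≥ 0.4 for 10–29, ≥ 0.3 for ≥ 30:
small crystal ensembles demand strong conservation while large ones
tolerate lower occupancy. The schedule is configurable.

MD and crystal predictions are merged by greedy global matching: repeatedly
pair the closest unmatched (MD, crystal) couple within 1.4 Å, each site used
once; the consensus centroid is the midpoint, occupancy the mean, and
ΔH/−TΔS carried from the MD site. Greedy matching was chosen over optimal
assignment for reproducibility; at hydration-site densities (inter-site
spacing ≫ threshold) the two rarely differ, and the tests compare against a
brute-force re-implementation of the same contract. Desolvation
thermodynamics are consumed from external CSV tables and attached to the
nearest site within 1 Å; ΔH strictly below −1.0 kcal/mol sets the
"favorable" flag (sites without ΔH stay unflagged).

## Conformation

Kabsch superposition is implemented via SVD of the weighted covariance with
the determinant sign correction enforcing a proper rotation; point sets with
covariance rank < 2 (collinear) are rejected as degenerate. Representative
structures are ensemble medoids — the structure minimizing summed pairwise
RMSD, which is how a mutual-similarity (3D-jury-style) ranking reduces under
an RMSD similarity; the original contact-overlap variant of that score is
deliberately not reproduced. Ties break to the lowest index.

Per-residue heavy-atom RMSD between representatives is measured after one
global superposition on the shared protein backbone (N, CA, C, O) with **no
per-residue refit**, so the value captures displacement plus rotamer change
— the quantity of interest for site adaptation. Residues missing from
either structure (truncated termini) are flagged with NaN rather than
reported as 0. Backbone RMSD series superpose each frame to the reference
independently.

## Enrichment

ROC AUC is computed from the rank-sum statistic on pooled scores
(lower = better; ties half credit), which is exactly
P(active outranks decoy); tests cross-check it against an independent
trapezoid-ROC implementation on thousands of tied instances. The score
shift is `mean(others) − mean(actives)` in kcal/mol, positive when actives
score better. Pose RMSD is in-place (both poses share the receptor frame,
so no re-superposition), with the minimum taken over user-supplied
symmetry-equivalent atom mappings; automated graph-automorphism detection
is intentionally omitted — flip-symmetric ligands are known and few, and an
explicit mapping is auditable. Distribution summaries are bin-free (mean,
median, IQR); the histogram-overlap coefficient uses a shared 0.5 kcal/mol
binning.

## Synthetic generators

The generators define the conditions under which the pipeline is validated:

* **Probe trajectories** — single-site probe pseudo-atoms: a uniform
  background at the count implied by the 5% v/v default loading (nominal
  per-molecule volumes: isopropanol 162.6 Å³, acetonitrile 86.8 Å³,
  pyrimidine 130.9 Å³; the count satisfies the volume fraction to ± 1
  molecule) plus Gaussian blobs whose point count per frame is the rounded
  expectation `(e−1)·ρ_bulk·(2πσ²)^{3/2}`, so the central density is the
  planted enrichment. Counts are fixed per frame — rather than Poisson —
  because a trajectory requires an identical atom roster across frames; the
  planted expectation is unchanged. The density benchmark uses 500 frames of
  200 probes in a 40 Å box, a planted blob with σ = 2 Å at 20× bulk.
* **Water observations** — each planted site contributes one point jittered
  by σ = 0.25 Å to each source with probability equal to the planted
  occupancy (benchmark: 0.8 over 20 sources), plus 2 uniform background
  waters per source to exercise noise rejection.
* **Alignments** — per non-reference receptor, site columns are identical /
  same-group / other-group versus the reference at configured fractions,
  either sampled per column or realized as exact counts; the expected
  conservation versus the reference is `100·(f_id + 0.5·f_gr)` (75% for the
  ½/½ benchmark over 20 columns). Pairs not involving the reference are not
  controlled.
* **Score tables** — Gaussian classes; the analytic active-vs-decoy AUC is
  `Φ((μ_d − μ_a)/√(σ_a² + σ_d²))`. The benchmark plants a 1.0 kcal/mol
  shift with σ = 1.0 (mirroring the observed improvement of a
  confirmed-active series), and uses σ = 0.5, n = 2000 per class for the
  analytic-recovery check.
* **Toy structures** — an ideal-helix-like 6–12-residue peptide with
  backbone + CB/CG atoms, and families of jittered (optionally rigidly
  moved) copies for superposition/medoid tests.

All generators are deterministic given their seed and return machine-readable
ground truth alongside the data. What they do **not** emulate: solvent
structure and excluded volume (probes can overlap a protein), correlated
frames, anisotropic B-factor-dependent water jitter, realistic docking-score
tails. Passing tests therefore demonstrate the correctness of the analysis
operations and their statistical behavior at planted effect sizes — not the
accuracy of any MD or docking engine.

## Simulation-plan accounting

Plan totals are `Σ replicates · (equilibration + production)`. The hydration
protocol (8 receptors × 2 sites × (2 + 20) ns) totals 352 ns; pure water is
8 × 3 × 40 ns = 960 ns; the cosolvent campaign is booked at its cumulative
1.2 μs per receptor because that figure is not derivable from the nominal
per-run parameters (3 probes × 10 runs × 5 ns) — run-count-based plans are
available separately with all parameters free. The full plan totals
10 912 ns, i.e. over 10 μs.

## Numerical conventions and degenerate inputs

Coordinates and thresholds are in Å, energies in kcal/mol, densities in
multiples of bulk. Empty point sets cluster to nothing; empty score groups,
empty plans, zero-atom structures and zero-volume boxes raise typed errors.
Sorting tie-breaks (hotspots by centroid, medoid by index, matching by index
pairs) are deterministic. Problem sizes in tests and the acceptance script
(500-frame densities, 60-point clustering oracles, 100-set medoid checks,
1000-instance AUC checks, n = 2000 score classes) were chosen so each
statistical assertion sits several standard errors from its threshold.

## Known limitations

* The conservation module consumes a precomputed MSA; structure-based
  alignment and MSA computation are out of scope.
* CNS maps cannot represent off-lattice origins (format limitation); OpenDX
  round-trips arbitrary origins.
* Greedy consensus matching is order-robust but not globally optimal in
  adversarial geometries; an assignment-based matcher would be a drop-in
  extension.
* Symmetry-aware pose RMSD relies on user-supplied atom mappings.
* The per-residue RMSD uses whole-shared-backbone superposition; a
  site-only superposition would emphasize local adaptation differently.
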
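# allosite

Comparative analysis of the two superficial allosteric sites on nuclear
receptor ligand-binding domains — the **AF-2** coactivator groove and the
adjacent **BF-3** surface — for structure-based drug design. Marketed drugs
against the orthosteric pocket of hormonal nuclear receptors (AR, ERα/β, GR,
MR, PR, TRα/β) suffer from resistance and poor selectivity; allosteric
inhibitors are an alternative, but the sites are conserved across the
receptor panel, so selectivity has to be assessed quantitatively. This
package implements the downstream analyses of such an assessment as a tested,
reusable library:

* **Site conservation** — site residues are the contact shell of a
  cocrystallized ligand (any heavy atom within *r* = 5 Å of any ligand heavy
  atom); across a multiple sequence alignment each residue pair scores 1.0
  (identical), 0.5 (same physicochemical group) or 0, and the pairwise
  conservation is `100 · Σ s_i / N_site` — a percentage of the maximally
  achievable score, yielding a symmetric receptor × receptor matrix.
* **Cosolvent hotspot mapping** — probe-molecule trajectory frames (e.g.
  isopropanol, acetonitrile, pyrimidine at 5% v/v) are histogrammed into a
  grid of bulk-normalized density `ρ(v) = ⟨n_v⟩ / (V_voxel · ρ_bulk)`;
  interaction hotspots are the face-connected components with `ρ ≥ 12`
  (twelve times bulk), exportable as OpenDX or CNS maps.
* **Hydration sites** — water-oxygen positions from MD snapshots and from
  pooled superimposed crystal structures are clustered with DBSCAN
  (ε = 0.9 Å, min_pts = 2); cluster occupancy is the fraction of sources
  represented; sites passing an occupancy schedule are conserved, and the MD
  and crystal predictions are merged into a consensus by greedy nearest-pair
  matching at 1.4 Å. Desolvation enthalpies are consumed from external
  tables; ΔH < −1.0 kcal/mol marks favorably displaceable waters.
* **Conformational adaptation** — Kabsch superposition, medoid
  (mutual-similarity) representative selection from an ensemble, per-residue
  heavy-atom RMSD between cosolvent and pure-water representatives, and
  backbone RMSD series.
* **Docking enrichment** — score distributions of confirmed actives vs the
  compound library, ROC AUC against decoys via the rank-sum statistic
  (`AUC = P(score_active < score_decoy)`, ties ½), and in-place redocking
  pose RMSD with optional symmetry-equivalent atom mappings.
* **Synthetic data** — seeded generators for every input class (probe
  trajectories with planted enrichment blobs, water sets with planted
  conserved sites, alignments with planted identity/group fractions,
  Gaussian score tables with analytic AUC) plus simulation-plan accounting.

## Worked example

```bash
python examples/probe_hotspots.py
```

```
grid mean density  : 1.035  (1.0 = bulk)
hotspots at iso 12 : 1
  centroid [20.29 19.84 20.12]  volume 31 A^3  peak 23.0x bulk  (centroid error 0.35 A)
```

A 500-frame trajectory of 200 probe pseudo-atoms in a 40 Å box, with one
Gaussian blob planted at (20, 20, 20) at 20× bulk enrichment, normalizes to
≈ 1.0 everywhere except a single recovered hotspot whose centroid lands
within half a voxel of the planted center. The other scripts in `examples/`
cover the conservation matrix (75% for half-identical/half-same-group
sites), hydration consensus (three planted sites recovered within ~0.2 Å
through both the MD and crystal routes), per-residue adaptation (a planted
60° rotamer swing shows up as a 0.64 Å heavy-atom RMSD at residue A:3), and
docking enrichment (a planted 1.0 kcal/mol shift gives AUC ≈ 0.76 against
decoys, matching the analytic Φ(Δ/√(σ₁²+σ₂²))).

A thin CLI mirrors the library (`allosite conserve / density / hydration /
conform / enrich / simulate`); run `allosite --help`.

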
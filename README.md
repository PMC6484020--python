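# allostat

Analysis toolkit for studying how designed peptidomimetic ligands
re-activate a loss-of-function mutant of the PRC2 histone
methyltransferase complex (the EED-I363M reader-subunit mutation). It
covers both halves of such a study:

* **Trajectory mechanism analysis** — given a multi-frame structural
  ensemble of a reader/enzyme/ligand complex: remove frames with an
  unbound ligand (ligand RMSD > 0.8 nm from its reference pose),
  compute inter-chain contact maps (frame-averaged minimum
  residue–residue heavy-atom distances), monitor folding of the
  stimulation-responsive motif (SRM) helix of EZH2 by region RMSD
  against an active-state reference, extract named interaction
  distances (d1 salt bridge to D362, d2 cation-π to W364, d3
  sulfur–pyrrolidine contact to M363), and summarize them by
  occupancy, median [MAD], Pearson correlation and 2D Gaussian-kernel
  density estimates.
* **Biochemical quantification** — from plate-reader tables: CPM →
  percent-activity normalization (no-compound control = 100%,
  no-enzyme background = 0%), turnover numbers k<sub>cat</sub> from
  scintillation-proximity time courses, activation/inhibition EC₅₀
  from four-parameter logistic fits, fold changes with error
  propagation, and tracer K<sub>d</sub> from fluorescence-polarization
  titrations using the exact ligand-depletion (quadratic) binding
  model.

Because multi-microsecond MD trajectories and raw plate data are not
shippable, the package includes a first-class synthetic-data module
that generates every input with known ground truth: a toy
reader/enzyme/ligand complex, state-switching trajectories whose
interaction distances follow a prescribed correlated lognormal, and
assay tables generated at stated truths. Every analysis operation is
validated against these ground truths and against independent
brute-force oracles.

## The models in brief

* **Unbound-frame filter.** Each frame is rigidly superposed
  (Kabsch) on the receptor backbone; a frame is removed iff the
  ligand heavy-atom RMSD from the reference pose is strictly greater
  than the 0.8 nm threshold.
* **Contact map.** Entry (i, j) = mean over kept frames of
  min<sub>a∈i, b∈j</sub> ‖x<sub>a</sub> − x<sub>b</sub>‖ over heavy
  atoms — the average minimum residue–residue distance.
* **Occupancy.** Fraction of frames with a distance ≤ cutoff
  (defaults: salt bridge 0.4 nm; cation-π 0.6 nm, centroid–centroid).
* **4PL dose response.** percent = bottom + (top − bottom) / (1 +
  (EC₅₀/c)<sup>h</sup>), fitted jointly over replicates; activation vs
  inhibition follows the sign of top − bottom.
* **k<sub>cat</sub>.** Least-squares slope of product (nM) vs time (h)
  divided by enzyme concentration (nM); single-timepoint endpoint data
  are fitted through the origin.
* **FP binding.** FP = FP<sub>min</sub> + (FP<sub>max</sub> −
  FP<sub>min</sub>)·f<sub>b</sub>, with bound fraction f<sub>b</sub>
  from the exact quadratic solution of P + L ⇌ PL at total tracer
  L₀ — required because L₀ = 40 nM is comparable to K<sub>d</sub>.

## Worked example

```python
import allostat as al

reference = al.build_reference_complex()
scenario = al.mutant_like(n_frames=2000, seed=42)
ensemble = al.simulate_trajectory(scenario, reference)

filtered, mask = al.filter_unbound_frames(ensemble, reference, threshold_nm=0.8)
print(f"kept {mask.n_kept}/{ensemble.n_frames} bound frames")

helix = al.region_rmsd(filtered, reference, fit_role="enzyme", measure_role="srm_helix")
print(f"SRM-helix RMSD median {helix.median:.3f} nm (MAD {helix.mad:.3f})")

groups = al.default_interaction_groups(reference)
d1 = al.distance_series(filtered, *groups["d1"][:2], mode=groups["d1"][2], label="d1")
d3 = al.distance_series(filtered, *groups["d3"][:2], mode=groups["d3"][2], label="d3")
print(f"d1 median {al.summarize(d1)['median']:.2f} nm, "
      f"salt-bridge occupancy {al.occupancy(d1, 0.4):.2f}")
print(f"r(d1, d3) = {al.pearson_r(d1, d3):.2f}")

sc = al.AssayScenario(ec50_true=2.3, noise_cv=0.03, seed=42)
norm, _ = al.normalize_activity(al.simulate_assay(sc, "dose_response"))
s = norm[norm.role == "sample"]
fit = al.fit_dose_response(s.compound_conc_uM.to_numpy(), s.percent_activity.to_numpy())
print(f"EC50 = {fit.ec50:.2f} ± {fit.se_ec50:.2f} uM ({fit.direction})")
```

prints

```
kept 1613/2000 bound frames
SRM-helix RMSD median 0.009 nm (MAD 0.001)
d1 median 0.30 nm, salt-bridge occupancy 0.95
r(d1, d3) = 0.73
EC50 = 2.07 ± 0.18 uM (activation)
```

Reading: ~80% of frames carry a bound ligand (the scenario's bound
fraction), the helix stays folded (RMSD ≪ the 0.35 nm unfolding
scale), the engineered salt bridge is persistent (occupancy 0.95 at
0.4 nm), the d1–d3 coupling generated at ρ = 0.75 is recovered as
r = 0.73, and the activation EC₅₀ generated at 2.3 µM is fitted to
2.1 ± 0.2 µM from one noisy triplicate plate.

## Command line

```bash
allostat simulate --preset mutant_like --n-frames 500 --seed 0 --out inputs/
allostat mechanism  --config run.yaml   # filter → contacts → RMSD → d1/d2/d3 → KDE
allostat enzymology --config run.yaml   # normalize → kcat → fold change → EC50 → Kd
```

A single YAML config drives both analysis commands (see
`allostat.pipeline`); outputs are plain CSV/TSV/JSON plus PNG figures,
and every output carries the config hash. Exit code 2 signals a
validation error.

## File formats

* **PDB** — ATOM/HETATM/MODEL/ENDMDL subset, fixed-width wwPDB v3.3;
  coordinates are converted Å ↔ nm (the package works in nm
  internally). First altloc kept; insertion codes rejected.
* **XYZ trajectory dialect** — per frame: line 1 = atom count, line 2 =
  `t=<time in ns>`, then one `element x y z` line per atom with
  coordinates in nm. Since it stores only elements, pass a matching
  PDB topology to `read_ensemble` to retain annotations.
* **Assay CSV** — tidy, one row per well: `dataset, role, cpm,
  compound_conc_uM, enzyme_conc_nM, substrate, time_h, replicate`;
  FP titrations use `dataset, protein_conc_nM, polarization,
  tracer_conc_nM, replicate`.
* **Region annotations** — YAML/JSON mapping role →
  `{chain, start, end}` (1-based, inclusive).

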
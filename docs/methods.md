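# Methods

This note documents the models implemented in `allostat`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical conventions. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Scope and units

The package analyses a three-component complex — a methyl-lysine
reader protein (EED-like, chain `E`), a methyltransferase (EZH2-like,
chain `Z`) whose catalytically decisive elements are a flexible loop
(residues 136–142, carrying two acidic side chains) and the adjacent
stimulation-responsive-motif (SRM) helix (residues 143–153), and a
cationic peptidomimetic ligand (chain `L`). All internal lengths are
nanometres; PDB I/O converts from/to Ångström. Residue ranges are
1-based and inclusive on both ends, matching crystallographic
numbering. Hydrogens are optional throughout: every geometric default
operates on heavy atoms, which makes the analyses insensitive to
protonation conventions.

## Trajectory mechanism analysis

**Superposition and RMSD.** Rigid fits use the Kabsch SVD solution
constrained to proper rotations (det = +1); fewer than three atom
pairs, or collinear geometry (second singular value ≤ 1e-12 of scale),
raise an error rather than returning an ill-defined rotation. Region
RMSD superposes each frame on the fit region (backbone N/CA/C/O by
default) and measures the target region without refitting. The SRM
helix RMSD defaults to CA atoms — the conventional choice for
fold/unfold monitoring, and the one least sensitive to side-chain
noise — and is configurable to heavy atoms.

**Unbound-frame filter.** A frame is discarded iff the ligand
heavy-atom RMSD from its reference pose, after superposing on the
combined enzyme + reader backbone, is *strictly* greater than the
threshold (default 0.8 nm); a frame at exactly the threshold is kept.
The receptor-backbone fit frame is a design choice — the filter should
flag ligand excursions, not global tumbling — and the strict inequality
follows the usual reading of a "> threshold" removal rule. Filtering
is idempotent, and if every frame is removed the pipeline aborts with
a validation error rather than silently analysing nothing.

**Contact maps.** Entry (i, j) is the arithmetic mean over kept frames
of the per-frame minimum heavy-atom distance between residues i and j
("average minimum" — the mean of minima, not the minimum of means).
When a ligand is annotated the map is computed on bound frames only by
default, since unbound excursions would swamp interface statistics;
averaging over all frames is available by skipping the filter.
Distances are computed without periodic-boundary imaging: inputs are
assumed whole and imaged, as produced by standard trajectory
post-processing. This is a documented limitation, not a target of this
package.

**Interaction distances.** Three named distances characterize the
ligand's pyrrolidine headgroup against the reader mutation site:

| label | contact | operationalization | occupancy cutoff |
|---|---|---|---|
| d1 | salt bridge to D362 | min over cation N / carboxylate O pairs | 0.4 nm |
| d2 | cation-π to W364 | pyrrolidine centroid ↔ aromatic-ring centroid | 0.6 nm |
| d3 | sulfur contact to M363 | SD atom ↔ pyrrolidine centroid | 0.6 nm |

The cutoffs are the common structural-biology operational values for
these interaction classes; they are exposed in the run config, since
no universal convention exists. Occupancy is the fraction of frames
with distance ≤ cutoff. Distribution summaries are the sample median
and the *unscaled* median absolute deviation (no 1.4826
normal-consistency factor): the MAD is reported in brackets next to
the median as a robust spread number, not as a σ estimate.

**Correlation and 2D densities.** Correlation between distance series
is Pearson's product–moment r (Spearman available as an option).
Two-dimensional densities use a product of Gaussian kernels with
per-axis Scott-rule bandwidth h = σ̂ n^(−1/6), evaluated on a regular
grid spanning the data range ± 4 bandwidths, so the trapezoidal grid
integral falls in [0.95, 1]. A product kernel (rather than a full
covariance kernel) keeps the x-marginal of the 2D estimate identical
to the 1D KDE of the x sample, which makes the estimate directly
comparable across panels. Frames are pooled across runs when several
trajectories are analysed together; per-run provenance stays in the
run report.

## Biochemical quantification

**Normalization.** Within each dataset, percent activity =
100·(CPM − mean background)/(mean control − mean background), where
no-compound controls define 100% and no-enzyme backgrounds define 0%.
The transform is exactly invariant under joint affine changes of all
CPM values (detector gain/offset). A control window ≤ background is a
hard error.

**kcat.** Product concentration (nM, from CPM via a declared linear
counts-per-pmol conversion — the tritium specific activity and
counting efficiency are instrument properties, so the conversion is a
generator/config constant) is regressed on time; kcat = slope /
[enzyme]. Endpoint designs (one incubation time, replicate wells) are
fitted through the origin, matching the assumption of a linear initial
regime starting at zero product; multi-timepoint input fits an
intercept. Uncertainty is propagated from the slope standard error; a
non-positive slope reports kcat = 0 with a flag instead of a negative
turnover.

**Dose response.** The four-parameter logistic is fitted by
least squares jointly over replicate points (weighting concentrations
by replicate count), with the Hill slope bounded to (0.2, 5) to
exclude unphysical step fits. The same 4PL serves activators and
inhibitors; the direction is read from the sign of top − bottom.
Fold changes of kcat between treated and control conditions use
first-order (delta-method) error propagation and refuse cross-substrate
or cross-complex comparisons.

**FP binding.** The bound tracer fraction is the exact root of the
mass-action quadratic at total protein P and total tracer L₀, so the
fit remains valid under ligand depletion (here L₀ = 40 nM against
Kd ≈ 150–230 nM; the trace-tracer hyperbola would bias Kd upward by
roughly L₀/2). The model reduces to the hyperbola within 1% for
L₀ ≤ Kd/100, which the tests verify. Titrations that do not approach
saturation (fitted bound fraction < 0.5 at the top concentration)
carry a wide-interval flag.

## Synthetic-data generators

The generators define the study conditions under which the analyses
are validated; they are statistical emulators, not physics.

**Reference complex.** A deterministic toy build: the reader chain
carries side-chain interaction markers on residues 362 (carboxylate),
363 (sulfur) and 364 (five-atom aromatic ring); the enzyme chain has
the acidic loop (ASP at 136 and 140) and an ideal α-helix (radius
0.23 nm, rise 0.15 nm/residue, twist 100°) for the SRM analog; the
ligand pairs a protonated pyrrolidine ring (engaging the reader
markers) with a lysine-mimic ammonium engaging ASP140. The ASP140–
ligand contact is the engineered persistent salt bridge that the
contact map should identify as the closest interface pair.

**Trajectories.** Per frame, independent Bernoulli draws set the
bound state (unbound frames displace the ligand chain by 2.0 nm in a
random direction — far beyond the 0.8 nm filter threshold, so truth
labels and filter decisions must agree) and the helix state (unfolded
frames disorder helix atoms with 0.35 nm per-atom displacements,
putting the helix RMSD well above the folded baseline). The three
interaction distances are sampled from a multivariate lognormal:
correlation is specified on the underlying normal scale, marginal
medians are exact by construction (median = exp(µ)), and the shape
parameter defaults to σ_log = 0.18, giving MAD/median ≈ 0.12 — a
realistic relative spread for a persistent contact. Sampled distances
are realized *exactly* by translating the corresponding marker groups
along fixed reference axes before noise injection, so generated truth
and measured series agree to placement precision. Scenario presets
differ only in declared parameters: `mutant_like` (the defaults) has a
stable loop (jitter 0.03 nm), a mostly folded helix (unfold
probability 0.10) and strong coupling (ρ(d1,d3) = 0.75, ρ(d2,d3) =
0.61); `wt_like` has a mobile loop (0.15 nm), a frequently unfolded
helix (0.45) and weak coupling (0.30/0.25), longer contact distances —
mirroring the qualitative wild-type/mutant contrast without claiming
to reproduce any real trajectory.

Global per-atom Gaussian jitter defaults to 0.005 nm. The value is set
by the generator's contract: jitter must stay small against the
lognormal distance spread (≈ 0.054 nm standard deviation), because
distance noise attenuates the recovered correlation by the factor
var(signal)/(var(signal)+var(noise)) per series; at 0.005 nm the
attenuation is under 1%, so the generated correlation is what the
analysis should recover.

**Assay tables.** Time courses follow product = kcat·[E]·t mapped to
CPM by a declared conversion (100 counts/pmol, 10 µL) over a constant
background (50 CPM); dose–response tables follow the 4PL with
bottom 100% / top 240% (an activator raising activity > 2-fold);
FP titrations use the quadratic bound fraction at 40 nM tracer over a
12-point, 2-fold dilution series from 2 µM. Default truths are
kcat = 24 h⁻¹ (20 nM enzyme), EC₅₀ = 2.3 µM, Kd = 156 nM; noise is
multiplicative Gaussian (CV 3% default; the validation studies use 5%
for time courses and 2% for FP, typical plate-reader precision).
Controls and backgrounds are always emitted — the normalization stage
refuses datasets without them. All generators are pure functions of
(scenario, seed); sub-streams are split from the single seed with
`numpy.random.SeedSequence.spawn`, so adding one consumer never
perturbs another.

**What passing tests do and do not show.** The generators have
independent frames (no autocorrelation), isotropic noise, exact
marker-realized distances, no solvent, no periodic boundaries and no
force field. Recovery of generated truths therefore validates the
*estimators* (filter thresholding, contact averaging, RMSD chain,
correlation, curve fits) — it says nothing about force-field accuracy
or sampling adequacy of any real simulation, and the `wt_like` /
`mutant_like` contrast is a constructed illustration, not a
prediction.

## Problem sizes and tolerances

The validation suite runs at desk scale: trajectory statistics at
2 500 frames (correlation recovery to ±0.05), convergence checks at
5 000 frames (medians to 3%), dose–response recovery over 200
simulated plates (8 concentrations × 3 replicates), and one full
mechanism pipeline at 5 000 frames as an end-to-end run. Geometric
operations are cross-checked against brute-force oracles (exhaustive
pair enumeration; an independent Wahba/SVD rotation solver) to 1e-9 nm
on 100 random fixtures. Fit internals use `scipy.optimize.curve_fit`
with analytic-free bounds stated above; degenerate inputs (zero
variance, empty selections, collinear fits, all-frames-removed
ensembles) raise typed errors from `allostat.errors` rather than
returning NaNs.

## Known limitations

* No PBC-aware distances, hydrogen-bond geometry, or DSSP-style
  secondary-structure assignment; helix state is monitored by RMSD
  only.
* mmCIF and binary trajectory formats (XTC/DCD) are out of scope; the
  XYZ dialect carries no atom annotations beyond the element.
* Enzymology fits report kcat at fixed substrate concentration — no
  Michaelis–Menten Km/Vmax surface and no progress-curve integration.
* The 4PL standard error from the covariance matrix understates
  uncertainty when plateaus are poorly sampled; such fits carry a
  `wide_interval` flag.
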
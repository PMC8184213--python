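# Methods

## The problem

A transmembrane (TM) helix reconstituted in magnetically aligned bicelles
gives a separated-local-field (SLF) spectrum in which each amide resonance
carries two orientation-dependent observables: the anisotropic ¹⁵N chemical
shift (CS, ppm) and the ¹⁵N-¹H dipolar coupling (DC, kHz).  For an ideal
helix these trace the well-known PISA (polar index slant angle) wheel, whose
position and size encode the whole-body helix tilt θ (angle of the helix
axis to the membrane normal), the azimuthal rotation ρ about the helix
axis, and a scalar order parameter S that uniformly scales the anisotropic
observables for rigid-body wobble and imperfect alignment.  `pisawheel`
implements the forward model, the exhaustive fit, its bootstrap error
analysis and significance tests; trajectory-ensemble metrics used to
characterize restrained-MD refinements of the corresponding protein
complex (contacts, hydrogen bonds, backbone PCA, KLD convergence,
inter-helix tilt correlations); the replica-averaged restraint and
annealing-schedule mathematics of such refinements, engine-free; and
synthetic-data generators that produce all of these inputs with known
ground truth.

The shipped reference data are the assigned TM resonances of monomeric
phospholamban (PLN) and its Ser16-phosphorylated form (pPLN), free in
flipped bicelles and bound to the calcium pump SERCA in its E2
(calcium-free) and E1 (calcium-bound) states — six datasets in total.

## Forward model

An ideal uniform helix with (φ, ψ) = (−63°, −42°) is built explicitly from
Engh–Huber backbone geometry (NeRF chain construction).  The amide proton
is placed in the peptide plane with a configurable Cα-N-H angle (default
119°, the value that best fits these spectra; the common default elsewhere
is 116°).  The derived helix has 3.634 residues/turn, a 1.545 Å rise, and
an azimuthal advance of 99.05°/residue.  The helix axis is obtained as the
screw axis of the exact rigid transform between consecutive residue
triads, which is exact for this uniform helix.

For a topology (θ, ρ, S) the magnetic field direction **B₀** (= membrane
normal in flipped bicelles) is expressed in the helix frame and each
residue's observables follow by projection:

- DC: ν_obs = S · ν∥ · ½(3cos²θ_NH − 1), with θ_NH the N-H/B₀ angle;
- CS: δ_obs = δ_iso + S · (**b**ᵀσ**b** − δ_iso), with σ the full ¹⁵N
  shift tensor assembled per residue from its principal axes.

In unflipped bicelles (normal ⊥ B₀) both anisotropic parts acquire an
extra factor −½; the flipped mode therefore doubles CS and DC ranges.
Peak lists store the DC as an unsigned splitting magnitude, as measured,
and the fit compares magnitudes on both sides; the signed coupling is
available from `back_calc_observables`.

### Tensor parameters and calibration

The ¹⁵N shift-tensor principal values, its orientation, and the
rigid-lattice coupling ν∥ are configuration, not hard-coded physics.  The
defaults are standard amide-¹⁵N literature values: δ = (57.3, 81.2, 228.1)
ppm, δ₃₃ in the peptide plane tilted β = 19.6° from the N-H bond toward
the preceding carbonyl, δ₂₂ perpendicular to the peptide plane, and
ν∥ = 10.735 kHz.  Because published PISA analyses rarely print these
constants, the package fixed β (within the 17–20° range reported across
the solution and solid-state literature) and the residual weighting (next
section) once, by requiring that fits of the six shipped reference
datasets reproduce their published (θ, ρ, S) within the published
uncertainties, and locked them.  They should be overridden wholesale when
analyzing data acquired or previously fit under different conventions.

### The ρ gauge

The zero direction and handedness of ρ are pure conventions.  Package-wide
convention: membrane normal = +z = B₀ (flipped), helix axis oriented
N→C, ρ referenced to a named residue (L31 for the shipped data) with a
fixed 203° offset from that residue's amide N-H azimuth and negative
right-handed sense about the axis.  The offset is a gauge constant chosen
once so that reported ρ values are directly comparable with the published
fits of the reference datasets; the coordinate-based analysis
(`helix_axis_and_topology`) uses the same convention, so spectral and
trajectory rotations agree.  When a structure carries no amide protons the
Cα radial azimuth is used instead, which shifts the zero by a constant.

## Fitting

`grid_search_fit` exhaustively searches θ ∈ [0°, 90°] (step 0.1°),
ρ ∈ [0°, 360°) (step 1°), and S free in [0.5, 1.0] (step 0.01) or fixed
(0.80 is used for the sparse pump-bound datasets).  The objective is the
combined root-mean-square residual over all assigned peaks,

RMSD² = Σᵢ [ w_cs·Δcsᵢ² + w_dc·Δdcᵢ² ] / 2n .

The default weighting ("frequency") converts CS residuals from ppm to kHz
using the ¹⁵N Larmor frequency of the 700-MHz spectrometer the reference
spectra were recorded on (70.94 MHz, i.e. 14.10 ppm ≙ 1 kHz), so both
dimensions carry equal weight per Hz.  A per-linewidth weighting (divide
by the 3 ppm / 0.8 kHz average FWHM) is available as `weighting="fwhm"`;
it is not the default because it does not reproduce the published fits of
the reference data (it lands the free-helix fit ~4° high in θ with
S ≈ 0.90).  Because the objective is quadratic in S, the solver evaluates
the exact grid minimum analytically per (θ, ρ) point; ties are broken
toward smaller θ, then ρ, then S, deterministically.  The 901 × 360 × 51
search runs in roughly a second on one CPU; the forward grid is cached and
reused across bootstrap repeats.  Fits with θ at or below one grid step
are flagged degenerate and ρ is reported as NaN (the wheel collapses to a
point at θ = 0, where ρ is unidentifiable).

Overlapped resonances (two residues sharing one peak) are retained as
independent data points sharing CS/DC values, as they were fit in the
reference analysis; a flag drops them instead.

### Uncertainty and significance

`bootstrap_uncertainty` refits 20 perturbed copies of the peak list; every
peak's CS and DC are shifted by independent Gaussian noise with sd equal
to the average linewidths (3 ppm, 0.8 kHz), overlapped duplicates
perturbed independently, and each ambiguity group re-drawn as one random
assignment permutation per repeat.  Reported uncertainties are sample
standard deviations over the repeats; ρ statistics are circular
(differences mapped to (−180°, 180°]), since ρ is periodic.
`compare_topologies` differences the bootstrap means and applies a
two-sided unpaired t-test (pooled-variance by default, matching the common
spreadsheet default; Welch by flag) on the two 20-sample sets.  All
randomness descends from a mandatory integer seed.

`estimate_populations` averages per-residue minor-state fractions
I_minor/(I_minor + I_major) over residues assigned in both states.

## Ensemble analysis

- **Helix axis from coordinates**: smoothed-Cα best-fit line (window of
  one turn) fixes the orientation; a bisector cross-product refinement
  (the two bonds flanking each Cα sum to a radial vector; cross products
  of consecutive radial vectors lie along the axis) makes the estimate
  exact for ideal helices.  The line fit alone carries a ~0.14° bias from
  the fractional residues/turn.
- **Contacts**: a residue is in contact in a frame when any of its atoms
  lies strictly within 3.5 Å of the partner selection; a k-d tree
  accelerates large selections and is checked bit-identical against the
  O(N²) loop.  No periodic imaging by default (inputs are assumed whole);
  an orthorhombic minimum-image option exists.
- **Hydrogen bonds**: donor-acceptor distance < 3 Å and deviation of the
  D-H···A arrangement from linearity < 20°, averaged per frame and grouped
  by residue pair.  Hydrogens must be present in the input; a donor
  without one is an error (no hydrogen building).
- **Backbone PCA**: ensembles are combined, iteratively rigid-body
  superposed onto their overall mean (re-fit after every mean update until
  convergence), and the covariance of the flattened coordinates is
  diagonalized.  Projections are returned per source ensemble; single
  structures are projected after fitting to the PCA mean.
- **KLD convergence**: the 2D (PC1, PC2) histogram uses 75² bins spanning
  the full data range per axis, fixed before truncation so p(x, t) and the
  final p(x) share bins; KLD(t) = Σᵢ p(xᵢ,t)·ln(p(xᵢ,t)/p(xᵢ)), empty
  truncated bins contribute 0, and KLD at the final time is exactly zero.
- **Tilt correlations**: Pearson correlation of mean-removed per-frame
  tilt series between helices; constant series give NaN (undefined), as
  flagged.

Cluster *discovery* in PCA space is out of scope; only projection and
histogramming are provided.

## Restraint mathematics

The replica-averaged restraint energy is
E = scale · Σ_res [ k_cs(⟨cs⟩−cs_exp)² + k_dc(⟨dc⟩−dc_exp)² ] with
k_cs ≤ 50 J/(mol·ppm²) and k_dc ≤ 800 J/(mol·kHz²), the averages taken
across replicas (eight in the reference protocol).  Flat-bottom walls are
harmonic beyond their bound: 30 Å upper walls (k = 5 J/(mol·nm²)) encode
paramagnetic relaxation-enhancement distance ceilings; 50 Å and 25 Å lower
walls drive the periodic detachment of the regulator's N-terminus.
Gradients are returned with respect to the averaged observables and the
wall distance — chaining into Cartesian forces belongs to the MD engine
and is deliberately out of scope.

The annealing cycle is piecewise-linear and continuous: detach (500 ps,
300→370 K, detach walls 0→max, CS/DC constants →½), hold (500 ps, 370 K),
rebind (1 ns, 370→300 K, detach walls →0, PRE walls 0→max, constants
restored), sample (2 ns, constant); 25 cycles × 8 replicas = 0.8 µs
aggregate, with the 2-ns sampling windows forming the analyzed ensemble.
During detachment the PRE walls ramp off (1→0) so the two wall families
never oppose each other; the schedule is continuous across the cycle wrap.
A separate single-phase, non-cyclic schedule models the initial 20-ns
force ramp-up.

## Synthetic data

The generators define the study conditions rather than adjustable test
dials:

- Peak lists: Gaussian scatter at the linewidth scale (3 ppm / 0.8 kHz),
  10 % intensity noise, residues 27–51 referenced to residue 31; the
  default two-state mixture is 70/30 between the free (θ = 37.5°) and
  phosphorylated (θ = 34.8°) topologies, matching the observed
  major/minor equilibrium.  A Student-t option exists for robustness
  testing only.
- Helix ensembles: ideal-helix frames rigid-rotated by per-frame tilts
  drawn from Gaussians (default means 32.8°/30.4°, the ensemble-average
  tilts of the refined complexes; sd 3°, a typical TM-helix tilt
  fluctuation, chosen here since no value is printed), correlated across
  helices through a shared latent normal when requested.  Ensembles
  round-trip through multi-model PDB so the reader is exercised
  end-to-end.
- Hydrogen-bond frames: donor/H/acceptor triplets constructed inside
  (2.8 Å, linear) or outside (3.6 Å, or 40° bent) the criteria with a
  recorded per-frame truth.

What passing these tests does *not* show about real data: real helices are
not ideal (kinks, fraying, per-residue dynamics), real noise is not i.i.d.
Gaussian, and real assignment ambiguity is structured rather than random;
the generators emulate only the statistical assumptions the analysis
itself makes.

## Numerical choices and limitations

- Grid tie-breaks are lexicographic (θ, ρ, S ascending) and documented;
  the analytic-in-S solver is exact on the grid but accumulates ~10⁻⁵
  cancellation noise in the reported RMSD at an exact zero.
- θ and 180° − θ are spectroscopically indistinguishable (the projection
  is quadratic in B₀), hence the [0°, 90°] search range.
- The fitted S trades off directly against ν∥ and the tensor anisotropy;
  absolute S values are only comparable between analyses using the same
  tensor constants.
- Bootstrap DC perturbations may cross zero for weak couplings; the
  magnitude convention folds them, which slightly skews those repeats.
- No gradient-based or Bayesian fitting, no exchange lineshapes, no
  automatic assignment, no ¹³C observables, no non-ideal helices in the
  forward model; per-residue order parameters are out of scope.
- The package computes restraint energies and schedules but never
  integrates equations of motion.
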
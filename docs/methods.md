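# Methods

## Scope and model

`msbptomo` reconstructs a sample's 3D refractive-index (RI) contrast
Δn(x, y, z) from 2D scattering measurements taken under angle-scanned
plane-wave illumination, using the multi-slice beam-propagation (MSBP)
scattering model. The sample is discretized into M thin phase screens
at spacing Δz in a homogeneous background of index n0. Light is pushed
through the stack by alternating angular-spectrum propagation over Δz
and multiplication by the unit-modulus slice transmittance
T_m = exp(j·k·Δz·Δn_m). The model is scalar, forward-only and
paraxial-in-spirit: reflections, polarization and absorption
(complex Δn) are outside its scope.

All lengths are μm and spatial frequencies are cycles/μm. The
propagation kernel is H_dz(ν) = exp(+j·2π·dz·√(κ² − |ν|²)) with
κ = n0/λ; evanescent components (|ν| > κ) are zeroed rather than
exponentially treated, so propagation is unitary on the travelling band
and back-propagation (needed for the imaging-plane model and the
adjoint) is stable. A `kernel="paper"` switch provides the variant with
n0 outside the square root; the two agree in the paraxial regime and at
ν = 0.

Imaging applies the detection chain to the exit field: back-propagation
by the focus offset ẑ (default M·Δz/2, i.e. a mid-volume conjugate
plane), optional extra defocus per record, and a hard circular pupil at
na_detect/λ. Predictions are background-normalized — the identical
pipeline run on Δn ≡ 0 defines the background field and the sample
prediction is complex-divided by it — so model outputs live in the same
normalized space as preprocessed experimental data.

### Slice-transmittance wavenumber

The thin-slice phase factor defaults to the vacuum wavenumber
k = 2π/λ, which reproduces the optical-path-length projection limit
exp(j·2π·Δn·d/λ) for a thin object of thickness d (verified to 0.3% on
a 5 μm weak bead). `mask_wavenumber="medium"` substitutes 2π·n0/λ for
users who want the medium-wavenumber convention; the Rytov
initialization follows whichever convention the configuration selects,
so the warm start and the solver always agree.

## Inverse problem

The estimate minimizes

    (1/2L) Σ_ℓ ‖y⁽ℓ⁾ − G⁽ℓ⁾{n}‖² + τ·TV(Δn)

where G returns the complex imaging-plane field (field cost) or its
modulus (amplitude cost). Gradients are computed by the exact adjoint
of the forward recursion: the residual is divided by the conjugate
background, zero-embedded into the (possibly padded) grid,
pupil-filtered, propagated to the exit plane, and swept backward
through the layers, accumulating Re{conj(j·k·Δz·T_m·E′_m)·A} per slice.
The amplitude cost reuses the same adjoint with the residual
G − y·exp(j∠G), i.e. the measured amplitude paired with the predicted
phase; this makes the two gradients structurally identical and the
amplitude gradient is, by construction, bitwise equal to the field
gradient of the synthetic measurement y·exp(j∠G). The phase factor is
defined as 0 at exact zeros of |G| (a measure-zero event). Both
gradients are validated against central finite differences (≤1e−5
relative for the field cost, ≤1e−4 for the amplitude cost) rather than
trusted by derivation.

### Optimization

Stochastic gradient descent over shuffled mini-batches of illumination
angles (all defocus records of an angle travel together; default one
angle per step), with an isotropic 3D total-variation proximal step
after every update and an optional Δn ≥ 0 projection. The TV prox is a
Chambolle-style dual projection with a fixed number of inner iterations
(default 20) and step 1/12 (the 3D contraction bound); it is validated
against an exact 1D taut-string solution.

Nesterov momentum with restart-on-cost-increase is available
(`momentum > 0`) but the shipped default is plain descent
(`momentum = 0`). The reason is quantitative: the amplitude cost is
exactly invariant to adding a constant to any layer's Δn (a pure global
phase), so the per-layer lateral mean lies in the data null space and
is controlled only by the regularizer and the positivity projection.
Accelerated iterates drift this weakly-determined direction upward
against the one-sided Δn ≥ 0 clip, which we measured as a systematic
≈5–6% overestimate of interior bead RI; momentum-free descent removes
the bias at the price of more epochs. This null space is also why
quantitative calibration uses `nonneg=True`: without a constraint
pinning the background to zero, amplitude-only data cannot determine
absolute contrast at all.

### Volume padding

`pad_fraction` adds that fraction of the lateral FOV as zero padding
(total, split half per side; 0.3 reproduces the "30% additional
padding" configuration). Illumination and propagation run on the padded
grid; predictions are cropped to the measurement FOV before residual
formation and residuals are zero-embedded for the adjoint. Padding
never changes Δz or M. Its purpose is to relax the periodic-FOV
assumption of FFT propagation when high-angle illumination shifts
sample information beyond the camera FOV; the corresponding edge
artifacts are quantified by `artifact_energy` (mean Δn² over a lateral
border band).

### Hyperparameter calibration

`calibrate_hyperparameters` grid-searches (step size, τ) by simulating
defocus-diverse amplitude measurements of synthetic beads of known
contrast (shipped fixtures: 2.5 μm beads at Δn = 0.01 and 0.04 on a
48² × 16 grid, 8 angles × 3 defocus planes), reconstructing each, and
scoring the interior-mean RI error (interior = central 70% of the bead
radius, excluding partial-volume and resolution-limited shell voxels).
The pair minimizing the worst case over beads wins; divergent runs
score infinity. The shipped defaults step_size = 0.05, τ = 1e−4 are the
output of this procedure (worst-case fixture error 1.9%), not
hand-picked numbers. Step sizes are in RI units per unit gradient; with
the default vacuum mask wavenumber and Δz ≈ 0.2–0.3 μm, descent is
stable up to roughly step ≈ 0.1–0.2 and diverges beyond.

## Weak-scattering initialization

The Rytov warm start maps each background-normalized field record to
its complex Rytov phase u_R = ln|E| + j·unwrap(arg E) and scatters its
2D spectrum onto the Ewald cap displaced by the illumination
wavevector, with nearest-voxel binning and count averaging; the
count-averaged spectrum is inverse-transformed to Δn. Three choices
deserve note:

- **Weighting.** The Helmholtz Fourier diffraction theorem weights each
  detected plane wave by its axial frequency νz. The MSBP forward model
  is paraxial: its exact linearization is Ψ̂(q) = j·k_mask·Δn̂(q), i.e.
  the obliquity evaluated at the band centre (νz → κ). The default
  `weighting="paraxial"` uses the MSBP-consistent constant so that the
  warm start is the true linearization of the solver it initializes
  (forward-model closure < 1e−3 on weak beads; linearity within 0.2%);
  `weighting="obliquity"` restores the Helmholtz-exact factor, which
  against MSBP-simulated data underestimates tilted-angle content by
  cos θ.
- **Phase reference.** Records are digitally refocused to the volume
  centre before mapping, and the accumulated spectrum is re-phased to
  the first-layer origin afterwards. Nearest-voxel axial binning on a
  spectrum carrying the fast phase ramp of an off-origin object commits
  O(1 rad) phase errors; referencing the centre makes the spectrum
  slowly varying where it matters.
- **Missing cone.** Left zero-filled. The output is an initial guess
  for the iterative solver, not a final reconstruction; axial
  elongation is expected and only lateral quantities are asserted.

Phase unwrapping is DCT-based least squares (Poisson solve under
Neumann boundaries): deterministic, parameter-free, and exact for
residue-free wrapped phases. It is cross-checked against an independent
library unwrapper in the tests.

## Holography preprocessing

Off-axis interferograms I = |E_s + a·e^{j2π c·r}|² are demodulated by
cropping the sideband carrying E_s·conj(ref) (centred at −c for a
reference tilt +c), recentering, inverse-transforming and dividing by
the reference amplitude; the crop window is a hard disk of radius
na_detect/λ by default. Background normalization is elementwise complex
division. Demodulation is exact when the object spectrum fits inside
the sideband and the carrier clears the DC autocorrelation
(|c| > bandwidth + object bandwidth). Defocus-diverse amplitude sets
are synthesized by restoring the illumination carrier, propagating the
total field by each z_d, and taking the modulus — exactly the operator
the solver's forward model applies, so synthesized records and model
predictions live in the same space. Default defocus planes are
{−T/2, −T/4, 0, +T/4, +T/2} with T = M·Δz.

## Synthetic phantoms

- **Beads**: uniform-contrast spheres with a one-voxel partial-volume
  boundary; interior voxels carry exactly Δn.
- **Rod-scattering cube**: layers of parallel rods (0.5 μm wide,
  1.8 μm tall) every 1.4 μm, orientation alternating 90°, lateral
  edge-to-edge gaps uniform in 0.7–3 μm. "Spacing" is interpreted as
  the gap between rod edges, which yields a ≈25% fill factor (the
  printed design statistic); overlapping rods (height exceeds the layer
  pitch) take the single polymer contrast. Default rod contrast 0.04
  (typical acrylate polymer against n = 1.512 index oil). Desk-scale
  defaults use 16–32 μm cubes on 0.1–0.125 μm lateral / 0.2–0.25 μm
  axial voxels in place of the 40–100 μm originals.
- **Cell-like target**: a shell, a sphere and bars at several scales
  down to a configurable minimum feature (default 0.3 μm), each with a
  known Δn and an integer label mask for per-feature scoring.

What the generators do not emulate: fabrication roughness, RI
dispersion and gradients within the polymer, camera noise beyond
additive circular complex Gaussian noise on the normalized field, and
illumination-angle miscalibration. Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not robustness to
every experimental nonideality.

## Test problem sizes

The suite runs at desk scale chosen to exercise each mechanism: the
parameter-recovery check uses a 3 μm, Δn = 0.01 bead at 128² × 32
voxels with 16 angles × 3 defocus planes; strategy-trend checks use
64²–176² grids. The padding trend is generated on a 96² world grid with
measurements cropped to a 64² FOV — with simulation and reconstruction
sharing one periodic grid the edge-artifact mechanism cannot occur, so
the world must be larger than the camera. Reported accuracies (interior
bead RI within ~2–5%) are measured by the acceptance tests themselves.

## Known limitations

- Amplitude-only reconstruction determines Δn only up to per-layer
  constants unless positivity (or a warm start) pins them.
- The field cost with zero initialization diverges readily on strongly
  scattering samples (wrapped-phase residuals); this is a property of
  the cost landscape the strategy comparison quantifies, not a solver
  defect.
- MSBP itself mismodels sharp RI interfaces and high-angle scattering;
  artifacts at such interfaces are expected and are not corrected here.
- The Rytov initialization assumes weak scattering; for strongly
  scattering samples it remains a biased (but often useful) guess.
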
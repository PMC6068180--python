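# Methods

## Image formation and PSF simulation

The microscope is modeled as shift-invariant in 3D: the focal stack is the
specimen volume (in photoelectrons emitted per exposure) convolved with a
depth-invariant intensity PSF, one camera exposure per focus position.
Because each 2D exposure collects the full photon flux of every emitter,
the PSF is normalized so that **each xy-slice sums to one**; consequently
the operator A conserves per-slice counts, and a voxel of the stack can
legitimately exceed the brightest voxel of the specimen (out-of-focus
light accumulates).

The PSF comes from the scalar Debye diffraction integral for an
Abbe-sine-corrected circular-aperture objective,

    h_A(r) = ∫₀^α √cos(φ) · J₀(2π k sin(φ) r) · sin(φ) dφ ,

with α = asin(NA/n), k = n/λ, evaluated by composite trapezoid quadrature
(default 256 nodes; the integrand is smooth, and the on-axis value matches
the closed-form antiderivative to ~1e-6 relative at that node count). The
constant prefactor involving magnification and objective focal length is
dropped — per-slice normalization removes it. The amplitude transfer
function is the inverse Fourier transform of this in-focus field; defocus
by z multiplies it by the phase factor exp{−i2πz√(k² − f_r²)} (f_r the
radial pupil frequency), with evanescent components (negative radicand)
set to zero. This defocus-phase route is valid beyond the paraxial
regime, which matters at NA 1.4. The intensity PSF |field|² is evaluated
on a laterally 4× supersampled grid whose sub-samples sit symmetrically
inside each sensor pixel, then box-averaged to the pixel pitch (pixel
integration). The symmetric sub-sampling keeps the binned PSF exactly
centrosymmetric; doubling the supersampling factor changes the result by
<0.2% L2.

Numerical caveat: the ATF of the *windowed* APSF is not perfectly
bandlimited — truncating the field of view leaves a Gibbs transition at
the pupil rim (a few percent of peak just outside NA/λ at desk-scale
windows). This leakage is physical to the discretization, harmless after
per-slice normalization, and quantified in the test suite as an
out-of-band energy bound rather than a pointwise one.

## Noise model and on-the-fly calibration

Camera counts follow y = γ·Poisson(Ax) + N(0, σ²). After dividing by the
gain, ỹ + σ̃² (σ̃ = σ/γ) is modeled as Poisson with rate Ax + σ̃² — the
shifted-Poisson surrogate, which matches the mean and variance of the
mixed model at every photon count and has a tractable likelihood.
Measurements so negative that ỹ + σ̃² < 0 (possible with read noise) carry
no probability under the surrogate and are clamped to a zero count.

γ and σ are estimated from the focal stack itself via the affine variance
law Var(y) = γ·E[y] + σ², in two steps:

1. **Local mean-variance pairs.** Each slice is tiled into 8×8 blocks.
   The block variance is taken from the residual of a quadratic surface
   fit (6 parameters, dof-corrected): plane fitting alone leaves blob-scale
   curvature in the residual and biases the slope upward, while quadratic
   detrending leaves the estimator unbiased on smooth signal. Blocks whose
   smoothed gradient energy exceeds the 75th percentile (texture) and
   blocks touching the saturation ceiling (99.5th percentile by default)
   are discarded.
2. **Weighted fit.** Iteratively reweighted least squares with weights
   1/(γm + σ²)², the inverse sampling variance of a block variance — a
   Gaussian working approximation to the maximum-likelihood fit. The
   physical constraint γ ≥ 0 is enforced by projection inside the loop;
   without it, signal-independent stacks trade slope against intercept and
   inflate σ̂². Results carry a `flagged` bit when the block-mean range is
   too narrow to identify the slope.

Under the study conditions (blob phantom, 256×256×22, peak 500 e⁻, γ=2,
σ=3) the estimator recovers the gain to well within ±10% and the read
noise within ±20%; the medians over ten seeds are within a few percent.
Noise parameters estimated once may be reused across a time series taken
with the same camera settings.

Dark-field and flat-field corrections are standard: subtract the mean
dark frame, divide by a flat field built as the per-pixel median of
autofluorescent-slide images, dark-subtracted and scaled to global
median 1.

## Reconstruction

The objective is the shifted-Poisson negative log-likelihood on the
measured region C, plus ν times the Frobenius-Hessian penalty, plus a
non-negativity indicator. All three terms are convex, so the minimizer is
global. ADMM splits three ways: z₁ = Ax (fidelity prox — closed-form
positive root of a voxelwise quadratic, evaluated cancellation-free;
identity on the margin voxels outside C), z₂ = Hx (per-voxel group
soft-threshold of the 6-component second-difference field; mixed
components carry √2 so the Euclidean norm of the 6-vector is the matrix
Frobenius norm), z₃ = x (clip at zero). The x-update solves the normal
equations in the Fourier domain using the periodic transfer functions of
A and H.

Implementation choices that matter:

* **Difference operators** use forward differences with replicate
  (Neumann) boundaries, and their exact adjoints; the x-update uses the
  periodic stencil transfer (for the Hessian, (p_x+p_y+p_z)² with
  p_a = 4sin²(πf_a)). The replicate/periodic mismatch at the volume edge
  is absorbed by the splitting and lands in the undetermined margin.
* **Penalty parameters.** A single ρ (default 0.05 in photoelectron
  units) is shared by the fidelity and non-negativity splits. The
  regularizer split scales it by the spectral norm of GᵀG (ρ₂ = ρ/‖GᵀG‖,
  144 for the Hessian): with a shared penalty the GᵀG term dominates the
  x-update denominator at high frequency and fine detail re-emerges ~100×
  more slowly than the data terms, which distorts any comparison made at
  a fixed iteration budget. The converged solution depends only on ν.
  ρ = 0.05 was chosen so the solver approaches its optimum within the
  150-iteration cap at the study's intensity scale (tens to hundreds of
  photoelectrons); at ρ = 1 the same cap leaves every fidelity far from
  convergence and model comparisons reflect trajectories, not optima.
* **Update order.** z- and dual-updates precede the x-update within an
  iteration: with zero initial duals an x-first sweep reproduces the
  initialization exactly and would trip the relative-change stopping rule
  at iteration 1.
* **Stopping.** Relative ℓ2 change of x over the full reconstruction
  grid < 1e-3, or 150 iterations, whichever comes first. The returned
  volume is clamped at zero so the non-negativity contract holds even
  when stopped early.
* **Boundary margins.** Default half the PSF support per axis; the
  `margins_for` helper rounds the expanded dimensions up to 5-smooth FFT
  lengths. For the hollow-shell study the axial margin is 24 slices —
  the widefield PSF's out-of-focus cone reaches far axially, and smaller
  margins let wrap-around light bias the ring radius inward by 2–4
  voxels.
* **Initialization** is the measurement (clamped at zero, edge-replicated
  into the margin); the problem is convex, so this affects speed only.
  Reconstructions are deterministic: two runs with identical inputs give
  bit-identical histories.
* Quadratic penalties (Tikhonov ν‖x‖², Laplacian ν‖Lx‖²) skip the z₂
  split entirely and enter the x-update denominator as 2ν·|transfer|.

## Synthetic data

Three phantom classes stand in for the morphologies of stained cells, on
the 65/150 nm voxel grid with the study optics (NA 1.4, λ 525 nm,
n 1.51) and camera noise (γ = 2.0 DN/e⁻, σ = 3.0 DN):

* **hollow_shell** — a surface-stained microsphere: voxels within half a
  thickness (default 300 nm) of the mid-surface radius are lit, interior
  exactly zero, so the line profile through the center peaks at a
  separation equal to the nominal diameter.
* **filaments** — random smooth tube paths rasterized and blurred to a
  default width of 250 nm. The width is deliberately at/above the
  diffraction scale: the cellular ground truths this emulates are
  themselves diffraction-limited (confocal-derived) intensity maps, not
  binary sub-voxel wires. With unrealistically crisp thin tubes the
  non-negative ML reconstruction is already near-perfect and no prior can
  improve on it.
* **blobs** — soft-edged random ellipsoids (nucleus-like), quartic
  falloff.

Filaments and blobs are confined to the central ~55% of z-slices
(`axial_fill`), emulating a thin specimen zero-padded along the optical
axis — this preserves genuinely dark slices, the regime in which noise
models differ. Photon-level conditions ("peak N photoelectrons") are set
on the expected measurement Ax: the clean blurred stack is rescaled so its
maximum is N, and the truth is rescaled identically.

What the phantoms do **not** emulate: spatially varying gain (CMOS),
depth-varying aberrated PSFs, autofluorescent background, or the exact
textures of real organelles. Passing tests therefore demonstrate internal
consistency of model + solver + estimator under the stated forward model,
not performance on any particular real microscope.

## Evaluation

* `snr_db(x̂, x)` = 10·log10(‖x‖₂²/MSE) in dB, implemented literally with
  a summed numerator and mean-squared denominator, so values carry a
  +10·log10(n_voxels) offset versus the per-voxel convention. Orderings
  and differences are unaffected.
* `nmse_affine` fits a·x̂ + b to the reference with adaptive Nelder-Mead
  seeded at the closed-form least-squares solution, then normalizes the
  residual by ‖reference‖₂². Intended for comparing reconstructions with
  arbitrary intensity scales against a common baseline, slice by slice.
* `tune_nu_golden` is golden-section search, by default over log₁₀ν
  (regularization sweeps are geometric), run until the bracket is
  narrower than 1e-5 in the search coordinate; a monotone objective drives
  it to the bracket endpoint.

In the model-comparison experiment (each phantom class rescaled to
100 peak photoelectrons, ten noise realizations, solver at its stopping
rule, ν for the Hessian prior tuned by a coarse golden search on one
held-out realization), the median SNR ordering is

    Gaussian  <  Poisson  ≤  shifted-Poisson  <  shifted-Poisson + FH

on all three phantom classes — the Gaussian model misses the
signal-dependence of shot noise, the plain Poisson model misattributes
read-noise fluctuations in dark regions to photons, and the Hessian prior
adds several dB on top of the correct noise model. Problem sizes for this
experiment (64×64×16 measurements, margins to 80×80×24) and for the bead
study (128×128×57, margins to 160×160×105) were chosen to keep a full run
in minutes on one CPU core while leaving the orderings and geometry
stable across seeds.

## Known limitations

* Depth-invariant PSF only; no Gibson–Lanni or Zernike aberration terms,
  no blind refinement. A measured PSF TIFF can be substituted anywhere a
  simulated one is used.
* Uniform gain across the sensor (CCD-like); per-pixel CMOS noise maps
  and hot/dead-pixel masking are out of scope.
* The ADMM splitting constraints are satisfied only asymptotically; at
  the default 150-iteration budget the solution is operationally
  converged (stable iterate, stable metrics) but primal/dual residuals
  are still a fraction of their initial norms, not numerically zero.
* The exact Poisson-Gaussian likelihood (an infinite series) is never
  evaluated; the shifted-Poisson surrogate is the model throughout.
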
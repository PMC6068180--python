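# spdeconv — convex 3D deconvolution for low-photon-count fluorescence imaging

`spdeconv` reconstructs 3D volumes from widefield fluorescence focal stacks
captured at very low light levels (peak intensities of tens of
photoelectrons per voxel), the regime of gentle live-cell imaging where both
photon shot noise and camera read noise matter. It is aimed at
microscopists and image-analysis developers who want a deconvolution whose
noise model, boundary handling, and prior are all explicit and testable.

## The model

A camera records, at voxel *j* of the focal stack,

```
y_j = γ·Poisson((Ax)_j) + Normal(0, σ²)
```

where **x** is the specimen volume in photoelectrons, **A** is 3D
convolution with the microscope PSF (simulated from the Debye diffraction
integral through the generalized-aperture/defocus-phase route, each
xy-slice normalized to unit sum), γ is the camera gain (DN/e⁻) and σ the
read noise (DN). After gain normalization (ỹ = y/γ, σ̃ = σ/γ) the mixed
noise is approximated by the shifted-Poisson surrogate — ỹ + σ̃² is treated
as Poisson with rate (Ax) + σ̃², which matches mean and variance exactly —
giving the convex reconstruction problem

```
minimize_x  Σ_{j∈C} [ (Ax)_j − (ỹ_j + σ̃²)·log((Ax)_j + σ̃²) ]
            + ν·Σ_j ‖H_j x‖_F  +  I_[0,∞)(x)
```

with `‖H_j x‖_F` the Frobenius norm of the local second-derivative
(Hessian) matrix — a prior for piecewise-smooth biological structure that,
unlike total variation, does not penalize gradual intensity ramps — and *C*
the measured region of a reconstruction grid deliberately larger than the
measurement (the "undetermined boundary", which absorbs FFT wrap-around
error). The problem is solved with ADMM: a closed-form voxelwise prox for
the fidelity, group soft-thresholding for the Hessian field, clipping for
non-negativity, and an FFT-diagonal x-update, at O(N log N) per iteration.
Gain and read noise are estimated from the focal stack itself by fitting
the affine variance law Var(y) = γ·E[y] + σ² to local block mean-variance
pairs, so no separate camera calibration is needed.

The package also ships the Gaussian and plain-Poisson fidelities and ℓ2,
Laplacian, ℓ1, and total-variation penalties for controlled comparisons, a
synthetic phantom generator (hollow microsphere shell, filament networks,
soft nuclear blobs) with the full camera-noise forward model, and the
evaluation metrics (SNR vs ground truth, affine-fitted NMSE, line
profiles, golden-section tuning of ν).

## Worked example

```python
import numpy as np
from spdeconv import (PhantomSpec, make_phantom, simulate_focal_stack,
                      estimate_noise_params, SolverConfig, admm_deconvolve,
                      snr_db, SIMULATION_OPTICS)
from spdeconv.phantoms import simulated_psf_cached
from spdeconv.solver import margins_for

spec = PhantomSpec(kind="blobs", shape=(16, 64, 64), peak_photoelectrons=120.0)
truth = make_phantom(spec, seed=1)
clean, noisy = simulate_focal_stack(truth, seed=2)   # γ=2 DN/e⁻, σ=3 DN

est = estimate_noise_params(noisy)
print(f"estimated gain {est.gain:.3f} DN/e-, read sigma {est.read_sigma:.3f} DN")

psf = simulated_psf_cached(SIMULATION_OPTICS, truth.shape)
cfg = SolverConfig(nu=0.1, rho=0.05, margins=margins_for(truth.shape, (4, 8, 8)),
                   fidelity="shifted_poisson", regularizer="fh", dtype="float32")
res = admm_deconvolve(noisy, psf, est, cfg)
print(f"{res.iterations} iterations, converged={res.converged}")
print(f"SNR raw {snr_db(noisy.values / est.gain, truth):.2f} dB -> "
      f"deconvolved {snr_db(res.x_cropped, truth):.2f} dB")
```

prints (seeds as above):

```
estimated gain 2.047 DN/e-, read sigma 2.863 DN
150 iterations, converged=False
SNR raw 29.93 dB -> deconvolved 34.06 dB
```

The gain and read noise come back within a few percent of the values used
to corrupt the stack, and deconvolution raises the SNR against the known
phantom by ~4 dB on this small example. (SNR here is `10·log10(‖x_true‖² / MSE)`, which carries
a `+10·log10(n_voxels)` offset relative to the per-voxel convention.)

A command-line surface wraps the same pipeline:

```bash
spdeconv simulate-psf --config optics.yaml --shape 57 128 128 --out psf.tif
spdeconv estimate-noise --input stack.tif --out noise.json
spdeconv deconvolve --input stack.tif --psf psf.tif --noise-json noise.json \
    --solver solver.yaml --out recon.tif
spdeconv evaluate --recon recon.tif --truth truth.tif --out metrics.json
```

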
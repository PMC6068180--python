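"""FFT convolution operator and ADMM solver behaviour."""

import numpy as np
import pytest
from scipy.fft import rfftn, irfftn
from scipy.ndimage import convolve as nd_convolve
from scipy.ndimage import gaussian_filter

from spdeconv.fidelity import BoundarySpec
from spdeconv.noise import NoiseParams, simulate_measurement
from spdeconv.solver import (
    SolverConfig,
    admm_deconvolve,
    convolve_psf,
    margins_for,
    psf_otf,
)
from spdeconv.stacks import FocalStack


class TestConvolvePsf:
    def test_delta_reproduces_psf(self, tiny_psf):
        shape = tiny_psf.shape
        x = np.zeros(shape)
        x[shape[0] // 2, shape[1] // 2, shape[2] // 2] = 1.0
        out = convolve_psf(x, tiny_psf)
        np.testing.assert_allclose(out, tiny_psf.values, atol=1e-12)

    def test_total_intensity_scales_with_slice_count(self, tiny_psf):
        # each xy-slice of the PSF sums to 1 (one camera exposure per focus
        # position), so total counts in the stack are nz x the emitted counts
        rng = np.random.default_rng(0)
        x = rng.random(tiny_psf.shape)
        out = convolve_psf(x, tiny_psf)
        assert out.sum() == pytest.approx(tiny_psf.shape[0] * x.sum(), rel=1e-9)

    def test_matches_direct_spatial_convolution(self, rng):
        # independent oracle: scipy.ndimage wrap-mode convolution
        x = rng.random((4, 8, 8))
        kern = rng.random((3, 5, 5))
        got = convolve_psf(x, kern)
        expected = nd_convolve(x, kern, mode="wrap")
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_linear(self, tiny_psf, rng):
        a = rng.random(tiny_psf.shape)
        b = rng.random(tiny_psf.shape)
        lhs = convolve_psf(2.0 * a + 3.0 * b, tiny_psf)
        rhs = 2.0 * convolve_psf(a, tiny_psf) + 3.0 * convolve_psf(b, tiny_psf)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def _smooth_positive_volume(shape, rng, floor=5.0, amp=10.0):
    x = gaussian_filter(rng.random(shape), 3)
    return floor + amp * x / x.max()


class TestAdmmDeconvolve:
    def test_matches_wiener_closed_form(self, tiny_psf, rng):
        # Gaussian fidelity + Tikhonov, zero margins, no active constraint:
        # the unique optimum is (AᵀA + 2νI)⁻¹Aᵀy in the Fourier domain
        shape = (32, 32, 32)
        x_true = _smooth_positive_volume(shape, rng)
        y = convolve_psf(x_true, tiny_psf)
        nu = 0.05
        cfg = SolverConfig(
            nu=nu, rho=1.0, max_iter=800, tol=1e-12,
            margins=((0, 0), (0, 0), (0, 0)),
            fidelity="gaussian", regularizer="l2",
        )
        res = admm_deconvolve(FocalStack(y, units="e-"), tiny_psf, None, cfg)
        otf = psf_otf(tiny_psf, shape)
        wiener = irfftn(
            np.conj(otf) * rfftn(y) / ((otf * np.conj(otf)).real + 2 * nu), s=shape
        )
        rel = np.linalg.norm(res.x - wiener) / np.linalg.norm(wiener)
        assert rel < 1e-4
        assert wiener.min() > 0  # sanity: the constraint really was inactive

    def test_noiseless_consistency_reaches_true_objective(self, tiny_psf, rng):
        from spdeconv.fidelity import nll_gaussian

        shape = (24, 24, 24)
        x_true = _smooth_positive_volume(shape, rng)
        y = convolve_psf(x_true, tiny_psf)
        cfg = SolverConfig(
            nu=0.0, rho=0.1, max_iter=800, tol=1e-12,
            margins=((0, 0), (0, 0), (0, 0)),
            fidelity="gaussian", regularizer="none",
        )
        res = admm_deconvolve(FocalStack(y, units="e-"), tiny_psf, None, cfg)
        obj_rec = nll_gaussian(convolve_psf(res.x, tiny_psf), y)
        obj_true = nll_gaussian(convolve_psf(x_true, tiny_psf), y)  # = 0
        # convex problem with consistent data: the solver approaches the
        # zero-residual optimum (threshold relative to the data energy)
        assert obj_rec <= obj_true + 1e-9 * nll_gaussian(np.zeros_like(y), y)

    def test_stops_exactly_at_iteration_cap(self, tiny_psf, rng):
        y = _smooth_positive_volume((16, 16, 16), rng)
        cfg = SolverConfig(
            nu=0.1, max_iter=20, tol=1e-30, margins=((0, 0),) * 3,
            fidelity="shifted_poisson", regularizer="fh",
        )
        res = admm_deconvolve(
            FocalStack(y, units="e-"), tiny_psf, NoiseParams(2, 3), cfg
        )
        assert res.iterations == 20
        assert not res.converged
        assert len(res.history["rel_change"]) == 20

    def test_stops_when_relative_change_small(self, tiny_psf, rng):
        y = _smooth_positive_volume((16, 16, 16), rng)
        cfg = SolverConfig(
            nu=0.0, max_iter=150, tol=0.5, margins=((0, 0),) * 3,
            fidelity="gaussian", regularizer="none",
        )
        res = admm_deconvolve(FocalStack(y, units="e-"), tiny_psf, None, cfg)
        assert res.converged
        assert res.iterations < 150
        assert res.history["rel_change"][-1] < 0.5

    def test_deterministic_given_inputs(self, tiny_psf, rng):
        y = simulate_measurement(
            _smooth_positive_volume((16, 16, 16), rng), NoiseParams(2, 3), 7
        )
        cfg = SolverConfig(nu=0.2, max_iter=25, margins=((2, 2), (4, 4), (4, 4)))
        r1 = admm_deconvolve(y, tiny_psf, NoiseParams(2, 3), cfg)
        r2 = admm_deconvolve(y, tiny_psf, NoiseParams(2, 3), cfg)
        np.testing.assert_array_equal(r1.x, r2.x)
        assert r1.history["objective"] == r2.history["objective"]

    def test_nonnegative_output_and_crop_shapes(self, tiny_psf, rng):
        y = simulate_measurement(
            _smooth_positive_volume((12, 16, 16), rng, floor=0.0, amp=20.0),
            NoiseParams(2, 3), 3,
        )
        margins = margins_for((12, 16, 16), (2, 4, 4))
        cfg = SolverConfig(nu=0.3, max_iter=30, margins=margins)
        res = admm_deconvolve(y, tiny_psf, NoiseParams(2, 3), cfg)
        assert np.all(res.x >= 0.0)
        assert res.x_cropped.shape == (12, 16, 16)
        assert res.x.shape == res.boundary.recon_shape

    def test_objective_eventually_non_increasing_windowed(self, tiny_psf, rng):
        y = simulate_measurement(
            _smooth_positive_volume((12, 16, 16), rng, floor=0.0, amp=30.0),
            NoiseParams(2, 3), 11,
        )
        cfg = SolverConfig(
            nu=0.2, rho=0.05, max_iter=80, tol=1e-9,
            margins=((2, 2), (4, 4), (4, 4)),
        )
        res = admm_deconvolve(y, tiny_psf, NoiseParams(2, 3), cfg)
        obj = np.array(res.history["objective"])
        # ADMM is not monotone; compare 10-iteration window minima instead
        w = 10
        window_min = [obj[i : i + w].min() for i in range(0, len(obj) - w, w)]
        assert all(b <= a + 1e-6 * abs(a) for a, b in zip(window_min, window_min[1:]))

    def test_residuals_fall_on_bead_phantom(self, study_optics, study_noise):
        from spdeconv.phantoms import (
            PhantomSpec, make_phantom, simulate_focal_stack, simulated_psf_cached,
        )

        shape = (16, 48, 48)
        spec = PhantomSpec(
            kind="hollow_shell", shape=shape, peak_photoelectrons=80.0,
            shell_diameter_nm=1500, shell_thickness_nm=260,
        )
        truth = make_phantom(spec)
        psf = simulated_psf_cached(study_optics, shape)
        _, noisy = simulate_focal_stack(truth, study_optics, study_noise, 4, psf=psf)
        cfg = SolverConfig(
            nu=0.2, rho=0.05, max_iter=150, tol=1e-9,
            margins=margins_for(shape, (4, 6, 6)), dtype="float32",
        )
        res = admm_deconvolve(noisy, psf, study_noise, cfg)
        # constraint violations shrink substantially over the 150-iteration
        # budget (exact satisfaction is only reached asymptotically)
        primal = res.history["primal"]
        dual = res.history["dual"]
        assert primal[-1] < 0.5 * primal[0]
        assert dual[-1] < 0.6 * dual[0]
        assert primal[-1] == min(primal)

    def test_all_zero_measurement_warns_and_returns_zero(self, tiny_psf):
        with pytest.warns(UserWarning, match="all-zero"):
            res = admm_deconvolve(
                FocalStack(np.zeros((8, 8, 8)), units="e-"),
                tiny_psf, None, SolverConfig(margins=((0, 0),) * 3),
            )
        assert np.all(res.x == 0.0)
        assert res.converged

    def test_nan_input_rejected(self, tiny_psf):
        y = np.zeros((8, 8, 8))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            admm_deconvolve(FocalStack(y, units="e-"), tiny_psf, None, SolverConfig())

    def test_dn_stack_requires_noise_params(self, tiny_psf):
        y = FocalStack(np.ones((8, 8, 8)), units="DN")
        with pytest.raises(ValueError, match="noise"):
            admm_deconvolve(y, tiny_psf, None, SolverConfig())

    def test_per_iteration_cost_scales_near_linearly(self, tiny_psf, rng):
        # O(N log N) per iteration: doubling the volume should cost well
        # under 3x per iteration (loose wall-clock check)
        import time

        def time_iters(shape):
            y = FocalStack(_smooth_positive_volume(shape, rng), units="e-")
            cfg = SolverConfig(
                nu=0.1, max_iter=8, tol=1e-30, margins=((0, 0),) * 3,
                dtype="float32",
            )
            t0 = time.perf_counter()
            admm_deconvolve(y, tiny_psf, NoiseParams(2, 3), cfg)
            return time.perf_counter() - t0

        t_small = min(time_iters((16, 32, 32)) for _ in range(3))
        t_big = min(time_iters((32, 32, 32)) for _ in range(3))
        assert t_big / t_small < 3.0
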
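"""ADMM deconvolution with FFT convolution and undetermined boundaries.

The reconstruction solves

    minimize_x  ℓ(Ax) + ν R(x) + I_[0,∞)(x)

where A is circular convolution with the slice-normalized PSF, ℓ a
data-fidelity term evaluated only on the measured region C of an expanded
reconstruction grid, and R a regularization penalty.  The problem is split
three ways — z1 = Ax (fidelity prox, identity on the margin), z2 = Gx
(regularizer prox on the operator image), z3 = x (non-negativity) — with
penalty ρ on the data/non-negativity splits and a spectrally scaled ρ₂ on
the regularizer split.  The x-update solves the Fourier-diagonal normal
equations

    (ρ AᵀA + ρ₂ GᵀG + ρ I) x = ρ Aᵀ(z1−u1) + ρ₂ Gᵀ(z2−u2) + ρ (z3−u3)

using the periodic transfer functions of A and G.  Quadratic penalties
(Tikhonov, Laplacian) need no splitting and are folded directly into the
denominator.  Iterations stop when the ℓ2 norm of the relative change of x
(over the full reconstruction grid) drops below ``tol``, or at ``max_iter``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfftn, rfftn

from .fidelity import BoundarySpec, get_fidelity
from .noise import NoiseParams, normalize_measurement
from .psf import PSFStack
from .regularizers import get_regularizer
from .stacks import UNITS_DN, FocalStack

__all__ = ["SolverConfig", "SolveResult", "convolve_psf", "psf_otf", "admm_deconvolve"]


@dataclass
class SolverConfig:
    """Knobs of the ADMM deconvolution.

    ``margins`` is per-axis (low, high) voxel counts of the undetermined
    boundary; None selects half the PSF support per axis.  ``nu`` is the
    regularization weight in photoelectron units.

    ``rho`` is the ADMM penalty shared by the fidelity and non-negativity
    splits.  The regularizer split uses ``rho / ||GᵀG||`` (the periodic
    spectral norm of the difference operator) unless ``rho_reg`` is given:
    with a shared penalty the GᵀG term dominates the x-update denominator at
    high spatial frequencies and the iterate recovers fine detail orders of
    magnitude more slowly than the data terms, which distorts comparisons at
    a fixed iteration budget.  The converged solution depends only on ν.
    """

    nu: float = 0.0
    rho: float = 0.05
    rho_reg: float | None = None
    max_iter: int = 150
    tol: float = 1e-3
    margins: tuple[tuple[int, int], ...] | None = None
    fidelity: str = "shifted_poisson"
    regularizer: str = "fh"
    log_every: int = 0
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError("nu must be >= 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class SolveResult:
    """Reconstruction output with convergence diagnostics."""

    x: np.ndarray
    x_cropped: np.ndarray
    iterations: int
    history: dict[str, list[float]]
    converged: bool
    boundary: BoundarySpec
    noise: NoiseParams | None = None


def _center_embed(psf: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Zero-pad or crop a centered PSF to ``shape``, keeping centers aligned."""
    out = np.zeros(shape, dtype=float)
    src_sl, dst_sl = [], []
    for n_src, n_dst in zip(psf.shape, shape):
        c_src, c_dst = n_src // 2, n_dst // 2
        n = min(n_src, n_dst)
        lo = n // 2
        hi = n - lo
        src_sl.append(slice(c_src - lo, c_src + hi))
        dst_sl.append(slice(c_dst - lo, c_dst + hi))
    out[tuple(dst_sl)] = psf[tuple(src_sl)]
    return out


def psf_otf(psf: PSFStack | np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """rFFT transfer function of the PSF on ``shape`` (center moved to origin)."""
    values = psf.values if isinstance(psf, PSFStack) else np.asarray(psf, dtype=float)
    kernel = _center_embed(values, shape)
    kernel = np.fft.ifftshift(kernel)
    return rfftn(kernel)


def convolve_psf(x: np.ndarray, psf: PSFStack | np.ndarray) -> np.ndarray:
    """Circular 3D convolution A x with the (centered) PSF."""
    x = np.asarray(x, dtype=float)
    otf = psf_otf(psf, x.shape)
    return irfftn(rfftn(x) * otf, s=x.shape)


def _default_margins(psf_shape: tuple[int, int, int]) -> tuple[tuple[int, int], ...]:
    """Half the PSF support per axis, so wrap-around ghosts fall in the margin."""
    return tuple((s // 2, s // 2) for s in psf_shape)


def margins_for(
    measured_shape: tuple[int, int, int],
    minimum: tuple[int, int, int],
) -> tuple[tuple[int, int], ...]:
    """Per-axis margins of at least ``minimum``, rounded up so every expanded
    dimension is an FFT-friendly (5-smooth) length."""
    from scipy.fft import next_fast_len

    out = []
    for m, lo in zip(measured_shape, minimum):
        n = next_fast_len(m + 2 * lo)
        extra = n - m
        out.append((extra // 2, extra - extra // 2))
    return tuple(out)


def admm_deconvolve(
    y: FocalStack | np.ndarray,
    psf: PSFStack,
    noise: NoiseParams | None,
    cfg: SolverConfig,
) -> SolveResult:
    """Deconvolve a focal stack; see the module docstring for the scheme.

    A stack in DN is first gain-normalized to photoelectrons using ``noise``;
    a stack already in photoelectrons uses ``noise`` only for σ̃ (σ̃ = 0 when
    ``noise`` is None).  The returned volume is clamped at 0 so the
    non-negativity invariant holds even short of full convergence.
    """
    if isinstance(y, FocalStack):
        if y.units == UNITS_DN:
            if noise is None:
                raise ValueError("a stack in DN requires noise parameters")
            y_stack, sigma_norm = normalize_measurement(y, noise)
            y_norm = y_stack.values
        else:
            y_norm = np.asarray(y.values, dtype=float)
            sigma_norm = noise.read_sigma_norm if noise is not None else 0.0
    else:
        y_norm = np.asarray(y, dtype=float)
        sigma_norm = noise.read_sigma_norm if noise is not None else 0.0

    if np.any(~np.isfinite(y_norm)):
        raise ValueError("measurement contains NaN or Inf")

    dtype = np.dtype(cfg.dtype)
    y_norm = y_norm.astype(dtype)
    fid = get_fidelity(cfg.fidelity)
    reg = get_regularizer(cfg.regularizer)

    margins = cfg.margins if cfg.margins is not None else _default_margins(psf.shape)
    boundary = BoundarySpec(tuple(y_norm.shape), tuple(tuple(m) for m in margins))
    shape = boundary.recon_shape
    region = boundary.region

    if not np.any(y_norm):
        import warnings

        warnings.warn("all-zero measurement; returning a zero volume")
        zeros = np.zeros(shape, dtype=dtype)
        return SolveResult(
            x=zeros,
            x_cropped=zeros[region].copy(),
            iterations=0,
            history={k: [] for k in ("objective", "rel_change", "primal", "dual")},
            converged=True,
            boundary=boundary,
            noise=noise,
        )

    otf = psf_otf(psf, shape).astype(np.result_type(dtype, np.complex64))
    otf_conj = np.conj(otf)
    abs_otf2 = (otf * otf_conj).real

    rho = float(cfg.rho)
    nu = float(cfg.nu)
    use_split_reg = reg.kind == "prox" and nu > 0
    denom = rho * (abs_otf2 + 1.0)
    rho_reg = rho
    if use_split_reg:
        transfer = reg.transfer(shape).astype(dtype)
        rho_reg = (
            float(cfg.rho_reg)
            if cfg.rho_reg is not None
            else rho / max(float(transfer.max()), 1.0)
        )
        denom = denom + rho_reg * transfer
    elif reg.kind == "quad" and nu > 0:
        denom = denom + 2.0 * nu * reg.transfer(shape).astype(dtype)

    # initialization: measurement edge-replicated into the expanded grid
    pad = tuple((lo, hi) for (lo, hi) in boundary.margins)
    x = np.pad(np.maximum(y_norm, 0.0), pad, mode="edge").astype(dtype)

    def A(v_hat):
        return irfftn(v_hat * otf, s=shape)

    def AT(v):
        return irfftn(rfftn(v) * otf_conj, s=shape)

    Ax = A(rfftn(x))
    z1 = Ax.copy()
    u1 = np.zeros_like(x)
    if use_split_reg:
        Gx = reg.apply(x)
        z2 = Gx.copy()
        u2 = np.zeros_like(Gx)
    z3 = np.maximum(x, 0.0)
    u3 = np.zeros_like(x)

    history: dict[str, list[float]] = {
        "objective": [],
        "rel_change": [],
        "primal": [],
        "dual": [],
    }
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        # z- and dual-updates first: with zero initial duals the x-update
        # alone would reproduce the initialization exactly and trip the
        # relative-change test before the data have pulled on the iterate
        z1_old = z1
        z3_old = z3
        z1 = fid.prox(Ax + u1, y_norm, sigma_norm, rho, boundary)
        z3 = np.maximum(x + u3, 0.0)
        u1 = u1 + Ax - z1
        u3 = u3 + x - z3
        if use_split_reg:
            z2_old = z2
            z2 = reg.prox(Gx + u2, nu / rho_reg)
            u2 = u2 + Gx - z2

        x_prev = x
        rhs = rho * (AT(z1 - u1) + (z3 - u3))
        if use_split_reg:
            rhs += rho_reg * reg.adjoint(z2 - u2)
        x_hat = rfftn(rhs) / denom
        x = irfftn(x_hat, s=shape)
        Ax = A(x_hat)
        if use_split_reg:
            Gx = reg.apply(x)

        # diagnostics
        obj = fid.nll(Ax[region], y_norm, sigma_norm)
        if nu > 0:
            # for split regularizers the operator image Gx is already in hand
            obj += nu * reg.penalty(Gx if use_split_reg else x)
        primal = float(
            np.sum((Ax - z1) ** 2)
            + np.sum((x - z3) ** 2)
            + (np.sum((Gx - z2) ** 2) if use_split_reg else 0.0)
        ) ** 0.5
        dual_vec = rho * (AT(z1 - z1_old) + (z3 - z3_old))
        if use_split_reg:
            dual_vec += rho_reg * reg.adjoint(z2 - z2_old)
        dual = float(np.linalg.norm(dual_vec))
        denom_norm = float(np.linalg.norm(x_prev))
        rel = float(np.linalg.norm(x - x_prev)) / max(denom_norm, 1e-30)

        history["objective"].append(float(obj))
        history["rel_change"].append(rel)
        history["primal"].append(primal)
        history["dual"].append(dual)
        if cfg.log_every and it % cfg.log_every == 0:
            print(f"iter {it:4d}  objective {obj:.6e}  rel_change {rel:.3e}")

        if rel < cfg.tol:
            converged = True
            break

    x = np.maximum(x, 0.0)
    return SolveResult(
        x=x,
        x_cropped=x[region].copy(),
        iterations=it,
        history=history,
        converged=converged,
        boundary=boundary,
        noise=noise,
    )
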
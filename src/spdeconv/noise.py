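"""Mixed Poisson-Gaussian camera noise: simulation, normalization, estimation.

A scientific camera records, at voxel j with expected photoelectron count
θ_j, the digital number

    y_j = γ · Poisson(θ_j) + Normal(0, σ²),

where γ is the gain (DN per photoelectron) and σ the read-noise standard
deviation in DN.  Dividing by γ yields ỹ = y/γ with read noise σ̃ = σ/γ in
photoelectrons; ỹ + σ̃² is then well approximated by a Poisson variable with
rate θ + σ̃² (the shifted-Poisson surrogate, which matches the mean and
variance of the mixed model at every photon count).

The law of total variance gives the affine mean-variance relation
Var(y) = γ·E[y] + σ², which identifies (γ, σ²) directly from a single focal
stack.  ``estimate_noise_params`` implements a two-step estimator in that
spirit: (1) collect local mean-variance pairs from small blocks, rejecting
textured and saturated blocks; (2) fit the affine law by iteratively
reweighted least squares with weights matched to the sampling variance of a
local variance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .stacks import UNITS_DN, UNITS_E, FocalStack

__all__ = [
    "NoiseParams",
    "CalibrationFrames",
    "NoiseEstimateConfig",
    "simulate_measurement",
    "normalize_measurement",
    "estimate_noise_params",
    "dark_flat_correct",
    "build_flat_field",
]


@dataclass(frozen=True)
class NoiseParams:
    """Camera gain γ (DN/e⁻) and read-noise σ (DN)."""

    gain: float
    read_sigma: float
    flagged: bool = False
    n_pairs: int | None = None

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")

    @property
    def read_sigma_norm(self) -> float:
        """σ̃ = σ/γ in photoelectrons."""
        return self.read_sigma / self.gain


@dataclass
class CalibrationFrames:
    """Mean dark image (DN) and dimensionless flat field (global median ≈ 1)."""

    dark: np.ndarray
    flat: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.flat = np.asarray(self.flat, dtype=float)
        if self.dark.shape != self.flat.shape:
            raise ValueError("dark and flat shapes must match")
        if np.any(self.flat <= 0):
            raise ValueError("flat field must be strictly positive everywhere")


def simulate_measurement(
    clean_e: np.ndarray,
    noise: NoiseParams,
    seed: int | np.random.Generator,
    dxy_nm: float | None = None,
    dz_nm: float | None = None,
) -> FocalStack:
    """Draw a raw camera stack y = γ·Poisson(Ax) + N(0, σ²), in DN."""
    clean_e = np.asarray(clean_e, dtype=float)
    if np.any(clean_e < 0):
        raise ValueError("expected photoelectron counts must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = noise.gain * rng.poisson(clean_e).astype(float)
    if noise.read_sigma > 0:
        y += rng.normal(0.0, noise.read_sigma, size=clean_e.shape)
    return FocalStack(values=y, units=UNITS_DN, dxy_nm=dxy_nm, dz_nm=dz_nm)


def normalize_measurement(y: FocalStack, noise: NoiseParams) -> tuple[FocalStack, float]:
    """Convert DN to photoelectrons: (y/γ, σ̃ = σ/γ)."""
    if noise.gain <= 0:
        raise ValueError("gain must be > 0")
    if y.units != UNITS_DN:
        raise ValueError("normalize_measurement expects a stack in DN")
    return y.with_values(y.values / noise.gain, units=UNITS_E), noise.read_sigma_norm


@dataclass(frozen=True)
class NoiseEstimateConfig:
    """Hyper-parameters of the block-based mean-variance collector."""

    block: int = 8
    texture_percentile: float = 75.0
    saturation_quantile: float = 0.995
    smooth_sigma: float = 2.0
    irls_iters: int = 12


def _block_pairs(
    slice2d: np.ndarray, cfg: NoiseEstimateConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-block (mean, residual variance, texture energy, max) for one slice."""
    b = cfg.block
    ny, nx = slice2d.shape
    nby, nbx = ny // b, nx // b
    if nby == 0 or nbx == 0:
        return (np.empty(0),) * 4
    img = slice2d[: nby * b, : nbx * b]
    blocks = img.reshape(nby, b, nbx, b).transpose(0, 2, 1, 3).reshape(-1, b * b)

    # quadratic surface detrending removes smooth signal structure so the
    # residual variance estimates the noise variance (dof-corrected)
    ii, jj = np.mgrid[0:b, 0:b]
    design = np.stack(
        [np.ones(b * b), ii.ravel(), jj.ravel(),
         (ii * ii).ravel(), (ii * jj).ravel(), (jj * jj).ravel()],
        axis=1,
    ).astype(float)
    proj = design @ np.linalg.pinv(design)
    resid = blocks - blocks @ proj.T
    dof = b * b - design.shape[1]
    variances = (resid * resid).sum(axis=1) / dof
    means = blocks.mean(axis=1)
    maxima = blocks.max(axis=1)

    smooth = gaussian_filter(slice2d, cfg.smooth_sigma)[: nby * b, : nbx * b]
    gy, gx = np.gradient(smooth)
    g2 = (gy * gy + gx * gx).reshape(nby, b, nbx, b).mean(axis=(1, 3)).ravel()
    return means, variances, g2, maxima


def estimate_noise_params(
    y: FocalStack | np.ndarray,
    config: NoiseEstimateConfig | None = None,
) -> NoiseParams:
    """Estimate (γ, σ) from a raw focal stack via the affine variance law.

    Step 1 accumulates local (mean, variance) pairs over small blocks of each
    slice, discarding blocks whose smoothed gradient energy is above the
    texture percentile and blocks touching the saturation ceiling.  Step 2
    fits Var(y) = γ·E[y] + σ² by iteratively reweighted least squares with
    weights 1/(γm + σ²)², the inverse sampling variance of a block variance.
    The result is flagged when the intensity range is too narrow to identify
    the slope reliably.
    """
    cfg = config or NoiseEstimateConfig()
    values = y.values if isinstance(y, FocalStack) else np.atleast_3d(np.asarray(y))
    ceiling = np.quantile(values, cfg.saturation_quantile)

    means, variances, textures, maxima = [], [], [], []
    for z in range(values.shape[0]):
        m, v, t, mx = _block_pairs(values[z].astype(float), cfg)
        means.append(m)
        variances.append(v)
        textures.append(t)
        maxima.append(mx)
    m = np.concatenate(means)
    v = np.concatenate(variances)
    t = np.concatenate(textures)
    mx = np.concatenate(maxima)

    keep = mx < ceiling
    if keep.sum() >= 8:
        m, v, t = m[keep], v[keep], t[keep]
    thresh = np.percentile(t, cfg.texture_percentile)
    keep = t <= thresh
    m, v = m[keep], v[keep]
    n_pairs = int(len(m))
    if n_pairs < 8:
        raise ValueError("too few usable blocks to estimate noise parameters")

    # IRLS on v = gain*m + sigma2, with the physical constraint gain >= 0
    # (an unconstrained fit on signal-independent noise trades slope against
    # intercept and biases sigma^2)
    design = np.stack([m, np.ones_like(m)], axis=1)
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    for _ in range(cfg.irls_iters):
        pred = design @ coef
        w = 1.0 / np.maximum(pred, 1e-12) ** 2
        wd = design * w[:, None]
        coef = np.linalg.solve(wd.T @ design, wd.T @ v)
        if coef[0] < 0.0:
            coef[0] = 0.0
            coef[1] = float(np.sum(w * v) / np.sum(w))
    gain = float(coef[0])
    sigma2 = float(coef[1])

    # identifiability: the mean range must exceed the scatter of the pairs
    pred_med = float(np.median(np.abs(design @ coef)))
    flagged = bool(np.ptp(m) < 10.0 * np.sqrt(max(pred_med, 1e-12)))
    if gain <= 0:
        gain = 1e-6  # NoiseParams requires strict positivity
        flagged = True
    return NoiseParams(
        gain=gain,
        read_sigma=float(np.sqrt(max(sigma2, 0.0))),
        flagged=flagged,
        n_pairs=n_pairs,
    )


def dark_flat_correct(raw: FocalStack, cal: CalibrationFrames) -> FocalStack:
    """Per-pixel (raw − dark)/flat, applied to every slice."""
    if cal.dark.shape != raw.values.shape[1:]:
        raise ValueError(
            f"calibration shape {cal.dark.shape} does not match "
            f"lateral stack shape {raw.values.shape[1:]}"
        )
    out = (raw.values - cal.dark[None]) / cal.flat[None]
    return raw.with_values(out)


def build_flat_field(
    slide_images: list[np.ndarray] | np.ndarray,
    dark: np.ndarray,
) -> np.ndarray:
    """Flat field from autofluorescent-slide images.

    The per-pixel median across the slide images, dark-subtracted, is divided
    by its global median so the result has global median 1.
    """
    imgs = np.asarray(slide_images, dtype=float)
    if imgs.ndim != 3 or imgs.shape[0] < 3:
        raise ValueError("need at least 3 slide images")
    med = np.median(imgs, axis=0) - np.asarray(dark, dtype=float)
    scale = np.median(med)
    if scale <= 0:
        raise ValueError("median slide intensity is non-positive after dark subtraction")
    flat = med / scale
    bad = np.argwhere(flat <= 0)
    if len(bad):
        raise ValueError(
            f"flat field non-positive at {len(bad)} pixel(s), first few: "
            f"{bad[:5].tolist()}"
        )
    return flat
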
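"""Synthetic ground-truth volumes and simulated focal stacks.

Three phantom classes stand in for the morphologies typical of stained
cellular structures: a hollow spherical shell (a fluorescent microsphere
whose surface is stained), smooth random curvilinear tubes (actin-like
filaments), and soft-edged ellipsoids (nucleus-like blobs).  A phantom is
blurred with the simulated widefield PSF and corrupted with mixed
Poisson-Gaussian camera noise to produce a full synthetic focal stack with
known ground truth.

Default simulation conditions: NA 1.4, emission wavelength 525 nm, immersion
refractive index 1.51, voxel pitch 65 nm laterally and 150 nm axially, gain
γ = 2.0 DN/e⁻ and read noise σ = 3.0 DN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .noise import NoiseParams, simulate_measurement
from .psf import OpticalParams, PSFStack, simulate_psf
from .solver import convolve_psf
from .stacks import FocalStack

__all__ = [
    "PhantomSpec",
    "SIMULATION_OPTICS",
    "SIMULATION_NOISE",
    "make_phantom",
    "simulate_focal_stack",
    "simulated_psf_cached",
]

#: optical settings of the simulation study
SIMULATION_OPTICS = OpticalParams(
    na=1.4,
    n_immersion=1.51,
    wavelength_nm=525.0,
    dxy_nm=65.0,
    dz_nm=150.0,
    oversample=4,
)

#: camera noise of the simulation study (realistic CCD statistics)
SIMULATION_NOISE = NoiseParams(gain=2.0, read_sigma=3.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic ground-truth volume.

    The hollow shell is centered on the mid-surface: voxels within
    ``shell_thickness_nm/2`` of radius ``shell_diameter_nm/2`` are lit, so a
    line profile through the center peaks at a separation equal to the
    nominal diameter.  The interior is exactly zero.
    """

    kind: str
    shape: tuple[int, int, int]
    peak_photoelectrons: float
    dxy_nm: float = 65.0
    dz_nm: float = 150.0
    shell_diameter_nm: float = 6000.0
    shell_thickness_nm: float = 300.0
    n_filaments: int = 12
    filament_width_nm: float = 250.0
    n_blobs: int = 20
    blob_radius_nm: tuple[float, float] = (400.0, 1500.0)
    #: fraction of z-slices that may contain structure (filaments/blobs only);
    #: emulates a thin specimen whose stack is zero-padded along the optical
    #: axis, leaving genuinely dark slices above and below
    axial_fill: float = 0.55

    def __post_init__(self) -> None:
        if self.kind not in ("hollow_shell", "filaments", "blobs"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.peak_photoelectrons <= 0:
            raise ValueError("peak_photoelectrons must be > 0")
        nz, ny, nx = self.shape
        if self.kind == "hollow_shell":
            r_out = (self.shell_diameter_nm + self.shell_thickness_nm) / 2.0
            if (
                r_out > nx * self.dxy_nm / 2.0
                or r_out > ny * self.dxy_nm / 2.0
                or r_out > nz * self.dz_nm / 2.0
            ):
                raise ValueError("shell does not fit inside the volume")


def _coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nz, ny, nx = spec.shape
    z = (np.arange(nz) - nz // 2) * spec.dz_nm
    y = (np.arange(ny) - ny // 2) * spec.dxy_nm
    x = (np.arange(nx) - nx // 2) * spec.dxy_nm
    return z[:, None, None], y[None, :, None], x[None, None, :]


def make_phantom(spec: PhantomSpec, seed: int = 0) -> np.ndarray:
    """Deterministic ground-truth volume with max value = peak_photoelectrons."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    if spec.kind == "hollow_shell":
        zc, yc, xc = _coords(spec)
        r = np.sqrt(zc * zc + yc * yc + xc * xc)
        vol = (np.abs(r - spec.shell_diameter_nm / 2.0) <= spec.shell_thickness_nm / 2.0).astype(float)
    elif spec.kind == "filaments":
        vol = np.zeros(spec.shape)
        step_nm = spec.dxy_nm / 2.0
        n_steps = int(3.0 * max(ny, nx))
        for _ in range(spec.n_filaments):
            pos = np.array([
                rng.uniform(0.2, 0.8) * nz,
                rng.uniform(0.1, 0.9) * ny,
                rng.uniform(0.1, 0.9) * nx,
            ])
            direction = rng.normal(size=3)
            direction[0] *= 0.15  # filaments wander mostly laterally
            direction /= np.linalg.norm(direction)
            for _ in range(n_steps):
                turn = rng.normal(scale=0.08, size=3)
                turn[0] *= 0.3
                direction = direction + turn
                direction /= np.linalg.norm(direction)
                pos = pos + direction * np.array(
                    [step_nm / spec.dz_nm, step_nm / spec.dxy_nm, step_nm / spec.dxy_nm]
                )
                iz, iy, ix = np.round(pos).astype(int)
                if 0 <= iz < nz and 0 <= iy < ny and 0 <= ix < nx:
                    vol[iz, iy, ix] += 1.0
                else:
                    break
        sig_xy = max(spec.filament_width_nm / 2.355 / spec.dxy_nm, 0.5)
        sig_z = max(spec.filament_width_nm / 2.355 / spec.dz_nm, 0.35)
        vol = gaussian_filter(vol, (sig_z, sig_xy, sig_xy))
    else:  # blobs
        zc, yc, xc = _coords(spec)
        vol = np.zeros(spec.shape)
        r_lo, r_hi = spec.blob_radius_nm
        for _ in range(spec.n_blobs):
            center = np.array([
                rng.uniform(-0.3, 0.3) * nz * spec.dz_nm,
                rng.uniform(-0.4, 0.4) * ny * spec.dxy_nm,
                rng.uniform(-0.4, 0.4) * nx * spec.dxy_nm,
            ])
            radii = rng.uniform(r_lo, r_hi, size=3)
            amp = rng.uniform(0.4, 1.0)
            rho2 = (
                ((zc - center[0]) / radii[0]) ** 2
                + ((yc - center[1]) / radii[1]) ** 2
                + ((xc - center[2]) / radii[2]) ** 2
            )
            vol += amp * np.clip(1.0 - rho2, 0.0, None) ** 2  # soft-edged bump
    if spec.kind != "hollow_shell" and 0.0 < spec.axial_fill < 1.0:
        n_fill = max(1, int(round(spec.axial_fill * nz)))
        lo = (nz - n_fill) // 2
        mask = np.zeros(spec.shape)
        mask[lo : lo + n_fill] = vol[lo : lo + n_fill]
        vol = mask
    peak = vol.max()
    if peak <= 0:
        raise ValueError("phantom came out empty; check the geometry parameters")
    return vol * (spec.peak_photoelectrons / peak)


_PSF_CACHE: dict[tuple, PSFStack] = {}


def simulated_psf_cached(params: OpticalParams, shape: tuple[int, int, int]) -> PSFStack:
    """Simulated PSF memoized on (params, shape) — the simulation study reuses
    one PSF per condition, and it is by far the most expensive stage."""
    key = (
        params.na, params.n_immersion, params.wavelength_nm, params.dxy_nm,
        params.dz_nm, params.oversample, params.quad_nodes, tuple(shape),
    )
    if key not in _PSF_CACHE:
        _PSF_CACHE[key] = simulate_psf(params, shape)
    return _PSF_CACHE[key]


def simulate_focal_stack(
    truth: np.ndarray,
    params: OpticalParams = SIMULATION_OPTICS,
    noise: NoiseParams = SIMULATION_NOISE,
    seed: int = 0,
    psf: PSFStack | None = None,
) -> tuple[np.ndarray, FocalStack]:
    """Blur a ground-truth volume with the simulated PSF and add camera noise.

    Returns ``(clean, noisy)``: the noise-free expected photoelectron volume
    Ax, and the raw stack in DN.
    """
    truth = np.asarray(truth, dtype=float)
    if psf is None:
        psf = simulated_psf_cached(params, truth.shape)
    clean = convolve_psf(truth, psf)
    clean = np.maximum(clean, 0.0)  # clip FFT round-off below zero
    noisy = simulate_measurement(
        clean, noise, seed, dxy_nm=params.dxy_nm, dz_nm=params.dz_nm
    )
    return clean, noisy
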
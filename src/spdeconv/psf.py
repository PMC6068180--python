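"""Widefield microscope PSF simulation via the generalized-aperture (Debye) model.

The in-focus amplitude PSF (APSF) of a high-NA, Abbe-sine-corrected objective
is computed by numerical quadrature of the Debye diffraction integral

    h_A(r) = ∫_0^α sqrt(cos φ) J0(2π k sin(φ) r) sin(φ) dφ,

with α = asin(NA/n) the aperture half-angle and k = n/λ the wavenumber in the
immersion medium.  The amplitude transfer function (ATF) is the inverse
Fourier transform of the APSF; defocus by z is a pure phase factor on the ATF
(Hanser's "defocus ATF", valid beyond the paraxial regime).  The intensity PSF
at each axial offset is the squared modulus of the refocused field, evaluated
on a laterally supersampled grid, box-averaged down to the sensor pixel pitch,
and finally normalized so each xy-slice sums to one (one camera exposure per
focal slice captures the full photon flux of a point emitter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.fft import fft2, fftfreq, fftshift, ifft2, ifftshift
from scipy.special import j0

__all__ = [
    "OpticalParams",
    "PSFStack",
    "apsf_infocus",
    "atf_from_apsf",
    "apsf_from_atf",
    "defocus_factor",
    "simulate_psf",
    "lateral_freqs",
    "default_z_offsets",
]


@dataclass(frozen=True)
class OpticalParams:
    """Optical configuration of the widefield system.

    All lengths are in nanometres in object space (the camera pixel pitch
    divided by the system magnification).  ``magnification`` and ``f_obj_mm``
    are informational only; the constant prefactor T/(f_obj^2 λ^2) of the
    diffraction integral is dropped because the PSF is normalized per-slice.
    """

    na: float
    n_immersion: float
    wavelength_nm: float
    dxy_nm: float
    dz_nm: float
    oversample: int = 4
    magnification: float | None = None
    f_obj_mm: float | None = None
    quad_nodes: int = 256

    def __post_init__(self) -> None:
        if not (0.0 < self.na < self.n_immersion):
            raise ValueError(
                f"need 0 < NA < n (got NA={self.na}, n={self.n_immersion}); "
                "the aperture half-angle asin(NA/n) must be defined"
            )
        for name in ("wavelength_nm", "dxy_nm", "dz_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.oversample < 1:
            raise ValueError("oversample must be a positive integer")
        if self.quad_nodes < 2:
            raise ValueError("quad_nodes must be >= 2")

    @property
    def alpha(self) -> float:
        """Aperture half-angle asin(NA/n), radians."""
        return float(np.arcsin(self.na / self.n_immersion))

    @property
    def wavenumber(self) -> float:
        """k = n/λ in cycles per nm."""
        return self.n_immersion / self.wavelength_nm

    @property
    def pupil_radius(self) -> float:
        """Pupil band limit NA/λ in cycles per nm."""
        return self.na / self.wavelength_nm


@dataclass
class PSFStack:
    """3D intensity PSF sampled at the sensor pitch, axis order (z, y, x)."""

    values: np.ndarray
    z_offsets_nm: np.ndarray
    normalized: bool
    dxy_nm: float | None = None
    dz_nm: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.z_offsets_nm = np.asarray(self.z_offsets_nm, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("PSF stack must be 3D (z, y, x)")
        if len(self.z_offsets_nm) != self.values.shape[0]:
            raise ValueError("z_offsets_nm length must match number of slices")
        if np.any(self.values < 0):
            raise ValueError("PSF values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def normalize(self) -> "PSFStack":
        """Return a copy with every xy-slice scaled to unit sum."""
        sums = self.values.sum(axis=(1, 2), keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("cannot normalize a PSF slice with non-positive sum")
        return PSFStack(
            values=self.values / sums,
            z_offsets_nm=self.z_offsets_nm,
            normalized=True,
            dxy_nm=self.dxy_nm,
            dz_nm=self.dz_nm,
        )


def default_z_offsets(nz: int, dz_nm: float) -> np.ndarray:
    """Axial offsets (i - nz//2) * dz, centered on the focal plane."""
    return (np.arange(nz) - nz // 2) * float(dz_nm)


def apsf_infocus(params: OpticalParams, r_nm: np.ndarray) -> np.ndarray:
    """In-focus amplitude PSF on a radial-coordinate field (nm).

    Composite-trapezoid quadrature of the Debye integral over φ ∈ [0, α] with
    ``params.quad_nodes`` nodes.  The integrand is real, so the returned
    complex field has zero imaginary part; the constant prefactor of the
    diffraction integral is omitted.  Exact radial symmetry is guaranteed by
    evaluating on the unique radii of the input field.
    """
    r = np.asarray(r_nm, dtype=float)
    phi = np.linspace(0.0, params.alpha, params.quad_nodes)
    w = np.full(params.quad_nodes, phi[1] - phi[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    amp = np.sqrt(np.cos(phi)) * np.sin(phi) * w

    r_unique, inverse = np.unique(r.ravel(), return_inverse=True)
    acc = np.zeros_like(r_unique)
    two_pi_k = 2.0 * np.pi * params.wavenumber
    for a, p in zip(amp, phi):
        acc += a * j0(two_pi_k * np.sin(p) * r_unique)
    out = acc[inverse].reshape(r.shape)
    return out.astype(complex)


def lateral_freqs(n: int, pitch_nm: float) -> np.ndarray:
    """Centered frequency coordinates (cycles/nm) for an n-sample axis."""
    return fftshift(fftfreq(n, d=pitch_nm))


def atf_from_apsf(apsf: np.ndarray, pitch_nm: float) -> np.ndarray:
    """Amplitude transfer function H(u, v) from a centered APSF field.

    Back-propagation from the image plane to the pupil is an inverse Fourier
    transform; the result is scaled as a Riemann-sum approximation of the
    continuous transform so that Parseval's identity holds with the physical
    cell areas (sum |H|^2 ΔuΔv = sum |h|^2 ΔxΔy).  Frequencies follow
    :func:`lateral_freqs`; the support is confined (up to numerical leakage)
    to the pupil disk u^2 + v^2 <= (NA/λ)^2.
    """
    apsf = np.asarray(apsf)
    n_total = apsf.size
    cell_area = pitch_nm * pitch_nm
    return fftshift(ifft2(ifftshift(apsf))) * (n_total * cell_area)


def apsf_from_atf(atf: np.ndarray, pitch_nm: float) -> np.ndarray:
    """Inverse of :func:`atf_from_apsf` (propagate pupil field to the image)."""
    atf = np.asarray(atf)
    n_total = atf.size
    cell_area = pitch_nm * pitch_nm
    return fftshift(fft2(ifftshift(atf))) / (n_total * cell_area)


def defocus_factor(
    u: np.ndarray | float,
    v: np.ndarray | float,
    z_nm: float,
    params: OpticalParams,
) -> np.ndarray | complex:
    """Defocus phase factor exp{-i 2π z sqrt(k² - (NA/λ)²(u² + v²))}.

    ``(u, v)`` are pupil coordinates normalized so that the pupil edge lies on
    the unit circle (physical frequency = (NA/λ)·(u, v)).  Outside the
    propagating band, where the radicand is negative, the evanescent
    components are discarded and the factor is defined as 0.  Inside the band
    the factor has unit modulus.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    radicand = params.wavenumber**2 - params.pupil_radius**2 * (u * u + v * v)
    inside = radicand >= 0.0
    root = np.sqrt(np.where(inside, radicand, 0.0))
    out = np.where(inside, np.exp(-1j * 2.0 * np.pi * z_nm * root), 0.0 + 0.0j)
    if out.ndim == 0:
        return complex(out)
    return out


def simulate_psf(
    params: OpticalParams,
    shape: tuple[int, int, int],
    z_offsets_nm: Sequence[float] | None = None,
) -> PSFStack:
    """Simulate the depth-invariant 3D intensity PSF.

    For each axial offset z the pupil field H·D(·,·,z) is propagated to the
    image plane, squared in modulus on a grid ``params.oversample`` times
    finer than the sensor pitch, box-averaged to the sensor pitch (pixel
    integration), and each xy-slice is normalized to unit sum.  The PSF peak
    sits at the array center voxel (nz//2, ny//2, nx//2).
    """
    nz, ny, nx = shape
    if nz <= 0 or ny <= 0 or nx <= 0:
        raise ValueError("PSF shape dims must be positive")
    if z_offsets_nm is None:
        z_offsets_nm = default_z_offsets(nz, params.dz_nm)
    z_offsets_nm = np.asarray(z_offsets_nm, dtype=float)
    if len(z_offsets_nm) != nz:
        raise ValueError("z_offsets_nm must have one entry per z slice")

    os_ = params.oversample
    fine_pitch = params.dxy_nm / os_
    # the supersampled grid must resolve the pupil band limit
    if 0.5 / fine_pitch <= params.pupil_radius:
        raise ValueError(
            "lateral sampling too coarse for the pupil support; "
            "increase oversample or decrease dxy_nm"
        )
    nyf, nxf = ny * os_, nx * os_

    # sub-samples sit symmetrically inside each sensor pixel (pixel i covers
    # offsets ((m+0.5)/os - 0.5)·dxy around its center (i - n//2)·dxy), so
    # box-averaging preserves the radial symmetry of the field exactly
    yc = ((np.arange(nyf) + 0.5) / os_ - 0.5 - ny // 2) * params.dxy_nm
    xc = ((np.arange(nxf) + 0.5) / os_ - 0.5 - nx // 2) * params.dxy_nm
    r = np.hypot(yc[:, None], xc[None, :])
    apsf = apsf_infocus(params, r)
    atf = atf_from_apsf(apsf, fine_pitch)

    fu = lateral_freqs(nxf, fine_pitch) / params.pupil_radius
    fv = lateral_freqs(nyf, fine_pitch) / params.pupil_radius
    uu, vv = np.meshgrid(fu, fv)

    cell_area = fine_pitch * fine_pitch
    n_total = atf.size
    slices = np.empty((nz, ny, nx), dtype=float)
    for iz, z in enumerate(z_offsets_nm):
        d = defocus_factor(uu, vv, float(z), params)
        field = fftshift(fft2(ifftshift(atf * d))) / (n_total * cell_area)
        intensity = np.abs(field) ** 2
        binned = intensity.reshape(ny, os_, nx, os_).mean(axis=(1, 3))
        slices[iz] = binned

    stack = PSFStack(
        values=slices,
        z_offsets_nm=z_offsets_nm,
        normalized=False,
        dxy_nm=params.dxy_nm,
        dz_nm=params.dz_nm,
    )
    return stack.normalize()
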
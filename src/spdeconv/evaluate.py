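"""Reconstruction-quality metrics and regularization-weight tuning.

SNR against a known ground truth is 10·log10(‖x_true‖₂² / MSE) in dB, with
MSE the mean squared error between reconstruction and truth.  NMSE against a
reference with a different intensity scale first fits an affine map
a·x̂ + b to the reference (derivative-free adaptive Nelder-Mead simplex,
seeded at the closed-form least-squares solution) and divides the residual
by ‖reference‖₂².  The regularization weight ν is tuned by golden-section
search, by default over log10(ν).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.signal import find_peaks

__all__ = [
    "snr_db",
    "nmse_affine",
    "line_profile",
    "peak_separation",
    "tune_nu_golden",
]


def snr_db(x_hat: np.ndarray, x_true: np.ndarray) -> float:
    """10·log10(‖x_true‖₂² / MSE(x_hat, x_true)) in dB; +inf on exact match."""
    x_hat = np.asarray(x_hat, dtype=float)
    x_true = np.asarray(x_true, dtype=float)
    if x_hat.shape != x_true.shape:
        raise ValueError("shapes must match")
    mse = float(np.mean((x_hat - x_true) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(np.sum(x_true**2) / mse))


def nmse_affine(
    x_hat: np.ndarray, reference: np.ndarray
) -> tuple[float, float, float]:
    """Minimize ‖a·x̂ + b − ref‖² over (a, b); return (nmse, a, b).

    The simplex search is initialized at the closed-form least-squares affine
    fit, and the minimum is normalized by ‖reference‖₂².
    """
    x = np.asarray(x_hat, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if x.shape != r.shape:
        raise ValueError("shapes must match")
    ref_energy = float(np.sum(r * r))
    if np.ptp(r) == 0.0 or ref_energy == 0.0:
        raise ValueError("reference is constant; NMSE normalization undefined")

    design = np.stack([x, np.ones_like(x)], axis=1)
    (a0, b0), *_ = np.linalg.lstsq(design, r, rcond=None)

    def cost(p: np.ndarray) -> float:
        d = p[0] * x + p[1] - r
        return float(d @ d)

    res = minimize(
        cost,
        np.array([a0, b0]),
        method="Nelder-Mead",
        options={"adaptive": True, "xatol": 1e-10, "fatol": 1e-12},
    )
    a, b = res.x
    return float(res.fun / ref_energy), float(a), float(b)


def line_profile(
    volume: np.ndarray,
    axis: int,
    through: tuple[int, int, int],
    normalize: bool = False,
) -> np.ndarray:
    """1D intensity profile along ``axis`` through the voxel ``through``."""
    volume = np.asarray(volume)
    if not all(0 <= i < n for i, n in zip(through, volume.shape)):
        raise IndexError(f"point {through} outside volume of shape {volume.shape}")
    idx = list(through)
    idx[axis] = slice(None)
    profile = np.asarray(volume[tuple(idx)], dtype=float)
    if normalize:
        peak = profile.max()
        if peak <= 0:
            raise ValueError("cannot normalize a non-positive profile")
        profile = profile / peak
    return profile


def peak_separation(profile: np.ndarray) -> float:
    """Distance in samples between the two most prominent peaks of a profile.

    Falls back to the argmax of each half when fewer than two interior peaks
    exist (e.g. peaks lying on the profile ends).
    """
    profile = np.asarray(profile, dtype=float)
    peaks, props = find_peaks(profile, prominence=0.0)
    if len(peaks) >= 2:
        order = np.argsort(props["prominences"])[::-1]
        p = np.sort(peaks[order[:2]])
        return float(p[1] - p[0])
    mid = len(profile) // 2
    left = int(np.argmax(profile[:mid]))
    right = mid + int(np.argmax(profile[mid:]))
    return float(right - left)


_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def tune_nu_golden(
    objective: Callable[[float], float],
    bracket: tuple[float, float],
    tol: float = 1e-5,
    log_scale: bool = True,
    maximize: bool = False,
) -> tuple[float, float]:
    """Golden-section search for the best regularization weight ν.

    The interval is shrunk until its width (in the search coordinate —
    log10(ν) by default) is below ``tol``.  A monotone objective drives the
    interval to the corresponding bracket endpoint.  Returns (ν*, objective).
    """
    lo, hi = bracket
    if lo <= 0 or hi <= 0:
        raise ValueError("bracket endpoints must be positive")
    if lo > hi:
        lo, hi = hi, lo

    to_x = (lambda v: float(np.log10(v))) if log_scale else float
    from_x = (lambda t: float(10.0**t)) if log_scale else float
    sign = -1.0 if maximize else 1.0

    a, b = to_x(lo), to_x(hi)
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc = sign * objective(from_x(c))
    fd = sign * objective(from_x(d))
    while (b - a) > tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = sign * objective(from_x(c))
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = sign * objective(from_x(d))
    x_best, f_best = (c, fc) if fc <= fd else (d, fd)
    return from_x(x_best), sign * f_best
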
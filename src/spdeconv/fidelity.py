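"""Data-fidelity terms and their proximal operators.

Each fidelity is the negative log-likelihood of the gain-normalized
measurement ỹ given model intensities v = Ax, restricted to the measured
region C of the (possibly expanded) reconstruction grid:

    shifted Poisson:  Σ_C  v_j − (ỹ_j + σ̃²) log(v_j + σ̃²)
    Poisson:          the same with σ̃ = 0
    Gaussian:         ½ Σ_C (v_j − ỹ_j)²

Voxels outside C (the undetermined boundary margin) are never constrained by
the data: their prox is the identity.

The shifted-Poisson prox solves, per voxel, the stationarity condition of
ℓ_j(v) + (ρ/2)(v − u)², which in w = v + σ̃² is the quadratic
ρw² + (1 − ρ(u + σ̃²))w − t = 0 with t = ỹ + σ̃².  The positive root keeps
v + σ̃² > 0 without any epsilon in the log; it is evaluated in a
cancellation-free form (larger-magnitude root first, the other via the
product of roots).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoundarySpec",
    "nll_shifted_poisson",
    "prox_shifted_poisson",
    "nll_poisson",
    "prox_poisson",
    "nll_gaussian",
    "prox_gaussian",
    "get_fidelity",
    "FIDELITIES",
]


@dataclass(frozen=True)
class BoundarySpec:
    """Mapping between the measured stack and the expanded reconstruction grid.

    ``margins`` holds per-axis (low, high) voxel counts appended around the
    measured shape; the measured region C is the central slab of the
    reconstruction grid that maps one-to-one onto the measurement.
    """

    measured_shape: tuple[int, int, int]
    margins: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.measured_shape) != 3 or len(self.margins) != 3:
            raise ValueError("BoundarySpec is 3D")
        for (lo, hi), m in zip(self.margins, self.measured_shape):
            if lo < 0 or hi < 0 or m <= 0:
                raise ValueError("margins must be >= 0 and measured dims > 0")

    @classmethod
    def zero(cls, measured_shape: tuple[int, int, int]) -> "BoundarySpec":
        return cls(tuple(measured_shape), ((0, 0), (0, 0), (0, 0)))

    @property
    def recon_shape(self) -> tuple[int, int, int]:
        return tuple(
            m + lo + hi for m, (lo, hi) in zip(self.measured_shape, self.margins)
        )

    @property
    def region(self) -> tuple[slice, slice, slice]:
        """Slices selecting the measured region C inside the recon grid."""
        return tuple(
            slice(lo, lo + m) for m, (lo, _) in zip(self.measured_shape, self.margins)
        )

    @property
    def n_measured(self) -> int:
        return int(np.prod(self.measured_shape))


def _shifted_rate(y_norm: np.ndarray, sigma_norm: float) -> np.ndarray:
    """Observed shifted-Poisson counts ỹ + σ̃², clamped at 0.

    Read noise can push a raw measurement below −σ̃²; a negative count has no
    likelihood under the surrogate model, so it is treated as zero.
    """
    y = np.asarray(y_norm)
    if not np.issubdtype(y.dtype, np.floating):
        y = y.astype(float)
    return np.maximum(y + sigma_norm**2, 0.0)


def nll_shifted_poisson(
    v: np.ndarray, y_norm: np.ndarray, sigma_norm: float
) -> float:
    """Shifted-Poisson negative log-likelihood Σ v − (ỹ+σ̃²) log(v+σ̃²)."""
    v = np.asarray(v, dtype=float)
    s = sigma_norm**2
    t = _shifted_rate(y_norm, sigma_norm)
    w = v + s
    if np.any(w <= 0):
        # outside the domain of the log; +inf by convention (t = 0 voxels
        # only need v + s >= 0)
        if np.any(w[t > 0] <= 0) or np.any(w < 0):
            return float("inf")
    out = np.sum(v)
    pos = t > 0
    out -= np.sum(t[pos] * np.log(w[pos]))
    return float(out)


def prox_shifted_poisson(
    u: np.ndarray,
    y_norm: np.ndarray,
    sigma_norm: float,
    rho: float,
    region: BoundarySpec | None = None,
) -> np.ndarray:
    """Prox of the shifted-Poisson NLL with penalty ρ; identity outside C."""
    if rho <= 0:
        raise ValueError("rho must be > 0")
    u = np.asarray(u)
    if not np.issubdtype(u.dtype, np.floating):
        u = u.astype(float)
    if region is None:
        return _prox_sp_core(u, y_norm, sigma_norm, rho)
    out = u.copy()
    sl = region.region
    out[sl] = _prox_sp_core(u[sl], np.asarray(y_norm), sigma_norm, rho)
    return out


def _prox_sp_core(
    u: np.ndarray, y_norm: np.ndarray, sigma_norm: float, rho: float
) -> np.ndarray:
    s = sigma_norm**2
    t = _shifted_rate(y_norm, sigma_norm)
    b = rho * (u + s) - 1.0
    disc = np.sqrt(b * b + 4.0 * rho * t)
    # larger root of rho*w^2 - b*w - t = 0, stable for either sign of b
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(b >= 0.0, (b + disc) / (2.0 * rho), 2.0 * t / (disc - b))
    w = np.where(t == 0.0, np.maximum(b, 0.0) / rho, w)
    return w - s


def nll_poisson(v: np.ndarray, y_norm: np.ndarray) -> float:
    return nll_shifted_poisson(v, y_norm, 0.0)


def prox_poisson(
    u: np.ndarray,
    y_norm: np.ndarray,
    rho: float,
    region: BoundarySpec | None = None,
) -> np.ndarray:
    return prox_shifted_poisson(u, y_norm, 0.0, rho, region)


def nll_gaussian(v: np.ndarray, y_norm: np.ndarray) -> float:
    d = np.asarray(v, dtype=float) - np.asarray(y_norm, dtype=float)
    return float(0.5 * np.sum(d * d))


def prox_gaussian(
    u: np.ndarray,
    y_norm: np.ndarray,
    rho: float,
    region: BoundarySpec | None = None,
) -> np.ndarray:
    if rho <= 0:
        raise ValueError("rho must be > 0")
    u = np.asarray(u, dtype=float)
    y = np.asarray(y_norm, dtype=float)
    if region is None:
        return (rho * u + y) / (rho + 1.0)
    out = u.copy()
    sl = region.region
    out[sl] = (rho * u[sl] + y) / (rho + 1.0)
    return out


class _Fidelity:
    """Uniform (nll, prox) surface over a choice of noise model."""

    def __init__(self, name: str):
        if name not in ("gaussian", "poisson", "shifted_poisson"):
            raise ValueError(f"unknown fidelity {name!r}")
        self.name = name

    def nll(self, v: np.ndarray, y_norm: np.ndarray, sigma_norm: float) -> float:
        if self.name == "gaussian":
            return nll_gaussian(v, y_norm)
        if self.name == "poisson":
            return nll_poisson(v, y_norm)
        return nll_shifted_poisson(v, y_norm, sigma_norm)

    def prox(
        self,
        u: np.ndarray,
        y_norm: np.ndarray,
        sigma_norm: float,
        rho: float,
        region: BoundarySpec | None = None,
    ) -> np.ndarray:
        if self.name == "gaussian":
            return prox_gaussian(u, y_norm, rho, region)
        if self.name == "poisson":
            return prox_poisson(u, y_norm, rho, region)
        return prox_shifted_poisson(u, y_norm, sigma_norm, rho, region)


FIDELITIES = ("gaussian", "poisson", "shifted_poisson")


def get_fidelity(name: str) -> _Fidelity:
    return _Fidelity(name)
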
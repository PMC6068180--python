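"""Regularization penalties, linear operators, and proximal operators.

The primary penalty is the Frobenius norm of the discrete 3D Hessian,
R(x) = Σ_j ‖H_j x‖_F, a Schatten-Hessian norm that promotes piecewise-smooth
volumes: it vanishes on affine intensity ramps, so gradual intensity changes
across biological structures are not penalized the way total variation
penalizes them.  Comparison penalties: squared ℓ2 (Tikhonov), squared ℓ2 of
a Laplacian-filtered volume, ℓ1 (Lasso), and isotropic 3D total variation.

Conventions
-----------
* Finite differences are forward differences with replicate (Neumann)
  boundaries; the adjoints are the exact transposes of those operators.
* A Hessian field is stored as a (6, nz, ny, nx) array with component order
  (xx, yy, zz, xy, xz, yz), where x is the last array axis.  The mixed
  components carry a factor √2 inside the operator so the plain Euclidean
  norm of the 6-vector equals the matrix Frobenius norm (mixed entries of
  the symmetric Hessian appear twice).
* No anisotropic weighting of the components is applied even when the axial
  pitch differs from the lateral pitch.
* For the FFT-diagonal solver update, each operator exposes the periodic
  transfer function of GᵀG; the replicate/periodic mismatch at the volume
  edge is absorbed by the ADMM splitting.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "HESSIAN_COMPONENTS",
    "forward_diff",
    "forward_diff_adjoint",
    "hessian_apply",
    "hessian_adjoint",
    "fh_penalty",
    "prox_frobenius_hessian",
    "grad_apply",
    "grad_adjoint",
    "tv_penalty",
    "prox_tv_group",
    "prox_l1",
    "l1_penalty",
    "l2_penalty",
    "laplacian_apply",
    "laplacian_penalty",
    "axis_transfer",
    "get_regularizer",
    "REGULARIZERS",
]

# x = last axis (2), y = axis 1, z = axis 0
_AXIS = {"x": 2, "y": 1, "z": 0}
HESSIAN_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")
_SQRT2 = np.sqrt(2.0)


def forward_diff(x: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference with replicate boundary (last difference is 0)."""
    d = np.zeros_like(x)
    sl_lo = [slice(None)] * x.ndim
    sl_hi = [slice(None)] * x.ndim
    sl_lo[axis] = slice(0, -1)
    sl_hi[axis] = slice(1, None)
    d[tuple(sl_lo)] = x[tuple(sl_hi)] - x[tuple(sl_lo)]
    return d


def forward_diff_adjoint(y: np.ndarray, axis: int) -> np.ndarray:
    """Exact transpose of :func:`forward_diff`."""
    out = np.zeros_like(y)
    n = y.shape[axis]
    idx = lambda s: tuple(s if a == axis else slice(None) for a in range(y.ndim))
    out[idx(slice(0, 1))] = -y[idx(slice(0, 1))]
    if n > 1:
        out[idx(slice(1, n - 1))] = (
            y[idx(slice(0, n - 2))] - y[idx(slice(1, n - 1))]
        )
        out[idx(slice(n - 1, n))] += y[idx(slice(n - 2, n - 1))]
    return out


def _as_float(x: np.ndarray) -> np.ndarray:
    """Pass floats through untouched (preserving float32), cast ints to float64."""
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    return x


def hessian_apply(x: np.ndarray) -> np.ndarray:
    """Discrete Hessian field, shape (6,) + x.shape, order HESSIAN_COMPONENTS.

    Pure terms are twice-applied forward differences along one axis; mixed
    terms are forward differences along the two axes, scaled by √2.
    """
    x = _as_float(x)
    dx = forward_diff(x, _AXIS["x"])
    dy = forward_diff(x, _AXIS["y"])
    dz = forward_diff(x, _AXIS["z"])
    out = np.empty((6,) + x.shape, dtype=x.dtype)
    out[0] = forward_diff(dx, _AXIS["x"])  # xx
    out[1] = forward_diff(dy, _AXIS["y"])  # yy
    out[2] = forward_diff(dz, _AXIS["z"])  # zz
    out[3] = _SQRT2 * forward_diff(dx, _AXIS["y"])  # xy
    out[4] = _SQRT2 * forward_diff(dx, _AXIS["z"])  # xz
    out[5] = _SQRT2 * forward_diff(dy, _AXIS["z"])  # yz
    return out


def hessian_adjoint(Y: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`hessian_apply` (same √2 mixed-term weighting)."""
    Y = _as_float(Y)
    ax, ay, az = _AXIS["x"], _AXIS["y"], _AXIS["z"]
    out = forward_diff_adjoint(forward_diff_adjoint(Y[0], ax), ax)
    out += forward_diff_adjoint(forward_diff_adjoint(Y[1], ay), ay)
    out += forward_diff_adjoint(forward_diff_adjoint(Y[2], az), az)
    out += _SQRT2 * forward_diff_adjoint(forward_diff_adjoint(Y[3], ay), ax)
    out += _SQRT2 * forward_diff_adjoint(forward_diff_adjoint(Y[4], az), ax)
    out += _SQRT2 * forward_diff_adjoint(forward_diff_adjoint(Y[5], az), ay)
    return out


def _group_norm(Y: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(Y * Y, axis=0))


def _group_shrink(Y: np.ndarray, tau: float) -> np.ndarray:
    """Per-voxel group soft-threshold Y · max(1 − τ/‖Y‖, 0); 0 stays 0."""
    if tau < 0:
        raise ValueError("threshold must be >= 0")
    norm = _group_norm(Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norm > 0.0, np.maximum(1.0 - tau / norm, 0.0), 0.0)
    return Y * scale


def fh_penalty(x_or_field: np.ndarray) -> float:
    """Σ_j ‖H_j x‖_F (accepts a volume or a precomputed Hessian field)."""
    Y = x_or_field if x_or_field.ndim == 4 else hessian_apply(x_or_field)
    return float(np.sum(_group_norm(Y)))


def prox_frobenius_hessian(Y: np.ndarray, threshold: float) -> np.ndarray:
    return _group_shrink(_as_float(Y), threshold)


def grad_apply(x: np.ndarray) -> np.ndarray:
    """Forward-difference gradient field, shape (3,) + x.shape, order (x, y, z)."""
    x = _as_float(x)
    return np.stack(
        [forward_diff(x, _AXIS["x"]), forward_diff(x, _AXIS["y"]), forward_diff(x, _AXIS["z"])]
    )


def grad_adjoint(G: np.ndarray) -> np.ndarray:
    G = _as_float(G)
    return (
        forward_diff_adjoint(G[0], _AXIS["x"])
        + forward_diff_adjoint(G[1], _AXIS["y"])
        + forward_diff_adjoint(G[2], _AXIS["z"])
    )


def tv_penalty(x_or_field: np.ndarray) -> float:
    """Isotropic 3D total variation Σ_j ‖(∇x)_j‖₂."""
    G = x_or_field if x_or_field.ndim == 4 else grad_apply(x_or_field)
    return float(np.sum(_group_norm(G)))


def prox_tv_group(G: np.ndarray, tau: float) -> np.ndarray:
    return _group_shrink(_as_float(G), tau)


def prox_l1(u: np.ndarray, tau: float) -> np.ndarray:
    """Soft threshold sign(u)·max(|u|−τ, 0)."""
    if tau < 0:
        raise ValueError("threshold must be >= 0")
    u = _as_float(u)
    return np.sign(u) * np.maximum(np.abs(u) - tau, 0.0)


def l1_penalty(x: np.ndarray) -> float:
    return float(np.sum(np.abs(x)))


def l2_penalty(x: np.ndarray) -> float:
    """Squared ℓ2 norm ‖x‖₂² (Tikhonov)."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * x))


def laplacian_apply(x: np.ndarray) -> np.ndarray:
    """7-point 3D Laplacian with replicate boundaries (sum of second diffs)."""
    x = _as_float(x)
    out = np.zeros_like(x)
    for a in range(3):
        out += forward_diff_adjoint(forward_diff(x, a), a)
    return -out  # DᵀD = −L for the replicate-BC Laplacian


def laplacian_penalty(x: np.ndarray) -> float:
    """Squared ℓ2 norm of the Laplacian-filtered volume ‖Lx‖₂²."""
    lx = laplacian_apply(x)
    return float(np.sum(lx * lx))


def axis_transfer(n: int, dtype=float) -> np.ndarray:
    """|exp(−2πi f) − 1|² = (2 sin(π f))² for the n-point periodic forward diff."""
    f = np.fft.fftfreq(n)
    return (2.0 * np.sin(np.pi * f)).astype(dtype) ** 2


def _sum_axis_transfers(shape: tuple[int, int, int], rfft_last: bool) -> np.ndarray:
    nz, ny, nx = shape
    pz = axis_transfer(nz)[:, None, None]
    py = axis_transfer(ny)[None, :, None]
    px = axis_transfer(nx)
    if rfft_last:
        px = px[: nx // 2 + 1]
    return pz + py + px[None, None, :]


class _Regularizer:
    """Uniform surface over the regularizer choices.

    ``kind`` is "prox" (handled by an ADMM split with a proximal operator on
    the operator image), "quad" (a quadratic penalty folded directly into the
    Fourier-diagonal x-update), or "none".
    """

    name: str
    kind: str

    def penalty(self, x: np.ndarray) -> float:
        raise NotImplementedError

    # prox-kind interface
    def apply(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def adjoint(self, Y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def prox(self, Y: np.ndarray, tau: float) -> np.ndarray:
        raise NotImplementedError

    def transfer(self, shape, rfft_last: bool = True) -> np.ndarray:
        """Periodic transfer function of GᵀG for the x-update denominator."""
        raise NotImplementedError


class _NoReg(_Regularizer):
    name, kind = "none", "none"

    def penalty(self, x):
        return 0.0


class _FH(_Regularizer):
    name, kind = "fh", "prox"
    penalty = staticmethod(fh_penalty)
    apply = staticmethod(hessian_apply)
    adjoint = staticmethod(hessian_adjoint)
    prox = staticmethod(prox_frobenius_hessian)

    def transfer(self, shape, rfft_last=True):
        # Σ pure |Da|⁴ + 2 Σ mixed |Da Db|² = (px + py + pz)²
        return _sum_axis_transfers(shape, rfft_last) ** 2


class _TV(_Regularizer):
    name, kind = "tv", "prox"
    penalty = staticmethod(tv_penalty)
    apply = staticmethod(grad_apply)
    adjoint = staticmethod(grad_adjoint)
    prox = staticmethod(prox_tv_group)

    def transfer(self, shape, rfft_last=True):
        return _sum_axis_transfers(shape, rfft_last)


class _L1(_Regularizer):
    name, kind = "l1", "prox"
    penalty = staticmethod(l1_penalty)

    def apply(self, x):
        return _as_float(x).copy()

    def adjoint(self, Y):
        return _as_float(Y).copy()

    prox = staticmethod(prox_l1)

    def transfer(self, shape, rfft_last=True):
        nz, ny, nx = shape
        nxr = nx // 2 + 1 if rfft_last else nx
        return np.ones((nz, ny, nxr))


class _L2(_Regularizer):
    name, kind = "l2", "quad"
    penalty = staticmethod(l2_penalty)

    def transfer(self, shape, rfft_last=True):
        nz, ny, nx = shape
        nxr = nx // 2 + 1 if rfft_last else nx
        return np.ones((nz, ny, nxr))


class _Laplacian(_Regularizer):
    name, kind = "laplacian", "quad"
    penalty = staticmethod(laplacian_penalty)

    def transfer(self, shape, rfft_last=True):
        return _sum_axis_transfers(shape, rfft_last) ** 2


REGULARIZERS = {
    "none": _NoReg(),
    "fh": _FH(),
    "tv": _TV(),
    "l1": _L1(),
    "l2": _L2(),
    "laplacian": _Laplacian(),
}


def get_regularizer(name: str) -> _Regularizer:
    try:
        return REGULARIZERS[name]
    except KeyError:
        raise ValueError(
            f"unknown regularizer {name!r}; choose from {sorted(REGULARIZERS)}"
        ) from None
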
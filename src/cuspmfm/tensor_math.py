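"""Symmetric positive-definite (SPD) tensor algebra.

Diffusion tensors are represented as plain symmetric 3x3 ``numpy`` arrays in
units of mm^2/s.  Optimization and regularization operate on the matrix
logarithm of the tensor (the *log-Euclidean* frame), where the set of SPD
matrices maps to the unconstrained vector space of symmetric matrices: any
symmetric matrix exponentiates back to a valid, non-degenerate tensor, so no
eigenvalue clamping is ever required.

Orientations use intrinsic z-y-z Euler angles ``(psi, theta, phi)``:
``R = Rz(psi) @ Ry(theta) @ Rz(phi)``.  The principal axis of a tensor built
from angles ``(psi, theta, .)`` is ``(cos psi sin theta, sin psi sin theta,
cos theta)``; restricting ``theta`` to ``[0, pi/2]`` (upper hemisphere) makes
the axial parameterization unique, since diffusion is antipodally symmetric.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "SPD_EIG_FLOOR",
    "is_spd",
    "matrix_log_spd",
    "matrix_exp_sym",
    "logeuclid_distance",
    "cylindrical_from_fa_trace",
    "cylindrical_tensor",
    "ScalarMeasures",
    "scalar_measures",
    "euler_rotation",
    "orientation_to_tensor",
    "tensor_to_orientation",
    "axis_from_angles",
    "principal_axis",
    "axial_angle_deg",
]

# Eigenvalues at or below this are treated as degenerate, not clamped.
SPD_EIG_FLOOR = 1e-12

_SYM_TOL = 1e-10


def _as_sym(m: np.ndarray, name: str = "matrix") -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"{name} must be 3x3, got shape {m.shape}")
    if np.max(np.abs(m - m.T)) > _SYM_TOL:
        raise ValueError(f"{name} is not symmetric")
    return 0.5 * (m + m.T)


def is_spd(m: np.ndarray) -> bool:
    """True if ``m`` is symmetric with all eigenvalues above ``SPD_EIG_FLOOR``."""
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3) or np.max(np.abs(m - m.T)) > _SYM_TOL:
        return False
    return bool(np.linalg.eigvalsh(0.5 * (m + m.T)).min() > SPD_EIG_FLOOR)


def matrix_log_spd(t: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD tensor via eigen-decomposition.

    Raises ``ValueError`` naming the offending eigenvalue if ``t`` is not SPD.
    """
    t = _as_sym(t, "tensor")
    w, v = np.linalg.eigh(t)
    if w.min() <= SPD_EIG_FLOOR:
        raise ValueError(f"tensor is not SPD: eigenvalue {w.min():.3e} <= {SPD_EIG_FLOOR:.0e}")
    return (v * np.log(w)) @ v.T


def matrix_exp_sym(l: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix; always returns an SPD tensor."""
    l = _as_sym(l, "log-tensor")
    w, v = np.linalg.eigh(l)
    return (v * np.exp(w)) @ v.T


def logeuclid_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Log-Euclidean distance: Frobenius norm of ``log(a) - log(b)``."""
    return float(np.linalg.norm(matrix_log_spd(a) - matrix_log_spd(b)))


def cylindrical_from_fa_trace(fa: float, trace: float) -> tuple[float, float, float]:
    """Eigenvalues ``(l_par, l_perp, l_perp)`` of the cylindrical tensor with
    the requested fractional anisotropy and trace.

    For a cylindrical tensor (two equal minor eigenvalues) the map
    (FA, trace) -> eigenvalues is invertible in closed form:

        l_par  = (trace/3) * (1 + 2 FA / sqrt(3 - 2 FA^2))
        l_perp = (trace/3) * (1 -   FA / sqrt(3 - 2 FA^2))
    """
    if not (0.0 <= fa < 1.0):
        raise ValueError(f"fa must be in [0, 1), got {fa}")
    if trace <= 0.0:
        raise ValueError(f"trace must be positive, got {trace}")
    m = trace / 3.0
    s = fa / np.sqrt(3.0 - 2.0 * fa * fa)
    return (m * (1.0 + 2.0 * s), m * (1.0 - s), m * (1.0 - s))


def cylindrical_tensor(axis: np.ndarray, l_par: float, l_perp: float) -> np.ndarray:
    """Cylindrical SPD tensor with principal axis ``axis`` (need not be unit)."""
    if l_par <= 0 or l_perp <= 0:
        raise ValueError("eigenvalues must be positive")
    n = np.asarray(axis, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValueError("axis must be non-zero")
    n = n / nn
    return l_perp * np.eye(3) + (l_par - l_perp) * np.outer(n, n)


class ScalarMeasures(NamedTuple):
    fa: float
    md: float
    ad: float
    rd: float


def scalar_measures(t: np.ndarray) -> ScalarMeasures:
    """Standard scalar summaries: FA, mean/axial/radial diffusivity."""
    t = _as_sym(t, "tensor")
    w = np.linalg.eigvalsh(t)
    if w.min() <= SPD_EIG_FLOOR:
        raise ValueError(f"tensor is not SPD: eigenvalue {w.min():.3e}")
    w = w[::-1]  # descending
    md = float(w.mean())
    num = np.sqrt(1.5) * np.linalg.norm(w - md)
    fa = float(num / np.linalg.norm(w))
    return ScalarMeasures(fa=fa, md=md, ad=float(w[0]), rd=float(0.5 * (w[1] + w[2])))


def euler_rotation(psi: float, theta: float, phi: float) -> np.ndarray:
    """Intrinsic z-y-z rotation matrix ``Rz(psi) @ Ry(theta) @ Rz(phi)``."""
    cp, sp = np.cos(psi), np.sin(psi)
    ct, st = np.cos(theta), np.sin(theta)
    cf, sf = np.cos(phi), np.sin(phi)
    rz1 = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
    rz2 = np.array([[cf, -sf, 0.0], [sf, cf, 0.0], [0.0, 0.0, 1.0]])
    return rz1 @ ry @ rz2


def axis_from_angles(psi: float, theta: float) -> np.ndarray:
    """Unit vector ``R(psi, theta, .) @ z`` — the principal axis direction."""
    st = np.sin(theta)
    return np.array([np.cos(psi) * st, np.sin(psi) * st, np.cos(theta)])


def orientation_to_tensor(angles: tuple[float, float, float],
                          eigenvalues: tuple[float, float, float]) -> np.ndarray:
    """SPD tensor ``R diag(eigenvalues) R^T`` with R from z-y-z Euler angles.

    Zero angles give ``diag(eigenvalues)`` exactly; the eigenvector of the
    first eigenvalue is the first column of R.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam <= 0):
        raise ValueError(f"eigenvalues must be positive, got {tuple(lam)}")
    r = euler_rotation(*angles)
    return (r * lam) @ r.T


def tensor_to_orientation(t: np.ndarray) -> tuple[tuple[float, float, float],
                                                  tuple[float, float, float]]:
    """Extract ``(angles, eigenvalues)`` such that ``orientation_to_tensor``
    reconstructs ``t``.  Eigenvalues come out descending; angles are bounded
    to ``psi, phi in [-pi, pi)``, ``theta in [0, pi/2]`` (the bounds that make
    the parameterization unique up to eigenvector sign symmetry).
    """
    t = _as_sym(t, "tensor")
    w, v = np.linalg.eigh(t)
    if w.min() <= SPD_EIG_FLOOR:
        raise ValueError(f"tensor is not SPD: eigenvalue {w.min():.3e}")
    w = w[::-1]
    v = v[:, ::-1]  # columns: descending eigenvalues
    r = np.array(v)
    if np.linalg.det(r) < 0:
        r[:, 2] = -r[:, 2]
    # tensor-preserving sign flip (two columns) to bring theta into [0, pi/2]
    if r[2, 2] < 0:
        r[:, 1] = -r[:, 1]
        r[:, 2] = -r[:, 2]
    ct = np.clip(r[2, 2], -1.0, 1.0)
    theta = float(np.arccos(ct))
    if np.sin(theta) > 1e-9:
        psi = float(np.arctan2(r[1, 2], r[0, 2]))
        phi = float(np.arctan2(r[2, 1], -r[2, 0]))
    else:  # gimbal: only psi + phi is determined
        psi = 0.0
        phi = float(np.arctan2(r[1, 0], r[0, 0]))
    if psi >= np.pi:
        psi -= 2 * np.pi
    if phi >= np.pi:
        phi -= 2 * np.pi
    return (psi, theta, phi), (float(w[0]), float(w[1]), float(w[2]))


def principal_axis(t: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue (sign: upper hemisphere)."""
    w, v = np.linalg.eigh(np.asarray(t, dtype=float))
    n = v[:, -1]
    nz = n[np.abs(n) > 1e-12]
    if nz.size and nz[-1] < 0:
        n = -n
    return n


def axial_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two axes, antipodally symmetric, in [0, 90]."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = abs(float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))
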
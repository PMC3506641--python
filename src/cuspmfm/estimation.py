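"""Maximum a posteriori estimation of the full multi-fascicle model.

The fit at each voxel proceeds through stages of gradually increasing model
complexity, each solved by a derivative-free bound-constrained optimizer:

1. robust log-linear least-squares one-tensor fit (initialization);
2. fascicle orientations + fractions with eigenvalues held fixed;
3. cylindrical eigenvalues added;
4. the full model including the free-water fraction.

Tensors are parameterized by Euler angles and eigenvalues, so every candidate
during optimization is symmetric positive definite by construction — no
eigenvalue clamping is needed anywhere.  Under the cylindrical constraint a
fascicle tensor has 4 free parameters (axis azimuth/inclination + two
eigenvalues); with the fraction simplex this gives ``5 N`` free parameters
for an ``N``-fascicle voxel.

The spatial prior couples, at each voxel and for each fascicle, the
log-tensor with its most similar neighbor on each side of every axis (a
finite-difference gradient that follows fascicles across voxels instead of
blindly averaging crossing fibers), fed through an edge-preserving penalty
``phi(s) = 2 sqrt(1 + s^2) - 2``.  The prior weight ``beta * alpha`` is
annealed over outer sweeps, low to high, so early sweeps explore and later
sweeps smooth.

Model order (1..3 fascicles) can be chosen per voxel by an ascending F-test
on nested residual sums of squares.

A warning is logged when fitting a full model to a single-shell acquisition:
with one non-zero b-value the tensor size and the compartment fractions are
collinear and the fit is not identifiable (see
:func:`cuspmfm.forward_model.gauge_transform`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .forward_model import FREE_WATER_DIFFUSIVITY, DWISignal, MFMVoxel, predict_values
from .gradients import GradientScheme
from .tensor_math import (
    axis_from_angles,
    cylindrical_tensor,
    is_spd,
    matrix_log_spd,
    orientation_to_tensor,
    tensor_to_orientation,
)

logger = logging.getLogger("cuspmfm")

__all__ = [
    "MFMField",
    "FitConfig",
    "UnderDeterminedError",
    "fit_single_tensor_ls",
    "initialize_mfm",
    "spatial_gradient_multitensor",
    "map_objective",
    "fit_voxel",
    "fit_field",
    "ftest_select",
    "n_free_parameters",
    "estimate_sigma",
]


class UnderDeterminedError(ValueError):
    """Raised when a scheme cannot determine the requested model."""


@dataclass
class MFMField:
    """3-D grid of fitted (or ground-truth) multi-fascicle voxels."""

    grid: np.ndarray  # object array of MFMVoxel (or None outside the mask)
    mask: np.ndarray  # bool, same shape

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    def voxels(self):
        """Iterate ``(index, MFMVoxel)`` over in-mask voxels in raster order."""
        for idx in np.ndindex(*self.grid.shape):
            if self.mask[idx]:
                yield idx, self.grid[idx]

    def validate(self) -> None:
        for _, v in self.voxels():
            v.validate()

    def log_tensors(self) -> np.ndarray:
        """Object array of per-voxel lists of fascicle log-tensors."""
        out = np.empty(self.grid.shape, dtype=object)
        for idx, v in self.voxels():
            out[idx] = [matrix_log_spd(d) for d in v.tensors]
        return out


@dataclass
class FitConfig:
    """Tunable parameters of the multi-fascicle fit."""

    max_fascicles: int = 2
    cylindrical: bool = True
    alpha: float = 1.0  # regularization strength
    K: float | None = None  # gradient normalization; None = median |grad L| of the one-tensor field
    beta_schedule: tuple[float, ...] | None = None  # None = linear 0..1 over n_sweeps
    n_sweeps: int = 5
    softmax_gamma: float | str = "exact-min"
    eigenvalue_bounds: tuple[float, float] = (1e-5, 9e-3)  # mm^2/s
    ftest_alpha: float = 0.05
    model_selection: bool = False
    d_iso: float = FREE_WATER_DIFFUSIVITY
    sigma: float | str | None = "estimate"
    seed: int = 0
    init_f_iso: float = 0.1
    init_shrink: float = 0.8
    optimizer: str = "powell"  # derivative-free stage optimizer; "cobyqa" also accepted
    stage_maxfev: tuple[int, int, int] = (300, 500, 600)
    n_restarts: int = 4  # orientation-stage restarts (multi-modal landscape)
    max_polish: int = 4  # repeats of the full-model stage until converged

    def __post_init__(self) -> None:
        lo, hi = self.eigenvalue_bounds
        if not (0 < lo < hi):
            raise ValueError(f"eigenvalue bounds must satisfy 0 < lo < hi, got {self.eigenvalue_bounds}")
        if not (1 <= self.max_fascicles <= 3):
            raise ValueError(f"max_fascicles must be 1..3, got {self.max_fascicles}")
        if self.beta_schedule is not None:
            bs = tuple(self.beta_schedule)
            if any(b2 < b1 for b1, b2 in zip(bs, bs[1:])):
                raise ValueError("beta_schedule must be nondecreasing")
            self.beta_schedule = bs

    def betas(self) -> tuple[float, ...]:
        if self.beta_schedule is not None:
            return self.beta_schedule
        if self.n_sweeps <= 0:
            return ()
        if self.n_sweeps == 1:
            return (1.0,)
        return tuple(np.linspace(0.0, 1.0, self.n_sweeps))


def n_free_parameters(n_fascicles: int, cylindrical: bool = True) -> int:
    """Free parameters of the voxel model: 4 per cylindrical tensor (two
    orientation angles + two eigenvalues; 6 unconstrained) plus ``N`` for the
    ``N + 1`` fractions constrained to the simplex."""
    per_tensor = 4 if cylindrical else 6
    return per_tensor * n_fascicles + n_fascicles


# ---------------------------------------------------------------------------
# Stage 1: robust log-linear one-tensor least squares
# ---------------------------------------------------------------------------

def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    b = scheme.bvals
    g = scheme.unit_directions
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx, -b * gy * gy, -b * gz * gz,
        -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
    ])


def _tensor_from_coeffs(c: np.ndarray) -> np.ndarray:
    return np.array([[c[1], c[4], c[5]],
                     [c[4], c[2], c[6]],
                     [c[5], c[6], c[3]]])


def fit_single_tensor_ls(signal: DWISignal | np.ndarray, scheme: GradientScheme,
                         n_robust_iter: int = 3) -> tuple[np.ndarray, float]:
    """Robust weighted log-linear least-squares one-tensor fit.

    Returns ``(tensor, s0)``.  Weights start at the squared signal (the
    standard variance correction for the log transform) and are iteratively
    refined with Cauchy weights on the log-domain residuals; on noise-free
    data the residuals vanish and the reweighting is a no-op.  If the
    solution is not SPD the robust scale is tightened and the fit repeated;
    as a last resort an isotropic tensor at the apparent mean diffusivity is
    returned (a constructed fallback, not an eigenvalue clamp).
    """
    y = signal.values if isinstance(signal, DWISignal) else np.asarray(signal, float)
    if not np.any(y > 0):
        raise ValueError("all-zero signal cannot be fit")
    if scheme.n_b0 == 0:
        raise UnderDeterminedError("scheme has no b=0 entry")
    nz = ~scheme.b0_mask
    a_full = _design_matrix(scheme)
    if np.linalg.matrix_rank(a_full[nz][:, 1:]) < 6:
        raise UnderDeterminedError(
            "scheme needs at least 6 non-collinear non-zero directions for a tensor fit")

    logy = np.log(np.maximum(y, 1e-12 * max(y.max(), 1.0)))
    w = y ** 2  # WLS weights for the log-linearized model

    def _solve(weights: np.ndarray) -> np.ndarray:
        sw = np.sqrt(weights)
        coef, *_ = np.linalg.lstsq(a_full * sw[:, None], logy * sw, rcond=None)
        return coef

    coef = _solve(w)
    cauchy_c = 2.385
    scale_floor = 1e-10 * max(1.0, float(np.max(np.abs(logy))))
    for _ in range(n_robust_iter):
        r = logy - a_full @ coef
        scale = 1.4826 * np.median(np.abs(r - np.median(r)))
        if scale <= scale_floor:
            break  # residuals at numerical zero: reweighting is a no-op
        u = r / (cauchy_c * scale)
        coef = _solve(w / (1.0 + u * u))

    d = _tensor_from_coeffs(coef)
    tighten = cauchy_c
    for _ in range(4):
        if is_spd(d):
            break
        tighten *= 0.5
        r = logy - a_full @ coef
        scale = 1.4826 * np.median(np.abs(r - np.median(r)))
        if scale <= 0:
            break
        u = r / (tighten * scale)
        coef = _solve(w / (1.0 + u * u))
        d = _tensor_from_coeffs(coef)
    if not is_spd(d):
        logger.warning("one-tensor fit not SPD after reweighting; isotropic fallback")
        s0 = float(np.mean(y[scheme.b0_mask]))
        b = scheme.bvals[nz]
        adc = float(np.mean(np.maximum(-np.log(np.maximum(y[nz] / s0, 1e-12)) / b, 1e-5)))
        return adc * np.eye(3), s0
    return d, float(np.exp(coef[0]))


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initialize_mfm(single_tensor: np.ndarray, s0: float, n_fascicles: int,
                   config: FitConfig, seed: int | np.random.Generator = 0) -> MFMVoxel:
    """Initial multi-fascicle voxel from the one-tensor solution.

    The first two fascicles point along the one-tensor principal axis rotated
    by ``+/- theta_init`` in the plane of its two largest eigenvalues, with
    ``theta_init = (pi/4) (lambda2 / lambda1)``: a prolate one-tensor fit
    (``lambda2 << lambda1``) yields two almost parallel fascicles, an oblate
    one (``lambda2 ~ lambda1``, the signature of a crossing) two
    perpendicular ones.  Each initial tensor is cylindrical about its rotated
    axis (consistent with the cylindrical fascicle constraint, and
    well-defined even when the one-tensor fit is planar-degenerate) with
    eigenvalues shrunk by the configured factor; a third fascicle is seeded
    by a random rotation.
    """
    if n_fascicles < 1:
        raise ValueError(f"n_fascicles must be >= 1, got {n_fascicles}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, v = np.linalg.eigh(single_tensor)
    w = w[::-1]
    v = v[:, ::-1]
    f_iso = config.init_f_iso
    f_each = (1.0 - f_iso) / n_fascicles
    if n_fascicles == 1:
        return MFMVoxel(s0=s0, f_iso=f_iso, fascicles=[(f_each, single_tensor.copy())],
                        d_iso=config.d_iso)
    l_par = config.init_shrink * w[0]
    l_perp = config.init_shrink * float(np.sqrt(w[1] * w[2]))
    theta_init = 0.25 * np.pi * (w[1] / w[0])
    fascicles = []
    for sign in (+1.0, -1.0):
        r = Rotation.from_rotvec(sign * theta_init * v[:, 2]).as_matrix()
        fascicles.append((f_each, cylindrical_tensor(r @ v[:, 0], l_par, l_perp)))
    if n_fascicles >= 3:
        r = Rotation.random(rng=rng).as_matrix()
        fascicles.append((f_each, cylindrical_tensor(r @ v[:, 0], l_par, l_perp)))
    return MFMVoxel(s0=s0, f_iso=f_iso, fascicles=fascicles[:n_fascicles],
                    d_iso=config.d_iso)


# ---------------------------------------------------------------------------
# Multi-tensor spatial gradient and MAP objective
# ---------------------------------------------------------------------------

def _side_tensor(candidates: list[np.ndarray], ref: np.ndarray,
                 gamma: float | str) -> np.ndarray:
    """Neighbor log-tensor most similar to ``ref`` (exact min over the
    log-Euclidean distance), or the softmax-weighted average for finite
    ``gamma``."""
    dists = np.array([np.linalg.norm(c - ref) for c in candidates])
    if gamma == "exact-min" or gamma is None:
        return candidates[int(np.argmin(dists))]
    wts = np.exp(-float(gamma) * (dists - dists.min()))
    wts /= wts.sum()
    return sum(w * c for w, c in zip(wts, candidates))


def _spatial_derivative(log_field: np.ndarray, mask: np.ndarray, idx: tuple,
                        j: int, axis: int, gamma: float | str) -> np.ndarray:
    """Finite-difference derivative of fascicle ``j``'s log-tensor along
    ``axis``, matching each side to the most similar neighbor fascicle
    (one-sided at mask boundaries, zero with no neighbors)."""
    ref = log_field[idx][j]
    shape = mask.shape
    sides = []
    for step in (+1, -1):
        nidx = list(idx)
        nidx[axis] += step
        nidx = tuple(nidx)
        if 0 <= nidx[axis] < shape[axis] and mask[nidx] and log_field[nidx]:
            sides.append(_side_tensor(log_field[nidx], ref, gamma))
        else:
            sides.append(None)
    plus, minus = sides
    if plus is not None and minus is not None:
        return 0.5 * (plus - minus)
    if plus is not None:
        return plus - ref
    if minus is not None:
        return ref - minus
    return np.zeros((3, 3))


def spatial_gradient_multitensor(log_field: np.ndarray, mask: np.ndarray,
                                 idx: tuple, j: int, axis: int,
                                 gamma: float | str = "exact-min") -> float:
    """Frobenius norm of the fascicle-matched finite-difference derivative."""
    return float(np.linalg.norm(_spatial_derivative(log_field, mask, idx, j, axis, gamma)))


def _phi(s: np.ndarray | float) -> np.ndarray | float:
    """Edge-preserving anisotropic penalty ``2 sqrt(1 + s^2) - 2``."""
    return 2.0 * np.sqrt(1.0 + np.square(s)) - 2.0


def _voxel_prior(log_field: np.ndarray, mask: np.ndarray, idx: tuple,
                 config: FitConfig, K: float) -> float:
    total = 0.0
    for j in range(len(log_field[idx])):
        g2 = 0.0
        for axis in range(mask.ndim):
            d = _spatial_derivative(log_field, mask, idx, j, axis, config.softmax_gamma)
            g2 += float(np.sum(d * d))
        total += _phi(np.sqrt(g2) / K)
    return total


def map_objective(field: MFMField, data: np.ndarray, scheme: GradientScheme,
                  config: FitConfig, beta: float) -> float:
    """Full-field MAP objective: squared residuals plus the annealed
    fascicle-matched smoothness prior.  ``beta = 0`` reduces to the pure
    least-squares criterion."""
    if data.shape[:-1] != field.shape or data.shape[-1] != len(scheme):
        raise ValueError(f"data shape {data.shape} does not match field "
                         f"{field.shape} + scheme length {len(scheme)}")
    total = 0.0
    for idx, vox in field.voxels():
        r = predict_values(vox, scheme) - data[idx]
        total += float(r @ r)
    if beta > 0 and config.alpha > 0:
        K = config.K if config.K is not None else 1.0
        log_field = field.log_tensors()
        for idx, _ in field.voxels():
            total += beta * config.alpha * _voxel_prior(log_field, field.mask, idx, config, K)
    return total


# ---------------------------------------------------------------------------
# Per-voxel staged fit
# ---------------------------------------------------------------------------

class _VoxelModel:
    """Fast parameterized signal predictor for one voxel under one scheme."""

    def __init__(self, scheme: GradientScheme, s0: float, config: FitConfig,
                 n_fascicles: int):
        self.b = scheme.bvals
        self.g = scheme.unit_directions
        self.s0 = s0
        self.n = n_fascicles
        self.cyl = config.cylindrical
        self.e_iso = np.exp(-self.b * config.d_iso)
        self.per = 4 if self.cyl else 6

    def attenuations(self, x: np.ndarray) -> np.ndarray:
        """Per-fascicle attenuation columns exp(-b g^T D_i g), shape (M, N)."""
        if self.cyl:
            p = x.reshape(self.n, 4)
            st = np.sin(p[:, 1])
            axes = np.column_stack([np.cos(p[:, 0]) * st, np.sin(p[:, 0]) * st,
                                    np.cos(p[:, 1])])  # (N, 3)
            proj2 = (self.g @ axes.T) ** 2  # (M, N)
            q = p[:, 3] + (p[:, 2] - p[:, 3]) * proj2
            return np.exp(-self.b[:, None] * q)
        cols = []
        for i in range(self.n):
            p = x[self.per * i: self.per * (i + 1)]
            d = orientation_to_tensor((p[0], p[1], p[2]), (p[3], p[4], p[5]))
            q = np.einsum("ki,ij,kj->k", self.g, d, self.g)
            cols.append(np.exp(-self.b * q))
        return np.column_stack(cols)

    def tensors(self, x: np.ndarray) -> list[np.ndarray]:
        out = []
        for i in range(self.n):
            p = x[self.per * i: self.per * (i + 1)]
            if self.cyl:
                out.append(cylindrical_tensor(axis_from_angles(p[0], p[1]), p[2], p[3]))
            else:
                out.append(orientation_to_tensor((p[0], p[1], p[2]), (p[3], p[4], p[5])))
        return out


def _stick_fractions(sticks: np.ndarray, f_iso: float) -> np.ndarray:
    """Stick-breaking map from ``n - 1`` box parameters in [0, 1] to ``n``
    fascicle fractions sharing ``1 - f_iso`` (bijective: no flat directions
    for the optimizer)."""
    remaining = 1.0 - f_iso
    out = []
    for s in sticks:
        out.append(remaining * s)
        remaining -= out[-1]
    out.append(remaining)
    return np.array(out)


def _fractions_to_sticks(fasc: np.ndarray, f_iso: float) -> np.ndarray:
    remaining = 1.0 - f_iso
    sticks = []
    for f in fasc[:-1]:
        sticks.append(np.clip(f / max(remaining, 1e-12), 0.0, 1.0))
        remaining -= f
    return np.array(sticks)


def fit_voxel(y: np.ndarray, scheme: GradientScheme, n_fascicles: int,
              config: FitConfig, seed: int | np.random.Generator = 0,
              prior=None) -> tuple[MFMVoxel, float]:
    """Staged derivative-free fit of one voxel.  Returns ``(voxel, rss)``.

    Orientation angles are given periodic bounds wider than their principal
    range so line searches never stall on a bound; the principal-range
    representative is recovered when the tensor is built.  The orientation
    stage is restarted from a few perturbed initializations (the crossing-
    angle landscape is multi-modal) and the full-model stage is repeated
    until the objective stops improving; the objective never increases from
    stage to stage.

    ``prior`` is an optional callable mapping the fascicle tensor list to a
    penalty added to the residual sum of squares (used by the regularized
    field sweeps); the returned ``rss`` excludes it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d1, _ = fit_single_tensor_ls(y, scheme)
    s0 = float(np.mean(y[scheme.b0_mask]))
    init = initialize_mfm(d1, s0, n_fascicles, config, rng)

    model = _VoxelModel(scheme, s0, config, n_fascicles)
    n = n_fascicles
    per = model.per
    lo, hi = config.eigenvalue_bounds
    two_pi = 2 * np.pi

    tp = []
    t_bounds = []
    for _, d in init.fascicles:
        (psi, th, ph), lam = tensor_to_orientation(d)
        lam = np.clip(lam, lo, hi)
        if config.cylindrical:
            tp += [psi, th, lam[0], float(np.sqrt(lam[1] * lam[2]))]
            t_bounds += [(-two_pi, two_pi), (-np.pi, np.pi), (lo, hi), (lo, hi)]
        else:
            tp += [psi, th, ph, lam[0], lam[1], lam[2]]
            t_bounds += [(-two_pi, two_pi), (-np.pi, np.pi), (-two_pi, two_pi),
                         (lo, hi), (lo, hi), (lo, hi)]
    tp = np.array(tp)
    n_ang = 2 if config.cylindrical else 3
    ang_idx = [per * i + k for i in range(n) for k in range(n_ang)]

    method = "COBYQA" if config.optimizer.lower() == "cobyqa" else "Powell"

    def run_stage(obj, x0, bounds, maxfev):
        opts = {"maxfev": maxfev, "xtol": 1e-8, "ftol": 1e-10} if method == "Powell" \
            else {"maxfev": maxfev}
        res = minimize(obj, x0, method=method, bounds=bounds, options=opts)
        f0 = obj(x0)
        return (res.x, res.fun) if res.fun <= f0 else (x0, f0)

    def rss_of(xt, f_iso, fasc):
        s = model.s0 * (f_iso * model.e_iso + model.attenuations(xt) @ fasc)
        r = s - y
        return float(r @ r)

    def with_prior(xt, base):
        return base + prior(model.tensors(xt)) if prior is not None else base

    # Stage A: orientations + fascicle fractions, eigenvalues and f_iso fixed
    f_iso0 = config.init_f_iso

    def obj_a(x):
        xt = tp.copy()
        xt[ang_idx] = x[: len(ang_idx)]
        fasc = _stick_fractions(x[len(ang_idx):], f_iso0)
        return with_prior(xt, rss_of(xt, f_iso0, fasc))

    sticks0 = _fractions_to_sticks(np.full(n, (1 - f_iso0) / n), f_iso0)
    ba = [t_bounds[i] for i in ang_idx] + [(0.0, 1.0)] * (n - 1)
    xa, fa = None, np.inf
    for k in range(max(config.n_restarts, 1)):
        x0 = np.concatenate([tp[ang_idx], sticks0])
        if k:
            x0[: len(ang_idx)] += rng.normal(0.0, 0.6, len(ang_idx))
            x0[: len(ang_idx)] = np.clip(x0[: len(ang_idx)],
                                         [b[0] for b in ba[: len(ang_idx)]],
                                         [b[1] for b in ba[: len(ang_idx)]])
        xk, fk = run_stage(obj_a, x0, ba, config.stage_maxfev[0])
        if fk < fa:
            xa, fa = xk, fk
    tp[ang_idx] = xa[: len(ang_idx)]
    sticks = xa[len(ang_idx):]

    # Stage B: add the (cylindrical) eigenvalues
    def obj_b(x):
        xt = x[: per * n]
        fasc = _stick_fractions(x[per * n:], f_iso0)
        return with_prior(xt, rss_of(xt, f_iso0, fasc))

    bb = t_bounds + [(0.0, 1.0)] * (n - 1)
    xb, fb = run_stage(obj_b, np.concatenate([tp, sticks]), bb, config.stage_maxfev[1])

    # Stage C: full model including the isotropic fraction; repeat until the
    # objective stops improving (Powell restarts rebuild its direction set)
    def obj_c(x):
        xt = x[: per * n]
        fasc = _stick_fractions(x[per * n: -1], x[-1])
        return with_prior(xt, rss_of(xt, x[-1], fasc))

    bc = t_bounds + [(0.0, 1.0)] * (n - 1) + [(0.0, 1.0)]
    lo_b = np.array([b[0] for b in bc])
    hi_b = np.array([b[1] for b in bc])
    xc = np.concatenate([xb[: per * n], xb[per * n:], [f_iso0]])
    fc = obj_c(xc)
    stalls = 0
    for it in range(config.max_polish):
        if stalls == 0:
            x_try = xc
        else:  # escape flat regions (e.g. a collapsed fascicle) by a seeded kick
            x_try = xc.copy()
            x_try[ang_idx] += rng.normal(0.0, 0.4, len(ang_idx))
            x_try[per * n:] += rng.normal(0.0, 0.05, n)
            x_try = np.clip(x_try, lo_b, hi_b)
        xc_new, fc_new = run_stage(obj_c, x_try, bc, config.stage_maxfev[2])
        if fc_new < fc - 1e-6 * max(fc, 1.0):
            xc, fc = xc_new, fc_new
            stalls = 0
        else:
            if fc_new < fc:
                xc, fc = xc_new, fc_new
            stalls += 1
            if stalls >= 2:
                break

    f_iso = float(xc[-1])
    fasc = _stick_fractions(xc[per * n: -1], f_iso)
    tensors = model.tensors(xc[: per * n])
    vox = MFMVoxel(s0=s0, f_iso=f_iso,
                   fascicles=list(zip(fasc.tolist(), tensors)), d_iso=config.d_iso)
    return vox, rss_of(xc[: per * n], f_iso, fasc)


# ---------------------------------------------------------------------------
# Model order selection
# ---------------------------------------------------------------------------

def ftest_select(rss: list[float], n_params: list[int], n_measurements: int,
                 alpha: float = 0.05) -> int:
    """Ascending nested F-test: accept order ``k + 1`` over ``k`` iff the
    extra parameters reduce the residual sum of squares more than chance.

    ``rss`` and ``n_params`` are aligned with orders 1..len(rss).  Returns
    the first order whose increment is rejected (or the largest order).
    """
    if any(p2 <= p1 for p1, p2 in zip(n_params, n_params[1:])):
        raise ValueError("parameter counts must be strictly increasing (nested models)")
    if n_measurements <= max(n_params):
        raise ValueError("need more measurements than parameters")
    selected = 1
    for k in range(len(rss) - 1):
        dp = n_params[k + 1] - n_params[k]
        dof = n_measurements - n_params[k + 1]
        if rss[k + 1] <= 0:
            f = np.inf if rss[k] > rss[k + 1] else 0.0
        else:
            f = ((rss[k] - rss[k + 1]) / dp) / (rss[k + 1] / dof)
        p = float(stats.f.sf(f, dp, dof)) if np.isfinite(f) else 0.0
        if p < alpha:
            selected = k + 2
        else:
            break
    return selected


# ---------------------------------------------------------------------------
# Field fit
# ---------------------------------------------------------------------------

def estimate_sigma(data: np.ndarray, scheme: GradientScheme,
                   mask: np.ndarray | None = None) -> float:
    """Noise scale from b=0 replicate differences: ``1.4826 MAD / sqrt(2)``,
    assuming constant noise characteristics across acquisitions."""
    b0 = data[..., scheme.b0_mask]
    if b0.shape[-1] < 2:
        raise ValueError("sigma estimation needs at least two b=0 images")
    if mask is not None:
        b0 = b0[mask]
    diffs = np.diff(b0, axis=-1).ravel()
    return float(1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2.0))


def fit_field(data: np.ndarray, scheme: GradientScheme, config: FitConfig | None = None,
              mask: np.ndarray | None = None) -> MFMField:
    """Fit the multi-fascicle model over a grid of measurements.

    ``data`` has shape ``grid + (len(scheme),)``.  Voxels are first fit
    independently (staged derivative-free optimization, optionally F-test
    model order selection), then — if ``config.alpha > 0`` and sweeps are
    configured — refined by outer sweeps that re-solve each voxel with the
    fascicle-matched smoothness prior at annealed ``beta`` values, neighbors
    held fixed.
    """
    config = config or FitConfig()
    data = np.asarray(data, dtype=float)
    if data.ndim < 2:
        raise ValueError("data must have shape grid + (n_measurements,)")
    grid_shape = data.shape[:-1]
    if data.shape[-1] != len(scheme):
        raise ValueError(f"data has {data.shape[-1]} volumes but scheme has {len(scheme)}")
    if scheme.n_b0 == 0:
        raise ValueError("scheme has no b=0 entry")
    if scheme.is_single_shell and config.max_fascicles >= 2:
        logger.warning(
            "single-shell scheme: tensor size and compartment fractions are "
            "collinear; the full multi-fascicle fit is not identifiable")
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)

    rng = np.random.default_rng(config.seed)
    grid = np.empty(grid_shape, dtype=object)
    rss_map = np.zeros(grid_shape)
    single_logs = np.empty(grid_shape, dtype=object)
    orders = range(1, config.max_fascicles + 1) if config.model_selection \
        else [config.max_fascicles]

    for idx in np.ndindex(*grid_shape):
        if not mask[idx]:
            continue
        vox_seed = np.random.default_rng(rng.integers(2 ** 31))
        y = data[idx]
        try:
            d1, _ = fit_single_tensor_ls(y, scheme)
            single_logs[idx] = [matrix_log_spd(d1)]
        except (UnderDeterminedError, ValueError) as exc:
            raise type(exc)(f"voxel {idx}: {exc}") from exc
        fits = {}
        for order in orders:
            fits[order] = fit_voxel(y, scheme, order, config, vox_seed)
        if config.model_selection and len(fits) > 1:
            sel = ftest_select([fits[o][1] for o in orders],
                               [n_free_parameters(o, config.cylindrical) for o in orders],
                               len(scheme), config.ftest_alpha)
        else:
            sel = list(orders)[-1]
        grid[idx], rss_map[idx] = fits[sel]

    fld = MFMField(grid=grid, mask=mask)

    betas = config.betas()
    if config.alpha > 0 and betas:
        K = config.K
        if K is None:
            norms = [spatial_gradient_multitensor(single_logs, mask, idx, 0, ax)
                     for idx in np.ndindex(*grid_shape) if mask[idx]
                     for ax in range(mask.ndim)]
            norms = [v for v in norms if v > 0]
            K = float(np.median(norms)) if norms else 1.0
        for beta in betas:
            if beta <= 0:
                continue
            log_field = fld.log_tensors()
            for idx, vox in fld.voxels():
                n_f = vox.n_fascicles

                def prior(tensors, _idx=idx):
                    log_field[_idx] = [matrix_log_spd(t) for t in tensors]
                    return beta * config.alpha * _voxel_prior(
                        log_field, mask, _idx, config, K)

                old_logs = list(log_field[idx])
                old_local = rss_map[idx] + prior(vox.tensors)
                new_vox, new_rss = fit_voxel(data[idx], scheme, n_f, config,
                                             np.random.default_rng(rng.integers(2 ** 31)),
                                             prior=prior)
                if new_rss + prior(new_vox.tensors) <= old_local:
                    grid[idx], rss_map[idx] = new_vox, new_rss
                    log_field[idx] = [matrix_log_spd(t) for t in new_vox.tensors]
                else:  # keep the previous solution (objective never increases)
                    log_field[idx] = old_logs
    return fld
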
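"""Synthetic ground-truth multi-fascicle fields.

Phantoms emulate the standard two-tensor simulation setup for crossing-fiber
estimation: cylindrical fascicle tensors built from a requested FA and trace,
an isotropic free-water compartment, and Rician noise at a stated b=0 SNR.
Defaults — trace 2.1e-3 mm^2/s, FA pair (0.8, 0.7), fractions
(f_iso, f1, f2) = (0.2, 0.4, 0.4), baseline signal 400 — are typical
white-matter values; everything is configurable and recorded in the
phantom's ``meta`` so a phantom regenerates bit-identically from it.

What these phantoms do *not* emulate: partial-volume geometry beyond the
straight-band crossing, fascicle curvature or fanning, spatially varying
noise, and eddy-current or motion artifacts of real acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .estimation import MFMField
from .forward_model import (
    FREE_WATER_DIFFUSIVITY,
    DWISignal,
    MFMVoxel,
    add_rician_noise,
    predict_signal,
    sigma_for_snr_db,
)
from .gradients import GradientScheme
from .tensor_math import cylindrical_from_fa_trace, cylindrical_tensor

__all__ = [
    "PhantomGroundTruth",
    "crossing_grid_phantom",
    "crossing_angle_sweep",
    "uniform_crossing_phantom",
    "rotate_phantom",
    "simulate_phantom_signals",
]

_DEF_TRACE = 2.1e-3
_DEF_FA_PAIR = (0.8, 0.7)
_DEF_FRACTIONS = (0.2, 0.4, 0.4)
_DEF_S0 = 400.0


@dataclass
class PhantomGroundTruth:
    """Ground-truth field + acquisition scheme + noise level + recipe."""

    field: MFMField
    scheme: GradientScheme | None
    sigma: float
    meta: dict

    def signals(self, seed: int | None = None,
                scheme: GradientScheme | None = None) -> np.ndarray:
        """Simulated measurements, shape ``grid + (len(scheme),)``.

        Noise-free when ``seed`` is None, Rician-corrupted at the phantom's
        sigma otherwise.
        """
        sch = scheme or self.scheme
        if sch is None:
            raise ValueError("no scheme attached to this phantom")
        rng = None if seed is None else np.random.default_rng(seed)
        out = np.zeros(self.field.shape + (len(sch),))
        for idx, vox in self.field.voxels():
            sig = predict_signal(vox, sch)
            if rng is not None and self.sigma > 0:
                sig = add_rician_noise(sig, self.sigma, rng)
            out[idx] = sig.values
        return out


def simulate_phantom_signals(phantom: PhantomGroundTruth, seed: int | None = None,
                             scheme: GradientScheme | None = None) -> np.ndarray:
    """Functional alias for :meth:`PhantomGroundTruth.signals`."""
    return phantom.signals(seed=seed, scheme=scheme)


def _two_crossing_tensors(angle_deg: float, fa_pair, trace, rotation: np.ndarray):
    a = np.radians(angle_deg)
    axes = [np.array([1.0, 0.0, 0.0]), np.array([np.cos(a), np.sin(a), 0.0])]
    out = []
    for fa, ax in zip(fa_pair, axes):
        l1, l2, _ = cylindrical_from_fa_trace(fa, trace)
        out.append(cylindrical_tensor(rotation @ ax, l1, l2))
    return out


def crossing_grid_phantom(angle_deg: float = 70.0, n_models: int = 100,
                          fa_pair=_DEF_FA_PAIR, trace: float = _DEF_TRACE,
                          fractions=_DEF_FRACTIONS, s0: float = _DEF_S0,
                          snr_db: float | None = 30.0,
                          scheme: GradientScheme | None = None,
                          d_iso: float = FREE_WATER_DIFFUSIVITY,
                          seed: int = 0) -> PhantomGroundTruth:
    """Grid of two-tensor models crossing at a fixed angle with a seeded
    random global orientation per voxel."""
    if not (0.0 <= angle_deg <= 90.0):
        raise ValueError(f"angle must be in [0, 90] degrees, got {angle_deg}")
    f_iso, f1, f2 = fractions
    if abs(f_iso + f1 + f2 - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    grid = np.empty((n_models, 1, 1), dtype=object)
    for i in range(n_models):
        r = Rotation.random(rng=rng).as_matrix()
        d1, d2 = _two_crossing_tensors(angle_deg, fa_pair, trace, r)
        grid[i, 0, 0] = MFMVoxel(s0=s0, f_iso=f_iso,
                                 fascicles=[(f1, d1), (f2, d2)], d_iso=d_iso)
    sigma = sigma_for_snr_db(s0, snr_db) if snr_db is not None else 0.0
    meta = dict(kind="crossing_grid", angle_deg=angle_deg, n_models=n_models,
                fa_pair=tuple(fa_pair), trace=trace, fractions=tuple(fractions),
                s0=s0, snr_db=snr_db, d_iso=d_iso, seed=seed)
    return PhantomGroundTruth(MFMField(grid, np.ones(grid.shape, bool)),
                              scheme, sigma, meta)


def crossing_angle_sweep(angles=None, **kwargs) -> list[PhantomGroundTruth]:
    """One phantom per crossing angle (default: ten angles, 30..90 deg)."""
    if angles is None:
        angles = np.linspace(30.0, 90.0, 10)
    return [crossing_grid_phantom(angle_deg=float(a), **kwargs) for a in angles]


def uniform_crossing_phantom(angle_deg: float = 60.0, length: int = 15,
                             fa_pair=_DEF_FA_PAIR, trace: float = _DEF_TRACE,
                             f_iso: float = 0.2, s0: float = _DEF_S0,
                             snr_db: float | None = 30.0, band_width: int = 3,
                             scheme: GradientScheme | None = None,
                             d_iso: float = FREE_WATER_DIFFUSIVITY,
                             seed: int = 0) -> PhantomGroundTruth:
    """Two straight uniform fascicle bands crossing on a 2-D slice.

    Fascicle 1 runs horizontally (x axis) through the middle rows; fascicle 2
    crosses it at ``angle_deg`` through the grid center.  Each fascicle's
    tensor is identical along its whole path; intersection voxels hold both
    tensors with fractions ``(1 - f_iso)/2`` each, single-band voxels one
    tensor with fraction ``1 - f_iso``.  Voxels in neither band are masked
    out.
    """
    if not (0.0 < angle_deg <= 90.0):
        raise ValueError(
            f"bands must cross at a non-zero angle in (0, 90], got {angle_deg}")
    d1, d2 = _two_crossing_tensors(angle_deg, fa_pair, trace, np.eye(3))
    grid = np.empty((length, length, 1), dtype=object)
    mask = np.zeros((length, length, 1), dtype=bool)
    c = (length - 1) / 2.0
    a = np.radians(angle_deg)
    u2 = np.array([np.cos(a), np.sin(a)])  # direction of fascicle 2 in-plane
    half = band_width / 2.0
    in_band1 = np.zeros((length, length), bool)
    in_band2 = np.zeros((length, length), bool)
    for x in range(length):
        for yy in range(length):
            in_band1[x, yy] = abs(yy - c) <= half
            # perpendicular distance of (x, yy) to the center line along u2
            rel = np.array([x - c, yy - c])
            dist = abs(rel[0] * u2[1] - rel[1] * u2[0])
            in_band2[x, yy] = dist <= half
    if not np.any(in_band1 & in_band2):
        raise ValueError("bands do not intersect for this geometry")
    for x in range(length):
        for yy in range(length):
            b1, b2 = in_band1[x, yy], in_band2[x, yy]
            if not (b1 or b2):
                continue
            if b1 and b2:
                fas = [((1 - f_iso) / 2, d1.copy()), ((1 - f_iso) / 2, d2.copy())]
            elif b1:
                fas = [(1 - f_iso, d1.copy())]
            else:
                fas = [(1 - f_iso, d2.copy())]
            grid[x, yy, 0] = MFMVoxel(s0=s0, f_iso=f_iso, fascicles=fas, d_iso=d_iso)
            mask[x, yy, 0] = True
    sigma = sigma_for_snr_db(s0, snr_db) if snr_db is not None else 0.0
    meta = dict(kind="uniform_crossing", angle_deg=angle_deg, length=length,
                fa_pair=tuple(fa_pair), trace=trace, f_iso=f_iso, s0=s0,
                snr_db=snr_db, band_width=band_width, d_iso=d_iso, seed=seed)
    return PhantomGroundTruth(MFMField(grid, mask), scheme, sigma, meta)


def horizontal_tract_path(phantom: PhantomGroundTruth) -> list[tuple[int, int, int]]:
    """Voxel indices along the center row of the horizontal fascicle band."""
    if phantom.meta.get("kind") != "uniform_crossing":
        raise ValueError("path extraction is defined for uniform-crossing phantoms")
    length = phantom.meta["length"]
    c = int(round((length - 1) / 2.0))
    return [(x, c, 0) for x in range(length)]


def rotate_phantom(p: PhantomGroundTruth, rotation) -> PhantomGroundTruth:
    """Conjugate every tensor by a proper rotation; fractions, eigenvalues
    and hence FA are untouched."""
    r = rotation.as_matrix() if isinstance(rotation, Rotation) else np.asarray(rotation, float)
    if r.shape != (3, 3) or abs(np.linalg.det(r) - 1.0) > 1e-9 \
            or np.max(np.abs(r @ r.T - np.eye(3))) > 1e-9:
        raise ValueError("rotation must be a proper (det = +1) orthogonal matrix")
    grid = np.empty(p.field.shape, dtype=object)
    for idx, vox in p.field.voxels():
        fas = [(f, r @ d @ r.T) for f, d in vox.fascicles]
        grid[idx] = MFMVoxel(s0=vox.s0, f_iso=vox.f_iso, fascicles=fas, d_iso=vox.d_iso)
    meta = dict(p.meta)
    meta["rotated"] = r.tolist()
    return PhantomGroundTruth(MFMField(grid, p.field.mask.copy()), p.scheme,
                              p.sigma, meta)
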
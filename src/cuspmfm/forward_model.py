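"""Multi-fascicle diffusion signal model and the single-shell gauge freedom.

The signal at a voxel holding an isotropic free-water compartment and up to
three anisotropic fascicle compartments is the mixture

    S(g) = S0 [ f_iso exp(-b d_iso) + sum_i f_i exp(-b g^T D_i g) ]

with unit direction ``g``, effective b-value ``b``, SPD fascicle tensors
``D_i`` and fractions summing to one.  Each compartment decays
mono-exponentially; the mixture does not, which is why the model can separate
free water from hindered fascicle diffusion — provided the acquisition
carries more than one non-zero b-value.

On a *single-shell* acquisition it cannot: for a two-fascicle voxel and any
admissible scalar ``eps``, rescaling one fraction and shifting both tensors
by isotropic log-terms (:func:`gauge_transform`) produces a different model
with bit-for-bit identical single-shell predictions.  Tensor size and
fractions of occupancy are collinear, so the least-squares problem has an
infinite solution set.  On any scheme with two distinct non-zero b-values
the same transformation changes the predictions, restoring identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gradients import GradientScheme
from .tensor_math import is_spd

__all__ = [
    "FREE_WATER_DIFFUSIVITY",
    "MFMVoxel",
    "DWISignal",
    "predict_values",
    "predict_signal",
    "gauge_transform",
    "add_rician_noise",
    "snr_db",
    "sigma_for_snr_db",
]

# Free-water diffusivity at body temperature, mm^2/s.
FREE_WATER_DIFFUSIVITY = 3.0e-3

_FRACTION_TOL = 1e-9


@dataclass
class MFMVoxel:
    """Per-voxel multi-fascicle model: fractions + tensors + free water."""

    s0: float
    f_iso: float
    fascicles: list[tuple[float, np.ndarray]]  # (fraction, SPD tensor)
    d_iso: float = FREE_WATER_DIFFUSIVITY

    @property
    def n_fascicles(self) -> int:
        return len(self.fascicles)

    @property
    def fractions(self) -> np.ndarray:
        """All fractions, isotropic first."""
        return np.array([self.f_iso] + [f for f, _ in self.fascicles])

    @property
    def tensors(self) -> list[np.ndarray]:
        return [d for _, d in self.fascicles]

    def validate(self) -> None:
        if self.d_iso <= 0:
            raise ValueError(f"d_iso must be positive, got {self.d_iso}")
        fr = self.fractions
        if np.any(fr < -_FRACTION_TOL) or np.any(fr > 1 + _FRACTION_TOL):
            raise ValueError(f"fractions outside [0, 1]: {fr}")
        if abs(fr.sum() - 1.0) > _FRACTION_TOL:
            raise ValueError(f"fractions sum to {fr.sum()}, expected 1")
        for i, d in enumerate(self.tensors):
            if not is_spd(d):
                raise ValueError(f"fascicle {i} tensor is not SPD")


@dataclass
class DWISignal:
    """Measurement vector aligned 1:1 with a scheme's entries."""

    values: np.ndarray
    sigma: float | None = None  # Rician noise scale; None when unknown

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def predict_values(voxel: MFMVoxel, scheme: GradientScheme) -> np.ndarray:
    """Noise-free mixture signal for every scheme entry (b=0 entries: s0)."""
    if voxel.d_iso <= 0:
        raise ValueError(f"d_iso must be positive, got {voxel.d_iso}")
    b = scheme.bvals
    g = scheme.unit_directions
    atten = voxel.f_iso * np.exp(-b * voxel.d_iso)
    for f, d in voxel.fascicles:
        q = np.einsum("ki,ij,kj->k", g, d, g)
        atten = atten + f * np.exp(-b * q)
    return voxel.s0 * atten


def predict_signal(voxel: MFMVoxel, scheme: GradientScheme) -> DWISignal:
    """Noise-free :class:`DWISignal` for ``voxel`` under ``scheme``."""
    return DWISignal(predict_values(voxel, scheme), sigma=0.0)


def gauge_transform(voxel: MFMVoxel, epsilon: float, b: float) -> MFMVoxel:
    """The single-shell gauge: an alternative two-fascicle model whose
    predictions at b-value ``b`` are identical to ``voxel``'s.

        f1' = eps f1          D1' = D1 + (ln eps / b) I
        f2' = f1 + f2 - f1'   D2' = D2 + (ln(f2'/f2) / b) I

    On any scheme whose non-zero entries all sit at effective b-value ``b``
    the predicted signals agree exactly (fraction sum preserved); on a scheme
    with a second distinct b-value they differ, exhibiting the
    non-identifiability of single-shell multi-tensor fitting.

    Raises ``ValueError`` if ``epsilon`` leaves the SPD-preserving range for
    either transformed tensor, and ``NotImplementedError`` for voxels without
    exactly two fascicles.
    """
    if voxel.n_fascicles != 2:
        raise NotImplementedError("gauge transform is defined for two-fascicle voxels")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if b <= 0:
        raise ValueError(f"b must be positive, got {b}")
    (f1, d1), (f2, d2) = voxel.fascicles
    f1t = epsilon * f1
    f2t = f1 + f2 - f1t
    if not (0.0 <= f1t <= 1.0 and 0.0 < f2t <= 1.0):
        raise ValueError(f"epsilon = {epsilon} drives fractions outside [0, 1]")
    d1t = d1 + (np.log(epsilon) / b) * np.eye(3)
    d2t = d2 + (np.log(f2t / f2) / b) * np.eye(3)
    if not is_spd(d1t):
        raise ValueError(f"epsilon = {epsilon} makes the first tensor degenerate")
    if not is_spd(d2t):
        raise ValueError(f"epsilon = {epsilon} makes the second tensor degenerate")
    return replace(voxel, fascicles=[(f1t, d1t), (f2t, d2t)])


def add_rician_noise(signal: DWISignal, sigma: float, seed: int | np.random.Generator = 0) -> DWISignal:
    """Rician-corrupted copy: each value v -> sqrt((v + n1)^2 + n2^2) with
    n1, n2 ~ Normal(0, sigma^2) (magnitude-MR noise)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return DWISignal(signal.values.copy(), sigma=0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=signal.values.shape)
    n2 = rng.normal(0.0, sigma, size=signal.values.shape)
    return DWISignal(np.hypot(signal.values + n1, n2), sigma=sigma)


def snr_db(signal: DWISignal, scheme: GradientScheme) -> float:
    """SNR in dB against the b=0 images: ``20 log10(mean b0 / sigma)``."""
    if signal.sigma is None or signal.sigma == 0:
        raise ValueError("noise scale sigma is unknown or zero")
    mask = scheme.b0_mask
    if not mask.any():
        raise ValueError("scheme has no b=0 entry")
    return float(20.0 * np.log10(signal.values[mask].mean() / signal.sigma))


def sigma_for_snr_db(s0: float, snr_db_target: float) -> float:
    """Noise scale giving the requested b=0 SNR for baseline signal ``s0``."""
    return float(s0 / 10.0 ** (snr_db_target / 20.0))
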
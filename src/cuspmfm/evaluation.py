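"""Ground-truth comparison metrics and residual-bootstrap uncertainty.

Estimated and reference multi-fascicle fields are compared fascicle-by-
fascicle, minimizing over the per-voxel matching permutation (at most 3
fascicles, so the search is exhaustive by construction):

- **tALED** — average log-Euclidean distance between matched tensors;
- **fAAD** — average absolute difference of the matched fractions (isotropic
  fraction included), reusing the tALED-optimal permutation;
- **tAMA** — average minimum axial angle from each reference principal axis
  to the nearest estimated axis (works across differing fascicle counts).

The residual bootstrap quantifies estimation uncertainty without repeated
acquisitions: per voxel, the fit residuals are resampled with replacement
onto the model predictions to form virtual acquisitions, each refit, and the
spread of the maximum per-fascicle FA (a proxy that tracks the same fascicle
across replicates) is reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitConfig, MFMField, fit_voxel
from .forward_model import predict_values
from .gradients import GradientScheme
from .tensor_math import axial_angle_deg, logeuclid_distance, principal_axis, scalar_measures

__all__ = [
    "MetricReport",
    "taled",
    "faad",
    "tama",
    "fa_profile",
    "residual_bootstrap",
]


@dataclass
class MetricReport:
    """Per-voxel metric values with summary statistics."""

    name: str
    indices: list[tuple]
    values: np.ndarray
    permutations: list[tuple[int, ...] | None]

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def variance(self) -> float:
        return float(np.var(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "voxel": [str(i) for i in self.indices],
            "metric": self.name,
            "value": self.values,
            "permutation": [str(p) for p in self.permutations],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _matched_pairs(est: MFMField, ref: MFMField, metric_name: str):
    for idx, rv in ref.voxels():
        ev = est.grid[idx]
        if ev is None:
            raise ValueError(f"voxel {idx} missing from the estimated field")
        if ev.n_fascicles != rv.n_fascicles:
            raise ValueError(
                f"voxel {idx}: estimated {ev.n_fascicles} fascicles vs reference "
                f"{rv.n_fascicles}; align model order (e.g. F-test selection) "
                f"before computing {metric_name}")
        yield idx, ev, rv


def taled(est: MFMField, ref: MFMField) -> MetricReport:
    """Permutation-matched average log-Euclidean tensor distance per voxel."""
    indices, values, perms = [], [], []
    for idx, ev, rv in _matched_pairs(est, ref, "tALED"):
        et, rt = ev.tensors, rv.tensors
        n = len(rt)
        best, best_perm = np.inf, None
        for perm in itertools.permutations(range(n)):
            d = np.mean([logeuclid_distance(et[perm[i]], rt[i]) for i in range(n)])
            if d < best:
                best, best_perm = d, perm
        indices.append(idx)
        values.append(best)
        perms.append(best_perm)
    return MetricReport("tALED", indices, np.array(values), perms)


def faad(est: MFMField, ref: MFMField, matching: MetricReport | None = None) -> MetricReport:
    """Average absolute fraction difference using the tALED-optimal matching
    (the fraction comparison follows the tensor correspondence)."""
    if matching is None:
        matching = taled(est, ref)
    perm_by_idx = dict(zip(matching.indices, matching.permutations))
    indices, values, perms = [], [], []
    for idx, ev, rv in _matched_pairs(est, ref, "fAAD"):
        perm = perm_by_idx[idx]
        ef = [f for f, _ in ev.fascicles]
        rf = [f for f, _ in rv.fascicles]
        diffs = [abs(ev.f_iso - rv.f_iso)]
        diffs += [abs(ef[perm[i]] - rf[i]) for i in range(len(rf))]
        indices.append(idx)
        values.append(float(np.mean(diffs)))
        perms.append(perm)
    return MetricReport("fAAD", indices, np.array(values), perms)


def tama(est: MFMField, ref: MFMField) -> MetricReport:
    """Average minimum axial angle (degrees, in [0, 90]) from each reference
    principal axis to the nearest estimated principal axis."""
    indices, values = [], []
    for idx, rv in ref.voxels():
        ev = est.grid[idx]
        if ev is None or ev.n_fascicles == 0:
            raise ValueError(f"voxel {idx}: empty estimate")
        est_axes = [principal_axis(d) for d in ev.tensors]
        angs = []
        for d in rv.tensors:
            ra = principal_axis(d)
            angs.append(min(axial_angle_deg(ra, ea) for ea in est_axes))
        indices.append(idx)
        values.append(float(np.mean(angs)))
    return MetricReport("tAMA", indices, np.array(values), [None] * len(indices))


def fa_profile(field: MFMField, path: list[tuple], reference_directions) -> tuple[np.ndarray, float]:
    """FA along a tract: at each path point, the fascicle whose principal
    axis is most aligned with the local reference direction is selected and
    its FA reported.  Returns ``(fa_sequence, variance)``."""
    if len(path) == 0:
        raise ValueError("empty path")
    ref_dirs = np.asarray(reference_directions, float)
    if ref_dirs.ndim == 1:
        ref_dirs = np.tile(ref_dirs, (len(path), 1))
    fas = []
    for idx, rd in zip(path, ref_dirs):
        vox = field.grid[tuple(idx)]
        if vox is None or vox.n_fascicles == 0:
            raise ValueError(f"voxel {tuple(idx)}: no fascicles on the path")
        angles = [axial_angle_deg(rd, principal_axis(d)) for d in vox.tensors]
        best = int(np.argmin(angles))
        fas.append(scalar_measures(vox.tensors[best]).fa)
    fas = np.array(fas)
    return fas, float(np.var(fas))


def _max_fa(voxel) -> float:
    """Maximum per-fascicle FA; ties broken by the larger fraction."""
    scored = sorted(((scalar_measures(d).fa, f) for f, d in voxel.fascicles),
                    key=lambda t: (t[0], t[1]))
    return scored[-1][0]


def residual_bootstrap(data: np.ndarray, scheme: GradientScheme, fitted: MFMField,
                       n_replicates: int, seed: int = 0,
                       config: FitConfig | None = None) -> np.ndarray:
    """Per-voxel standard deviation of the maximum-fascicle-FA across
    residual-bootstrap replicates.

    Residuals ``r = y - yhat`` of the fitted model are resampled with
    replacement (raw, per voxel) onto the predictions to form virtual
    acquisitions; each is refit with the same configuration.  Returns an
    array shaped like the grid (NaN outside the mask).
    """
    if n_replicates < 2:
        raise ValueError(f"n_replicates must be >= 2, got {n_replicates}")
    config = config or FitConfig(alpha=0.0, n_sweeps=0)
    rng = np.random.default_rng(seed)
    out = np.full(fitted.shape, np.nan)
    m = len(scheme)
    for idx, vox in fitted.voxels():
        y = data[idx]
        yhat = predict_values(vox, scheme)
        resid = y - yhat
        # one optimizer seed per voxel, shared by all replicates, so the
        # replicate spread reflects the resampled data rather than the
        # stochastic restarts of the fitter
        opt_seed = int(rng.integers(2 ** 31))
        fas = []
        for _ in range(n_replicates):
            y_star = yhat + resid[rng.integers(0, m, size=m)]
            y_star = np.maximum(y_star, 1e-9)
            rep_vox, _ = fit_voxel(y_star, scheme, vox.n_fascicles, config, opt_seed)
            fas.append(_max_fa(rep_vox))
        out[idx] = float(np.std(fas))
    return out
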
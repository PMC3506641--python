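"""Gradient encoding scheme design inside the cube of constant echo time.

A diffusion acquisition is described by an ordered list of gradient-coil
vectors.  A *unit-norm* vector produces the scheme's nominal b-value; the
diffusion sensitization grows with the square of the vector norm, so any
vector inside the enclosing cube of the unit sphere (every component at most
1 in magnitude — the *cube of constant TE*) can be played at the same echo
time while reaching b-values up to 3x nominal at the cube corners.

CUSP (CUbe and SPhere) schemes combine a unit-sphere shell with cube
gradients and therefore always contain at least two distinct non-zero
b-values, which is what makes full multi-tensor models identifiable (see
:mod:`cuspmfm.forward_model`).  Three constructions are provided:

``cusp_t``
    truncated multi-shell: unit shell + the six hexahedral (edge-midpoint,
    b = 2x nominal) and four tetrahedral (corner, b = 3x nominal) gradients.
``cusp_xt``
    shells with geometrically spaced radii in (1, sqrt(3)], truncated to the
    cube so each retained direction keeps the echo time unchanged.
``cusp_p``
    unit inner shell + an outer direction set projected onto the cube faces,
    with the tetrahedral/hexahedral vectors force-included.

Plain ``single_shell`` and ``multi_shell`` HARDI constructions are provided
for comparison; multi-shell entries with norm above 1 fall outside the cube
and are flagged by their shell label.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "SchemeEntry",
    "GradientScheme",
    "effective_bvalue",
    "project_to_cube",
    "cube_lattice_gradients",
    "repulsion_energy",
    "unit_directions_repulsion",
    "build_scheme",
]

_CUBE_TOL = 1e-9


@dataclass(frozen=True)
class SchemeEntry:
    """One acquisition: a gradient-coil vector with its effective b-value."""

    vector: tuple[float, float, float]
    effective_bvalue: float  # s/mm^2
    shell_label: str  # b0 | inner | hexahedral | tetrahedral | projected | shell-k

    @property
    def is_b0(self) -> bool:
        return self.effective_bvalue == 0.0

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vector))

    @property
    def exceeds_cube(self) -> bool:
        """True when the vector cannot be played at the unit-shell echo time."""
        return max(abs(c) for c in self.vector) > 1.0 + _CUBE_TOL


@dataclass
class GradientScheme:
    """Ordered gradient table with a nominal (unit-norm) b-value."""

    entries: list[SchemeEntry]
    nominal_bvalue: float

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def vectors(self) -> np.ndarray:
        return np.array([e.vector for e in self.entries], dtype=float)

    @property
    def bvals(self) -> np.ndarray:
        return np.array([e.effective_bvalue for e in self.entries], dtype=float)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0.0

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def unit_directions(self) -> np.ndarray:
        """Unit directions, zero rows for b=0 entries."""
        v = self.vectors
        n = np.linalg.norm(v, axis=1)
        out = np.zeros_like(v)
        nz = n > 0
        out[nz] = v[nz] / n[nz, None]
        return out

    @property
    def distinct_nonzero_bvalues(self) -> np.ndarray:
        b = np.sort(self.bvals[~self.b0_mask])
        if b.size == 0:
            return b
        keep = [b[0]]
        for x in b[1:]:
            if x - keep[-1] > 1e-6 * max(abs(x), 1.0):
                keep.append(x)
        return np.array(keep)

    @property
    def is_single_shell(self) -> bool:
        """True iff all non-zero effective b-values agree to 1e-6 relative."""
        return len(self.distinct_nonzero_bvalues) == 1

    def validate(self, require_b0: bool = True) -> None:
        if require_b0 and self.n_b0 == 0:
            raise ValueError("scheme has no b=0 entry")
        for i, e in enumerate(self.entries):
            nrm2 = float(np.dot(e.vector, e.vector))
            if e.effective_bvalue == 0.0:
                if nrm2 != 0.0:
                    raise ValueError(f"entry {i}: b=0 entry with non-zero vector")
            else:
                expect = self.nominal_bvalue * nrm2
                if abs(e.effective_bvalue - expect) > 1e-6 * max(expect, 1.0):
                    raise ValueError(
                        f"entry {i}: effective b-value {e.effective_bvalue} "
                        f"inconsistent with nominal x ||v||^2 = {expect}")


def effective_bvalue(vector, nominal_bvalue: float) -> float:
    """b-value of a gradient vector: ``nominal x ||vector||^2``."""
    if nominal_bvalue < 0:
        raise ValueError(f"nominal_bvalue must be >= 0, got {nominal_bvalue}")
    v = np.asarray(vector, dtype=float)
    return float(nominal_bvalue * np.dot(v, v))


def project_to_cube(direction) -> np.ndarray:
    """Scale a direction onto the faces of the cube of constant TE.

    The orientation is preserved; the returned vector has its largest
    component magnitude exactly 1 (the gradient strength is reduced until
    the cube surface is reached).
    """
    d = np.asarray(direction, dtype=float)
    m = np.max(np.abs(d))
    if m == 0:
        raise ValueError("cannot project the zero vector")
    return d / m


def cube_lattice_gradients() -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Unique non-antipodal cube-corner (tetrahedral) and edge-midpoint
    (hexahedral) gradients of the cube of constant TE.

    Returns ``(tetrahedral, hexahedral)``: 4 corners with squared norm 3 and
    6 edge midpoints with components in {-1, 0, 1} and squared norm 2.
    """
    tetra: list[np.ndarray] = []
    hexa: list[np.ndarray] = []
    seen: list[np.ndarray] = []

    def _is_new(v: np.ndarray) -> bool:
        for s in seen:
            if np.array_equal(v, s) or np.array_equal(v, -s):
                return False
        return True

    for comps in itertools.product((-1.0, 0.0, 1.0), repeat=3):
        v = np.array(comps)
        n2 = int(v @ v)
        if n2 not in (2, 3):
            continue
        if _is_new(v):
            seen.append(v)
            (tetra if n2 == 3 else hexa).append(_canonical_axis(v))
    return tetra, hexa


def _canonical_axis(v: np.ndarray) -> np.ndarray:
    """Antipodal representative: last non-zero component <= 0 (ties by
    lexicographic order, matching the predominantly non-positive z convention
    of printed gradient tables)."""
    nz = np.nonzero(np.abs(v) > 1e-12)[0]
    if nz.size and v[nz[-1]] > 0:
        return -v
    return v


def repulsion_energy(dirs: np.ndarray, fixed: np.ndarray | None = None) -> float:
    """Antipodally symmetrized Coulomb energy of unit directions.

    Pairwise terms ``1/|gi - gj| + 1/|gi + gj|`` within ``dirs`` and between
    ``dirs`` and ``fixed`` (fixed-fixed interactions are constant and
    omitted).
    """
    dirs = np.atleast_2d(np.asarray(dirs, float))
    e = 0.0
    n = len(dirs)
    if n > 1:
        diff = dirs[:, None, :] - dirs[None, :, :]
        summ = dirs[:, None, :] + dirs[None, :, :]
        iu = np.triu_indices(n, 1)
        e += float(np.sum(1.0 / np.linalg.norm(diff[iu], axis=-1)))
        e += float(np.sum(1.0 / np.linalg.norm(summ[iu], axis=-1)))
    if fixed is not None and len(fixed):
        fixed = np.atleast_2d(np.asarray(fixed, float))
        d = np.linalg.norm(dirs[:, None, :] - fixed[None, :, :], axis=-1)
        s = np.linalg.norm(dirs[:, None, :] + fixed[None, :, :], axis=-1)
        e += float(np.sum(1.0 / d) + np.sum(1.0 / s))
    return e


def _repulsion_force(dirs: np.ndarray, fixed: np.ndarray | None) -> np.ndarray:
    """Cartesian gradient dE/d(dirs), shape (n, 3)."""
    n = len(dirs)
    grad = np.zeros_like(dirs)
    others = dirs if fixed is None or not len(fixed) else np.vstack([dirs, fixed])
    diff = dirs[:, None, :] - others[None, :, :]
    summ = dirs[:, None, :] + others[None, :, :]
    dn = np.linalg.norm(diff, axis=-1)
    sn = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(dn[:, :n], np.inf)  # self difference term excluded
    # self sum term: |2 di| is constant (unit vectors) -> gradient tangentially 0,
    # but exclude it anyway for exactness before tangent projection
    np.fill_diagonal(sn[:, :n], np.inf)
    grad -= np.einsum("ijk,ij->ik", diff, dn ** -3)
    grad -= np.einsum("ijk,ij->ik", summ, sn ** -3)
    return grad


def _dirs_from_sph(x: np.ndarray) -> np.ndarray:
    th, ph = x[0::2], x[1::2]
    st = np.sin(th)
    return np.column_stack([st * np.cos(ph), st * np.sin(ph), np.cos(th)])


def unit_directions_repulsion(n: int, fixed=None, seed: int = 0,
                              n_restarts: int = 10) -> list[np.ndarray]:
    """Uniformly distributed unit directions by electrostatic repulsion.

    Minimizes the antipodally symmetric Coulomb energy among ``n`` free
    directions and against the ``fixed`` set, by multi-restart local descent
    (L-BFGS over spherical coordinates with the analytic force); the best of
    ``n_restarts`` seeded restarts is kept, so the result is deterministic
    for a given seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    fixed_arr = None
    if fixed is not None and len(fixed):
        fixed_arr = np.array([np.asarray(f, float) / np.linalg.norm(f) for f in fixed])
    rng = np.random.default_rng(seed)

    def energy_grad(x: np.ndarray):
        th, ph = x[0::2], x[1::2]
        st, ct = np.sin(th), np.cos(th)
        sp, cp = np.sin(ph), np.cos(ph)
        dirs = np.column_stack([st * cp, st * sp, ct])
        e = repulsion_energy(dirs, fixed_arr)
        f = _repulsion_force(dirs, fixed_arr)
        # chain rule to spherical coordinates
        d_th = np.column_stack([ct * cp, ct * sp, -st])
        d_ph = np.column_stack([-st * sp, st * cp, np.zeros(n)])
        g = np.empty_like(x)
        g[0::2] = np.sum(f * d_th, axis=1)
        g[1::2] = np.sum(f * d_ph, axis=1)
        return e, g

    best_x, best_e = None, np.inf
    for _ in range(n_restarts):
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        x0 = np.empty(2 * n)
        x0[0::2] = np.arccos(np.clip(v[:, 2], -1, 1))
        x0[1::2] = np.arctan2(v[:, 1], v[:, 0])
        res = minimize(energy_grad, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-14})
        if res.fun < best_e:
            best_e, best_x = res.fun, res.x
    dirs = _dirs_from_sph(best_x)
    return [_canonical_axis(d / np.linalg.norm(d)) for d in dirs]


def _entries_b0(n_b0: int) -> list[SchemeEntry]:
    return [SchemeEntry((0.0, 0.0, 0.0), 0.0, "b0") for _ in range(n_b0)]


def _entry(vec: np.ndarray, nominal: float, label: str) -> SchemeEntry:
    v = tuple(float(c) for c in vec)
    return SchemeEntry(v, effective_bvalue(v, nominal), label)


def build_scheme(variant: str, *, nominal_bvalue: float = 1000.0, n_b0: int = 5,
                 n_inner: int = 16, n_outer: int = 30, n_directions: int = 30,
                 tetra_repeats: int = 2, hexa_repeats: int = 1,
                 n_shells: int = 3, n_per_shell: int = 10,
                 shell_bvalues=None, seed: int = 0) -> GradientScheme:
    """Construct a named gradient scheme.

    Variants:

    - ``cusp_t``: ``n_b0`` + ``n_inner`` unit-shell directions + the six
      hexahedral gradients (x ``hexa_repeats``) + the four tetrahedral
      gradients (x ``tetra_repeats``).  Defaults give the 35-image scheme
      (CUSP35).
    - ``cusp_xt``: unit shell + ``n_shells`` truncated shells with radii
      ``3**(j / (2 n_shells))`` (geometric in b-value), each ``n_per_shell``
      candidate directions truncated to the cube.
    - ``cusp_p``: ``n_inner`` unit shell + ``n_outer`` outer directions
      projected to the cube, with the 10 tetrahedral/hexahedral vectors
      force-included before repulsion optimization of the remainder.
      Defaults give the 65-image scheme (CUSP65).
    - ``single_shell``: ``n_directions`` unit directions (HARDI).
    - ``multi_shell``: unprojected shells at the b-values in
      ``shell_bvalues`` (default nominal x (1, 2, 3)); entries with norm
      above 1 exceed the cube and are flagged by their ``shell-k`` label.
    """
    tetra, hexa = cube_lattice_gradients()
    entries = _entries_b0(n_b0)

    if variant == "cusp_t":
        inner = unit_directions_repulsion(n_inner, seed=seed)
        entries += [_entry(d, nominal_bvalue, "inner") for d in inner]
        for _ in range(hexa_repeats):
            entries += [_entry(v, nominal_bvalue, "hexahedral") for v in hexa]
        for _ in range(tetra_repeats):
            entries += [_entry(v, nominal_bvalue, "tetrahedral") for v in tetra]

    elif variant == "cusp_xt":
        inner = unit_directions_repulsion(n_inner, seed=seed)
        entries += [_entry(d, nominal_bvalue, "inner") for d in inner]
        fixed = list(inner)
        for j in range(1, n_shells + 1):
            r = 3.0 ** (j / (2.0 * n_shells))
            dirs = unit_directions_repulsion(n_per_shell, fixed=fixed,
                                             seed=seed + j)
            fixed += dirs
            for d in dirs:
                v = r * d
                if np.max(np.abs(v)) <= 1.0 + _CUBE_TOL:  # truncation to cube
                    entries.append(_entry(v, nominal_bvalue, f"shell-{j}"))

    elif variant == "cusp_p":
        forced = tetra + hexa
        if n_outer < len(forced):
            raise ValueError(
                f"n_outer = {n_outer} below the {len(forced)} forced "
                "tetrahedral/hexahedral gradients")
        inner = unit_directions_repulsion(n_inner, seed=seed)
        entries += [_entry(d, nominal_bvalue, "inner") for d in inner]
        forced_units = [f / np.linalg.norm(f) for f in forced]
        n_free = n_outer - len(forced)
        if n_free > 0:
            free = unit_directions_repulsion(
                n_free, fixed=inner + forced_units, seed=seed + 1)
        else:
            free = []
        outer = forced + [project_to_cube(d) for d in free]
        entries += [_entry(v, nominal_bvalue, "projected") for v in outer]

    elif variant == "single_shell":
        dirs = unit_directions_repulsion(n_directions, seed=seed)
        entries += [_entry(d, nominal_bvalue, "inner") for d in dirs]

    elif variant == "multi_shell":
        if shell_bvalues is None:
            shell_bvalues = [nominal_bvalue, 2 * nominal_bvalue, 3 * nominal_bvalue]
        fixed: list[np.ndarray] = []
        for j, b in enumerate(shell_bvalues, start=1):
            r = float(np.sqrt(b / nominal_bvalue))
            dirs = unit_directions_repulsion(n_per_shell, fixed=fixed,
                                             seed=seed + j)
            fixed += dirs
            entries += [_entry(r * d, nominal_bvalue, f"shell-{j}") for d in dirs]

    else:
        raise ValueError(f"unknown scheme variant {variant!r}")

    scheme = GradientScheme(entries, nominal_bvalue)
    scheme.validate(require_b0=n_b0 > 0)
    return scheme
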
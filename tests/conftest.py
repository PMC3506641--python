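"""Shared fixtures: reference schemes, fit configurations, phantoms.

Heavy objects (schemes, which run a repulsion optimization) are
session-scoped; fit configurations come in two strengths — ``fast_config``
for the large noisy contrast simulations (where the scheme contrast, not
per-voxel convergence, is under test) and ``thorough_config`` for noise-free
parameter recovery.
"""

from pathlib import Path

import numpy as np
import pytest

from cuspmfm import build_scheme
from cuspmfm.estimation import FitConfig

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def cusp35():
    """35-image truncated CUSP scheme (5 b=0, 16 inner, 6 hexa, 2x4 tetra)."""
    return build_scheme("cusp_t", seed=1)


@pytest.fixture(scope="session")
def hardi35():
    """35-image single-shell comparison scheme (5 b=0, 30 directions)."""
    return build_scheme("single_shell", n_directions=30, seed=1)


@pytest.fixture(scope="session")
def cusp65():
    """65-image projected CUSP scheme (5 b=0, 30 inner, 30 projected)."""
    return build_scheme("cusp_p", n_inner=30, n_outer=30, seed=1)


@pytest.fixture(scope="session")
def cusp65_reference_text():
    return (DATA_DIR / "cusp65_reference.dvs").read_text()


@pytest.fixture()
def fast_config():
    """Light optimizer budget for large noisy simulation batches."""
    return FitConfig(alpha=0.0, n_sweeps=0, n_restarts=2, max_polish=2,
                     stage_maxfev=(200, 300, 400))


@pytest.fixture()
def thorough_config():
    """Tight convergence for noise-free parameter-recovery checks."""
    return FitConfig(alpha=0.0, n_sweeps=0, n_restarts=6, max_polish=8,
                     stage_maxfev=(400, 600, 900))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
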
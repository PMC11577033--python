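"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths:
``brute_force_distance_map`` finds each foreground voxel's nearest
background voxel by exhaustive search over physical coordinates, and
``grid_search_fit`` minimizes the mono-exponential sum of squared errors
over an explicit (S0, T2*) grid.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist


def brute_force_distance_map(mask: np.ndarray, voxel_dims_mm) -> np.ndarray:
    """Exhaustive nearest-background Euclidean distance (mm) per foreground
    voxel; NaN on background. The grid border counts as background."""
    mask = np.asarray(mask, bool)
    dims = np.asarray(voxel_dims_mm, float)
    padded = np.pad(mask, 1)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    out = np.full(padded.shape, np.nan)
    if fg.size:
        d = cdist(fg * dims, bg * dims)
        out[tuple(fg.T)] = d.min(axis=1)
    return out[1:-1, 1:-1, 1:-1]


def grid_search_fit(
    te: np.ndarray,
    signal: np.ndarray,
    s0_grid: np.ndarray,
    t2_grid: np.ndarray,
) -> tuple[float, float, float]:
    """Exhaustive SSE minimization of S0*exp(-TE/T2*) over the given grids.

    Evaluates the SSE for every (s0, t2) grid pair via the expansion
    sum_i (y_i - s0*m_i)^2 = C - 2*s0*A(t2) + s0^2*B(t2), which is exact.
    Returns (s0, t2, sse) at the grid minimum.
    """
    te = np.asarray(te, float)
    y = np.asarray(signal, float)
    model = np.exp(-te[None, :] / t2_grid[:, None])  # (n_t2, n_echo)
    A = model @ y
    B = np.einsum("ij,ij->i", model, model)
    C = float(y @ y)
    sse = C - 2.0 * np.outer(s0_grid, A) + np.outer(s0_grid**2, B)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return float(s0_grid[i]), float(t2_grid[j]), float(sse[i, j])


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
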
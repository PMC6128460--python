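"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately use naive, direct algorithms (all-pairs dominance
scans, exhaustive window loops, BFS flood fill) so they share no code path
with the package implementations they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# ranking oracles

def oracle_dominates(u, v) -> bool:
    """Weak Pareto dominance by direct elementwise comparison."""
    all_le = all(a <= b for a, b in zip(u, v))
    any_lt = any(a < b for a, b in zip(u, v))
    return all_le and any_lt


def oracle_nds_indices(X) -> list[int]:
    """Indices of non-dominated rows by all-pairs scan."""
    X = np.asarray(X, dtype=float)
    out = []
    for i in range(len(X)):
        if not any(oracle_dominates(X[j], X[i]) for j in range(len(X)) if j != i):
            out.append(i)
    return out


def oracle_pareto_ranks(X) -> np.ndarray:
    """Brute-force front peeling: recompute the NDS of the remainder each pass."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    ranks = np.zeros(n, dtype=int)
    remaining = list(range(n))
    current = 0
    while remaining:
        current += 1
        front = [
            i
            for i in remaining
            if not any(oracle_dominates(X[j], X[i]) for j in remaining if j != i)
        ]
        for i in front:
            ranks[i] = current
        remaining = [i for i in remaining if i not in front]
    return ranks


def oracle_pareto_ranks_matrix(X) -> np.ndarray:
    """Front peeling from an explicitly stored all-pairs dominance matrix.

    Independent of the package implementation (which never materializes the
    K x K matrix and deduplicates rows first): here the full matrix is built
    once and the non-dominated set of the remaining rows is re-read from it
    each pass.  Usable up to a few thousand rows.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    le = (X[:, None, :] <= X[None, :, :]).all(axis=2)
    lt = (X[:, None, :] < X[None, :, :]).any(axis=2)
    dom = le & lt  # dom[i, j]: row i dominates row j
    ranks = np.zeros(n, dtype=int)
    remaining = np.ones(n, dtype=bool)
    current = 0
    while remaining.any():
        current += 1
        dominated = dom[remaining][:, remaining].any(axis=0)
        idx = np.nonzero(remaining)[0]
        front = idx[~dominated]
        ranks[front] = current
        remaining[front] = False
    return ranks


# ---------------------------------------------------------------------------
# window / patch oracles

def oracle_focal_counts(indicator, weights, radius, cell_size):
    """Exhaustive circular-window numerator/denominator per cell.

    ``weights`` gives the per-cell contribution to the numerator (e.g. the
    indicator itself, or urban + 0.3 * agriculture); the denominator counts
    all in-grid cells whose centers fall within the radius.
    """
    indicator = np.asarray(indicator, dtype=float)
    weights = np.asarray(weights, dtype=float)
    rows, cols = indicator.shape
    r_cells = int(radius // cell_size)
    num = np.zeros((rows, cols))
    den = np.zeros((rows, cols))
    for i in range(rows):
        for j in range(cols):
            for di in range(-r_cells, r_cells + 1):
                for dj in range(-r_cells, r_cells + 1):
                    if (di * di + dj * dj) * cell_size**2 > radius**2:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < rows and 0 <= jj < cols:
                        den[i, j] += 1
                        num[i, j] += weights[ii, jj]
    return num, den


def oracle_patch_areas(open_cells, cell_size):
    """BFS flood fill over 4-connected open cells; area in hectares per cell."""
    open_cells = np.asarray(open_cells, dtype=bool)
    rows, cols = open_cells.shape
    out = np.full((rows, cols), np.nan)
    seen = np.zeros_like(open_cells)
    cell_ha = cell_size**2 / 10_000.0
    for i in range(rows):
        for j in range(cols):
            if not open_cells[i, j] or seen[i, j]:
                continue
            comp = []
            queue = deque([(i, j)])
            seen[i, j] = True
            while queue:
                ci, cj = queue.popleft()
                comp.append((ci, cj))
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = ci + di, cj + dj
                    if 0 <= ni < rows and 0 <= nj < cols and open_cells[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        queue.append((ni, nj))
            area = len(comp) * cell_ha
            for ci, cj in comp:
                out[ci, cj] = area
    return out


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def landscape():
    """Small synthetic landscape shared by pipeline-level tests."""
    from paretoprior import derive_standard_attributes, synthetic_landscape

    stack = synthetic_landscape(rows=40, cols=40, missing_fraction=0.1, n_zones=4, seed=7)
    return derive_standard_attributes(stack)
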
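"""Shared fixtures: small worlds, and an independent shortest-path oracle."""

import heapq
import math

import numpy as np
import pytest

from geoaccess import WorldConfig, make_world
from geoaccess.friction import FrictionGrid
from geoaccess.grid import GridSpec


def naive_travel_time(friction: FrictionGrid, seed_cells) -> np.ndarray:
    """Brute-force multi-source Dijkstra over an explicitly enumerated edge list.

    Deliberately independent of the package's graph construction: plain
    Python loops, a heapq frontier, and per-edge weights recomputed from
    first principles.  Returns minutes with inf for unreachable and NaN for
    barrier cells.
    """
    t = friction.minutes
    barrier = friction.barrier_mask
    n_rows, n_cols = friction.grid.shape
    dist = {}
    frontier = []
    for r, c in seed_cells:
        if not barrier[r, c]:
            dist[(r, c)] = 0.0
            heapq.heappush(frontier, (0.0, r, c))
    while frontier:
        d, r, c = heapq.heappop(frontier)
        if d > dist.get((r, c), math.inf):
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols) or barrier[rr, cc]:
                    continue
                w = 0.5 * (t[r, c] + t[rr, cc])
                if dr != 0 and dc != 0:
                    w *= math.sqrt(2.0)
                nd = d + w
                if nd < dist.get((rr, cc), math.inf) - 1e-18:
                    dist[(rr, cc)] = nd
                    heapq.heappush(frontier, (nd, rr, cc))
    out = np.full((n_rows, n_cols), np.inf)
    for (r, c), d in dist.items():
        out[r, c] = d
    out[barrier] = np.nan
    return out


@pytest.fixture(scope="session")
def oracle_travel_time():
    return naive_travel_time


@pytest.fixture(scope="session")
def small_world():
    """A compact world reused by read-only tests."""
    return make_world(
        WorldConfig(n_rows=80, n_cols=80, n_settlements=8, total_population=20_000),
        seed=11,
    )


@pytest.fixture
def unit_grid():
    """10x10 grid of 1 m cells with origin at (0, 10) — cell (r,c) spans integers."""
    return GridSpec(10, 10, 0.0, 10.0, 1.0)


def uniform_friction(n: int, minutes: float = 1.0, cell_size: float = 100.0) -> FrictionGrid:
    grid = GridSpec(n, n, 0.0, n * cell_size, cell_size)
    return FrictionGrid(
        minutes=np.full((n, n), minutes),
        barrier_mask=np.zeros((n, n), dtype=bool),
        grid=grid,
    )


@pytest.fixture(scope="session")
def make_uniform_friction():
    return uniform_friction
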
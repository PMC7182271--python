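"""Shared fixtures: small synthetic scenarios and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from geodose import (
    PlumeConfig,
    PopulationConfig,
    generate_plume,
    generate_population_map,
    select_boundary_subdivisions,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_plume():
    """Fast, coarse plume for unit tests (few vertices, small raster)."""
    cfg = PlumeConfig(
        epicenter=(0.0, 0.0),
        bearing_deg=60.0,
        length_km=6.0,
        width_km=2.0,
        vertex_density=400,
    )
    return generate_plume(cfg, seed=7, grid_n=400)


@pytest.fixture(scope="session")
def small_map():
    cfg = PopulationConfig(n_subdivisions=9, region=(-4.0, -4.0, 10.0, 10.0))
    return generate_population_map(cfg, seed=3)


@pytest.fixture(scope="session")
def eligible_ids(small_map, small_plume):
    return select_boundary_subdivisions(small_map, small_plume)


# ---------------------------------------------------------------------------
# independent oracles


def ray_cast_inside(poly_xy: np.ndarray, x: float, y: float) -> bool:
    """Brute-force even-odd ray casting, independent of shapely."""
    n = len(poly_xy)
    inside = False
    j = n - 1
    for i in range(n):
        xi, yi = poly_xy[i]
        xj, yj = poly_xy[j]
        if (yi > y) != (yj > y):
            x_cross = xi + (y - yi) / (yj - yi) * (xj - xi)
            if x < x_cross:
                inside = not inside
        j = i
    return inside


def dense_kriging_oracle(coords, values, model, target, method="ordinary", mean=None):
    """Loop-built kriging system solved densely: the reference for all variants."""
    n = len(coords)
    gamma = model.gamma
    if method == "simple":
        mu = float(np.mean(values)) if mean is None else mean
        C = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                h = np.hypot(*(coords[i] - coords[j]))
                C[i, j] = model.sill - gamma(h)
        c0 = np.array(
            [model.sill - gamma(np.hypot(*(coords[i] - target))) for i in range(n)]
        )
        lam = np.linalg.solve(C, c0)
        return mu + lam @ (values - mu), model.sill - lam @ c0, lam

    f = 1 if method == "ordinary" else 3
    A = np.zeros((n + f, n + f))
    for i in range(n):
        for j in range(n):
            A[i, j] = gamma(np.hypot(*(coords[i] - coords[j])))
        A[i, n] = A[n, i] = 1.0
        if f == 3:
            A[i, n + 1] = A[n + 1, i] = coords[i][0]
            A[i, n + 2] = A[n + 2, i] = coords[i][1]
    b = np.zeros(n + f)
    for i in range(n):
        b[i] = gamma(np.hypot(*(coords[i] - target)))
    b[n] = 1.0
    if f == 3:
        b[n + 1], b[n + 2] = target
    w = np.linalg.solve(A, b)
    pred = w[:n] @ values
    var = w @ b
    return pred, var, w[:n]


def raster_area(geom, bounds, n=1000) -> float:
    """Area of a shapely geometry by dense point-in-polygon rasterization."""
    import shapely

    xmin, ymin, xmax, ymax = bounds
    xs = np.linspace(xmin, xmax, n, endpoint=False) + (xmax - xmin) / (2 * n)
    ys = np.linspace(ymin, ymax, n, endpoint=False) + (ymax - ymin) / (2 * n)
    X, Y = np.meshgrid(xs, ys)
    hits = shapely.contains_xy(geom, X.ravel(), Y.ravel())
    return hits.sum() * (xmax - xmin) * (ymax - ymin) / (n * n)
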
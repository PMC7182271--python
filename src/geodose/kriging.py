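"""Kriging engine: semivariogram estimation and gridded dose prediction.

Implements the classical variants (ordinary, simple, universal) as dense
linear solves of the kriging systems, plus an empirical-Bayesian-style
variant (:func:`ebk`) that propagates semivariogram uncertainty by building a
per-locality ensemble of models via simulate-and-refit and predicting with a
likelihood-weighted mixture.  All variants return both a prediction and a
kriging standard error per grid cell; the standard error drives the adaptive
densification stage.

Design notes
------------
* Semivariogram convention: ``gamma(h) = nugget + psill * g(h / range)`` for
  h > 0 and gamma(0) = 0, with ``range`` the practical range (g reaches ~0.95
  of its sill there for the exponential/gaussian families).
* For small sample sets the full kriging system is factored once and solved
  against all grid cells; beyond ``global_threshold`` samples, a k-nearest
  neighborhood is used per cell with batched stacked solves.
* Predictions are clamped at 0 Gy (dose is physical); kriging variances are
  clamped at 0 before taking square roots.
* An optional boolean ``window`` restricts estimation to cells near the data;
  outside the window the prediction is 0 and the standard error is the prior
  standard deviation sqrt(nugget + psill).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.cluster.vq import kmeans2
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist

log = logging.getLogger(__name__)

__all__ = [
    "Grid",
    "SemivariogramModel",
    "KrigedSurface",
    "KrigingError",
    "empirical_semivariogram",
    "fit_semivariogram",
    "fit_reml",
    "krige",
    "ebk",
]


class KrigingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# grid


@dataclass(frozen=True)
class Grid:
    """Regular prediction grid; ``(x0, y0)`` is the lower-left corner."""

    x0: float
    y0: float
    cellsize: float
    nx: int
    ny: int

    @classmethod
    def from_bounds(
        cls, bounds: tuple[float, float, float, float], n: int = 200, margin: float = 0.1
    ) -> "Grid":
        xmin, ymin, xmax, ymax = bounds
        mx = (xmax - xmin) * margin
        my = (ymax - ymin) * margin
        xmin, xmax = xmin - mx, xmax + mx
        ymin, ymax = ymin - my, ymax + my
        cell = max(xmax - xmin, ymax - ymin) / n
        return cls(x0=xmin, y0=ymin, cellsize=cell, nx=n, ny=n)

    @property
    def xs(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cellsize

    @property
    def ys(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cellsize

    def centers(self) -> np.ndarray:
        """(ny*nx, 2) array of cell centers, row-major from the south row."""
        X, Y = np.meshgrid(self.xs, self.ys)
        return np.column_stack([X.ravel(), Y.ravel()])

    @property
    def cell_area(self) -> float:
        return self.cellsize**2

    def window_mask(
        self, bounds: tuple[float, float, float, float], expand: float = 0.4
    ) -> np.ndarray:
        """(ny, nx) mask of cells within an expanded bounding box."""
        xmin, ymin, xmax, ymax = bounds
        ex = max((xmax - xmin), self.cellsize) * expand
        ey = max((ymax - ymin), self.cellsize) * expand
        X, Y = np.meshgrid(self.xs, self.ys)
        return (
            (X >= xmin - ex) & (X <= xmax + ex) & (Y >= ymin - ey) & (Y <= ymax + ey)
        )


# ---------------------------------------------------------------------------
# semivariogram models


def _structure(family: str, h: np.ndarray, rng_: float) -> np.ndarray:
    t = np.asarray(h, dtype=float) / max(rng_, 1e-12)
    if family == "exponential":
        return 1.0 - np.exp(-3.0 * t)
    if family == "spherical":
        return np.where(t < 1.0, 1.5 * t - 0.5 * t**3, 1.0)
    if family == "gaussian":
        return 1.0 - np.exp(-3.0 * t**2)
    raise KrigingError(f"unknown semivariogram family {family!r}")


@dataclass(frozen=True)
class SemivariogramModel:
    family: str = "exponential"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_km: float = 1.0

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_km <= 0:
            raise KrigingError("nugget, sill must be >= 0 and range > 0")
        _structure(self.family, 0.0, 1.0)  # validates family

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h: np.ndarray) -> np.ndarray:
        """Semivariance at lag h; exactly 0 at h = 0."""
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.partial_sill * _structure(self.family, h, self.range_km)
        return np.where(h > 1e-12, g, 0.0)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """C(h) = sill - gamma(h); C(0) = sill."""
        return self.sill - self.gamma(h)


def _coords_values(samples) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(samples, "coords"):
        return samples.coords, samples.measured
    coords, values = samples
    return np.asarray(coords, dtype=float), np.asarray(values, dtype=float)


def _dedup(coords: np.ndarray, values: np.ndarray, tol: float = 1e-8):
    key = np.round(coords / tol).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    idx = np.sort(idx)
    return coords[idx], values[idx]


def empirical_semivariogram(
    samples,
    n_bins: int = 15,
    max_lag: float | None = None,
    max_points: int = 3000,
) -> np.ndarray:
    """Binned empirical semivariogram.

    Returns an array of rows ``(lag midpoint, semivariance, pair count)``
    where semivariance in a bin is the mean of ``0.5 * (z_i - z_j)^2`` over
    the sample pairs whose separation falls in the bin; empty bins are
    omitted.  For very large sample sets an evenly strided subset of
    ``max_points`` samples is used.
    """
    coords, values = _coords_values(samples)
    coords, values = _dedup(coords, values)
    if len(coords) < 2:
        raise KrigingError("need at least 2 distinct sample locations")
    if len(coords) > max_points:
        stride = np.linspace(0, len(coords) - 1, max_points).astype(int)
        coords, values = coords[stride], values[stride]
    d = pdist(coords)
    dz = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = float(d.max())
    keep = d <= max_lag
    d, dz = d[keep], dz[keep]
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        cnt = int(m.sum())
        if cnt == 0:
            continue
        rows.append((0.5 * (edges[b] + edges[b + 1]), float(dz[m].mean()), cnt))
    return np.asarray(rows)


def fit_semivariogram(
    empirical: np.ndarray,
    family: str = "exponential",
    fix_nugget: float | None = None,
) -> SemivariogramModel:
    """Fit a semivariogram model by pair-count-weighted least squares.

    On optimizer failure falls back to a flat heuristic (zero nugget, sill at
    the mean empirical semivariance, range at half the maximum lag) with a
    logged warning.
    """
    emp = np.asarray(empirical, dtype=float)
    if emp.ndim != 2 or len(emp) < 3:
        raise KrigingError("need at least 3 empirical semivariogram points")
    lags, semis, counts = emp[:, 0], emp[:, 1], emp[:, 2]
    w = np.sqrt(counts)
    max_lag = float(lags.max())
    s_hi = float(semis.max())

    def resid(x):
        nug, psill, rng_ = x
        if fix_nugget is not None:
            nug = fix_nugget
        g = nug + psill * _structure(family, lags, rng_)
        return w * (g - semis)

    nug0 = 0.0 if fix_nugget is not None else max(0.0, float(semis[0]) * 0.5)
    x0 = [nug0, max(s_hi - nug0, 1e-9), max_lag / 3.0]
    try:
        res = optimize.least_squares(
            resid,
            x0,
            bounds=([0.0, 0.0, max_lag * 1e-3], [np.inf, np.inf, max_lag * 10.0]),
            max_nfev=5000,
        )
        if not res.success:
            raise RuntimeError(res.message)
        nug, psill, rng_ = res.x
        if fix_nugget is not None:
            nug = fix_nugget
        return SemivariogramModel(family, float(nug), float(psill), float(rng_))
    except Exception as exc:  # noqa: BLE001 - deliberate robust fallback
        log.warning("semivariogram fit failed (%s); using flat heuristic", exc)
        return SemivariogramModel(
            family,
            0.0 if fix_nugget is None else fix_nugget,
            float(semis.mean()),
            max_lag / 2.0,
        )


def _stable_subsample(coords: np.ndarray, k: int) -> np.ndarray:
    """Pick k points by a coordinate-keyed pseudo-random priority.

    Each point's priority depends only on its own coordinates, so growing the
    point set displaces at most a few members of the selection -- unlike an
    index-based draw, which reshuffles completely when the set size changes.
    """
    u = np.modf(np.sin(coords[:, 0] * 12.9898 + coords[:, 1] * 78.233) * 43758.5453)[0]
    return np.argsort(u, kind="stable")[:k]


def fit_reml(
    samples,
    family: str = "exponential",
    max_points: int = 80,
    seed: int = 0,
    x0: SemivariogramModel | None = None,
) -> SemivariogramModel:
    """Restricted-maximum-likelihood fit of a constant-mean Gaussian field.

    REML integrates out the unknown mean, so the fitted nugget/sill/range are
    unbiased by mean estimation -- the hallmark of the empirical-Bayesian
    kriging variant.  For tractability the likelihood is evaluated on a
    seeded random subset of at most ``max_points`` samples.
    """
    coords, values = _coords_values(samples)
    coords, values = _dedup(coords, values)
    n = len(coords)
    if n < 5:
        raise KrigingError("need at least 5 distinct samples for REML")
    if n > max_points:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=max_points, replace=False)
        coords, values = coords[idx], values[idx]
        n = max_points
    D = cdist(coords, coords)
    var = max(float(values.var()), 1e-8)
    max_lag = float(D.max())
    ones = np.ones(n)

    def nll(logx):
        nug, psill, rng_ = np.exp(np.clip(logx, -40.0, 40.0))
        C = psill * (1.0 - _structure(family, D, rng_)) + nug * np.eye(n)
        try:
            L = np.linalg.cholesky(C + 1e-10 * var * np.eye(n))
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.log(np.diag(L)).sum()
        a = np.linalg.solve(L, values)
        b = np.linalg.solve(L, ones)
        btb = b @ b
        mean = (b @ a) / btb
        r = a - mean * b
        return 0.5 * (logdet + math.log(btb) + r @ r)

    if x0 is None:
        x0 = SemivariogramModel(family, 0.05 * var, var, max_lag / 4.0)
    start = np.log(
        [max(x0.nugget, 1e-6 * var), max(x0.partial_sill, 1e-6 * var), x0.range_km]
    )
    res = optimize.minimize(
        nll, start, method="Nelder-Mead", options={"maxiter": 300, "xatol": 1e-3}
    )
    nug, psill, rng_ = np.exp(np.clip(res.x, -40.0, 40.0))
    return SemivariogramModel(family, float(nug), float(psill), float(rng_))


# ---------------------------------------------------------------------------
# kriged surfaces


@dataclass
class KrigedSurface:
    """Gridded dose prediction with per-cell kriging standard errors."""

    grid: Grid
    prediction: np.ndarray  # (ny, nx), Gy, clamped >= 0
    std_error: np.ndarray  # (ny, nx), Gy, >= 0
    method: str
    model: object = None  # SemivariogramModel or list of ensembles (ebk)
    window: np.ndarray | None = None  # (ny, nx) bool, cells actually estimated

    def to_ascii_grid(self, path: str | Path, nodata: float = -9999.0) -> None:
        """Write the prediction as an ESRI ASCII grid (plain text)."""
        g = self.grid
        with open(path, "w") as fh:
            fh.write(
                f"ncols {g.nx}\nnrows {g.ny}\n"
                f"xllcorner {g.x0}\nyllcorner {g.y0}\n"
                f"cellsize {g.cellsize}\nNODATA_value {nodata}\n"
            )
            for row in self.prediction[::-1]:  # north row first
                fh.write(" ".join(f"{v:.5f}" for v in row) + "\n")

    def std_error_csv(self, path: str | Path) -> None:
        import pandas as pd

        centers = self.grid.centers()
        pd.DataFrame(
            {
                "x_km": centers[:, 0],
                "y_km": centers[:, 1],
                "std_error_gy": self.std_error.ravel(),
            }
        ).to_csv(path, index=False)


class _NeighborPlan:
    """Model-independent geometry shared by all kriging solves on one grid.

    Precomputes, per prediction target, either the full sample-distance
    matrices (global mode) or the k-nearest-neighbor indices and pairwise
    distance blocks (local mode), so that multi-model ensembles pay the
    geometry cost once.
    """

    def __init__(
        self,
        coords: np.ndarray,
        targets: np.ndarray,
        k: int = 32,
        global_threshold: int = 500,
        chunk: int = 4000,
    ):
        self.coords = coords
        self.targets = targets
        n = len(coords)
        self.global_mode = n <= max(global_threshold, k)
        if self.global_mode:
            self.D = cdist(coords, coords)
            self.d0 = cdist(targets, coords)
        else:
            tree = cKDTree(coords)
            self.d0, self.idx = tree.query(targets, k=k)
            self.chunk = chunk
            self._cache: list[tuple[int, int, np.ndarray]] = []

    def _chunks(self):
        # neighbor-pair distance blocks are model-independent: compute once,
        # reuse for every model of an ensemble
        if self._cache:
            yield from self._cache
            return
        m = len(self.targets)
        for a in range(0, m, self.chunk):
            b = min(a + self.chunk, m)
            P = self.coords[self.idx[a:b]]  # (c, k, 2)
            diff = P[:, :, None, :] - P[:, None, :, :]
            D = np.sqrt((diff**2).sum(-1))
            self._cache.append((a, b, D))
            yield a, b, D

    def solve(
        self,
        model: SemivariogramModel,
        values: np.ndarray,
        method: str = "ordinary",
        mean: float | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Kriging prediction and variance at every target for one model."""
        if method not in ("ordinary", "simple", "universal"):
            raise KrigingError(f"unknown kriging method {method!r}")
        if self.global_mode:
            return self._solve_global(model, values, method, mean)
        return self._solve_local(model, values, method, mean)

    # -- global: one factorization, all targets as right-hand sides
    def _solve_global(self, model, values, method, mean):
        n = len(self.coords)
        G = model.gamma(self.D)
        g0 = model.gamma(self.d0)  # (m, n)
        if method == "simple":
            mu = float(values.mean()) if mean is None else float(mean)
            C = model.covariance(self.D)
            c0 = model.sill - g0
            lam = _solve_with_fallback(C, c0.T).T  # (m, n)
            pred = mu + lam @ (values - mu)
            var = model.sill - (lam * c0).sum(1)
            return pred, var
        F = _drift(self.coords, method)  # (n, f)
        f0 = _drift(self.targets, method)  # (m, f)
        f = F.shape[1]
        A = np.zeros((n + f, n + f))
        A[:n, :n] = G
        A[:n, n:] = F
        A[n:, :n] = F.T
        B = np.hstack([g0, f0])  # (m, n+f)
        W = _solve_with_fallback(A, B.T).T  # (m, n+f)
        pred = W[:, :n] @ values
        var = (W * B).sum(1)
        return pred, var

    # -- local: batched stacked solves over neighbor systems
    def _solve_local(self, model, values, method, mean):
        m, k = self.idx.shape
        pred = np.empty(m)
        var = np.empty(m)
        mu = float(values.mean()) if mean is None else (mean or 0.0)
        for a, b, D in self._chunks():
            c = b - a
            zn = values[self.idx[a:b]]  # (c, k)
            g0 = model.gamma(self.d0[a:b])  # (c, k)
            if method == "simple":
                C = model.covariance(D)
                c0 = model.sill - g0
                lam = _batch_solve(C, c0)
                pred[a:b] = mu + (lam * (zn - mu)).sum(1)
                var[a:b] = model.sill - (lam * c0).sum(1)
                continue
            G = model.gamma(D)
            Fn = _drift_batch(self.coords[self.idx[a:b]], method)  # (c, k, f)
            f0 = _drift(self.targets[a:b], method)  # (c, f)
            f = Fn.shape[2]
            A = np.zeros((c, k + f, k + f))
            A[:, :k, :k] = G
            A[:, :k, k:] = Fn
            A[:, k:, :k] = np.transpose(Fn, (0, 2, 1))
            B = np.concatenate([g0, f0], axis=1)  # (c, k+f)
            W = _batch_solve(A, B)
            pred[a:b] = (W[:, :k] * zn).sum(1)
            var[a:b] = (W * B).sum(1)
        return pred, var


def _drift(pts: np.ndarray, method: str) -> np.ndarray:
    ones = np.ones((len(pts), 1))
    if method == "ordinary":
        return ones
    return np.hstack([ones, pts])  # universal: first-order trend


def _drift_batch(pts: np.ndarray, method: str) -> np.ndarray:
    c, k, _ = pts.shape
    ones = np.ones((c, k, 1))
    if method == "ordinary":
        return ones
    return np.concatenate([ones, pts], axis=2)


def _solve_with_fallback(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, B, rcond=None)[0]


def _batch_solve(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, B[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(B)
        for i in range(len(A)):
            try:
                out[i] = np.linalg.solve(A[i], B[i])
            except np.linalg.LinAlgError:
                out[i] = np.linalg.lstsq(A[i], B[i], rcond=None)[0]
        return out


def _assemble(
    grid: Grid,
    window: np.ndarray | None,
    pred_flat: np.ndarray,
    var_flat: np.ndarray,
    prior_sd: float,
    method: str,
    model,
) -> KrigedSurface:
    shape = (grid.ny, grid.nx)
    if window is None:
        pred = pred_flat.reshape(shape)
        sd = np.sqrt(np.clip(var_flat, 0.0, None)).reshape(shape)
    else:
        pred = np.zeros(shape)
        sd = np.full(shape, prior_sd)
        pred[window] = pred_flat
        sd[window] = np.sqrt(np.clip(var_flat, 0.0, None))
    return KrigedSurface(
        grid=grid,
        prediction=np.clip(pred, 0.0, None),
        std_error=sd,
        method=method,
        model=model,
        window=window,
    )


def krige(
    samples,
    model: SemivariogramModel,
    grid: Grid,
    method: str = "ordinary",
    mean: float | None = None,
    k_neighbors: int = 32,
    global_threshold: int = 500,
    window: np.ndarray | None = None,
) -> KrigedSurface:
    """Classical kriging of the sample set onto a grid.

    ``method`` is one of ``ordinary`` (unknown constant mean, weights sum to
    1), ``simple`` (known mean, default the sample mean of measured doses) or
    ``universal`` (first-order spatial trend).  Duplicate coordinates are
    removed before solving.
    """
    coords, values = _coords_values(samples)
    coords, values = _dedup(coords, values)
    if len(coords) < 2:
        raise KrigingError("need at least 2 distinct samples to krige")
    centers = grid.centers()
    if window is not None:
        targets = centers[window.ravel()]
    else:
        targets = centers
    plan = _NeighborPlan(
        coords, targets, k=min(k_neighbors, len(coords)), global_threshold=global_threshold
    )
    pred, var = plan.solve(model, values, method=method, mean=mean)
    return _assemble(grid, window, pred, var, math.sqrt(model.sill), method, model)


# ---------------------------------------------------------------------------
# empirical-Bayesian-style ensemble kriging


def _simulate_refit(
    coords: np.ndarray,
    base: SemivariogramModel,
    mean: float,
    rng: np.random.Generator,
    family: str,
    n_sims: int,
) -> list[SemivariogramModel]:
    """Simulate data from the fitted model and refit: the model ensemble."""
    n = len(coords)
    D = cdist(coords, coords)
    C = base.partial_sill * (1.0 - _structure(family, D, base.range_km))
    C += (base.nugget + 1e-10 * max(base.sill, 1e-9)) * np.eye(n)
    L = np.linalg.cholesky(C)
    out = []
    span = max(cdist(coords, coords).max(), 1e-6)
    for _ in range(n_sims):
        z = mean + L @ rng.standard_normal(n)
        try:
            emp = empirical_semivariogram((coords, z), n_bins=12)
            m = fit_semivariogram(emp, family=family)
            # keep refits within physically sane bounds of the base fit
            m = SemivariogramModel(
                family,
                min(m.nugget, 10.0 * base.sill + 1e-9),
                min(m.partial_sill, 10.0 * base.sill + 1e-9),
                float(np.clip(m.range_km, 0.05 * base.range_km, 2.0 * span)),
            )
            out.append(m)
        except KrigingError:
            out.append(base)
    return out


def _loglik(coords, values, model: SemivariogramModel) -> float:
    n = len(coords)
    D = cdist(coords, coords)
    C = model.covariance(D) + 1e-10 * max(model.sill, 1e-9) * np.eye(n)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return -1e12
    a = np.linalg.solve(L, values)
    b = np.linalg.solve(L, np.ones(n))
    mean = (b @ a) / (b @ b)
    r = a - mean * b
    return float(-0.5 * (2 * np.log(np.diag(L)).sum() + r @ r))


def ebk(
    samples,
    grid: Grid,
    n_subsets: int = 10,
    n_sims: int = 30,
    seed: int = 0,
    k_neighbors: int = 32,
    global_threshold: int = 500,
    window: np.ndarray | None = None,
    family: str = "exponential",
    fit_max_points: int = 80,
    min_samples: int = 8,
    centroids: np.ndarray | None = None,
) -> KrigedSurface:
    """Ensemble kriging in the spirit of empirical Bayesian kriging.

    Samples are partitioned into ``n_subsets`` spatial localities (k-means on
    coordinates).  Each locality gets a REML-fitted base semivariogram plus
    ``n_sims - 1`` models obtained by simulating data from the base fit and
    refitting -- a distribution of semivariograms expressing how uncertain the
    spatial structure is given this many samples.  Grid cells are predicted by
    the locality nearest to them, as the likelihood-weighted mixture of
    per-model ordinary-kriging predictions; the reported variance adds the
    between-model spread to the within-model kriging variance.  With one
    subset and one simulation this reduces exactly to ordinary kriging with
    the REML fit.  Deterministic given ``seed``.

    This is a documented approximation of the proprietary EBK procedure in
    commercial GIS software, not a reimplementation of it.
    """
    coords, values = _coords_values(samples)
    coords, values = _dedup(coords, values)
    rng = np.random.default_rng(seed)

    if len(coords) < max(min_samples, 2):
        log.warning("ebk: too few samples (%d); downgrading to ordinary kriging", len(coords))
        emp = empirical_semivariogram((coords, values))
        model = fit_semivariogram(emp, family=family)
        return krige(
            (coords, values), model, grid, "ordinary",
            k_neighbors=k_neighbors, global_threshold=global_threshold, window=window,
        )

    n_subsets = max(1, min(n_subsets, len(coords) // max(min_samples, 5)))
    if centroids is not None:
        # caller-fixed localities (e.g. held constant across pipeline
        # iterations so the partition does not drift as samples accumulate)
        centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
        labels = np.argmin(cdist(coords, centroids), axis=1)
        present = np.unique(labels)
        centroids = centroids[present]
        labels = np.searchsorted(present, labels)
    elif n_subsets == 1:
        labels = np.zeros(len(coords), dtype=int)
        centroids = coords.mean(axis=0, keepdims=True)
    else:
        centroids, labels = kmeans2(
            coords, n_subsets, minit="++", seed=int(rng.integers(2**31 - 1))
        )
        present = np.unique(labels)
        centroids = np.array([coords[labels == s].mean(axis=0) for s in present])
        labels = np.searchsorted(present, labels)

    # global WLS fit as initialization and as fallback for thin subsets
    try:
        global_model = fit_semivariogram(
            empirical_semivariogram((coords, values)), family=family
        )
    except KrigingError:
        global_model = SemivariogramModel(family, 0.0, max(values.var(), 1e-6), 1.0)

    ensembles: list[list[SemivariogramModel]] = []
    weights: list[np.ndarray] = []
    for s in range(len(centroids)):
        sc, sv = coords[labels == s], values[labels == s]
        # keyed by subset index, so one subset's draws do not shift another's
        sub_seed = int(
            np.random.SeedSequence([int(seed), 7919, s]).generate_state(1)[0]
            % (2**31 - 1)
        )
        if len(sc) > fit_max_points:
            pick = _stable_subsample(sc, fit_max_points)
            sc, sv = sc[pick], sv[pick]
        try:
            base = fit_reml((sc, sv), family=family, max_points=fit_max_points,
                            seed=sub_seed, x0=global_model)
        except KrigingError:
            base = global_model
        models = [base]
        if n_sims > 1:
            models += _simulate_refit(
                sc, base, float(sv.mean()),
                np.random.default_rng(sub_seed + 1), family, n_sims - 1,
            )
        # per-observation mean log-likelihood: tempered weights, so the
        # mixture stays a mixture instead of collapsing onto one member
        ll = np.array([_loglik(sc, sv, m) for m in models]) / max(len(sv), 1)
        w = np.exp(ll - ll.max())
        weights.append(w / w.sum())
        ensembles.append(models)

    centers = grid.centers()
    targets = centers[window.ravel()] if window is not None else centers
    owner = np.argmin(cdist(targets, centroids), axis=1)

    pred = np.zeros(len(targets))
    var = np.zeros(len(targets))
    for s, (models, w) in enumerate(zip(ensembles, weights)):
        cells = owner == s
        if not cells.any():
            continue
        plan = _NeighborPlan(
            coords, targets[cells], k=min(k_neighbors, len(coords)),
            global_threshold=global_threshold,
        )
        mix_p = np.zeros(int(cells.sum()))
        mix_m2 = np.zeros_like(mix_p)
        for m, wm in zip(models, w):
            p, v = plan.solve(m, values, method="ordinary")
            mix_p += wm * p
            mix_m2 += wm * (np.clip(v, 0.0, None) + p**2)
        pred[cells] = mix_p
        var[cells] = np.clip(mix_m2 - mix_p**2, 0.0, None)

    prior_sd = math.sqrt(max(m.sill for m in ensembles[0]))
    return _assemble(grid, window, pred, var, prior_sd, "ebk", ensembles)
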
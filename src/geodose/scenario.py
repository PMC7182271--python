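"""Synthetic ground-truth scenarios: dispersion-style dose plumes and census-like
population maps.

The ground truth in a real deployment would come from an atmospheric
transport/dispersion model; here an anisotropic, downwind-skewed ("teardrop")
dose field stands in for it.  Only the *contour representation* matters to the
rest of the pipeline: a plume is an ordered stack of nested closed rings, one
per dose level, traced by dense boundary vertices.  True dose at any point is
defined as the level of the outermost ring that does NOT contain it plus one
step -- i.e. a point between the 2.5 and 3.0 Gy rings is assigned 2.5 Gy, the
level of the outer boundary of the band it falls in.  That step-function
convention is a deliberate, documented source of systematic error in the
method being simulated.

Coordinates are planar kilometres throughout; bearings are degrees clockwise
from north (so the downwind unit vector of bearing b is (sin b, cos b)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import voronoi_diagram
from skimage import measure

__all__ = [
    "PlumeConfig",
    "GroundTruthPlume",
    "Subdivision",
    "SubdivisionMap",
    "ScenarioError",
    "generate_plume",
    "generate_population_map",
    "dose_at",
    "dose_at_many",
    "URBAN_RURAL_DENSITY_BOUNDARY",
]

# 10,000 persons per square mile, the urban/rural boundary, in persons/km^2.
URBAN_RURAL_DENSITY_BOUNDARY = 10_000 / 2.589988


class ScenarioError(ValueError):
    """Invalid scenario configuration or geometry."""


# Weather acts as a fixed multiplicative reshaping of the plume: precipitation
# scavenges fallout, shortening and narrowing the footprint.
WEATHER_FACTORS = {
    "none": (1.0, 1.0),
    "rain": (0.85, 0.90),
    "snow": (0.80, 0.85),
}


@dataclass(frozen=True)
class PlumeConfig:
    """Parameters of the synthetic dose field.

    ``length_km``/``width_km`` are the nominal downwind extent and maximum
    crosswind extent of the lowest (0.5 Gy) contour.  ``peak_dose_gy`` caps the
    contour stack; levels run ``step, 2*step, ...`` up to the largest multiple
    of ``step`` not exceeding the peak.  ``roughness`` adds a smooth seeded
    angular perturbation so replicate scenarios are not perfect ellipses.
    """

    epicenter: tuple[float, float] = (0.0, 0.0)
    bearing_deg: float = 60.0
    length_km: float = 8.0
    width_km: float = 2.5
    peak_dose_gy: float = 8.0
    contour_step_gy: float = 0.5
    vertex_density: int = 4000
    weather_variant: str = "none"
    roughness: float = 0.04
    upwind_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.length_km <= 0 or self.width_km <= 0:
            raise ScenarioError("plume length and width must be positive")
        if self.peak_dose_gy <= self.contour_step_gy:
            raise ScenarioError("peak dose must exceed the contour step")
        if self.weather_variant not in WEATHER_FACTORS:
            raise ScenarioError(f"unknown weather variant {self.weather_variant!r}")


@dataclass
class GroundTruthPlume:
    """Nested dose-contour stack: the oracle for true dose at any location."""

    epicenter: tuple[float, float]
    bearing_deg: float
    contours: list[tuple[float, Polygon]]  # ascending level, rings nest inward
    vertex_density: int
    weather_variant: str = "none"
    config: PlumeConfig | None = None

    @property
    def levels(self) -> list[float]:
        return [lv for lv, _ in self.contours]

    @property
    def footprint(self) -> Polygon:
        """Outermost (lowest-level) ring: the >0 Gy envelope."""
        return self.contours[0][1]

    def innermost(self) -> tuple[float, Polygon]:
        return self.contours[-1]


@dataclass(frozen=True)
class Subdivision:
    id: str
    boundary: Polygon
    population: int

    @property
    def area_km2(self) -> float:
        return self.boundary.area

    @property
    def density(self) -> float:
        return self.population / self.boundary.area


@dataclass
class SubdivisionMap:
    subdivisions: list[Subdivision]
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

    def __getitem__(self, sid: str) -> Subdivision:
        for s in self.subdivisions:
            if s.id == sid:
                return s
        raise KeyError(sid)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subdivisions]

    @property
    def total_population(self) -> int:
        return sum(s.population for s in self.subdivisions)


# ---------------------------------------------------------------------------
# dose field


def _downwind_frame(epicenter: Sequence[float], bearing_deg: float):
    b = math.radians(bearing_deg)
    d = np.array([math.sin(b), math.cos(b)])  # downwind unit vector
    c = np.array([math.cos(b), -math.sin(b)])  # crosswind unit vector
    e = np.asarray(epicenter, dtype=float)
    return e, d, c


def _field_factory(cfg: PlumeConfig, seed: int):
    """Smooth unimodal dose field whose superlevel sets are the plume bands.

    F(u, v) = A * exp(-(u^2 / (2 s_u(u)^2) + v^2 / (2 s_c(u)^2))) * r(x, y)

    with u the downwind and v the crosswind coordinate.  The downwind scale is
    much longer than the upwind one (teardrop skew) and the crosswind scale
    widens with distance downwind.  The amplitude sits half a contour step
    above the configured peak so the topmost ring is a genuine polygon.  A
    low-order angular Fourier perturbation (seeded, amplitude ``roughness``,
    suppressed near the epicenter) roughens the contours the way a real
    dispersion run is rough; superlevel sets of any scalar field nest, so the
    contour-nesting invariant survives the perturbation.
    """
    lf, wf = WEATHER_FACTORS[cfg.weather_variant]
    length = cfg.length_km * lf
    width = cfg.width_km * wf
    amplitude = cfg.peak_dose_gy + 0.5 * cfg.contour_step_gy
    # kappa: number of downwind "sigmas" from peak to the lowest contour.
    kappa = math.sqrt(2.0 * math.log(amplitude / cfg.contour_step_gy))
    s_down = length / kappa
    s_up = s_down * cfg.upwind_fraction
    c_base = (width / 2.0) / kappa

    rng = np.random.default_rng(seed)
    modes = np.arange(2, 6)
    amps = rng.normal(0.0, 1.0, size=modes.size)
    amps *= cfg.roughness / max(1e-12, np.abs(amps).sum())
    phases = rng.uniform(0.0, 2.0 * np.pi, size=modes.size)

    e, d, c = _downwind_frame(cfg.epicenter, cfg.bearing_deg)

    def field(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx = np.asarray(x, dtype=float) - e[0]
        dy = np.asarray(y, dtype=float) - e[1]
        u = dx * d[0] + dy * d[1]
        v = dx * c[0] + dy * c[1]
        su = np.where(u >= 0.0, s_down, s_up)
        # crosswind widening: narrow at the source, widest downwind
        frac = np.clip(u / max(length, 1e-9), 0.0, 1.0)
        sc = c_base * (0.45 + 0.55 * frac)
        q = (u / su) ** 2 + (v / sc) ** 2
        base = amplitude * np.exp(-0.5 * q)
        if cfg.roughness > 0.0:
            theta = np.arctan2(v, u)
            r = np.hypot(u, v)
            ramp = np.clip(r / (0.15 * length), 0.0, 1.0)  # flat at epicenter
            pert = np.zeros_like(base)
            for m, a, p in zip(modes, amps, phases):
                pert += a * np.cos(m * theta + p)
            base = base * np.exp(ramp * pert)
        return base

    extent = max(length, width) * 1.6
    return field, extent


def _resample_ring(xy: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n vertices at equal arc length."""
    if not np.allclose(xy[0], xy[-1]):
        xy = np.vstack([xy, xy[0]])
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, xy[:, 0])
    y = np.interp(t, s, xy[:, 1])
    return np.column_stack([x, y])


def generate_plume(config: PlumeConfig, seed: int, grid_n: int = 700) -> GroundTruthPlume:
    """Generate a nested-contour ground-truth plume from the synthetic field.

    Contours are level sets of the smooth field extracted on a ``grid_n``-point
    raster by marching squares, then resampled to ``vertex_density`` vertices
    at equal arc-length spacing.  Deterministic given ``seed``.
    """
    field, extent = _field_factory(config, seed)
    e = np.asarray(config.epicenter, dtype=float)
    _, d, _ = _downwind_frame(config.epicenter, config.bearing_deg)

    # raster window comfortably containing the lowest contour
    lo = e - extent
    hi = e + extent
    xs = np.linspace(lo[0], hi[0], grid_n)
    ys = np.linspace(lo[1], hi[1], grid_n)
    X, Y = np.meshgrid(xs, ys)
    Z = field(X, Y)

    step = config.contour_step_gy
    n_levels = int(math.floor(config.peak_dose_gy / step + 1e-9))
    levels = [step * (k + 1) for k in range(n_levels)]

    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    contours: list[tuple[float, Polygon]] = []
    for lv in levels:
        curves = measure.find_contours(Z, lv)
        if not curves:
            raise ScenarioError(f"level {lv} Gy produced no contour; peak too low?")
        best = max(curves, key=len)
        # find_contours returns (row, col) = (y index, x index)
        xy = np.column_stack([lo[0] + best[:, 1] * dx, lo[1] + best[:, 0] * dy])
        xy = _resample_ring(xy, config.vertex_density)
        ring = Polygon(xy)
        if not ring.is_valid:
            ring = ring.buffer(0)
            if ring.geom_type != "Polygon":
                ring = max(ring.geoms, key=lambda g: g.area)
        contours.append((lv, ring))

    return GroundTruthPlume(
        epicenter=tuple(e),
        bearing_deg=config.bearing_deg,
        contours=contours,
        vertex_density=config.vertex_density,
        weather_variant=config.weather_variant,
        config=config,
    )


# ---------------------------------------------------------------------------
# dose queries


def dose_at(plume: GroundTruthPlume, point: Sequence[float]) -> float:
    """True dose at a point: the level of the innermost ring containing it.

    Points between two rings take the *outer* boundary's level; points outside
    every ring take 0 Gy.
    """
    return float(dose_at_many(plume, np.asarray([point], dtype=float))[0])


def dose_at_many(plume: GroundTruthPlume, points: np.ndarray) -> np.ndarray:
    """Vectorized :func:`dose_at` over an (n, 2) array of coordinates."""
    pts = np.asarray(points, dtype=float)
    doses = np.zeros(len(pts))
    inside_prev = np.ones(len(pts), dtype=bool)
    for lv, ring in plume.contours:
        idx = np.flatnonzero(inside_prev)
        if idx.size == 0:
            break
        hit = shapely.contains_xy(ring, pts[idx, 0], pts[idx, 1])
        doses[idx[hit]] = lv
        mask = np.zeros(len(pts), dtype=bool)
        mask[idx[hit]] = True
        inside_prev = mask
    return doses


# ---------------------------------------------------------------------------
# population maps


@dataclass(frozen=True)
class PopulationConfig:
    n_subdivisions: int = 9
    density_regime: str = "urban"  # urban: >10,000/mi^2; rural: below
    total_population: int | None = None
    region: tuple[float, float, float, float] = (-5.0, -5.0, 15.0, 15.0)

    def __post_init__(self) -> None:
        if self.n_subdivisions < 1:
            raise ScenarioError("need at least one subdivision")
        xmin, ymin, xmax, ymax = self.region
        if xmax <= xmin or ymax <= ymin:
            raise ScenarioError("degenerate region box")
        if self.total_population is not None and self.total_population < 0:
            raise ScenarioError("population must be non-negative")
        if self.density_regime not in ("urban", "rural"):
            raise ScenarioError(f"unknown density regime {self.density_regime!r}")


# Density bands straddling the 10,000/mi^2 (3861/km^2) urban/rural boundary.
_DENSITY_BANDS = {"urban": (4200.0, 7000.0), "rural": (100.0, 1000.0)}


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    quota = total * w / w.sum()
    alloc = np.floor(quota).astype(int)
    short = total - alloc.sum()
    order = np.argsort(-(quota - alloc))
    alloc[order[:short]] += 1
    return alloc


def generate_population_map(config: PopulationConfig, seed: int) -> SubdivisionMap:
    """Tile the region into n simple polygons with census-like populations.

    The tiling is the Voronoi diagram of n seeded random points clipped to the
    region box, so subdivisions are simple, non-overlapping, and cover the box
    exactly.  Each subdivision draws a population density uniformly from its
    regime's band (urban entirely above, rural entirely below, the
    10,000/mi^2 boundary); an explicitly configured total population overrides
    the regime-implied total and is apportioned by largest remainder so the
    configured total is conserved exactly.
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = config.region
    region = box(xmin, ymin, xmax, ymax)
    n = config.n_subdivisions

    if n == 1:
        polys = [region]
    else:
        # rejection: re-seed until voronoi yields exactly n clipped cells
        for _ in range(20):
            pts = np.column_stack(
                [rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)]
            )
            cells = voronoi_diagram(
                shapely.multipoints(pts), envelope=region.buffer(2.0)
            )
            polys_try = [g.intersection(region) for g in cells.geoms]
            polys_try = [p for p in polys_try if p.geom_type == "Polygon" and p.area > 0]
            if len(polys_try) == n:
                polys = polys_try
                break
        else:  # pragma: no cover - voronoi of distinct points is well posed
            raise ScenarioError("region too small to tile into that many subdivisions")

    areas = np.array([p.area for p in polys])
    lo, hi = _DENSITY_BANDS[config.density_regime]
    densities = rng.uniform(lo, hi, size=len(polys))
    raw = densities * areas

    if config.total_population is None:
        pops = np.round(raw).astype(int)
    else:
        pops = _largest_remainder(raw, config.total_population)

    subs = [
        Subdivision(id=f"S{i:02d}", boundary=p, population=int(pop))
        for i, (p, pop) in enumerate(zip(polys, pops))
    ]
    return SubdivisionMap(subdivisions=subs, bounds=(xmin, ymin, xmax, ymax))
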
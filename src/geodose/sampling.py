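"""Population-proportional sampling and simulated field measurement.

Initial sampling mirrors a responder protocol: each census-like subdivision
that overlaps or immediately surrounds the plume contributes a quota of
uniform random locations equal to a fixed fraction (default 0.1%) of its
population.  Restricting the unirradiated (0 Gy) locations to the surrounding
subdivisions keeps the many background points from depressing the kriged
plume while still bounding it.  Measurement is simulated by reading the
ground-truth dose, optionally perturbed by a bounded uniform error emulating
physical or cytogenetic dosimetry uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .scenario import GroundTruthPlume, SubdivisionMap, dose_at_many

__all__ = [
    "SampleSet",
    "SamplingError",
    "InsufficientSamplingError",
    "select_boundary_subdivisions",
    "draw_initial_samples",
    "draw_biased_samples",
    "inject_dose_error",
    "sampling_bearing_error",
]

COLUMNS = [
    "x_km",
    "y_km",
    "true_dose_gy",
    "measured_dose_gy",
    "iteration",
    "source",
    "subdivision_id",
]


class SamplingError(ValueError):
    pass


class InsufficientSamplingError(SamplingError):
    """All subdivision quotas rounded to zero; advise a larger fraction."""


@dataclass
class SampleSet:
    """Accumulating set of located dose measurements.

    Backed by a DataFrame with one row per sample (columns in ``COLUMNS``);
    rows are append-only across pipeline iterations.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        return self.df[["x_km", "y_km"]].to_numpy(dtype=float)

    @property
    def measured(self) -> np.ndarray:
        return self.df["measured_dose_gy"].to_numpy(dtype=float)

    @property
    def true(self) -> np.ndarray:
        return self.df["true_dose_gy"].to_numpy(dtype=float)

    @property
    def n_irradiated(self) -> int:
        """Samples whose true location lies inside the plume (>0 Gy)."""
        return int((self.df["true_dose_gy"] > 0).sum())

    def extend(self, other: "SampleSet") -> "SampleSet":
        df = pd.concat([self.df, other.df], ignore_index=True)
        return SampleSet(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSet":
        df = pd.read_csv(path)
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise SamplingError(f"sample CSV missing columns: {sorted(missing)}")
        return cls(df[COLUMNS])


def select_boundary_subdivisions(
    smap: SubdivisionMap, plume: GroundTruthPlume
) -> set[str]:
    """Subdivisions intersecting the plume footprint, plus their neighbors.

    Adjacency means a shared boundary segment of positive length (corner
    touches do not count).  Sampling is restricted to this set so that 0 Gy
    locations bound the plume without flooding the interpolation.
    """
    footprint = plume.footprint
    hit = {s.id for s in smap.subdivisions if s.boundary.intersects(footprint)}
    if not hit:
        raise SamplingError("plume footprint intersects no subdivision")
    out = set(hit)
    hit_polys = [smap[sid].boundary for sid in hit]
    for s in smap.subdivisions:
        if s.id in out:
            continue
        for hp in hit_polys:
            inter = s.boundary.boundary.intersection(hp.boundary)
            if inter.length > 1e-9:
                out.add(s.id)
                break
    return out


def _points_in_polygon(poly, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points strictly inside a polygon via bbox rejection sampling."""
    xmin, ymin, xmax, ymax = poly.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(32, int((n - len(pts)) * 2.5))
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[keep]])
    return pts[:n]


def _quota(fraction: float, population: int) -> int:
    """Round-half-up quota: reproducible, documented rounding rule."""
    return int(math.floor(fraction * population + 0.5))


def draw_biased_samples(
    smap: SubdivisionMap,
    plume: GroundTruthPlume,
    fractions: dict[str, float],
    seed: int,
    eligible: set[str] | None = None,
) -> SampleSet:
    """Draw per-subdivision quotas with possibly unequal sampling fractions.

    Unequal fractions emulate sampling under a mis-specified wind bearing
    (oversampling an unaffected subdivision while undersampling the affected
    one).  With all fractions equal this is exactly
    :func:`draw_initial_samples`.
    """
    if eligible is None:
        eligible = select_boundary_subdivisions(smap, plume)
    known = set(smap.ids)
    for sid in fractions:
        if sid not in known:
            raise SamplingError(f"unknown subdivision id {sid!r}")
    for sid, f in fractions.items():
        if not (0.0 < f <= 1.0):
            raise SamplingError(f"fraction for {sid!r} must be in (0, 1]")

    rng = np.random.default_rng(seed)
    rows = []
    total = 0
    for s in smap.subdivisions:  # fixed order => determinism
        if s.id not in eligible or s.id not in fractions:
            continue
        q = _quota(fractions[s.id], s.population)
        total += q
        if q == 0:
            continue
        pts = _points_in_polygon(s.boundary, q, rng)
        rows.append(
            pd.DataFrame(
                {
                    "x_km": pts[:, 0],
                    "y_km": pts[:, 1],
                    "subdivision_id": s.id,
                }
            )
        )
    if total == 0:
        raise InsufficientSamplingError(
            "all subdivision quotas rounded to zero; increase the sampling "
            "fraction (e.g. 0.2% or 1.0% in low-density regions)"
        )
    df = pd.concat(rows, ignore_index=True)
    dose = dose_at_many(plume, df[["x_km", "y_km"]].to_numpy())
    df["true_dose_gy"] = dose
    df["measured_dose_gy"] = dose
    df["iteration"] = 0
    df["source"] = "initial"
    return SampleSet(df[COLUMNS])


def draw_initial_samples(
    smap: SubdivisionMap,
    plume: GroundTruthPlume,
    fraction: float = 0.001,
    seed: int = 0,
    eligible: set[str] | None = None,
) -> SampleSet:
    """Uniform-fraction initial sampling (default 0.1% of each subdivision)."""
    if not (0.0 < fraction <= 1.0):
        raise SamplingError("fraction must be in (0, 1]")
    if eligible is None:
        eligible = select_boundary_subdivisions(smap, plume)
    fractions = {sid: fraction for sid in eligible}
    return draw_biased_samples(smap, plume, fractions, seed, eligible=eligible)


def inject_dose_error(samples: SampleSet, max_error: float, seed: int) -> SampleSet:
    """Perturb measured doses by U(-max_error, +max_error), clamped at 0 Gy.

    Applied to every sample; emulates bounded dosimetry uncertainty (e.g.
    ±0.5 Gy for dicentric assays, ±1.0 Gy for micronucleus assays).
    """
    if max_error < 0:
        raise SamplingError("max_error must be non-negative")
    df = samples.df.copy()
    if max_error > 0 and len(df):
        rng = np.random.default_rng(seed)
        u = rng.uniform(-max_error, max_error, size=len(df))
        df["measured_dose_gy"] = np.clip(df["true_dose_gy"].to_numpy() + u, 0.0, None)
    else:
        df["measured_dose_gy"] = df["true_dose_gy"]
    return SampleSet(df)


def sampling_bearing_error(samples: SampleSet, plume: GroundTruthPlume) -> float:
    """Angular difference (degrees) between sample-centroid bearing and wind.

    The bearing from the epicenter to the centroid of all sampled locations is
    compared with the plume's downwind bearing; a large difference diagnoses a
    directional sampling bias.  Returns a value in [0, 180].
    """
    if len(samples) == 0:
        raise SamplingError("need at least one sample")
    cx, cy = samples.coords.mean(axis=0)
    ex, ey = plume.epicenter
    dx, dy = cx - ex, cy - ey
    if math.hypot(dx, dy) < 1e-12:
        raise SamplingError("sample centroid coincides with the epicenter")
    bearing = math.degrees(math.atan2(dx, dy)) % 360.0
    diff = abs(bearing - plume.bearing_deg % 360.0)
    return min(diff, 360.0 - diff)
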
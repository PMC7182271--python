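"""Adaptive densification: choose the next round of sampling locations.

The selection criterion mirrors the "upper quartile above threshold" rule of
the GIS densification tool this emulates: a grid cell is eligible when the
upper quartile of its predicted dose distribution -- prediction plus
0.6745 standard errors under a Gaussian assumption -- reaches the treatment
threshold (default 2 Gy).  Eligible cells are ranked by descending kriging
standard error (sample where the map is least certain), thinned to a minimum
spacing, deduplicated against already-sampled locations, and capped at
``max_n`` (default 200).  Cells inside the 0 Gy envelope -- subdivisions
whose every sample so far read 0 Gy and which do not touch the current
derived plume -- are never proposed: responders need not revisit confirmed
background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union

from .kriging import KrigedSurface
from .sampling import COLUMNS, SampleSet
from .scenario import GroundTruthPlume, SubdivisionMap, dose_at_many

__all__ = [
    "CandidateSet",
    "densify",
    "measure_candidates",
    "zero_envelope",
    "GAUSSIAN_UPPER_QUARTILE",
]

GAUSSIAN_UPPER_QUARTILE = 0.6745  # z-score of the 75th percentile


@dataclass
class CandidateSet:
    """Proposed sampling locations with the surface state that selected them."""

    df: pd.DataFrame  # columns: x_km, y_km, prediction_gy, std_error_gy
    threshold: float
    requested: int
    iteration: int

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        return self.df[["x_km", "y_km"]].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def densify(
    surface: KrigedSurface,
    existing: SampleSet,
    threshold: float = 2.0,
    max_n: int = 200,
    exclusion=None,
    iteration: int = 0,
    spacing_cells: int = 2,
) -> CandidateSet:
    """Select up to ``max_n`` new sampling locations from a kriged surface.

    Returns an empty set when no cell is eligible, which signals to the
    orchestrator that the plume has (possibly prematurely) stabilized.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    grid = surface.grid
    pred = surface.prediction
    se = surface.std_error

    upper = pred + GAUSSIAN_UPPER_QUARTILE * se
    eligible = upper >= threshold
    if surface.window is not None:
        eligible &= surface.window
    rows, cols = np.nonzero(eligible)
    if rows.size == 0:
        return CandidateSet(
            pd.DataFrame(columns=["x_km", "y_km", "prediction_gy", "std_error_gy"]),
            threshold, max_n, iteration,
        )

    xs = grid.x0 + (cols + 0.5) * grid.cellsize
    ys = grid.y0 + (rows + 0.5) * grid.cellsize
    if exclusion is not None and not exclusion.is_empty:
        keep = ~shapely.contains_xy(exclusion, xs, ys)
        rows, cols, xs, ys = rows[keep], cols[keep], xs[keep], ys[keep]
        if rows.size == 0:
            return CandidateSet(
                pd.DataFrame(columns=["x_km", "y_km", "prediction_gy", "std_error_gy"]),
                threshold, max_n, iteration,
            )

    cell_se = se[rows, cols]
    # deterministic ranking: descending std error, ties by (row, col)
    order = np.lexsort((cols, rows, -cell_se))

    min_dist = spacing_cells * grid.cellsize
    dedup_tol = grid.cellsize  # one grid cell, mirrors GIS duplicate behavior
    existing_xy = existing.coords if len(existing) else np.empty((0, 2))

    chosen: list[int] = []
    chosen_xy: list[tuple[float, float]] = []
    for i in order:
        x, y = xs[i], ys[i]
        if len(existing_xy) and (
            np.hypot(existing_xy[:, 0] - x, existing_xy[:, 1] - y).min() < dedup_tol
        ):
            continue
        ok = True
        for cx, cy in chosen_xy:
            if np.hypot(cx - x, cy - y) < min_dist:
                ok = False
                break
        if not ok:
            continue
        chosen.append(i)
        chosen_xy.append((x, y))
        if len(chosen) == max_n:
            break

    idx = np.asarray(chosen, dtype=int)
    df = pd.DataFrame(
        {
            "x_km": xs[idx],
            "y_km": ys[idx],
            "prediction_gy": pred[rows[idx], cols[idx]],
            "std_error_gy": cell_se[idx],
        }
    )
    return CandidateSet(df, threshold, max_n, iteration)


def measure_candidates(
    candidates: CandidateSet,
    plume: GroundTruthPlume,
    max_error: float = 0.0,
    seed: int = 0,
) -> SampleSet:
    """Simulate responder measurements at the candidate locations.

    True dose comes from the ground-truth contour stack (outer-boundary
    assignment); measured dose applies the bounded uniform error model used
    for the initial samples.
    """
    xy = candidates.coords
    true = dose_at_many(plume, xy) if len(xy) else np.empty(0)
    measured = true.copy()
    if max_error > 0 and len(xy):
        rng = np.random.default_rng(seed)
        measured = np.clip(
            true + rng.uniform(-max_error, max_error, size=len(xy)), 0.0, None
        )
    df = pd.DataFrame(
        {
            "x_km": xy[:, 0] if len(xy) else [],
            "y_km": xy[:, 1] if len(xy) else [],
            "true_dose_gy": true,
            "measured_dose_gy": measured,
            "iteration": candidates.iteration,
            "source": "densification",
            "subdivision_id": None,
        }
    )
    return SampleSet(df[COLUMNS])


def zero_envelope(smap: SubdivisionMap, samples: SampleSet, derived_region=None):
    """Union of subdivisions confirmed unirradiated by every sample so far.

    A subdivision joins the envelope when it has at least one sample, all its
    samples measured 0 Gy, and it does not intersect the current derived
    plume (>0.5 Gy region) if one is supplied.  Returns a (possibly empty)
    shapely geometry.
    """
    df = samples.df
    polys = []
    for s in smap.subdivisions:
        sub = df[df["subdivision_id"] == s.id]
        if len(sub) == 0 or (sub["measured_dose_gy"] > 0).any():
            continue
        if derived_region is not None and not derived_region.is_empty:
            if s.boundary.intersects(derived_region):
                continue
        polys.append(s.boundary)
    if not polys:
        return shapely.geometry.GeometryCollection()
    return unary_union(polys)
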
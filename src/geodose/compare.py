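"""Dose-band extraction, overlap heat matrices, convergence metrics, scoring.

Successive kriged plumes are compared band-by-band on the eight clinical dose
ranges <1, 1-2, ..., 6-7, >7 Gy.  The overlap heat matrix holds, for every
pair of bands (one from the current plume, one from the previous), the
symmetric average overlap fraction of their areas; identical plumes give the
identity matrix.  Two scalar dissimilarities of the matrix diagonal drive the
stopping rule:

    BCD  = sum_i |1 - A_i| / sum_i (1 + A_i)        (Bray-Curtis, diagonal)
    RMSD = sqrt( mean_i (1 - A_i)^2 )

with A_i the diagonal overlap of band i.  For a uniform diagonal a these
reduce to (1-a)/(1+a) and 1-a, so the 90%-overlap stopping thresholds are
exactly 1/19 and 0.1.  Iteration stops when either metric drops strictly
below its threshold.

Accuracy against ground truth is population-weighted: the overlap area inside
each subdivision is converted to persons via the subdivision's uniform
density (population / area).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.ops import unary_union

from .kriging import Grid, KrigedSurface, empirical_semivariogram, fit_semivariogram, krige
from .scenario import GroundTruthPlume, SubdivisionMap

__all__ = [
    "BAND_LABELS",
    "N_BANDS",
    "DerivedPlume",
    "OverlapMatrix",
    "ConvergenceRecord",
    "extract_bands",
    "overlap_matrix",
    "bcd",
    "rmsd",
    "check_convergence",
    "thresholds_for_stringency",
    "truth_surface",
    "accuracy",
    "population_of_region",
]

N_BANDS = 8
BAND_LABELS = ["<1Gy", "1-2Gy", "2-3Gy", "3-4Gy", "4-5Gy", "5-6Gy", "6-7Gy", ">7Gy"]


def _mask_to_polygon(grid: Grid, mask: np.ndarray):
    """Union of the grid cells in ``mask`` as a shapely polygon.

    Cells are merged row-wise into run-length rectangles first, so the union
    is cheap and the polygon's area equals the cell count times the cell area
    exactly (pixel-exact contouring).
    """
    if not mask.any():
        return shapely.geometry.GeometryCollection()
    cs = grid.cellsize
    boxes = []
    for r in np.flatnonzero(mask.any(axis=1)):
        row = mask[r]
        # run-length encode the row
        d = np.diff(np.concatenate([[0], row.view(np.int8), [0]]))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        y0 = grid.y0 + r * cs
        for a, b in zip(starts, ends):
            boxes.append(shapely.box(grid.x0 + a * cs, y0, grid.x0 + b * cs, y0 + cs))
    return unary_union(boxes)


@dataclass
class DerivedPlume:
    """Eight disjoint dose bands extracted from a kriged surface.

    ``labels`` assigns each grid cell its band index (floor of the predicted
    dose, capped at 7) or -1 where the prediction is 0.  Band polygons are
    built lazily; their union is exactly the >0 Gy region.
    """

    grid: Grid
    labels: np.ndarray  # (ny, nx) int8, -1 = no dose
    source: str = ""
    iteration: int = 0

    @functools.cached_property
    def band_areas(self) -> np.ndarray:
        counts = np.array([(self.labels == i).sum() for i in range(N_BANDS)])
        return counts * self.grid.cell_area

    def band_polygon(self, i: int):
        return _mask_to_polygon(self.grid, self.labels == i)

    def region_geq(self, threshold: float):
        """Polygon of cells predicted at or above ``threshold`` Gy (integer)."""
        k = int(np.ceil(threshold))
        return _mask_to_polygon(self.grid, self.labels >= min(k, N_BANDS - 1))

    @property
    def total_area(self) -> float:
        return float((self.labels >= 0).sum()) * self.grid.cell_area

    @property
    def is_empty(self) -> bool:
        return not (self.labels >= 0).any()


def extract_bands(surface: KrigedSurface, iteration: int = 0) -> DerivedPlume:
    """Band decomposition of the surface: half-open ranges [k, k+1), last open.

    A cell belongs to band k when its predicted dose lies in [k, k+1) Gy (the
    last band is >= 7 Gy); cells with zero prediction belong to no band.  An
    all-zero surface yields an empty plume, which is valid output and signals
    a reconstruction failure upstream.
    """
    pred = surface.prediction
    labels = np.where(
        pred > 0.0, np.minimum(np.floor(pred), N_BANDS - 1).astype(np.int8), -1
    ).astype(np.int8)
    return DerivedPlume(surface.grid, labels, source=surface.method, iteration=iteration)


@dataclass
class OverlapMatrix:
    """8x8 band-overlap heat matrix; rows = current bands, cols = previous."""

    values: np.ndarray  # (8, 8) in [0, 1]
    row_labels: tuple = tuple(BAND_LABELS)
    col_labels: tuple = tuple(BAND_LABELS)

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.values)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels).to_csv(
            path
        )


def _band_intersections_cells(cur: DerivedPlume, prev: DerivedPlume) -> np.ndarray:
    """(8, 8) intersection areas by joint cell counting (shared grid)."""
    a = cur.labels.ravel()
    b = prev.labels.ravel()
    keep = (a >= 0) & (b >= 0)
    joint = np.zeros((N_BANDS, N_BANDS))
    if keep.any():
        idx = a[keep].astype(int) * N_BANDS + b[keep].astype(int)
        counts = np.bincount(idx, minlength=N_BANDS * N_BANDS)
        joint = counts.reshape(N_BANDS, N_BANDS).astype(float)
    return joint * cur.grid.cell_area


def overlap_matrix(current: DerivedPlume, previous: DerivedPlume) -> OverlapMatrix:
    """Average overlap percentage between every pair of dose bands.

    cell(i, j) = 0.5 * [ |C_i ∩ P_j| / |C_i| + |C_i ∩ P_j| / |P_j| ] -- the
    mean of the two one-sided overlap fractions, which is 1 iff the bands
    coincide.  Diagonal cells where both bands are empty count as full
    agreement (1); a band empty on one side only counts as 0.  Identical
    plumes therefore yield the identity matrix.
    """
    if current.grid == previous.grid:
        inter = _band_intersections_cells(current, previous)
        area_c = current.band_areas
        area_p = previous.band_areas
    else:
        polys_c = [current.band_polygon(i) for i in range(N_BANDS)]
        polys_p = [previous.band_polygon(j) for j in range(N_BANDS)]
        inter = np.zeros((N_BANDS, N_BANDS))
        for i, pc in enumerate(polys_c):
            if pc.is_empty:
                continue
            for j, pp in enumerate(polys_p):
                if pp.is_empty:
                    continue
                inter[i, j] = pc.intersection(pp).area
        area_c = np.array([p.area for p in polys_c])
        area_p = np.array([p.area for p in polys_p])

    vals = np.zeros((N_BANDS, N_BANDS))
    for i in range(N_BANDS):
        for j in range(N_BANDS):
            if area_c[i] == 0.0 and area_p[j] == 0.0:
                vals[i, j] = 1.0 if i == j else 0.0
            elif area_c[i] == 0.0 or area_p[j] == 0.0:
                vals[i, j] = 0.0
            else:
                vals[i, j] = 0.5 * (
                    inter[i, j] / area_c[i] + inter[i, j] / area_p[j]
                )
    return OverlapMatrix(np.clip(vals, 0.0, 1.0))


def bcd(matrix: OverlapMatrix) -> float:
    """Diagonal Bray-Curtis dissimilarity against the identity matrix."""
    a = matrix.diagonal
    return float(np.abs(1.0 - a).sum() / (1.0 + a).sum())


def rmsd(matrix: OverlapMatrix) -> float:
    """Root-mean-square deviation of the diagonal from perfect overlap."""
    a = matrix.diagonal
    return float(np.sqrt(np.mean((1.0 - a) ** 2)))


def thresholds_for_stringency(stringency: float = 0.90) -> tuple[float, float]:
    """(BCD, RMSD) stopping thresholds equivalent to a uniform overlap level.

    90% overlap gives 1/19 and 0.1; 99% gives 1/199 and 0.01.
    """
    if not (0.0 < stringency < 1.0):
        raise ValueError("stringency must be in (0, 1)")
    return (1.0 - stringency) / (1.0 + stringency), 1.0 - stringency


@dataclass(frozen=True)
class ConvergenceRecord:
    iteration: int
    bcd: float
    rmsd: float
    bcd_threshold: float = 1.0 / 19.0
    rmsd_threshold: float = 0.1
    converged: bool = False
    stop_reason: str | None = None  # 'bcd' | 'rmsd' | None


def check_convergence(
    iteration: int,
    bcd_value: float,
    rmsd_value: float,
    bcd_threshold: float = 1.0 / 19.0,
    rmsd_threshold: float = 0.1,
) -> ConvergenceRecord:
    """Stop-on-either rule with strict inequality ("dropped below")."""
    reason = None
    if bcd_value < bcd_threshold:
        reason = "bcd"
    elif rmsd_value < rmsd_threshold:
        reason = "rmsd"
    return ConvergenceRecord(
        iteration=iteration,
        bcd=bcd_value,
        rmsd=rmsd_value,
        bcd_threshold=bcd_threshold,
        rmsd_threshold=rmsd_threshold,
        converged=reason is not None,
        stop_reason=reason,
    )


def truth_surface(
    plume: GroundTruthPlume,
    grid: Grid,
    per_ring: int = 150,
    k_neighbors: int = 32,
    window_expand: float = 0.3,
) -> KrigedSurface:
    """Krige the ground-truth contour vertices onto the shared grid.

    The nested-ring ground truth and the gridded derived plumes are different
    representations; kriging every ring's vertices (valued at the ring level,
    zero nugget so vertices interpolate exactly) produces a comparison
    surface in the same gridded form.  Rings are subsampled to ``per_ring``
    vertices for tractability.  Fully deterministic.
    """
    pts = []
    vals = []
    for lv, ring in plume.contours:
        xy = np.asarray(ring.exterior.coords)[:-1]
        if len(xy) > per_ring:
            stride = np.linspace(0, len(xy) - 1, per_ring).astype(int)
            xy = xy[stride]
        pts.append(xy)
        vals.append(np.full(len(xy), lv))
    coords = np.vstack(pts)
    values = np.concatenate(vals)

    emp = empirical_semivariogram((coords, values), n_bins=15)
    model = fit_semivariogram(emp, family="exponential", fix_nugget=0.0)
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    window = grid.window_mask((xmin, ymin, xmax, ymax), expand=window_expand)
    return krige(
        (coords, values), model, grid, method="ordinary",
        k_neighbors=k_neighbors, window=window,
    )


def population_of_region(region, smap: SubdivisionMap) -> float:
    """Persons inside ``region`` under uniform within-subdivision density."""
    if region is None or region.is_empty:
        return 0.0
    total = 0.0
    for s in smap.subdivisions:
        if not s.boundary.intersects(region):
            continue
        total += s.boundary.intersection(region).area * s.population / s.boundary.area
    return total


def accuracy(
    derived: DerivedPlume,
    truth: DerivedPlume,
    smap: SubdivisionMap,
    threshold: float = 2.0,
) -> dict[str, float]:
    """Population-weighted recall and false-positive fraction at a threshold.

    recall = population(derived >= t  ∩  truth >= t) / population(truth >= t)
    fp     = population(derived >= t  \\ truth >= t) / population(derived >= t)

    both as percentages.  Raises when the ground truth has no population at
    or above the threshold (recall undefined).
    """
    region_d = derived.region_geq(threshold)
    region_t = truth.region_geq(threshold)
    pop_t = population_of_region(region_t, smap)
    if pop_t <= 0.0:
        raise ValueError(f"ground truth has no population >= {threshold} Gy")
    if region_d.is_empty:
        return {"recall_pct": 0.0, "false_positive_pct": 0.0}
    inter = region_d.intersection(region_t)
    pop_d = population_of_region(region_d, smap)
    pop_hit = population_of_region(inter, smap)
    fp = 100.0 * (pop_d - pop_hit) / pop_d if pop_d > 0 else 0.0
    return {
        "recall_pct": 100.0 * pop_hit / pop_t,
        "false_positive_pct": max(fp, 0.0),
    }
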
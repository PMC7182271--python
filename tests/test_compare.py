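"""Band extraction, overlap matrices, convergence metrics and scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from geodose import (
    Grid,
    KrigedSurface,
    accuracy,
    bcd,
    check_convergence,
    extract_bands,
    overlap_matrix,
    rmsd,
    thresholds_for_stringency,
    truth_surface,
)
from geodose.compare import N_BANDS, OverlapMatrix, population_of_region
from geodose.scenario import PopulationConfig, generate_population_map

from conftest import raster_area


def _surface_from(pred, cellsize=1.0, x0=0.0, y0=0.0):
    pred = np.asarray(pred, dtype=float)
    grid = Grid(x0, y0, cellsize, pred.shape[1], pred.shape[0])
    return KrigedSurface(grid, pred, np.zeros_like(pred), method="test")


def _disk_surface(value, radius=6.0, n=40, cellsize=0.5):
    grid = Grid(0.0, 0.0, cellsize, n, n)
    X, Y = np.meshgrid(grid.xs, grid.ys)
    c = n * cellsize / 2
    pred = np.where((X - c) ** 2 + (Y - c) ** 2 <= radius**2, value, 0.0)
    return KrigedSurface(grid, pred, np.zeros_like(pred), method="test")


# ---------------------------------------------------------------------------
# band extraction


def test_constant_disk_lands_entirely_in_its_band():
    surf = _disk_surface(2.5)
    plume = extract_bands(surf)
    areas = plume.band_areas
    assert areas[2] > 0  # 2-3 Gy band
    assert areas[[0, 1, 3, 4, 5, 6, 7]].sum() == 0
    assert areas[2] == pytest.approx(plume.total_area)


def test_band_areas_partition_the_positive_region():
    rng = np.random.default_rng(3)
    pred = np.clip(rng.normal(2.0, 3.0, (30, 30)), 0.0, None)
    plume = extract_bands(_surface_from(pred))
    assert plume.band_areas.sum() == pytest.approx(plume.total_area, rel=1e-12)
    # bands are pairwise disjoint by construction of the label array
    assert ((plume.labels >= -1) & (plume.labels < N_BANDS)).all()


def test_band_polygon_areas_match_rasterization_oracle():
    rng = np.random.default_rng(5)
    pred = np.clip(rng.normal(1.5, 2.5, (25, 25)), 0.0, None)
    surf = _surface_from(pred)
    plume = extract_bands(surf)
    bounds = (0.0, 0.0, 25.0, 25.0)
    for i in range(N_BANDS):
        poly = plume.band_polygon(i)
        if poly.is_empty:
            assert plume.band_areas[i] == 0.0
            continue
        assert poly.area == pytest.approx(plume.band_areas[i], rel=1e-9)
        assert poly.area == pytest.approx(raster_area(poly, bounds, n=1000), rel=0.01)


def test_all_zero_surface_gives_empty_plume():
    plume = extract_bands(_surface_from(np.zeros((5, 5))))
    assert plume.is_empty
    assert plume.band_areas.sum() == 0.0


def test_doses_above_seven_gray_pool_in_the_top_band():
    plume = extract_bands(_surface_from([[7.0, 9.5, 120.0]]))
    assert (plume.labels == 7).all()


# ---------------------------------------------------------------------------
# overlap matrix


def test_identical_plumes_give_identity_matrix():
    rng = np.random.default_rng(11)
    pred = np.clip(rng.normal(2.0, 3.0, (20, 20)), 0.0, None)
    plume = extract_bands(_surface_from(pred))
    m = overlap_matrix(plume, plume)
    assert np.allclose(m.values, np.eye(N_BANDS))
    assert bcd(m) == 0.0 and rmsd(m) == 0.0


def test_disjoint_same_band_regions_have_zero_diagonal():
    a = np.zeros((4, 8))
    b = np.zeros((4, 8))
    a[:, :3] = 2.5
    b[:, 5:] = 2.5
    ma = extract_bands(_surface_from(a))
    mb = extract_bands(_surface_from(b))
    m = overlap_matrix(ma, mb)
    assert m.values[2, 2] == 0.0


def test_half_overlapping_squares_score_one_half():
    # two equal squares sharing half their area: mean of 0.5 and 0.5
    a = np.zeros((4, 8))
    b = np.zeros((4, 8))
    a[:, 0:4] = 2.5
    b[:, 2:6] = 2.5
    m = overlap_matrix(
        extract_bands(_surface_from(a)), extract_bands(_surface_from(b))
    )
    assert m.values[2, 2] == pytest.approx(0.5)


def test_overlap_matrix_on_distinct_grids_uses_polygons():
    a = _disk_surface(2.5, radius=5.0, n=40, cellsize=0.5)
    b = _disk_surface(2.5, radius=5.0, n=20, cellsize=1.0)
    m = overlap_matrix(extract_bands(a), extract_bands(b))
    assert m.values[2, 2] == pytest.approx(1.0, abs=0.05)  # same disk, two grids


def test_both_empty_bands_agree_one_sided_empty_disagrees():
    a = _surface_from([[2.5]])
    b = _surface_from([[2.5]])
    m = overlap_matrix(extract_bands(a), extract_bands(b))
    assert np.allclose(np.diag(m.values), 1.0)  # empty bands count as agreement
    c = _surface_from([[5.5]])
    m2 = overlap_matrix(extract_bands(a), extract_bands(c))
    assert m2.values[2, 2] == 0.0 and m2.values[5, 5] == 0.0


# ---------------------------------------------------------------------------
# BCD / RMSD


def _uniform_diag(a: float) -> OverlapMatrix:
    return OverlapMatrix(np.eye(N_BANDS) * a)


def test_ninety_percent_overlap_hits_the_published_thresholds():
    m = _uniform_diag(0.9)
    assert bcd(m) == pytest.approx(1.0 / 19.0, abs=1e-12)
    assert rmsd(m) == pytest.approx(0.1, abs=1e-12)


def test_uniform_diagonal_closed_forms_by_hand():
    assert bcd(_uniform_diag(0.8)) == pytest.approx(1.0 / 9.0)
    m = OverlapMatrix(np.diag([1, 1, 1, 1, 1, 1, 1, 0.2]).astype(float))
    assert rmsd(m) == pytest.approx(np.sqrt(0.64 / 8))


@given(a=st.floats(0.0, 1.0))
def test_uniform_diagonal_matches_analytic_forms(a):
    m = _uniform_diag(a)
    assert bcd(m) == pytest.approx((1 - a) / (1 + a), abs=1e-12)
    assert rmsd(m) == pytest.approx(1 - a, abs=1e-12)
    assert 0.0 <= bcd(m) <= 1.0 and 0.0 <= rmsd(m) <= 1.0


@given(
    diag=st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8),
    k=st.integers(0, 7),
    bump=st.floats(0.01, 0.5),
)
def test_metrics_strictly_decrease_as_overlap_improves(diag, k, bump):
    d = np.array(diag)
    if d[k] + bump > 1.0:
        return
    better = d.copy()
    better[k] += bump
    m0, m1 = OverlapMatrix(np.diag(d)), OverlapMatrix(np.diag(better))
    assert bcd(m1) < bcd(m0)
    assert rmsd(m1) <= rmsd(m0)


def test_convergence_is_strict_or_rule():
    assert check_convergence(2, 0.04, 0.15).converged  # BCD branch
    assert check_convergence(2, 0.04, 0.15).stop_reason == "bcd"
    assert check_convergence(2, 0.06, 0.09).stop_reason == "rmsd"
    # exactly at the thresholds: NOT converged (strict inequality)
    rec = check_convergence(2, 1.0 / 19.0, 0.1)
    assert not rec.converged


def test_stringency_thresholds():
    assert thresholds_for_stringency(0.90) == pytest.approx((1 / 19, 0.1))
    assert thresholds_for_stringency(0.99) == pytest.approx((1 / 199, 0.01))


# ---------------------------------------------------------------------------
# truth surface and population-weighted accuracy


def test_truth_surface_tracks_dose_oracle(small_plume):
    from geodose import dose_at_many

    grid = Grid(-4.0, -4.0, 0.25, 48, 48)
    surf = truth_surface(small_plume, grid, per_ring=120)
    mask = surf.window if surf.window is not None else np.ones(surf.prediction.shape, bool)
    centers = grid.centers()[mask.ravel()]
    truth = dose_at_many(small_plume, centers)
    pred = surf.prediction[mask]
    inside = truth > 0
    agree = np.abs(pred[inside] - truth[inside]) <= 0.5 + 1e-9
    assert agree.mean() >= 0.90  # within one contour step nearly everywhere


def test_truth_surface_is_deterministic(small_plume):
    grid = Grid(-4.0, -4.0, 0.5, 24, 24)
    a = truth_surface(small_plume, grid, per_ring=80)
    b = truth_surface(small_plume, grid, per_ring=80)
    assert np.array_equal(a.prediction, b.prediction)


def test_population_weighting_formula_by_hand():
    # one 10 km^2 subdivision with 50,000 people; a 2 km^2 overlap -> 10,000
    import shapely

    cfg = PopulationConfig(n_subdivisions=1, total_population=50_000,
                           region=(0, 0, 5, 2))
    smap = generate_population_map(cfg, seed=1)
    region = shapely.box(0, 0, 2, 1)  # 2 km^2
    assert population_of_region(region, smap) == pytest.approx(10_000.0)


def test_population_conservation_over_whole_map(small_map):
    import shapely

    xmin, ymin, xmax, ymax = small_map.bounds
    whole = shapely.box(xmin, ymin, xmax, ymax)
    assert population_of_region(whole, small_map) == pytest.approx(
        small_map.total_population, rel=1e-9
    )


def test_perfect_reconstruction_scores_100_recall_0_fp(small_map):
    surf = _disk_surface(3.5, radius=4.0, n=20, cellsize=0.5)
    plume = extract_bands(surf)
    out = accuracy(plume, plume, small_map, threshold=2.0)
    assert out["recall_pct"] == pytest.approx(100.0)
    assert out["false_positive_pct"] == pytest.approx(0.0)


def test_half_coverage_scores_50_percent_under_uniform_density():
    cfg = PopulationConfig(n_subdivisions=1, total_population=100_000,
                           region=(0, 0, 20, 20))
    smap = generate_population_map(cfg, seed=2)
    truth = np.zeros((20, 20))
    truth[4:12, 4:12] = 2.5
    derived = np.zeros((20, 20))
    derived[4:8, 4:12] = 2.5  # exactly half the truth area
    t = extract_bands(_surface_from(truth))
    d = extract_bands(_surface_from(derived))
    out = accuracy(d, t, smap, threshold=2.0)
    assert out["recall_pct"] == pytest.approx(50.0)
    assert out["false_positive_pct"] == pytest.approx(0.0)


def test_empty_truth_region_raises():
    smap = generate_population_map(
        PopulationConfig(n_subdivisions=1, total_population=1000, region=(0, 0, 5, 5)),
        seed=1,
    )
    d = extract_bands(_surface_from([[3.0]]))
    t = extract_bands(_surface_from([[0.5]]))
    with pytest.raises(ValueError):
        accuracy(d, t, smap, threshold=2.0)
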
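"""Semivariogram estimation and the kriging variants against dense oracles."""

import numpy as np
import pytest

from geodose import (
    Grid,
    SemivariogramModel,
    ebk,
    empirical_semivariogram,
    fit_reml,
    fit_semivariogram,
    krige,
)
from geodose.kriging import KrigingError

from conftest import dense_kriging_oracle

RNG = np.random.default_rng(2024)


def _random_instance(n=8, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 10, size=(n, 2))
    values = rng.uniform(0, 6, size=n)
    return coords, values


# ---------------------------------------------------------------------------
# empirical semivariogram


def test_constant_field_has_zero_semivariance():
    coords = RNG.uniform(0, 5, (20, 2))
    emp = empirical_semivariogram((coords, np.full(20, 3.0)))
    assert np.allclose(emp[:, 1], 0.0)


def test_two_sample_semivariance_by_hand():
    emp = empirical_semivariogram(
        (np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([0.0, 2.0])), n_bins=1
    )
    assert emp.shape == (1, 3)
    assert emp[0, 1] == pytest.approx(2.0)  # 0.5 * (0 - 2)^2


def test_pair_counts_sum_to_n_choose_2():
    coords, values = _random_instance(n=25, seed=3)
    emp = empirical_semivariogram((coords, values), n_bins=8)
    assert emp[:, 2].sum() == 25 * 24 / 2


def test_single_location_rejected():
    with pytest.raises(KrigingError):
        empirical_semivariogram(
            (np.array([[0.0, 0.0], [0.0, 0.0]]), np.array([1.0, 2.0]))
        )


# ---------------------------------------------------------------------------
# model fitting


def test_fit_recovers_noiseless_exponential_parameters():
    true = SemivariogramModel("exponential", nugget=0.2, partial_sill=2.0, range_km=3.0)
    lags = np.linspace(0.2, 8, 20)
    emp = np.column_stack([lags, true.gamma(lags), np.full(20, 50.0)])
    fit = fit_semivariogram(emp, family="exponential")
    assert fit.nugget == pytest.approx(true.nugget, rel=0.05, abs=0.02)
    assert fit.partial_sill == pytest.approx(true.partial_sill, rel=0.05)
    assert fit.range_km == pytest.approx(true.range_km, rel=0.05)


def test_flat_semivariance_fits_as_pure_nugget_plus_sill():
    lags = np.linspace(0.5, 10, 12)
    emp = np.column_stack([lags, np.full(12, 1.7), np.full(12, 30.0)])
    fit = fit_semivariogram(emp)
    # total sill reproduces the flat level with negligible long-range structure
    assert fit.gamma(np.array([10.0]))[0] == pytest.approx(1.7, rel=0.05)


def test_fit_requires_three_empirical_points():
    with pytest.raises(KrigingError):
        fit_semivariogram(np.array([[1.0, 1.0, 5.0], [2.0, 1.5, 5.0]]))


def test_model_gamma_is_zero_at_origin_and_nondecreasing():
    for family in ("exponential", "spherical", "gaussian"):
        m = SemivariogramModel(family, nugget=0.3, partial_sill=1.5, range_km=2.0)
        assert m.gamma(np.array([0.0]))[0] == 0.0
        h = np.linspace(1e-6, 10, 200)
        g = m.gamma(h)
        assert (np.diff(g) >= -1e-12).all()


def test_reml_recovers_structure_from_simulated_field():
    true = SemivariogramModel("exponential", nugget=0.0, partial_sill=1.0, range_km=2.0)
    rng = np.random.default_rng(5)
    coords = rng.uniform(0, 10, (70, 2))
    from scipy.spatial.distance import cdist

    C = true.covariance(cdist(coords, coords)) + 1e-9 * np.eye(70)
    z = np.linalg.cholesky(C) @ rng.standard_normal(70) + 3.0
    fit = fit_reml((coords, z), seed=1)
    # order-of-magnitude recovery: structured variance dominates the nugget
    assert fit.partial_sill > fit.nugget
    assert 0.3 < fit.range_km < 8.0


# ---------------------------------------------------------------------------
# kriging variants vs the dense oracle


@pytest.mark.parametrize("method", ["ordinary", "simple", "universal"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_variants_match_dense_solver_oracle(method, seed):
    coords, values = _random_instance(n=8, seed=seed)
    model = SemivariogramModel("exponential", nugget=0.1, partial_sill=2.0, range_km=4.0)
    grid = Grid(x0=2.0, y0=2.0, cellsize=1.0, nx=4, ny=4)
    surf = krige((coords, values), model, grid, method=method)
    centers = grid.centers()
    for ci in range(0, 16, 3):
        pred, var, _ = dense_kriging_oracle(
            coords, values, model, centers[ci], method=method
        )
        assert surf.prediction.ravel()[ci] == pytest.approx(max(pred, 0.0), abs=1e-8)
        assert surf.std_error.ravel()[ci] == pytest.approx(
            np.sqrt(max(var, 0.0)), abs=1e-8
        )


def test_ordinary_weights_sum_to_one():
    coords, values = _random_instance(n=6, seed=7)
    model = SemivariogramModel("spherical", nugget=0.0, partial_sill=1.0, range_km=5.0)
    target = np.array([4.2, 3.7])
    _, _, lam = dense_kriging_oracle(coords, values, model, target, method="ordinary")
    assert lam.sum() == pytest.approx(1.0, abs=1e-9)


def test_constant_data_predicts_the_constant_everywhere():
    coords, _ = _random_instance(n=10, seed=4)
    values = np.full(10, 2.5)
    model = SemivariogramModel("exponential", 0.0, 1.0, 3.0)
    grid = Grid(0.0, 0.0, 1.0, 6, 6)
    surf = krige((coords, values), model, grid, method="ordinary")
    assert np.allclose(surf.prediction, 2.5, atol=1e-8)


def test_zero_nugget_interpolates_samples_exactly():
    model = SemivariogramModel("exponential", 0.0, 2.0, 3.0)
    # put samples exactly at cell centers
    grid = Grid(0.0, 0.0, 1.0, 5, 5)
    centers = grid.centers()
    idx = [0, 7, 13, 24]
    coords = centers[idx]
    values = np.array([1.0, 4.0, 0.5, 3.0])
    surf = krige((coords, values), model, grid, method="ordinary")
    for i, v in zip(idx, values):
        assert surf.prediction.ravel()[i] == pytest.approx(v, abs=1e-7)
        assert surf.std_error.ravel()[i] == pytest.approx(0.0, abs=1e-6)


def test_adding_a_sample_cannot_increase_variance_there():
    model = SemivariogramModel("exponential", 0.0, 1.0, 4.0)
    coords, values = _random_instance(n=7, seed=9)
    target = np.array([5.0, 5.0])
    _, var_before, _ = dense_kriging_oracle(coords, values, model, target)
    coords2 = np.vstack([coords, target])
    values2 = np.append(values, 2.0)
    _, var_after, _ = dense_kriging_oracle(coords2, values2, model, target)
    assert var_after <= var_before + 1e-12


def test_duplicate_coordinates_are_deduplicated_not_fatal():
    coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 0.5]])
    values = np.array([1.0, 9.0, 2.0, 3.0])
    model = SemivariogramModel("exponential", 0.0, 1.0, 2.0)
    grid = Grid(0.0, 0.0, 1.0, 3, 3)
    surf = krige((coords, values), model, grid)
    assert np.isfinite(surf.prediction).all()


def test_fewer_than_two_samples_rejected():
    model = SemivariogramModel()
    grid = Grid(0.0, 0.0, 1.0, 2, 2)
    with pytest.raises(KrigingError):
        krige((np.array([[0.0, 0.0]]), np.array([1.0])), model, grid)


# ---------------------------------------------------------------------------
# ensemble (EBK-style) kriging


def test_single_subset_single_sim_reduces_to_ordinary_with_reml_fit():
    coords, values = _random_instance(n=30, seed=12)
    grid = Grid(0.0, 0.0, 1.0, 8, 8)
    surf_e = ebk((coords, values), grid, n_subsets=1, n_sims=1, seed=3)
    # degenerate ensemble: exactly one model, the REML base fit
    assert len(surf_e.model) == 1 and len(surf_e.model[0]) == 1
    model = surf_e.model[0][0]
    surf_o = krige((coords, values), model, grid, method="ordinary")
    assert np.allclose(surf_e.prediction, surf_o.prediction, atol=1e-10)
    assert np.allclose(surf_e.std_error, surf_o.std_error, atol=1e-10)


def test_ensemble_std_error_at_least_min_member_std_error():
    coords, values = _random_instance(n=10, seed=21)
    grid = Grid(0.0, 0.0, 2.0, 5, 5)
    surf = ebk((coords, values), grid, n_subsets=1, n_sims=5, seed=11)
    models = surf.model[0]
    per_model_se = np.stack(
        [
            krige((coords, values), m, grid, method="ordinary").std_error
            for m in models
        ]
    )
    assert (surf.std_error >= per_model_se.min(axis=0) - 1e-9).all()


def test_ebk_is_deterministic_given_seed():
    coords, values = _random_instance(n=40, seed=14)
    grid = Grid(0.0, 0.0, 1.0, 10, 10)
    a = ebk((coords, values), grid, n_subsets=3, n_sims=4, seed=77)
    b = ebk((coords, values), grid, n_subsets=3, n_sims=4, seed=77)
    assert np.array_equal(a.prediction, b.prediction)
    assert np.array_equal(a.std_error, b.std_error)


def test_ebk_with_too_few_samples_downgrades_to_ordinary():
    coords, values = _random_instance(n=4, seed=2)
    grid = Grid(0.0, 0.0, 1.0, 4, 4)
    surf = ebk((coords, values), grid, n_subsets=5, n_sims=5, seed=1)
    assert surf.method == "ordinary"


def test_ascii_grid_round_trip(tmp_path):
    coords, values = _random_instance(n=6, seed=1)
    model = SemivariogramModel("exponential", 0.0, 1.0, 3.0)
    grid = Grid(0.0, 0.0, 1.0, 4, 3)
    surf = krige((coords, values), model, grid)
    path = tmp_path / "pred.asc"
    surf.to_ascii_grid(path)
    lines = path.read_text().splitlines()
    assert lines[0].split() == ["ncols", "4"]
    assert lines[1].split() == ["nrows", "3"]
    data = np.loadtxt(lines[6:])
    assert data.shape == (3, 4)
    assert np.allclose(data[::-1], surf.prediction, atol=1e-5)
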
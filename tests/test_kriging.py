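import numpy as np
import pytest

from microgeostat import (
    CvReport,
    OrdinaryKriging,
    VariogramModel,
    build_prediction_grid,
    loo_cross_validation,
    ordinary_kriging,
    prediction_accuracy_flag,
)
from microgeostat.transect import DuplicateCoordinateWarning


def naive_ok_solve(coords, z, model, target):
    """Independent assembly + solve of the ordinary-kriging system."""
    n = len(coords)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            A[i, j] = model(np.linalg.norm(coords[i] - coords[j]))
        A[i, n] = 1.0
        A[n, i] = 1.0
    b = np.ones(n + 1)
    for i in range(n):
        b[i] = model(np.linalg.norm(coords[i] - target))
    sol = np.linalg.lstsq(A, b, rcond=None)[0]
    return float(sol[:n] @ z)


class TestPredictionGrid:
    def test_unit_square_exact_tiling(self):
        ring = [[0, 0], [1, 0], [1, 1], [0, 1]]
        grid = build_prediction_grid(ring, 0.25)
        assert grid.n_cells == 4
        assert grid.expected_cells == 4

    def test_published_area_ratio_gives_3000_pixels(self):
        """A 7,141 m2 polygon rasterized at 2.38 m2 -> 3,000 pixels."""
        width = 7141.0 / 211.0
        ring = [[0, 0], [211, 0], [211, width], [0, width]]
        grid = build_prediction_grid(ring, 2.38)
        assert grid.expected_cells == 3000
        # centre-in-polygon keeps partial boundary cells: count tracks the
        # area ratio to within a couple of percent
        assert abs(grid.n_cells * 2.38 - 7141.0) / 7141.0 < 0.02

    def test_kept_area_bounded_by_bounding_box(self):
        ring = [[0, 0], [10, 0], [5, 8]]
        grid = build_prediction_grid(ring, 1.0)
        assert grid.n_cells * grid.pixel_area <= 10 * 8 + 1e-9

    def test_degenerate_polygon_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_prediction_grid([[0, 0], [1, 1], [2, 2]], 1.0)


@pytest.fixture
def scatter():
    rng = np.random.default_rng(10)
    coords = rng.uniform(0, 100, (13, 2))
    z = rng.normal(10, 2, 13)
    return coords, z


class TestOrdinaryKriging:
    def test_exact_interpolation_with_zero_nugget(self, scatter):
        coords, z = scatter
        model = VariogramModel("spherical", 0.0, 1.0, 60.0)
        res = OrdinaryKriging(coords, values=z, model=model).predict(coords)
        assert np.abs(res.predictions - z).max() < 1e-8
        assert np.abs(res.variances).max() < 1e-8

    def test_pure_nugget_gives_sample_mean_and_uniform_weights(self, scatter):
        coords, z = scatter
        model = VariogramModel("nugget", 1.0, 0.0, 10.0)
        ok = OrdinaryKriging(coords, values=z, model=model)
        res = ok.predict([[50.0, 50.0]], return_weights=True)
        assert res.predictions[0] == pytest.approx(z.mean(), abs=1e-10)
        assert np.abs(res.weights - 1 / 13).max() < 1e-10

    def test_weights_sum_to_one_everywhere(self, scatter):
        coords, z = scatter
        rng = np.random.default_rng(11)
        targets = rng.uniform(-50, 150, (1000, 2))
        for fam in ("spherical", "exponential", "gaussian", "periodic"):
            model = VariogramModel(fam, 0.2, 1.0, 40.0)
            res = OrdinaryKriging(coords, values=z, model=model).predict(
                targets, return_weights=True)
            assert np.abs(res.weights.sum(axis=1) - 1.0).max() < 1e-8

    def test_matches_naive_solver_on_random_configurations(self):
        model = VariogramModel("spherical", 0.3, 1.2, 45.0)
        rng = np.random.default_rng(12)
        for _ in range(50):
            coords = rng.uniform(0, 100, (5, 2))
            z = rng.normal(0, 1, 5)
            target = rng.uniform(0, 100, 2)
            ours = OrdinaryKriging(coords, values=z, model=model).predict(
                target).predictions[0]
            assert abs(ours - naive_ok_solve(coords, z, model, target)) < 1e-8

    def test_three_sample_line_toy_against_naive_solver(self):
        coords = np.array([[0, 0], [10, 0], [30, 0]], float)
        z = np.array([1.0, 3.0, 2.0])
        model = VariogramModel("spherical", 0.1, 1.0, 25.0)
        got = ordinary_kriging(coords, values=z, model=model,
                               targets=[[15.0, 0.0]]).predictions[0]
        assert got == pytest.approx(naive_ok_solve(coords, z, model,
                                                   np.array([15.0, 0.0])),
                                    abs=1e-10)

    def test_pure_nugget_prediction_within_data_range(self, scatter):
        coords, z = scatter
        model = VariogramModel("nugget", 1.0, 0.0, 10.0)
        res = OrdinaryKriging(coords, values=z, model=model).predict(
            np.random.default_rng(13).uniform(0, 100, (50, 2)))
        assert (res.predictions >= z.min() - 1e-9).all()
        assert (res.predictions <= z.max() + 1e-9).all()

    def test_nearest_sample_dominates_on_transect(self):
        coords = np.column_stack([np.arange(0.0, 100.0, 10.0), np.zeros(10)])
        z = np.random.default_rng(14).normal(size=10)
        for fam in ("spherical", "exponential", "gaussian"):
            model = VariogramModel(fam, 0.0, 1.0, 40.0)
            res = OrdinaryKriging(coords, values=z, model=model).predict(
                [[32.0, 0.0]], return_weights=True)
            assert np.argmax(np.abs(res.weights[0])) == 3  # x = 30

    def test_conflicting_duplicate_locations_raise(self):
        coords = np.array([[0, 0], [0, 0], [10, 0]], float)
        model = VariogramModel("spherical", 0.1, 1.0, 20.0)
        with pytest.raises(np.linalg.LinAlgError, match="share a location"):
            OrdinaryKriging(coords, values=[1.0, 2.0, 3.0], model=model)

    def test_identical_duplicates_deduplicated_with_warning(self):
        coords = np.array([[0, 0], [0, 0], [10, 0]], float)
        model = VariogramModel("spherical", 0.1, 1.0, 20.0)
        with pytest.warns(DuplicateCoordinateWarning):
            ok = OrdinaryKriging(coords, values=[1.0, 1.0, 3.0], model=model)
        assert len(ok.values) == 2


class TestCrossValidation:
    def test_pure_nugget_loo_equals_leave_one_out_means(self, scatter):
        coords, z = scatter
        model = VariogramModel("nugget", 1.0, 0.0, 10.0)
        cv = loo_cross_validation(coords, values=z, model=model)
        loom = np.array([np.delete(z, j).mean() for j in range(len(z))])
        assert np.abs(cv.predicted - loom).max() < 1e-10

    def test_rmse_formula_on_toy_vectors(self):
        obs = np.array([1.0, 2.0, 3.0])
        cv = _report(obs, obs)
        assert cv.rmse == 0.0
        cv = _report(obs, np.array([2.0, 2.0, 2.0]))
        assert cv.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert cv.ase == 0.0  # constant predictions have zero spread
        assert cv.rmse_r == pytest.approx(np.sqrt(2 / 3) / np.std(obs, ddof=1))

    def test_smooth_field_predicted_accurately(self):
        """A dense linear field under a long-range model: small LOO error."""
        coords = np.column_stack([np.linspace(0, 100, 15), np.zeros(15)])
        z = 2.0 + 0.05 * coords[:, 0]
        model = VariogramModel("spherical", 0.0, 1.0, 200.0)
        cv = loo_cross_validation(coords, values=z, model=model)
        assert cv.rmse_r < 0.15

    def test_needs_three_samples(self):
        model = VariogramModel("nugget", 1.0, 0.0, 10.0)
        with pytest.raises(ValueError, match="at least 3"):
            loo_cross_validation(np.array([[0, 0], [1, 0]], float),
                                 values=[1.0, 2.0], model=model)


def _report(obs, pred):
    ase = float(np.sqrt(np.mean((pred - pred.mean()) ** 2)))
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    s_z = float(np.std(obs, ddof=1))
    return CvReport(observed=obs, predicted=pred, ase=ase, rmse=rmse,
                    rmse_r=rmse / s_z, s_z=s_z)


class TestAccuracyFlags:
    def test_equal_ase_rmse_is_similar(self):
        cv = CvReport(observed=np.array([1.0, 2.0, 3.0]),
                      predicted=np.array([1.1, 2.0, 2.9]),
                      ase=0.5, rmse=0.5, rmse_r=0.5, s_z=1.0)
        assert prediction_accuracy_flag(cv)["ase_rmse_similar"]
        cv.ase = 0.1
        assert not prediction_accuracy_flag(cv)["ase_rmse_similar"]

    def test_published_water_content_rmse_r_flags_inaccurate(self):
        cv = _report(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))
        cv.rmse_r = 1.108
        assert not prediction_accuracy_flag(cv)["rmse_r_accurate"]

    def test_rmse_r_near_forty_percent_is_accurate(self):
        cv = _report(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))
        cv.rmse_r = 0.38
        assert prediction_accuracy_flag(cv)["rmse_r_accurate"]
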
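"""GPR behavior mapping: splits, Bayesian optimization, surfaces, grids."""

import numpy as np
import pandas as pd
import pytest
from sklearn.gaussian_process.kernels import RBF

from nanomap import mapping, synth
from nanomap.mapping import (
    GPHyperparameters,
    ObservationSet,
    assemble_observations,
    fit_surface,
    holdout_error,
    marginalize_to_size_curve,
    optimize_hyperparameters,
    predict_grid,
    split_holdout,
)
from nanomap.optics import SizeCalibration, exponential_profile, fit_size_calibration
from nanomap.quant import SegmentedObject, TileIntensity


def make_obs(n=100, seed=0, fn=None):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1000, n)
    y = rng.uniform(0, 1000, n)
    z = fn(x, y) if fn else rng.normal(size=n)
    return ObservationSet("test", pd.DataFrame(
        {"x_um": x, "y_um": y, "z": z}))


def seg(i, x, y, area=20.0):
    return SegmentedObject(i, x, y, int(area), area * 0.65**2, 18.0, 0.8,
                           6.0, 4.0, 100.0)


class TestAssembleObservations:
    def test_objects_become_rows(self):
        objs = [seg(i, float(i), float(i)) for i in range(100)]
        obs = assemble_observations(objs, "area_um2")
        assert len(obs) == 100
        assert obs.provenance == "per_cell"

    def test_mixed_provenance_rejected(self):
        objs = [seg(i, 0.0, 0.0) for i in range(5)]
        tiles = [TileIntensity(i, 0.0, 0.0, 1.0, (8, 8)) for i in range(5)]
        with pytest.raises(ValueError, match="mixed"):
            assemble_observations(objs + tiles, "mean_intensity")

    def test_too_few_rows_rejected(self):
        objs = [seg(i, float(i), 0.0) for i in range(5)]
        with pytest.raises(ValueError, match="usable rows"):
            assemble_observations(objs, "area_um2")

    def test_dataframe_input_with_nan_dropped(self):
        df = pd.DataFrame({"x_um": np.arange(20.0),
                           "y_um": np.arange(20.0),
                           "area": [np.nan] * 3 + list(range(17))})
        obs = assemble_observations(df, "area")
        assert len(obs) == 17


class TestSplitHoldout:
    def test_ninety_ten_split_counts(self):
        obs = make_obs(1000)
        train, test = split_holdout(obs, 0.10, seed=1)
        assert len(test) == 100 and len(train) == 900

    def test_minimum_one_test_row(self):
        obs = make_obs(10)
        train, test = split_holdout(obs, 0.10, seed=1)
        assert len(test) == 1 and len(train) == 9

    def test_disjoint_and_exhaustive(self):
        obs = make_obs(137)
        train, test = split_holdout(obs, 0.10, seed=5)
        tr, te = set(train.indices), set(test.indices)
        assert tr.isdisjoint(te)
        assert tr | te == set(range(137))

    def test_seed_reproducibility(self):
        obs = make_obs(50)
        a = split_holdout(obs, 0.2, seed=9)[1].data
        b = split_holdout(obs, 0.2, seed=9)[1].data
        assert a.equals(b)

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.5, -0.2])
    def test_fraction_bounds(self, frac):
        with pytest.raises(ValueError):
            split_holdout(make_obs(50), frac, seed=0)


class TestOptimizeHyperparameters:
    def test_incumbent_monotone_nonincreasing(self):
        obs = make_obs(60, seed=3,
                       fn=lambda x, y: np.sin(x / 200) + 0.1 * y / 1000)
        _, trace = optimize_hyperparameters(obs, 15, seed=0)
        inc = trace["incumbent"].to_numpy()
        assert np.all(np.diff(inc) <= 0)

    def test_fixed_seed_identical_trace(self):
        obs = make_obs(40, seed=3, fn=lambda x, y: np.cos(x / 300))
        _, t1 = optimize_hyperparameters(obs, 12, seed=7)
        _, t2 = optimize_hyperparameters(obs, 12, seed=7)
        assert np.allclose(t1["objective"], t2["objective"])

    def test_constant_labels_degenerate_model_warns(self):
        obs = make_obs(30, fn=lambda x, y: np.full_like(x, 2.0))
        with pytest.warns(UserWarning, match="identical"):
            hp, _ = optimize_hyperparameters(obs, 10, seed=0)
        assert hp.noise_variance > 0

    def test_length_scale_recovery_from_gp_draw(self):
        # self-consistency: data drawn from a known GP prior
        rng = np.random.default_rng(12)
        n, ls_true, noise_sd = 500, 150.0, 0.05
        X = rng.uniform(0, 1000, (n, 2))
        K = RBF(ls_true)(X) + 1e-10 * np.eye(n)
        z = np.linalg.cholesky(K) @ rng.normal(size=n) \
            + noise_sd * rng.normal(size=n)
        obs = ObservationSet("gp", pd.DataFrame(
            {"x_um": X[:, 0], "y_um": X[:, 1], "z": z}))
        hp, _ = optimize_hyperparameters(obs, 25, seed=1)
        for ls in (hp.length_scale_x, hp.length_scale_y):
            assert ls_true / 2 <= ls <= ls_true * 2


class TestFitSurface:
    def test_noise_free_fit_interpolates_training_points(self):
        obs = make_obs(40, seed=1, fn=lambda x, y: np.sin(x / 150) * y / 500)
        hp = GPHyperparameters(200.0, 200.0, 1.0, 1e-10)
        surf = fit_surface(obs, hp)
        pred = surf.predict(obs.X)
        assert np.allclose(pred, obs.z, atol=1e-6 * max(1, np.abs(obs.z).max()))

    def test_constant_labels_predict_constant(self):
        obs = make_obs(25, fn=lambda x, y: np.full_like(x, 3.0))
        hp = GPHyperparameters(100.0, 100.0, 1.0, 1e-8)
        surf = fit_surface(obs, hp)
        pred = surf.predict(np.array([[500.0, 500.0], [1e4, 1e4]]))
        assert np.allclose(pred, 3.0, atol=1e-6)

    def test_far_prediction_reverts_to_prior(self):
        obs = make_obs(30, seed=2, fn=lambda x, y: 5.0 + np.sin(x / 100))
        hp = GPHyperparameters(50.0, 50.0, 2.0, 1e-6)
        surf = fit_surface(obs, hp)
        mu, sd = surf.predict(np.array([[1e6, 1e6]]), return_std=True)
        assert mu[0] == pytest.approx(obs.z.mean(), abs=1e-3)
        assert sd[0] == pytest.approx(np.sqrt(2.0 + 1e-6), rel=1e-3)

    def test_predictive_sd_nonnegative_and_small_at_train(self):
        obs = make_obs(30, seed=2, fn=lambda x, y: x / 1000)
        hp = GPHyperparameters(300.0, 300.0, 1.0, 1e-10)
        surf = fit_surface(obs, hp)
        _, sd = surf.predict(obs.X, return_std=True)
        assert np.all(sd >= 0)
        assert sd.max() < 1e-3


class TestPredictGrid:
    def test_default_grid_has_250000_points(self):
        obs = make_obs(20, seed=0, fn=lambda x, y: x / 1000)
        surf = fit_surface(obs, GPHyperparameters(300, 300, 1, 1e-4))
        grid = predict_grid(surf)
        assert grid.total_points == 250_000
        assert grid.z_mean.shape == (500, 500)

    def test_corners_equal_observation_bounding_box(self):
        obs = make_obs(20, seed=0, fn=lambda x, y: x / 1000)
        surf = fit_surface(obs, GPHyperparameters(300, 300, 1, 1e-4))
        grid = predict_grid(surf, obs.bounding_box, total_points=2500)
        x0, x1, y0, y1 = obs.bounding_box
        assert grid.x_um[0] == x0 and grid.x_um[-1] == x1
        assert grid.y_um[0] == y0 and grid.y_um[-1] == y1

    def test_nonsquare_box_keeps_exact_total(self):
        obs = make_obs(20, seed=0, fn=lambda x, y: x / 1000)
        surf = fit_surface(obs, GPHyperparameters(300, 300, 1, 1e-4))
        grid = predict_grid(surf, (0, 4000, 0, 1000), total_points=250_000)
        assert grid.total_points == 250_000
        # aspect-preserving: more columns than rows for a wide box
        assert len(grid.x_um) > len(grid.y_um)

    def test_void_predictions_finite_and_bounded(self, exp_profile,
                                                 growth_model):
        scene = synth.make_scene(exp_profile, growth_model, 4000.0, 0.3,
                                 seed=5)
        sub = scene.cells.sample(200, random_state=0)
        obs = ObservationSet("axonal_growth", sub.rename(
            columns={"value": "z"})[["x_um", "y_um", "z"]].reset_index(
                drop=True))
        hp, _ = optimize_hyperparameters(obs, 10, seed=0)
        surf = fit_surface(obs, hp)
        grid = predict_grid(surf, obs.bounding_box, total_points=2500)
        assert np.all(np.isfinite(grid.z_mean))
        prior_sd = np.sqrt(hp.signal_variance + hp.noise_variance)
        lo = obs.z.min() - 3 * prior_sd
        hi = obs.z.max() + 3 * prior_sd
        assert grid.z_mean.min() >= lo and grid.z_mean.max() <= hi

    def test_void_rmse_within_twice_populated_rmse(self, exp_profile,
                                                   growth_model):
        scene = synth.make_scene(exp_profile, growth_model, 6000.0, 0.3,
                                 seed=8)
        sub = scene.cells.sample(250, random_state=0)
        obs = ObservationSet("axonal_growth", sub.rename(
            columns={"value": "z"})[["x_um", "y_um", "z"]].reset_index(
                drop=True))
        hp, _ = optimize_hyperparameters(obs, 12, seed=0)
        surf = fit_surface(obs, hp)
        grid = predict_grid(surf, obs.bounding_box, total_points=2500)
        xx, yy = np.meshgrid(grid.x_um, grid.y_um)
        truth = growth_model.mean(exp_profile.period_at(xx.ravel()))
        err = (grid.z_mean.ravel() - truth) ** 2
        in_void = np.zeros(xx.size, dtype=bool)
        for (vx0, vy0, vx1, vy1) in scene.void_regions:
            in_void |= ((xx.ravel() >= vx0) & (xx.ravel() < vx1)
                        & (yy.ravel() >= vy0) & (yy.ravel() < vy1))
        rmse_void = np.sqrt(err[in_void].mean())
        rmse_pop = np.sqrt(err[~in_void].mean())
        assert rmse_void <= 2.0 * rmse_pop


class TestHoldoutError:
    def test_interpolating_fit_has_near_zero_rmse_on_train(self):
        obs = make_obs(40, seed=1, fn=lambda x, y: np.sin(x / 150))
        hp = GPHyperparameters(200.0, 200.0, 1.0, 1e-10)
        surf = fit_surface(obs, hp)
        rmse, r2 = holdout_error(surf, obs)
        assert rmse == pytest.approx(0.0, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_constant_predictor_nonpositive_r2(self):
        train = make_obs(25, fn=lambda x, y: np.full_like(x, 1.0))
        test = make_obs(25, seed=4, fn=lambda x, y: x / 1000)
        surf = fit_surface(train, GPHyperparameters(100, 100, 1e-6, 1.0))
        _, r2 = holdout_error(surf, test)
        assert r2 <= 0.05


class TestMarginalizeToSizeCurve:
    def _surface_grid(self, fn, n=200, seed=0):
        obs = make_obs(n, seed=seed, fn=fn)
        hp, _ = optimize_hyperparameters(obs, 10, seed=0)
        surf = fit_surface(obs, hp)
        return predict_grid(surf, (0, 1000, 0, 1000), total_points=2500)

    def test_y_independent_surface_reindexed_by_size(self):
        cal = SizeCalibration(np.log(0.5), np.log(40) / 1000, 1.0, (0, 1000))
        grid = self._surface_grid(lambda x, y: x / 1000)
        curve = marginalize_to_size_curve(grid, cal, 6)
        # response increases with x, size increases with x -> monotone curve
        assert np.all(np.diff(curve.mean) > -0.02)

    def test_peak_recovered_in_correct_size_bin(self, exp_profile,
                                                exp_calibration,
                                                growth_model):
        scene = synth.make_scene(exp_profile, growth_model, 6000.0, 0.3,
                                 seed=13)
        sub = scene.cells.sample(250, random_state=1)
        obs = ObservationSet("axonal_growth", sub.rename(
            columns={"value": "z"})[["x_um", "y_um", "z"]].reset_index(
                drop=True))
        hp, _ = optimize_hyperparameters(obs, 12, seed=0)
        surf = fit_surface(obs, hp)
        grid = predict_grid(surf, obs.bounding_box, total_points=2500)
        curve = marginalize_to_size_curve(grid, exp_calibration, 8)
        best = int(np.argmax(curve.mean))
        lo = curve.bin_edges_um[best]
        hi = curve.bin_edges_um[best + 1]
        assert lo <= 5.0 <= hi

    def test_calibration_range_mismatch_rejected(self):
        cal = SizeCalibration(0.0, 0.001, 1.0, (0, 100))
        grid = self._surface_grid(lambda x, y: x / 1000)
        with pytest.raises(ValueError, match="calibrated range"):
            marginalize_to_size_curve(grid, cal, 6)
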
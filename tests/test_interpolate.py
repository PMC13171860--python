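import numpy as np
import pandas as pd
import pytest

from canopystack.grids import GridSpec, Raster
from canopystack.interpolate import (
    IDWOptimizerConfig,
    InterpolationReport,
    evaluate_interpolation,
    idw,
    optimize_beta,
    ordinary_kriging,
    r_squared,
    realization_cv,
    resample_nearest,
    RealizationStack,
    select_convergent_n,
    sgcs,
)
from canopystack.synthdata import simulate_gaussian_field
from canopystack.variogram import VariogramModel, semivariance


@pytest.fixture
def model():
    return VariogramModel("spherical", 0.0, 1.0, 300.0)


class TestOrdinaryKriging:
    def test_exactness_at_observation(self, model, scattered_obs):
        xy, z = scattered_obs
        res = ordinary_kriging(xy, z, xy[:5], model)
        np.testing.assert_allclose(res.estimates, z[:5])
        np.testing.assert_allclose(res.variances, 0.0)

    def test_constant_observations(self, model):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 500, (30, 2))
        z = np.full(30, 4.2)
        res = ordinary_kriging(xy, z, rng.uniform(0, 500, (10, 2)), model)
        np.testing.assert_allclose(res.estimates, 4.2, rtol=1e-8)

    def test_hand_assembled_system(self, model):
        # 3 observations, 1 target: solve the 4x4 OK system independently
        xy = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        z = np.array([1.0, 2.0, 4.0])
        target = np.array([[40.0, 40.0]])

        A = np.zeros((4, 4))
        for i in range(3):
            for j in range(3):
                A[i, j] = semivariance(model, np.linalg.norm(xy[i] - xy[j]))
        A[3, :3] = 1.0
        A[:3, 3] = 1.0
        b = np.append(
            [semivariance(model, np.linalg.norm(xy[i] - target[0])) for i in range(3)],
            1.0,
        )
        sol = np.linalg.solve(A, b)
        expected = sol[:3] @ z

        res = ordinary_kriging(xy, z, target, model)
        assert res.estimates[0] == pytest.approx(expected, rel=1e-10)

    def test_weights_sum_to_one_and_exactness_100_random(self, model):
        # invariant sweep: random configurations, checked to 1e-8
        for trial in range(100):
            rng = np.random.default_rng(trial)
            n = rng.integers(5, 25)
            xy = rng.uniform(0, 1000, (n, 2))
            z = rng.normal(size=n)
            target = rng.uniform(0, 1000, (1, 2))
            # weight-sum check via constant-shift invariance: OK(z + c) = OK(z) + c
            e1 = ordinary_kriging(xy, z, target, model).estimates[0]
            e2 = ordinary_kriging(xy, z + 5.0, target, model).estimates[0]
            assert e2 - e1 == pytest.approx(5.0, abs=1e-8)
            # exactness at a random observation
            j = rng.integers(0, n)
            at_obs = ordinary_kriging(xy, z, xy[[j]], model)
            assert at_obs.estimates[0] == pytest.approx(z[j], abs=1e-8)
            assert at_obs.variances[0] == 0.0

    def test_pure_nugget_gives_neighborhood_mean(self):
        m = VariogramModel("spherical", 1.0, 0.0, 100.0)
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 300, (12, 2))
        z = rng.normal(size=12)
        res = ordinary_kriging(xy, z, np.array([[150.0, 150.0]]), m, max_neighbors=12)
        assert res.estimates[0] == pytest.approx(z.mean(), rel=1e-8)

    def test_duplicate_points_deduplicated(self, model):
        xy = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        z = np.array([1.0, 3.0, 2.0, 4.0])
        res = ordinary_kriging(xy, z, np.array([[0.0, 0.0]]), model)
        assert res.estimates[0] == pytest.approx(2.0)  # averaged duplicate

    def test_grid_output(self, model, small_grid, scattered_obs):
        xy, z = scattered_obs
        res = ordinary_kriging(xy, z, small_grid, model)
        assert isinstance(res.estimates, Raster)
        assert res.estimates.values.shape == small_grid.shape
        assert np.all(res.variances.values >= 0)


class TestSGCS:
    def _setup(self, n_obs=90, grid_n=32, seed=3, nugget=0.05):
        g = GridSpec(0, 0, 30.0, grid_n, grid_n)
        m = VariogramModel("spherical", nugget, 1.0, 400.0)
        fld = simulate_gaussian_field(g, m, 10.0, seed=seed)
        rng = np.random.default_rng(0)
        idx = rng.choice(grid_n * grid_n, n_obs, replace=False)
        rows, cols = idx // grid_n, idx % grid_n
        x, y = g.cell_center(rows, cols)
        return g, m, np.column_stack([x, y]), fld.values[rows, cols], rows, cols

    def test_zero_sill_constant(self, small_grid):
        m = VariogramModel("spherical", 0.0, 0.0, 100.0)
        xy = np.array([[10.0, -10.0], [50.0, -50.0]])
        with pytest.warns(UserWarning):
            st = sgcs(xy, np.array([3.0, 3.0]), small_grid, m, 3, seed=0)
        assert np.all(st.as_array() == 3.0)

    def test_honors_data_every_realization(self):
        g, m, xy, z, rows, cols = self._setup(n_obs=40, grid_n=24)
        st = sgcs(xy, z, g, m, n_realizations=5, seed=2)
        arr = st.as_array()
        for k in range(5):
            np.testing.assert_allclose(arr[k, rows, cols], z, atol=1e-9)

    def test_realizations_differ(self):
        g, m, xy, z, *_ = self._setup(n_obs=40, grid_n=24)
        st = sgcs(xy, z, g, m, n_realizations=2, seed=2)
        assert not np.array_equal(st.realizations[0].values, st.realizations[1].values)

    def test_reproducible_and_extensible(self):
        g, m, xy, z, *_ = self._setup(n_obs=30, grid_n=16)
        a = sgcs(xy, z, g, m, n_realizations=3, seed=5)
        b = sgcs(xy, z, g, m, n_realizations=5, seed=5)
        for k in range(3):
            np.testing.assert_array_equal(a.realizations[k].values,
                                          b.realizations[k].values)


class TestRealizationCV:
    def _stack(self, arrays):
        g = GridSpec(0, 0, 30.0, 1, len(arrays[0]))
        m = VariogramModel("spherical", 0.0, 1.0, 100.0)
        rasters = [Raster(g, np.asarray(a, dtype=float).reshape(1, -1)) for a in arrays]
        return RealizationStack(rasters, m, 0)

    def test_identical_realizations_zero(self):
        st = self._stack([[5.0, 7.0], [5.0, 7.0], [5.0, 7.0]])
        assert realization_cv(st) == 0.0

    def test_hand_arithmetic(self):
        st = self._stack([[9.0], [11.0]])
        assert realization_cv(st) == pytest.approx(np.std([9, 11], ddof=1) / 10.0)

    def test_single_realization_error(self):
        st = self._stack([[1.0, 2.0]])
        with pytest.raises(ValueError):
            realization_cv(st)


class TestConvergence:
    def test_vacuous_tolerance_picks_second(self):
        g = GridSpec(0, 0, 30.0, 12, 12)
        m = VariogramModel("spherical", 0.0, 1.0, 200.0)
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 360, (20, 2))
        z = rng.normal(10, 1, 20)
        n, trace, conv = select_convergent_n(xy, z, g, m, [3, 5, 8], tol=np.inf, seed=0)
        assert n == 5 and conv

    def test_chosen_n_matches_recomputed_trace(self):
        g = GridSpec(0, 0, 30.0, 12, 12)
        m = VariogramModel("spherical", 0.1, 1.0, 250.0)
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 360, (25, 2))
        z = rng.normal(10, 1, 25)
        tol = 0.002
        n, trace, conv = select_convergent_n(xy, z, g, m, [5, 10, 15], tol=tol, seed=3)
        # independent recomputation from a fresh full stack
        full = sgcs(xy, z, g, m, 15, seed=3)
        cvs = {k: realization_cv(RealizationStack(full.realizations[:k], m, 3))
               for k in [5, 10, 15]}
        expected = None
        for prev, cur in [(5, 10), (10, 15)]:
            if abs(cvs[cur] - cvs[prev]) <= tol:
                expected = cur
                break
        assert trace == cvs
        assert n == (expected if expected is not None else 15)

    def test_too_few_candidates(self):
        g = GridSpec(0, 0, 30.0, 4, 4)
        m = VariogramModel("spherical", 0.0, 1.0, 100.0)
        with pytest.raises(ValueError):
            select_convergent_n(np.zeros((3, 2)), np.zeros(3), g, m, [5], tol=0.1)


class TestIDW:
    def test_target_at_observation(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0]])
        z = np.array([1.0, 9.0])
        assert idw(xy, z, np.array([[0.0, 0.0]]))[0] == 1.0

    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0, 4.0])
    def test_equidistant_symmetry(self, beta):
        xy = np.array([[-10.0, 0.0], [10.0, 0.0]])
        z = np.array([0.0, 10.0])
        assert idw(xy, z, np.array([[0.0, 0.0]]), beta=beta)[0] == pytest.approx(5.0)

    def test_hand_weighted_mean(self):
        xy = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        z = np.array([2.0, 4.0, 8.0])
        target = np.array([[0.0, 1.0]])  # distances 1, sqrt(10), 3
        w = np.array([1.0, 10.0 ** -1, 9.0 ** -1])
        expected = (w @ z) / w.sum()
        assert idw(xy, z, target, beta=2.0)[0] == pytest.approx(expected)

    def test_bounded_by_neighborhood(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 100, (40, 2))
        z = rng.normal(size=40)
        pred = idw(xy, z, rng.uniform(0, 100, (200, 2)), beta=2.5)
        assert np.all(pred >= z.min() - 1e-12) and np.all(pred <= z.max() + 1e-12)

    def test_no_observations_error(self):
        with pytest.raises(ValueError):
            idw(np.empty((0, 2)), np.empty(0), np.array([[0.0, 0.0]]))


class TestOptimizeBeta:
    def test_grid_candidate_count(self, scattered_obs):
        xy, z = scattered_obs
        _, trace = optimize_beta(xy, z, IDWOptimizerConfig(method="grid", seed=0))
        assert len(trace) == 46

    def test_constant_values_tie_rule(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 100, (20, 2))
        z = np.full(20, 3.0)
        with pytest.warns(UserWarning):
            beta, _ = optimize_beta(xy, z, IDWOptimizerConfig(method="grid", seed=0))
        assert beta == 0.1  # lower bound by the degenerate-objective rule

    def test_optimizers_beat_untuned_default(self, scattered_obs):
        from canopystack.interpolate import _cv_rmse

        xy, z = scattered_obs
        base = _cv_rmse(xy, z, 2.0, 5, 11, 15)
        for method in ("pso", "ga", "grid"):
            cfg = IDWOptimizerConfig(method=method, seed=11)
            beta, _ = optimize_beta(xy, z, cfg)
            assert _cv_rmse(xy, z, beta, 5, 11, 15) <= base + 1e-12

    def test_invalid_method(self):
        with pytest.raises(ValueError):
            IDWOptimizerConfig(method="annealing")


class TestEvaluate:
    def _footprints(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 600, (n, 2))
        return pd.DataFrame({
            "x": xy[:, 0], "y": xy[:, 1],
            "m": np.sin(xy[:, 0] / 150) + 0.3 * rng.normal(size=n),
        })

    def test_r2_formula_oracle(self):
        z = np.array([1.0, 2.0, 3.0, 4.0])
        zh = np.array([1.1, 1.9, 3.2, 3.9])
        expected = 1 - np.sum((z - zh) ** 2) / np.sum((z - z.mean()) ** 2)
        assert r_squared(z, zh) == pytest.approx(expected)

    def test_perfect_method_retained(self, monkeypatch):
        fp = self._footprints()
        import canopystack.interpolate as interp

        monkeypatch.setattr(
            interp, "_predict_method",
            lambda method, txy, tz, sxy, model, nr, seed, grid:
                np.sin(sxy[:, 0] / 150) + 0.3 * 0,
        )
        fp["m"] = np.sin(fp["x"] / 150)
        rep = interp.evaluate_interpolation(fp, "m", "idw", seed=1)
        assert rep.r2_test == pytest.approx(1.0)
        assert rep.retained

    def test_split_sizes(self):
        fp = self._footprints(n=100)
        rep = evaluate_interpolation(fp, "m", "idw", seed=2)
        assert rep.n_train == 80 and rep.n_test == 20
        assert rep.n_train + rep.n_test == len(fp)

    def test_unknown_method(self):
        fp = self._footprints()
        with pytest.raises(ValueError):
            evaluate_interpolation(fp, "m", "spline")


class TestResample:
    def test_identical_grid_identity(self, gaussian_field):
        out = resample_nearest(gaussian_field, gaussian_field.grid)
        np.testing.assert_array_equal(out.values, gaussian_field.values)

    def test_2x_upsample_block_replication(self):
        g = GridSpec(0, 0, 30.0, 2, 2)
        r = Raster(g, np.array([[1.0, 2.0], [3.0, 4.0]]))
        fine = GridSpec(0, 0, 15.0, 4, 4)
        out = resample_nearest(r, fine)
        expected = np.repeat(np.repeat(r.values, 2, axis=0), 2, axis=1)
        np.testing.assert_array_equal(out.values, expected)

    def test_no_new_values(self):
        rng = np.random.default_rng(8)
        g = GridSpec(0, 0, 25.0, 9, 7)
        r = Raster(g, rng.normal(size=(9, 7)))
        target = GridSpec(10, -5, 17.0, 11, 12)
        out = resample_nearest(r, target)
        src = set(r.values.ravel())
        dst = set(out.values[out.values != out.nodata].ravel())
        assert dst <= src

    def test_disjoint_extents_warn(self):
        g = GridSpec(0, 0, 30.0, 4, 4)
        r = Raster(g, np.ones((4, 4)))
        far = GridSpec(10_000, 10_000, 30.0, 4, 4)
        with pytest.warns(UserWarning):
            out = resample_nearest(r, far)
        assert np.all(out.values == out.nodata)
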
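"""Stratified split, evaluation metrics and the SVM learner."""

import numpy as np
import pytest

from anthospec.evaluate import (ModelReport, SVMRegressorCV, SplitResult,
                                evaluate_predictions, r_squared,
                                reports_to_frame, rmse, rpd, rpd_class,
                                run_model_grid, stratified_split)


class TestStratifiedSplit:
    def test_ten_sample_example(self):
        """10 samples spread over 5 strata, ratio 0.7 -> exactly 7 train,
        3 validation."""
        ant = np.array([10., 20., 210., 220., 410., 420., 610., 620.,
                        810., 820.])
        split = stratified_split(ant, ratio=0.7, n_strata=5, seed=0)
        assert split.train_idx.size == 7
        assert split.val_idx.size == 3
        assert np.array_equal(np.sort(np.concatenate(
            [split.train_idx, split.val_idx])), np.arange(10))

    def test_global_count_exact(self, rng):
        for n in (29, 50, 300):
            ant = rng.uniform(0, 1400, size=n)
            split = stratified_split(ant, ratio=0.7, n_strata=5, seed=1)
            assert split.train_idx.size == round(0.7 * n)
            assert split.n == n

    def test_strata_are_equal_width(self, rng):
        ant = rng.uniform(0, 1000, size=200)
        split = stratified_split(ant, n_strata=5, seed=0)
        edges = np.linspace(ant.min(), ant.max(), 6)
        expect = np.clip(np.digitize(ant, edges[1:-1]), 0, 4)
        np.testing.assert_array_equal(split.stratum, expect)

    def test_deterministic_and_seed_sensitive(self, rng):
        ant = rng.uniform(0, 1400, size=100)
        a = stratified_split(ant, seed=7)
        b = stratified_split(ant, seed=7)
        c = stratified_split(ant, seed=8)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        assert not np.array_equal(a.train_idx, c.train_idx)

    def test_empty_stratum_merged_with_warning(self):
        # bimodal: middle strata empty
        ant = np.concatenate([np.full(10, 10.0) + np.arange(10),
                              np.full(10, 1000.0) + np.arange(10)])
        with pytest.warns(UserWarning, match="empty"):
            split = stratified_split(ant, n_strata=5, seed=0)
        assert split.n == 20

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.arange(10.0), ratio=1.0)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitResult(np.array([0, 1]), np.array([1, 2]),
                        np.zeros(3, dtype=int), 0)

    def test_json_round_trip(self, tmp_path):
        split = stratified_split(np.linspace(0, 1000, 20), seed=3)
        back = SplitResult.from_json(split.to_json(tmp_path / "s.json"))
        np.testing.assert_array_equal(back.train_idx, split.train_idx)
        np.testing.assert_array_equal(back.val_idx, split.val_idx)


class TestMetrics:
    y = np.array([1.0, 2.0, 3.0, 4.0])

    def test_perfect_prediction(self):
        assert r_squared(self.y, self.y) == 1.0
        assert rmse(self.y, self.y) == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        yhat = np.full(4, self.y.mean())
        assert r_squared(self.y, yhat) == pytest.approx(0.0)

    def test_hand_values(self):
        yhat = np.array([1.5, 2.0, 2.5, 4.5])
        # residuals 0.5, 0, -0.5, -0.5 -> SS_res = 0.75; SS_tot = 5
        assert r_squared(self.y, yhat) == pytest.approx(1 - 0.75 / 5)
        assert rmse(self.y, yhat) == pytest.approx(np.sqrt(0.75 / 4))

    def test_rpd_definition(self):
        value = rpd(self.y, 0.5)
        assert value == pytest.approx(self.y.std(ddof=1) / 0.5)

    def test_rpd_zero_rmse_is_inf(self):
        assert rpd(self.y, 0.0) == np.inf

    def test_rpd_classes(self):
        assert rpd_class(2.5) == "very good"
        assert rpd_class(1.9) == "good"
        assert rpd_class(1.5) == "usable"
        assert rpd_class(1.0) == "unreliable"

    def test_rpd_r2_relation(self, rng):
        """For large n, RPD ~ 1/sqrt(1 - R2) when RMSE is computed on the
        same samples as the SD."""
        y = rng.normal(size=5000)
        yhat = y + 0.5 * rng.normal(size=5000)
        r2 = r_squared(y, yhat)
        value = rpd(y, rmse(y, yhat))
        assert value == pytest.approx(1 / np.sqrt(1 - r2), rel=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(4), np.ones(4))

    def test_evaluate_predictions_keys(self):
        out = evaluate_predictions(self.y, self.y, self.y, self.y + 0.1)
        assert set(out) == {"r2_c", "rmse_c", "rpd_c",
                            "r2_v", "rmse_v", "rpd_v"}
        assert out["r2_c"] == 1.0
        assert out["rmse_v"] == pytest.approx(0.1)


class TestSVMRegressorCV:
    def make_problem(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(n, 4))
        y = 100.0 + 50.0 * X[:, 0] + 20.0 * X[:, 1] ** 2 \
            + 2.0 * rng.normal(size=n)
        return X, y

    def small_grid(self, seed=0):
        return SVMRegressorCV(log2_C=(0, 3, 6), log2_gamma=(-3, 0),
                              epsilon_frac=(0.1,), seed=seed)

    def test_learns_smooth_function(self):
        X, y = self.make_problem()
        model = self.small_grid().fit(X, y)
        assert r_squared(y, model.predict(X)) > 0.9
        assert set(model.best_params_) == {"C", "gamma", "epsilon_frac"}
        assert model.cv_rmse_ > 0

    def test_deterministic(self):
        X, y = self.make_problem(seed=2)
        p1 = self.small_grid(seed=5).fit(X, y).predict(X)
        p2 = self.small_grid(seed=5).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_grid_point(self):
        X, y = self.make_problem()
        model = SVMRegressorCV(log2_C=(3,), log2_gamma=(0,),
                               epsilon_frac=(0.1,)).fit(X, y)
        assert model.best_params_ == {"C": 8.0, "gamma": 1.0,
                                      "epsilon_frac": 0.1}

    def test_no_leakage_on_pure_noise(self):
        """CV RMSE on unlearnable noise must not undercut sd(y) by much:
        a leaky scaler would look artificially accurate."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        model = self.small_grid().fit(X, y)
        assert model.cv_rmse_ > 0.8 * y.std(ddof=1)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            self.small_grid().fit(np.zeros((10, 2)), np.ones(10))


class TestModelGrid:
    def test_grid_shape_and_reports(self, rng):
        n = 60
        ant = rng.uniform(50, 1200, size=n)
        features = {
            (d, s): np.column_stack([ant + 20 * rng.normal(size=n)
                                     for _ in range(5)])
            for d in ("fd", "sd") for s in ("CARS", "RFECV")
        }
        split = stratified_split(ant, seed=0)
        learners = {"SVM": lambda s: SVMRegressorCV(
            log2_C=(3,), log2_gamma=(-2,), epsilon_frac=(0.1,), seed=s)}
        reports = run_model_grid(features, ant, split, learners, seed=0)
        assert len(reports) == 4
        ids = {r.model_id for r in reports}
        assert "fd-CARS-SVM" in ids and "sd-RFECV-SVM" in ids
        frame = reports_to_frame(reports)
        assert frame["best"].sum() == 1
        best_row = frame[frame["best"]].iloc[0]
        assert best_row["r2_v"] == frame["r2_v"].max()

    def test_row_mismatch_rejected(self, rng):
        ant = rng.uniform(0, 100, size=20)
        split = stratified_split(ant, seed=0)
        with pytest.raises(ValueError, match="rows"):
            run_model_grid({("fd", "CARS"): np.zeros((19, 3))}, ant, split,
                           {"SVM": lambda s: SVMRegressorCV(seed=s)})

    def test_report_to_dict(self):
        r = ModelReport("fd", "SFLA", "SVM", 0.9, 10.0, 3.0,
                        0.85, 12.0, 2.5)
        d = r.to_dict()
        assert d["model_id"] == "fd-SFLA-SVM"
        assert d["rpd_v_class"] == "very good"
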
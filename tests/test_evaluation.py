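"""CV plan invariants, metric closed forms, grid search and the roster."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countgs import (
    GridSpec,
    apc,
    average_across_traits,
    bootstrap_se,
    grid_search,
    maape,
    make_benchmark_dataset,
    make_cv_plan,
    mse,
    percent_superiority,
    run_roster,
)
from countgs.evaluation import GPR_ALPHAS, ROSTER
from countgs.glm import GPRConfig


class TestCVPlan:
    def test_64_16_20_split(self):
        plan = make_cv_plan(100, n_folds=5, tune_fraction=0.2, seed=0)
        for f in range(5):
            assert len(plan.test_idx(f)) == 20
            assert len(plan.tune_idx[f]) == 16
            assert len(plan.train_idx(f)) == 64

    def test_partition_exactness(self):
        plan = make_cv_plan(103, n_folds=5, seed=1)
        all_test = np.concatenate([plan.test_idx(f) for f in range(5)])
        assert len(all_test) == 103
        assert len(np.unique(all_test)) == 103
        for f in range(5):
            assert not np.intersect1d(plan.tune_idx[f], plan.test_idx(f)).size

    def test_same_seed_same_plan(self):
        a = make_cv_plan(60, seed=7)
        b = make_cv_plan(60, seed=7)
        assert np.array_equal(a.fold_of, b.fold_of)
        for ta, tb in zip(a.tune_idx, b.tune_idx):
            assert np.array_equal(ta, tb)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(3, n_folds=5)


class TestMetrics:
    def test_mse_closed_forms(self):
        assert mse([1, 2], [1, 2]) == 0.0
        assert mse([1, 3], [2, 2]) == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        two_pass = sum((a - b) ** 2 for a, b in zip(y, yhat)) / 50
        assert mse(y, yhat) == pytest.approx(two_pass, abs=1e-12)

    def test_maape_worked_values(self):
        assert maape([2.0, 5.0], [2.0, 5.0]) == 0.0
        assert maape([1.0], [2.0]) == pytest.approx(np.pi / 4)
        assert maape([0.0], [5.0]) == pytest.approx(np.pi / 2)
        assert maape([0.0], [0.0]) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_maape_bounded(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.poisson(3.0, size=20).astype(float)
        yhat = rng.uniform(0, 10, size=20)
        val = maape(y, yhat)
        assert 0.0 <= val <= np.pi / 2

    def test_apc_affine_invariance(self):
        y = np.array([1.0, 2.0, 3.0])
        assert apc(y, 2 * y + 1, ["A"] * 3) == pytest.approx(1.0)

    def test_apc_two_env_average(self):
        y = np.array([1.0, 2, 3, 1, 2, 3])
        yhat = np.array([1.0, 2, 3, 3, 2, 1])
        envs = ["A"] * 3 + ["B"] * 3
        assert apc(y, yhat, envs) == pytest.approx(0.0, abs=1e-12)

    def test_apc_matches_per_slice_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=40)
        yhat = y + rng.normal(scale=0.5, size=40)
        envs = np.repeat(["A", "B", "C", "D"], 10)
        expected = np.mean(
            [np.corrcoef(y[envs == e], yhat[envs == e])[0, 1] for e in "ABCD"]
        )
        assert apc(y, yhat, envs) == pytest.approx(expected, abs=1e-12)

    def test_apc_degenerate_slices(self):
        y = np.array([1.0, 1.0, 1.0, 2.0, 3.0])
        yhat = np.array([2.0, 1.0, 3.0, 4.0, 6.0])
        envs = ["A", "A", "A", "B", "B"]  # A has zero variance in y -> skipped
        assert apc(y, yhat, envs) == pytest.approx(1.0)
        assert np.isnan(apc(y[:3], yhat[:3], envs[:3]))

    def test_empty_rejected(self):
        for fn in (mse, maape):
            with pytest.raises(ValueError):
                fn([], [])


class TestBootstrapSE:
    def test_zero_on_perfect_predictions(self):
        y = np.arange(10.0)
        assert bootstrap_se(y, y, "mse", n_boot=50, seed=0) == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(4.0, size=30).astype(float)
        yhat = y + rng.normal(size=30)
        a = bootstrap_se(y, yhat, "maape", n_boot=100, seed=5)
        b = bootstrap_se(y, yhat, "maape", n_boot=100, seed=5)
        assert a == b

    def test_matches_delta_method_for_mse(self):
        # SE(mean of squared errors) ~ sd(e^2)/sqrt(n)
        rng = np.random.default_rng(6)
        n = 500
        y = rng.poisson(5.0, size=n).astype(float)
        yhat = y + rng.normal(size=n)
        e2 = (y - yhat) ** 2
        analytic = e2.std(ddof=1) / np.sqrt(n)
        boot = bootstrap_se(y, yhat, "mse", n_boot=2000, seed=2)
        assert boot == pytest.approx(analytic, rel=0.15)

    def test_apc_requires_env_labels(self):
        with pytest.raises(ValueError):
            bootstrap_se([1.0, 2.0], [1.0, 2.0], "apc", n_boot=10, seed=0)


class TestSummaries:
    def test_average_across_traits(self):
        assert average_across_traits([49.792, 51.319]) == pytest.approx(50.5555)
        assert average_across_traits([8.362, 10.523, 7.357]) == pytest.approx(8.747333, abs=1e-6)
        assert average_across_traits([3.2]) == 3.2

    def test_percent_superiority(self):
        assert percent_superiority(50.556, 33.6) == pytest.approx(50.464, abs=5e-4)
        assert percent_superiority(0.652, 0.582) == pytest.approx(12.0274, abs=1e-3)
        assert percent_superiority(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            percent_superiority(1.0, 0.0)


class TestGridSearch:
    @pytest.fixture
    def small_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 8))
        B = rng.normal(scale=0.25, size=(8, 2))
        Y = rng.poisson(np.exp(0.8 + X @ B)).astype(float)
        return X[:90], Y[:90], X[90:], Y[90:]

    def test_single_candidate_selected(self, small_data):
        Xtr, Ytr, Xtu, Ytu = small_data
        grid = GridSpec(units=(6,), l1_lambda=(0.001,), dropout=(0.0,),
                        batch_size=32, max_epochs=15)
        best, refit, board = grid_search("mpdn", 1, grid, (Xtr, Ytr), (Xtu, Ytu), seed=0)
        assert best == {"units": 6, "l1_lambda": 0.001, "dropout": 0.0}
        assert len(board) == 1
        assert refit.predict(Xtu).shape == (30, 2)

    def test_scoreboard_covers_grid(self, small_data):
        Xtr, Ytr, Xtu, Ytu = small_data
        grid = GridSpec(units=(4, 8), l1_lambda=(0.001, 0.01), dropout=(0.0,),
                        batch_size=32, max_epochs=10)
        best, _, board = grid_search("updn", 2, grid, (Xtr, Ytr[:, :1]), (Xtu, Ytu[:, :1]), seed=1)
        assert len(board) == 4  # 2 units x 2 lambda
        assert board["tun_mse"].min() == board.loc[
            (board["units"] == best["units"])
            & (board["l1_lambda"] == best["l1_lambda"]),
            "tun_mse",
        ].iloc[0]

    def test_invalid_family_and_depth(self, small_data):
        Xtr, Ytr, Xtu, Ytu = small_data
        grid = GridSpec(units=(4,))
        with pytest.raises(ValueError):
            grid_search("gpr", 1, grid, (Xtr, Ytr), (Xtu, Ytu))
        with pytest.raises(ValueError):
            grid_search("mpdn", 5, grid, (Xtr, Ytr), (Xtu, Ytu))


class TestRoster:
    def test_default_grids_match_protocol(self):
        from countgs.evaluation import DATASET1_GRID, DATASET2_GRID

        assert len(DATASET1_GRID.combinations()) == 10  # 5 units x 2 lambda
        assert DATASET1_GRID.batch_size == 273
        assert len(DATASET2_GRID.combinations()) == 16  # 4 x 2 x 2
        assert DATASET2_GRID.batch_size == 500
        assert len(ROSTER) == 13
        assert set(GPR_ALPHAS.values()) == {0.0, 0.25, 0.5, 0.75, 1.0}

    def test_unknown_model_listed(self, tiny_phenotypes, tiny_markers):
        with pytest.raises(ValueError, match="UPDN_1"):
            run_roster(tiny_phenotypes, tiny_markers, roster=["UPDNX"])

    def test_empty_roster_rejected(self, tiny_phenotypes, tiny_markers):
        with pytest.raises(ValueError, match="empty"):
            run_roster(tiny_phenotypes, tiny_markers, roster=[])

    def test_small_roster_report_structure(self):
        mk, ph = make_benchmark_dataset(1, scale=0.12, seed=3)
        report = run_roster(
            ph, mk, roster=["GPR_Ridge", "UPDN_1"],
            grids=GridSpec(units=(6,), l1_lambda=(0.001,), max_epochs=10,
                           batch_size=32),
            seed=2, gpr_config=GPRConfig(alpha=0.0, n_lambda=8, max_iter=40),
            n_boot=50,
        )
        t = report.table
        # 2 models x (2 traits + Average)
        assert len(t) == 6
        assert list(t.columns) == [
            "Model", "Interaction", "Trait", "MSE", "SE_1", "MAAPE", "SE_2", "APC", "SE_3",
        ]
        assert set(t["Interaction"]) == {"WI"}
        report.validate()
        report.check_no_leakage()
        sup = report.superiority_matrix("MSE")
        assert sup.loc["GPR_Ridge", "GPR_Ridge"] == pytest.approx(0.0)

    def test_report_round_trip_files(self, tmp_path):
        mk, ph = make_benchmark_dataset(1, scale=0.12, seed=4)
        report = run_roster(
            ph, mk, roster=["GPR_Lasso"],
            seed=5, gpr_config=GPRConfig(alpha=1.0, n_lambda=8, max_iter=40),
            n_boot=20,
        )
        report.to_csv(tmp_path / "report.csv")
        report.to_json(tmp_path / "report.json")
        import json

        with open(tmp_path / "report.json") as fh:
            payload = json.load(fh)
        assert payload["metadata"]["roster"] == ["GPR_Lasso"]
        assert len(payload["table"]) == len(report.table)
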
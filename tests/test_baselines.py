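import numpy as np
import pandas as pd
import pytest

import accident_baselines as ab
from accident_baselines.baselines import HyperparameterGrid, SELECTED_HYPERPARAMETERS

FEATURES = ("age", "sex", "community", "activity")


def make_scheme():
    return ab.FeatureScheme.make(
        {
            "age": ["<35", "35–49", "≥50"],
            "sex": ["F", "M"],
            "community": [f"R{i}" for i in range(4)],
            "activity": [str(i) for i in range(5)],
        }
    )


def simulated_ratio_table(seed=0, structure="additive", noise=0.0, workers=5000):
    """Cell ratio table with controllable structure: additive effects,
    multiplicative (log-additive) effects, or a depth-2 age-sex interaction."""
    scheme = make_scheme()
    rng = np.random.default_rng(seed)
    cells = pd.DataFrame(list(scheme.iter_cells()), columns=list(FEATURES))
    effects = {f: rng.normal(0, 0.4, size=len(scheme.categories[f])) for f in FEATURES}
    lin = np.zeros(len(cells))
    for f in FEATURES:
        idx = cells[f].map({c: i for i, c in enumerate(scheme.categories[f])}).to_numpy()
        lin += effects[f][idx]
    if structure == "additive":
        rate = 3000 + 1500 * lin
    elif structure == "multiplicative":
        rate = 3000 * np.exp(lin)
    elif structure == "interaction":
        ia = rng.normal(0, 0.8, size=(3, 2))
        ai = cells["age"].map({c: i for i, c in enumerate(scheme.categories["age"])}).to_numpy()
        si = cells["sex"].map({c: i for i, c in enumerate(scheme.categories["sex"])}).to_numpy()
        rate = 3000 * np.exp(0.3 * lin + ia[ai, si])
    else:
        raise ValueError(structure)
    rate = np.clip(rate, 50, None)
    if noise > 0:
        rate = rate * np.exp(rng.normal(0, noise, size=len(rate)))
    cells["workers"] = workers
    cells["accidents"] = np.round(rate * workers / 100_000).astype(int)
    return ab.table_from_counts(scheme, FEATURES, cells)


class TestHyperparameterGrid:
    def test_full_cartesian_product(self):
        grid = HyperparameterGrid(axes={"max_depth": [2, 3], "n_estimators": [10, 20, 30]})
        assert len(grid.points()) == 6

    def test_default_grid_matches_search_protocol(self):
        grid = HyperparameterGrid()
        assert len(grid.points()) == 6 * 4 * 9 * 5
        assert grid.fixed["objective"] == "count:poisson"
        assert grid.fixed["subsample"] == 0.8

    def test_nonpositive_axis_rejected(self):
        with pytest.raises(ValueError):
            HyperparameterGrid(axes={"max_depth": [0, 2]})


class TestSearchHyperparameters:
    def test_single_point_grid_selected(self):
        table = simulated_ratio_table(seed=1, noise=0.1)
        grid = HyperparameterGrid(axes={"max_depth": [3], "n_estimators": [20]})
        sel = ab.search_hyperparameters(table, grid, n_splits=3, seed=0)
        assert sel.chosen == {"max_depth": 3, "n_estimators": 20}

    def test_identical_candidates_first_selected(self):
        table = simulated_ratio_table(seed=1, noise=0.1)
        grid = HyperparameterGrid(axes={"max_depth": [3, 3], "n_estimators": [20]})
        sel = ab.search_hyperparameters(table, grid, n_splits=3, seed=0)
        assert int(sel.scores.sort_values("candidate").iloc[0]["candidate"]) == 0
        assert sel.chosen["max_depth"] == 3

    def test_deterministic_given_seed(self):
        table = simulated_ratio_table(seed=2, noise=0.15)
        grid = HyperparameterGrid(axes={"max_depth": [2, 4], "n_estimators": [20, 50]})
        a = ab.search_hyperparameters(table, grid, n_splits=4, seed=7)
        b = ab.search_hyperparameters(table, grid, n_splits=4, seed=7)
        assert a.chosen == b.chosen
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_shallow_depth_selected_on_depth2_structure(self):
        # the response has only main effects and a depth-2 interaction, so
        # deep trees can only add variance: selection should prefer depth <= 3
        grid = HyperparameterGrid(
            fixed={"learning_rate": 0.1, "subsample": 0.8,
                   "objective": "count:poisson", "colsample_bylevel": 1.0},
            axes={"max_depth": [2, 3, 6], "n_estimators": [100],
                  "colsample_bytree": [1.0]},
        )
        shallow = 0
        n_seeds = 20
        for seed in range(n_seeds):
            table = simulated_ratio_table(seed=seed, structure="interaction", noise=0.15)
            sel = ab.search_hyperparameters(table, grid, n_splits=8, seed=seed)
            shallow += sel.chosen["max_depth"] <= 3
        assert shallow >= 0.8 * n_seeds

    def test_degenerate_response_rejected(self):
        scheme = make_scheme()
        cells = pd.DataFrame(list(scheme.iter_cells()), columns=list(FEATURES))
        cells["workers"] = 1000
        cells["accidents"] = 20
        table = ab.table_from_counts(scheme, FEATURES, cells)
        with pytest.raises(ValueError, match="degenerate"):
            ab.search_hyperparameters(table, HyperparameterGrid(axes={"max_depth": [2]}), n_splits=2)


class TestPredictBaselines:
    def test_own_group_excluded_from_training(self):
        # perturbing every observation in a cell's community-activity group
        # must leave that cell's baseline unchanged
        table = simulated_ratio_table(seed=3, noise=0.1)
        base = ab.predict_baselines(table, n_runs=2, seed=0)
        perturbed = table.table.copy()
        mask = (perturbed["community"] == "R1") & (perturbed["activity"] == "2")
        perturbed.loc[mask, "accidents"] *= 5
        table2 = ab.table_from_counts(table.scheme, FEATURES, perturbed)
        base2 = ab.predict_baselines(table2, n_runs=2, seed=0)
        sel = (base.table["community"] == "R1") & (base.table["activity"] == "2")
        assert np.allclose(base.table.loc[sel, "baseline"], base2.table.loc[sel, "baseline"])
        assert not np.allclose(base.table.loc[~sel, "baseline"], base2.table.loc[~sel, "baseline"])

    def test_constant_rate_recovered_within_mc_error(self):
        # constant true rate with Poisson noise: baselines concentrate near it
        scheme = make_scheme()
        rng = np.random.default_rng(5)
        lam = 2000.0
        cells = pd.DataFrame(list(scheme.iter_cells()), columns=list(FEATURES))
        cells["workers"] = 20_000
        cells["accidents"] = rng.poisson(lam * 20_000 / 100_000, size=len(cells))
        table = ab.table_from_counts(scheme, FEATURES, cells)
        base = ab.predict_baselines(table, n_runs=4, seed=1)
        mc_se = 100_000 * np.sqrt(lam * 20_000 / 100_000) / 20_000  # per-cell count se
        assert np.abs(base.table["baseline"] - lam).median() < 2 * mc_se

    def test_strict_exclusion_mode_never_sees_group_features(self):
        table = simulated_ratio_table(seed=4, noise=0.1)
        base = ab.predict_baselines(table, n_runs=1, seed=0, exclusion_mode="either")
        assert len(base.table) == len(table.valid)

    def test_too_few_training_cells_raises(self):
        scheme = ab.FeatureScheme.make(
            {"community": ["A", "B"], "activity": ["x", "y"]})
        cells = pd.DataFrame(list(scheme.iter_cells()), columns=["community", "activity"])
        cells["workers"] = 100
        cells["accidents"] = [1, 2, 3, 4]
        table = ab.table_from_counts(scheme, ("community", "activity"), cells)
        with pytest.raises(ValueError, match="training cells"):
            ab.predict_baselines(table, n_runs=1, min_train=5)

    def test_negative_predictions_clipped(self):
        table = simulated_ratio_table(seed=6, structure="additive", noise=0.1)
        base = ab.predict_baselines(table, model="linear")
        assert (base.table["baseline"] >= 0).all()

    def test_run_averaging_reduces_spread(self):
        table = simulated_ratio_table(seed=7, noise=0.2)
        few = ab.predict_baselines(table, n_runs=2, seed=3)
        many = ab.predict_baselines(table, n_runs=8, seed=3)
        # the sd column reports spread across runs; the mean of more runs is
        # a steadier estimate, so its MC standard error shrinks
        assert (many.table["baseline_sd"].mean() / np.sqrt(8)) < (
            few.table["baseline_sd"].mean() / np.sqrt(2)
        )


class TestAggregateBaselines:
    def test_single_cell_unchanged(self):
        table = simulated_ratio_table(seed=8, noise=0.1)
        base = ab.predict_baselines(table, n_runs=1, seed=0)
        agg = ab.aggregate_baselines(base, [])
        assert np.allclose(agg["baseline"], base.table["baseline"])

    def test_equal_workers_weighted_mean(self, two_feature_scheme):
        bt = ab.BaselineTable(
            scheme=two_feature_scheme,
            features=("sex", "age"),
            table=pd.DataFrame(
                {"sex": ["Male", "Male"], "age": ["18–45", "50-"],
                 "workers": [500, 500], "accidents": [5, 15],
                 "ratio": [1000.0, 3000.0], "baseline": [1000.0, 3000.0],
                 "baseline_sd": [0.0, 0.0]}
            ),
            n_runs=1,
        )
        agg = ab.aggregate_baselines(bt, ["age"])
        assert agg["baseline"].iloc[0] == pytest.approx(2000.0)
        assert agg["baseline_display"].iloc[0] == 2000

    def test_ratio_of_sums_not_mean_of_ratios(self):
        table = simulated_ratio_table(seed=9, noise=0.2)
        base = ab.predict_baselines(table, n_runs=1, seed=0)
        agg = ab.aggregate_baselines(base, ["age", "sex", "community"])
        t = base.table
        for _, row in agg.iterrows():
            cells = t[t["activity"] == row["activity"]]
            expected = 100_000 * (cells["baseline"] * cells["workers"]).sum() / (
                100_000 * cells["workers"].sum())
            assert row["baseline"] == pytest.approx(expected)
            assert row["baseline"] != pytest.approx(cells["baseline"].mean(), rel=1e-3) or (
                cells["workers"].nunique() == 1)


class TestLinearComparator:
    def test_perfectly_additive_rates(self):
        # workers = 100,000 puts the count-quantization granularity at one
        # ratio unit, so the additive model is exact to rounding
        table = simulated_ratio_table(seed=10, structure="additive", noise=0.0, workers=100_000)
        assert ab.fit_linear_comparator(table) == pytest.approx(1.0, abs=1e-4)

    def test_constant_response_gives_zero(self):
        scheme = make_scheme()
        cells = pd.DataFrame(list(scheme.iter_cells()), columns=list(FEATURES))
        cells["workers"] = 1000
        cells["accidents"] = 30
        table = ab.table_from_counts(scheme, FEATURES, cells)
        assert ab.fit_linear_comparator(table) == 0.0

    def test_interaction_structure_favours_ensemble(self):
        # with a strong age-sex interaction the boosted ensemble's forecast
        # beats the linear forecast under the same leave-group-out protocol
        wins = 0
        for seed in range(5):
            table = simulated_ratio_table(seed=seed + 20, structure="interaction", noise=0.05)
            ens = ab.baseline_r2(ab.predict_baselines(table, n_runs=3, seed=seed))
            lin = ab.baseline_r2(ab.predict_baselines(table, model="linear", seed=seed))
            wins += ens > lin
        assert wins >= 4
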
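import numpy as np
import pandas as pd
import pytest

import accident_baselines as ab
from accident_baselines.weighting import ConvergenceError, InfeasibleTargetsError

from conftest import ipf_weights, random_feasible_instance


class TestIndicatorMatrix:
    def test_published_two_instance_construction(self):
        # (Female, Senior) and (Male, Young) under features [F/M, Senior/Young]
        scheme = ab.FeatureScheme.make({"sex": ["Female", "Male"], "age": ["Senior", "Young"]})
        sample = ab.SurveySample(
            scheme=scheme,
            values=pd.DataFrame({"sex": ["Female", "Male"], "age": ["Senior", "Young"]}),
        )
        Y = ab.build_indicator_matrix(sample, scheme)
        assert Y.y.T.tolist() == [[1, 0, 1, 0], [0, 1, 0, 1]]

    def test_single_instance_single_feature(self):
        scheme = ab.FeatureScheme.make({"sex": ["M", "F"]})
        sample = ab.SurveySample(scheme=scheme, values=pd.DataFrame({"sex": ["F"]}))
        Y = ab.build_indicator_matrix(sample, scheme)
        assert Y.y.shape == (2, 1) and Y.y.sum() == 1 and Y.y[1, 0] == 1

    def test_identical_instances_give_identical_columns(self, two_feature_scheme):
        sample = ab.SurveySample(
            scheme=two_feature_scheme,
            values=pd.DataFrame({"sex": ["Male"] * 4, "age": ["50-"] * 4}),
        )
        Y = ab.build_indicator_matrix(sample, two_feature_scheme)
        assert (Y.y == Y.y[:, [0]]).all()

    def test_column_sums_equal_feature_count(self, worked_sample, two_feature_scheme):
        sample, _ = worked_sample
        Y = ab.build_indicator_matrix(sample, two_feature_scheme)
        assert (Y.y.sum(axis=0) == two_feature_scheme.n_features).all()

    def test_unknown_category_rejected(self, two_feature_scheme):
        sample = ab.SurveySample(
            scheme=two_feature_scheme,
            values=pd.DataFrame({"sex": ["Other"], "age": ["50-"]}),
        )
        with pytest.raises(ValueError):
            ab.build_indicator_matrix(sample, two_feature_scheme)


class TestSolveWeights:
    def test_single_feature_closed_form(self):
        # 60% male / 40% female sample calibrated to 50/50: the entropy
        # optimum is the classical 0.8 / 1.25 multiplicative adjustment,
        # i.e. per-instance weights 0.5/(0.6 S) and 0.5/(0.4 S)
        S = 10
        scheme = ab.FeatureScheme.make({"sex": ["M", "F"]})
        sample = ab.SurveySample(scheme=scheme, values=pd.DataFrame({"sex": ["M"] * 6 + ["F"] * 4}))
        targets = ab.MarginalTargets(proportions={"sex": {"M": 0.5, "F": 0.5}}, n_pop=100)
        w = ab.solve_weights(ab.build_indicator_matrix(sample, scheme), targets)
        assert np.allclose(w.w[:6], 0.5 / (0.6 * S), atol=1e-8)
        assert np.allclose(w.w[6:], 0.5 / (0.4 * S), atol=1e-8)
        # the multiplicative adjustment relative to uniform 1/S: 50/60 and 50/40
        assert np.allclose(w.w[:6] * S, 50 / 60, atol=1e-6)
        assert np.allclose(w.w[6:] * S, 50 / 40, atol=1e-6)

    def test_consistent_targets_give_uniform_weights(self, two_feature_scheme):
        values = pd.DataFrame(
            {"sex": ["Male", "Male", "Female", "Female"], "age": ["18–45", "50-", "18–45", "50-"]}
        )
        sample = ab.SurveySample(scheme=two_feature_scheme, values=values)
        targets = ab.MarginalTargets(
            proportions={"sex": {"Male": 0.5, "Female": 0.5}, "age": {"18–45": 0.5, "50-": 0.5}},
            n_pop=100,
        )
        w = ab.solve_weights(ab.build_indicator_matrix(sample, two_feature_scheme), targets)
        assert np.allclose(w.w, 0.25, atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_ipf_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scheme, sample, Y, targets = random_feasible_instance(rng)
        w = ab.solve_weights(Y, targets)
        oracle = ipf_weights(np.asarray(Y.y, float), targets.as_vector(scheme), scheme)
        assert np.abs(w.w - oracle).max() < 1e-6

    def test_within_cell_equality(self, small_pipeline):
        # entropy maximization gives equal weight to identical category vectors
        sample, w = small_pipeline["sample"], small_pipeline["weights"]
        df = sample.values.copy()
        df["w"] = w.w
        spread = df.groupby(list(sample.scheme.features), observed=True)["w"].agg(np.ptp)
        assert spread.max() < 1e-9

    def test_constraints_satisfied_on_converged_run(self, small_pipeline):
        settings = ab.SolverSettings()
        assert np.abs(small_pipeline["weights"].residuals).max() <= 10 * settings.eps_abs
        w = small_pipeline["weights"].w
        assert (w >= 0).all() and abs(w.sum() - 1) <= 1e-9

    def test_infeasible_targets_named(self, two_feature_scheme):
        sample = ab.SurveySample(
            scheme=two_feature_scheme,
            values=pd.DataFrame({"sex": ["Male", "Male"], "age": ["18–45", "50-"]}),
        )
        targets = ab.MarginalTargets(
            proportions={"sex": {"Male": 0.9, "Female": 0.1}, "age": {"18–45": 0.5, "50-": 0.5}},
            n_pop=100,
        )
        with pytest.raises(InfeasibleTargetsError, match="Female"):
            ab.solve_weights(ab.build_indicator_matrix(sample, two_feature_scheme), targets)

    def test_zero_target_category_pinned_to_zero(self):
        scheme = ab.FeatureScheme.make({"sex": ["M", "F"]})
        sample = ab.SurveySample(scheme=scheme, values=pd.DataFrame({"sex": ["M", "M", "F"]}))
        targets = ab.MarginalTargets(proportions={"sex": {"M": 1.0, "F": 0.0}}, n_pop=10)
        w = ab.solve_weights(ab.build_indicator_matrix(sample, scheme), targets)
        assert w.w[2] == 0 and np.allclose(w.w[:2], 0.5)

    def test_entropy_never_below_feasible_perturbations(self, worked_sample, worked_targets, two_feature_scheme):
        # optimality spot-check: random feasible reweightings have lower entropy
        sample, _ = worked_sample
        Y = ab.build_indicator_matrix(sample, two_feature_scheme)
        w = ab.solve_weights(Y, worked_targets)
        best = ab.weight_entropy(w)
        rng = np.random.default_rng(0)
        y = np.asarray(Y.y, float)
        p = worked_targets.as_vector(two_feature_scheme)
        found_other = 0
        for _ in range(50):
            # project a random perturbation back onto the affine constraint set
            delta = rng.normal(0, 0.01, size=w.S)
            A = np.vstack([y, np.ones(w.S)])
            delta -= A.T @ np.linalg.lstsq(A.T, delta, rcond=None)[0]
            cand = w.w + delta
            if (cand < 0).any():
                continue
            assert np.abs(y @ cand - p).max() < 1e-8
            found_other += 1
            assert ab.weight_entropy(cand) <= best + 1e-12
        assert found_other > 0


class TestCheckFeasibility:
    def test_flags_empty_category_with_positive_target(self, two_feature_scheme):
        sample = ab.SurveySample(
            scheme=two_feature_scheme,
            values=pd.DataFrame({"sex": ["Male"], "age": ["50-"]}),
        )
        Y = ab.build_indicator_matrix(sample, two_feature_scheme)
        targets = ab.MarginalTargets(
            proportions={"sex": {"Male": 0.9, "Female": 0.1}, "age": {"18–45": 0.0, "50-": 1.0}},
            n_pop=10,
        )
        report = ab.check_feasibility(Y, targets)
        assert not report["feasible"]
        assert report["empty_categories"][0]["category"] == "Female"

    def test_worked_example_is_feasible(self, worked_sample, worked_targets, two_feature_scheme):
        sample, _ = worked_sample
        Y = ab.build_indicator_matrix(sample, two_feature_scheme)
        assert ab.check_feasibility(Y, worked_targets)["feasible"]


class TestEntropy:
    def test_uniform_closed_form(self):
        w = np.full(100, 0.01)
        assert ab.weight_entropy(w) == pytest.approx(np.log(100), abs=1e-12)
        assert ab.uniform_entropy(100) == pytest.approx(np.log(100))

    def test_degenerate_weight_vector(self):
        w = np.zeros(50)
        w[0] = 1.0
        assert ab.weight_entropy(w) == 0.0

    def test_solution_entropy_bounded_by_uniform(self, small_pipeline):
        w = small_pipeline["weights"]
        assert ab.weight_entropy(w) <= ab.uniform_entropy(w.S)
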
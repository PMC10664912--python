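import numpy as np
import pandas as pd
import pytest

import accident_baselines as ab


@pytest.fixture(scope="session")
def two_feature_scheme():
    """Sex x age scheme of the published two-feature weighting example."""
    return ab.FeatureScheme.make({"sex": ["Male", "Female"], "age": ["18–45", "50-"]})


@pytest.fixture(scope="session")
def worked_sample(two_feature_scheme):
    """The 8-instance sample of the published worked example, with its
    printed weights (which sum to 0.998 due to print rounding)."""
    values = pd.DataFrame(
        {
            "sex": ["Male"] * 5 + ["Female"] * 3,
            "age": ["18–45", "18–45", "50-", "50-", "50-", "18–45", "50-", "50-"],
        }
    )
    weights = np.array([0.05, 0.05, 0.116, 0.116, 0.116, 0.3, 0.125, 0.125])
    return ab.SurveySample(scheme=two_feature_scheme, values=values), weights


@pytest.fixture(scope="session")
def worked_targets():
    """Population marginals of the worked example: 45/55 by sex, 40/60 by age."""
    return ab.MarginalTargets(
        proportions={
            "sex": {"Male": 0.45, "Female": 0.55},
            "age": {"18–45": 0.40, "50-": 0.60},
        },
        n_pop=1000,
    )


@pytest.fixture(scope="session")
def small_scenario():
    """Desk-size simulated scenario shared across tests (4 regions, 50k
    workers, 2k survey)."""
    cfg = ab.ScenarioConfig(n_regions=4, n_pop=50_000, survey_size=2_000, seed=11)
    return cfg, ab.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_scenario):
    """The small scenario run through harmonize -> weights -> population ->
    ratios, for tests that need realistic intermediate objects."""
    cfg, data = small_scenario
    scheme = data.truth.scheme
    sample, survey_report = ab.filter_survey(data.survey, scheme)
    register, register_report = ab.filter_accidents(data.register, scheme)
    Y = ab.build_indicator_matrix(sample, scheme)
    w = ab.solve_weights(Y, data.marginals)
    pop = ab.weights_to_population(sample, w, scheme, data.marginals.n_pop)
    ratio_table = ab.compute_ratios(register, pop)
    return {
        "config": cfg,
        "data": data,
        "scheme": scheme,
        "sample": sample,
        "survey_report": survey_report,
        "register": register,
        "register_report": register_report,
        "weights": w,
        "population": pop,
        "ratios": ratio_table,
    }


def ipf_weights(y: np.ndarray, p: np.ndarray, scheme, tol: float = 1e-12, maxiter: int = 100_000):
    """Independent iterative-proportional-fitting oracle from a uniform start.

    Classical raking: cycle over features, rescaling the weights of each
    category's members so the weighted share matches its target. From a
    uniform start the fixed point is the maximum-entropy solution.
    """
    S = y.shape[1]
    w = np.full(S, 1.0 / S)
    slices = []
    k = 0
    for f in scheme.features:
        j = len(scheme.categories[f])
        slices.append(slice(k, k + j))
        k += j
    for _ in range(maxiter):
        for sl in slices:
            shares = y[sl] @ w
            factors = np.divide(p[sl], shares, out=np.ones_like(shares), where=shares > 0)
            # each instance has exactly one category per feature, so this
            # picks out its category's rescaling factor
            w = w * (y[sl].T @ factors)
        w = w / w.sum()
        if np.abs(y @ w - p).max() < tol:
            return w
    raise RuntimeError("IPF oracle did not converge")


def random_feasible_instance(rng, max_features: int = 4, max_samples: int = 50):
    """Random small calibration instance whose targets come from a weighting
    of the sample itself (hence guaranteed feasible)."""
    n_feat = rng.integers(1, max_features + 1)
    cats = {f"f{i}": [f"c{j}" for j in range(rng.integers(2, 5))] for i in range(n_feat)}
    scheme = ab.FeatureScheme.make(cats)
    S = int(rng.integers(n_feat + 2, max_samples + 1))
    values = pd.DataFrame({f: rng.choice(cs, size=S) for f, cs in cats.items()})
    sample = ab.SurveySample(scheme=scheme, values=values)
    Y = ab.build_indicator_matrix(sample, scheme)
    ref = rng.dirichlet(np.ones(S) * 5)
    p = Y.y @ ref
    props = {}
    for f in scheme.features:
        props[f] = {}
        for c in scheme.categories[f]:
            props[f][c] = float(p[scheme.flat_index(f, c)])
        total = sum(props[f].values())
        props[f] = {c: v / total for c, v in props[f].items()}
    targets = ab.MarginalTargets(proportions=props, n_pop=1000)
    return scheme, sample, Y, targets
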
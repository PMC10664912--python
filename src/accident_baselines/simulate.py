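"""Ground-truth scenario generator for end-to-end pipeline testing.

Real inputs (labour-force survey microdata, affiliation summaries, the
accident register) are access-restricted, so every pipeline stage is
exercised against simulated sources with known ground truth:

* a worker population over (age block x sex x community x activity) cells,
  allocated multinomially with log-linear cell attractiveness plus cell-level
  noise (the joint is deliberately not exactly product-form);
* a survey whose inclusion probability is tilted by a product of per-feature
  response-propensity factors — the regime where entropy calibration is
  consistent — with an optional non-product tilt to demonstrate the failure
  mode; raw rows use survey-style coding (age in years, province codes,
  10-block activity) and include non-working and blank-province rows so the
  filters have work to do;
* marginal summaries computed from the true population;
* an accident register with per-cell Poisson counts at log-linear true rates,
  written in register-style coding (CNAE divisions, province codes, age in
  years) with relapse and commuting ('in itinere') records injected on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import MarginalTargets, load_province_table
from .scheme import AGE_BLOCKS, COMMUNITIES, FeatureScheme, default_scheme

#: register-style representative CNAE division per activity block
BLOCK_TO_CNAE = {"0": "01", "1": "10", "2": "20", "3": "26", "4": "41",
                 "5": "45", "6": "49", "7": "64", "8": "84", "9": "90"}

_AGE_RANGES = {AGE_BLOCKS[0]: (16, 34), AGE_BLOCKS[1]: (35, 49), AGE_BLOCKS[2]: (50, 70)}
_SEX_TO_CODE = {"M": "1", "F": "2"}


def _community_to_province() -> dict[str, str]:
    table = load_province_table()
    out: dict[str, str] = {}
    for code, community in table.items():
        out.setdefault(community, code)
    return out


def _default_bias() -> dict[str, list[float]]:
    # per-feature response-propensity factors, indexed like the category lists
    return {
        "age": [0.8, 1.0, 1.4],
        "sex": [1.3, 1.0],                      # women over-represented
        "community": [],                        # filled per region count: 0.9/1.1 alternating
        "activity": [0.7 + 0.08 * b for b in range(10)],
    }


@dataclass
class ScenarioConfig:
    """Study conditions for one simulated scenario.

    Defaults are desk-scale but shaped like the Spanish problem: 8
    communities give ~480 cells; the overall accident rate is around 3,000
    per 100,000 workers-year (the order observed nationally); the survey
    covers 2.5% of the population, comparable to a large labour-force survey;
    about a tenth of raw register rows are commuting accidents and a few
    percent are relapses.
    """

    n_regions: int = 8
    n_pop: int = 200_000
    survey_size: int = 5_000
    # population allocation: log-linear attractiveness + cell noise
    pop_effect_sd: float = 0.5
    pop_cell_noise_sd: float = 0.15
    # survey response propensity (product form across features)
    bias_factors: dict[str, list[float]] = field(default_factory=_default_bias)
    misspecified_bias_sd: float = 0.0   # >0 adds a non-product cell tilt
    # accident-rate model, per 100,000 workers-year, log-linear; effect
    # spreads are per feature (sex and age dominate stratum-level incidence
    # differences; regional variation is comparatively modest)
    rate_intercept: float = 3000.0
    rate_effect_sd: dict[str, float] = field(default_factory=lambda: {
        "age": 0.35, "sex": 0.45, "community": 0.15, "activity": 0.50})
    rate_agesex_sd: float = 0.30        # age x sex interaction (learnable)
    rate_interaction_sd: float = 0.06   # community x activity, low by default
    # filter-exercising noise rows
    relapse_fraction: float = 0.04
    in_itinere_fraction: float = 0.10
    non_working_fraction: float = 0.20
    blank_province_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("relapse_fraction", "in_itinere_fraction",
                     "non_working_fraction", "blank_province_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_pop < self.survey_size:
            raise ValueError("n_pop must be at least the survey size")
        if not 1 <= self.n_regions <= len(COMMUNITIES):
            raise ValueError("n_regions out of range")

    def make_scheme(self) -> FeatureScheme:
        return default_scheme(communities=COMMUNITIES[: self.n_regions])

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class GroundTruth:
    """True cell counts and true accident rates (per 100,000 workers-year)."""

    scheme: FeatureScheme
    cells: pd.DataFrame  # feature labels, count, rate
    n_pop: int

    def __post_init__(self) -> None:
        assert int(self.cells["count"].sum()) == self.n_pop
        assert (self.cells["rate"] > 0).all()


def generate_population(config: ScenarioConfig) -> GroundTruth:
    """Draw the true worker population and true cell accident rates.

    Cell attractiveness is exp(sum of per-feature effects + cell noise); the
    population is a single multinomial draw of n_pop workers over cells.
    Rates are exp(log intercept + per-feature effects + community-activity
    interaction); with all spreads at zero every cell rate equals the
    intercept exactly.
    """
    scheme = config.make_scheme()
    rng = config._rng(0)
    cells = pd.DataFrame(list(scheme.iter_cells()), columns=list(scheme.features))
    L = len(cells)

    def cat_idx(f: str) -> np.ndarray:
        return cells[f].map({c: i for i, c in enumerate(scheme.categories[f])}).to_numpy()

    def feature_effects(sd_of) -> np.ndarray:
        total = np.zeros(L)
        for f in scheme.features:
            sd = sd_of(f)
            n = len(scheme.categories[f])
            eff = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
            total += eff[cat_idx(f)]
        return total

    log_attr = feature_effects(lambda f: config.pop_effect_sd)
    if config.pop_cell_noise_sd > 0:
        log_attr += rng.normal(0.0, config.pop_cell_noise_sd, size=L)
    probs = np.exp(log_attr - log_attr.max())
    probs /= probs.sum()
    counts = rng.multinomial(config.n_pop, probs)

    log_rate = math.log(config.rate_intercept) + feature_effects(
        lambda f: config.rate_effect_sd.get(f, 0.0))
    if config.rate_agesex_sd > 0:
        ia = rng.normal(0.0, config.rate_agesex_sd,
                        size=(len(scheme.categories["age"]), len(scheme.categories["sex"])))
        log_rate += ia[cat_idx("age"), cat_idx("sex")]
    if config.rate_interaction_sd > 0:
        inter = rng.normal(0.0, config.rate_interaction_sd,
                           size=(len(scheme.categories["community"]), len(scheme.categories["activity"])))
        log_rate += inter[cat_idx("community"), cat_idx("activity")]

    cells = cells.copy()
    cells["count"] = counts
    cells["rate"] = np.exp(log_rate)
    return GroundTruth(scheme=scheme, cells=cells, n_pop=config.n_pop)


def _bias_per_cell(truth: GroundTruth, config: ScenarioConfig) -> np.ndarray:
    scheme = truth.scheme
    cells = truth.cells
    bias = np.ones(len(cells))
    for f in scheme.features:
        factors = list(config.bias_factors.get(f, []))
        cats = scheme.categories[f]
        if not factors:
            factors = [0.9 if i % 2 == 0 else 1.1 for i in range(len(cats))]
        if len(factors) != len(cats):
            raise ValueError(f"bias factors for {f!r} must match its {len(cats)} categories")
        if min(factors) <= 0:
            raise ValueError("bias factors must be positive")
        idx = cells[f].map({c: i for i, c in enumerate(cats)}).to_numpy()
        bias *= np.asarray(factors)[idx]
    if config.misspecified_bias_sd > 0:
        rng = config._rng(3)
        bias *= np.exp(rng.normal(0.0, config.misspecified_bias_sd, size=len(cells)))
    return bias


def sample_survey(truth: GroundTruth, config: ScenarioConfig) -> pd.DataFrame:
    """Draw survey rows with product-form response bias, in raw survey coding.

    Inclusion probability of a cell is proportional to its worker count times
    the product of per-feature propensity factors. Non-working and
    blank-province rows are appended at the configured fractions (counts are
    round(fraction * survey size)) and the rows shuffled.
    """
    if config.survey_size > truth.n_pop:
        raise ValueError("survey size exceeds population")
    rng = config._rng(1)
    scheme = truth.scheme
    cells = truth.cells
    probs = cells["count"].to_numpy(float) * _bias_per_cell(truth, config)
    probs /= probs.sum()
    per_cell = rng.multinomial(config.survey_size, probs)
    prov_of = _community_to_province()

    rows = []
    for (_, cell), n in zip(cells.iterrows(), per_cell):
        if n == 0:
            continue
        lo, hi = _AGE_RANGES[cell["age"]]
        ages = rng.integers(lo, hi + 1, size=n)
        for a in ages:
            rows.append({
                "work_status": "1",
                "age": int(a),
                "sex": _SEX_TO_CODE[cell["sex"]],
                "activity": cell["activity"],
                "province": prov_of[cell["community"]],
            })
    n_nw = round(config.non_working_fraction * config.survey_size)
    n_bp = round(config.blank_province_fraction * config.survey_size)
    any_prov = next(iter(prov_of.values()))
    for _ in range(n_nw):
        rows.append({"work_status": "0", "age": int(rng.integers(16, 71)),
                     "sex": rng.choice(["1", "2"]), "activity": str(rng.integers(0, 10)),
                     "province": any_prov})
    for _ in range(n_bp):
        rows.append({"work_status": "1", "age": int(rng.integers(16, 71)),
                     "sex": rng.choice(["1", "2"]), "activity": str(rng.integers(0, 10)),
                     "province": ""})
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1))).reset_index(drop=True)


def generate_register(truth: GroundTruth, config: ScenarioConfig) -> pd.DataFrame:
    """Draw the accident register in raw register coding.

    Per-cell accident counts are Poisson(count * rate / 100,000). Relapse
    rows (type 2) and commuting rows (place 3) are injected on top at the
    configured fractions of the genuine total, so the downstream filters must
    remove exactly those counts.
    """
    rng = config._rng(2)
    cells = truth.cells
    lam = cells["count"].to_numpy(float) * cells["rate"].to_numpy(float) / 100_000.0
    counts = rng.poisson(lam)
    prov_of = _community_to_province()

    def make_row(cell, *, acc_type="1", place=None):
        lo, hi = _AGE_RANGES[cell["age"]]
        return {
            "type": acc_type,
            "sex": _SEX_TO_CODE[cell["sex"]],
            "cnae": BLOCK_TO_CNAE[cell["activity"]],
            "province": prov_of[cell["community"]],
            "place": place if place is not None else str(rng.choice([1, 2, 4])),
            "age": int(rng.integers(lo, hi + 1)),
        }

    rows = []
    for (_, cell), n in zip(cells.iterrows(), counts):
        rows.extend(make_row(cell) for _ in range(n))
    total = len(rows)
    n_rel = round(config.relapse_fraction * total)
    n_iti = round(config.in_itinere_fraction * total)
    pick = cells.sample(n=n_rel + n_iti, replace=True,
                        random_state=int(rng.integers(2**31 - 1)))
    for i, (_, cell) in enumerate(pick.iterrows()):
        if i < n_rel:
            rows.append(make_row(cell, acc_type="2"))
        else:
            rows.append(make_row(cell, place="3"))
    df = pd.DataFrame(rows, columns=["type", "sex", "cnae", "province", "place", "age"])
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1))).reset_index(drop=True)


def true_marginals(truth: GroundTruth) -> MarginalTargets:
    """Per-feature category shares of the true population plus the worker
    total — the affiliation-summary analogue."""
    scheme = truth.scheme
    props: dict[str, dict[str, float]] = {}
    for f in scheme.features:
        g = truth.cells.groupby(f, observed=True)["count"].sum()
        # exact simplex normalization to guard against float round-off
        shares = {c: g.get(c, 0) / truth.n_pop for c in scheme.categories[f]}
        total = sum(shares.values())
        props[f] = {c: v / total for c, v in shares.items()}
    return MarginalTargets(proportions=props, n_pop=truth.n_pop)


@dataclass
class SimulatedData:
    truth: GroundTruth
    survey: pd.DataFrame
    register: pd.DataFrame
    marginals: MarginalTargets


def simulate_scenario(config: ScenarioConfig | None = None) -> SimulatedData:
    """Generate every input the pipeline needs for one scenario."""
    config = config or ScenarioConfig()
    truth = generate_population(config)
    return SimulatedData(
        truth=truth,
        survey=sample_survey(truth, config),
        register=generate_register(truth, config),
        marginals=true_marginals(truth),
    )
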
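"""Expand the calibrated weights into an integer synthetic worker population.

Each cell of the feature scheme gets n_pop times its total weight mass,
integerized by largest-remainder apportionment so the counts conserve the
worker total exactly. Against the simulated ground truth this step can be
scored directly.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import accident_baselines as ab

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"

if __name__ == "__main__":
    targets = ab.MarginalTargets.from_dict(json.loads((OUT / "marginals.json").read_text()))
    scheme = targets.implied_scheme()
    sample = ab.SurveySample(scheme=scheme, values=pd.read_csv(OUT / "harmonized_survey.csv", dtype=str))
    w = pd.read_csv(OUT / "weights.csv")["weight"].to_numpy(float)

    pop = ab.weights_to_population(sample, w, scheme, targets.n_pop)
    pop.table.to_csv(OUT / "population.csv", index=False)

    # residual distortion of the integerized population vs the targets
    marg = ab.population_marginals(pop)
    worst = max(
        abs(marg[f][c] - p)
        for f, cats in targets.proportions.items() for c, p in cats.items()
    )
    print(f"synthetic population: {pop.n_pop:,} workers over {pop.L} cells "
          f"({(pop.table['m'] == 0).sum()} empty)")
    print(f"worst marginal distortion after integerization: {worst:.2e}")

    truth = ab.read_cell_table(OUT / "truth.csv", scheme)
    est = pop.counts().reindex([tuple(r) for r in truth[list(scheme.features)].to_numpy()]).to_numpy(float)
    true = truth["count"].to_numpy(float)
    mask = true > 0
    med = np.median(np.abs(est[mask] - true[mask]) / true[mask])
    print(f"median relative cell-count error vs simulated truth: {med:.3f}")
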
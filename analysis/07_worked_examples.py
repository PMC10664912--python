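"""Reproduce the published worked examples with the package's own operations.

Two self-contained checks that need no simulated data: expanding the printed
two-feature sample weights into a 1,000-worker synthetic population, and the
published stratum/aggregation ratio arithmetic under floor display rounding.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import accident_baselines as ab
from accident_baselines.ratios import display_ratio

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    scheme = ab.FeatureScheme.make({"sex": ["Male", "Female"], "age": ["18–45", "50-"]})
    sample = ab.SurveySample(scheme=scheme, values=pd.DataFrame({
        "sex": ["Male"] * 5 + ["Female"] * 3,
        "age": ["18–45", "18–45", "50-", "50-", "50-", "18–45", "50-", "50-"],
    }))
    weights = np.array([0.05, 0.05, 0.116, 0.116, 0.116, 0.3, 0.125, 0.125])
    pop = ab.weights_to_population(sample, weights, scheme, 1000)
    counts = pop.counts()
    print("synthetic population from the printed 8-instance weights (N = 1,000):")
    for cell, m in counts.items():
        print(f"  {cell[0]:>6}/{cell[1]}: {m}")

    ratio_examples = [(746, 22455), (449, 32800), (145, 5522), (1960, 74399), (1177, 75571)]
    print("stratum ratio arithmetic (accidents, workers -> per 100,000, floored):")
    for a, wk in ratio_examples:
        print(f"  {a:>5,} / {wk:>6,} -> {display_ratio(a, wk):,}")

    OUT.mkdir(exist_ok=True)
    (OUT / "worked_examples.json").write_text(json.dumps({
        "synthetic_counts": {f"{c[0]}/{c[1]}": int(m) for c, m in counts.items()},
        "ratios": {f"{a}/{w}": display_ratio(a, w) for a, w in ratio_examples},
    }, indent=2))
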
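"""Observed accident ratios per 100,000 workers per stratum.

Accidents per cell come from the harmonized register; workers per cell from
the synthetic population. Aggregations re-divide summed accidents by summed
workers — never average cell ratios.
"""

import json
from pathlib import Path

import pandas as pd

import accident_baselines as ab

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"

if __name__ == "__main__":
    targets = ab.MarginalTargets.from_dict(json.loads((OUT / "marginals.json").read_text()))
    scheme = targets.implied_scheme()
    register = ab.AccidentRegister(
        scheme=scheme, records=pd.read_csv(OUT / "harmonized_register.csv", dtype=str))
    ptab = ab.read_cell_table(OUT / "population.csv", scheme)
    pop = ab.SyntheticPopulation(scheme=scheme, table=ptab, n_pop=int(ptab["m"].sum()))

    table = ab.compute_ratios(register, pop)
    table.table.to_csv(OUT / "ratios.csv", index=False)
    by_activity = ab.aggregate_ratios(table, ["age", "sex", "community"])
    by_activity.table.to_csv(OUT / "ratios_by_activity.csv", index=False)
    national = ab.aggregate_ratios(table, list(scheme.features)).table.iloc[0]

    n_valid = int(table.table["valid"].sum())
    print(f"{int(table.table['accidents'].sum()):,} accidents over {len(table.table)} cells "
          f"({n_valid} with workers > 0)")
    print(f"national ratio: {int(national['ratio_display']):,} per 100,000 workers-year")
    print("ratio per 100,000 by activity block:")
    for _, row in by_activity.table.iterrows():
        print(f"  block {row['activity']}: {int(row['ratio_display']):>6,}")
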
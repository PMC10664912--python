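"""Filter and harmonize the raw survey and register onto the common scheme.

Survey: keep working respondents with a province inside the country, map age
in years to the three age blocks, province to autonomous community, activity
to the 10-block classification. Register: discard relapses and commuting
('in itinere') accidents, then harmonize the same way.
"""

import json
from pathlib import Path

import pandas as pd

import accident_baselines as ab

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"

if __name__ == "__main__":
    targets = ab.MarginalTargets.from_dict(json.loads((OUT / "marginals.json").read_text()))
    scheme = targets.implied_scheme()
    survey_raw = pd.read_csv(OUT / "survey.csv", dtype=str)
    register_raw = pd.read_csv(OUT / "register.csv", dtype=str)

    sample, s_rep = ab.filter_survey(survey_raw, scheme)
    register, r_rep = ab.filter_accidents(register_raw, scheme)

    sample.values.to_csv(OUT / "harmonized_survey.csv", index=False)
    register.records.to_csv(OUT / "harmonized_register.csv", index=False)
    (OUT / "filter_report.json").write_text(
        json.dumps({"survey": s_rep.to_dict(), "register": r_rep.to_dict()}, indent=2))

    print(f"survey: {s_rep.rows_in:,} rows in, {s_rep.retained:,} retained, dropped {s_rep.dropped}")
    print(f"register: {r_rep.rows_in:,} rows in, {r_rep.retained:,} retained, dropped {r_rep.dropped}")
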
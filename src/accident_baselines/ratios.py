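"""Observed accident ratios per 100,000 workers per cell.

The ratio of a cell is the number of retained register accidents with that
cell's characteristics divided by the synthetic-population worker count of
the cell, scaled to accidents per 100,000 workers and year. Exact rational
values are kept internally; the display convention truncates toward zero.
Aggregations over features always re-divide summed accidents by summed
workers — never average cell ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harmonize import AccidentRegister
from .scheme import FeatureScheme
from .synthpop import SyntheticPopulation

PER = 100_000


def display_ratio(accidents: float, workers: float) -> int:
    """Accidents per 100,000 workers, truncated toward zero for display."""
    return math.floor(PER * accidents / workers)


@dataclass
class RatioTable:
    """Per-cell accidents A, workers W, and ratio per 100,000 workers·year.

    ``table`` columns: the feature labels, ``accidents``, ``workers``,
    ``ratio`` (exact float), ``ratio_display`` (floored int), ``valid``
    (False where workers == 0, ratio undefined).
    """

    scheme: FeatureScheme
    features: tuple[str, ...]
    table: pd.DataFrame

    @property
    def valid(self) -> pd.DataFrame:
        return self.table[self.table["valid"]]


def compute_ratios(
    register: AccidentRegister,
    pop: SyntheticPopulation,
    use_raw_masses: bool = False,
) -> RatioTable:
    """Accident ratio per cell from the harmonized register and the synthetic
    population (integerized counts by default)."""
    if register.scheme.features != pop.scheme.features:
        raise ValueError("register and population use different schemes")
    scheme = pop.scheme
    acc = register.cell_counts()
    table = pop.table[list(scheme.features)].copy()
    key = pd.MultiIndex.from_frame(table)
    table["accidents"] = acc.reindex(key, fill_value=0).to_numpy().astype(np.int64)
    table["workers"] = (pop.table["raw_mass"] if use_raw_masses else pop.table["m"]).to_numpy()
    return _finalize(scheme, scheme.features, table)


def _finalize(scheme: FeatureScheme, features: tuple[str, ...], table: pd.DataFrame) -> RatioTable:
    w = table["workers"].to_numpy(float)
    a = table["accidents"].to_numpy(float)
    valid = w > 0
    ratio = np.full(len(table), np.nan)
    ratio[valid] = PER * a[valid] / w[valid]
    table = table.copy()
    table["ratio"] = ratio
    table["ratio_display"] = [display_ratio(ai, wi) if v else -1 for ai, wi, v in zip(a, w, valid)]
    table["valid"] = valid
    return RatioTable(scheme=scheme, features=tuple(features), table=table.reset_index(drop=True))


def table_from_counts(
    scheme: FeatureScheme,
    features: tuple[str, ...] | list[str],
    counts: pd.DataFrame,
) -> RatioTable:
    """Build a ratio table directly from per-cell accident and worker counts
    (columns ``accidents`` and ``workers`` plus the feature labels) — e.g.
    published stratum totals."""
    return _finalize(scheme, tuple(features), counts[list(features) + ["accidents", "workers"]])


def aggregate_ratios(table: RatioTable, drop_features: list[str]) -> RatioTable:
    """Marginalize features out of a ratio table.

    Accidents and workers are summed over the dropped features' categories
    and the ratio recomputed from the sums; dropping every feature leaves the
    single national cell. Order-independent.
    """
    drop = set(drop_features)
    unknown = drop - set(table.features)
    if unknown:
        raise ValueError(f"cannot drop unknown features {sorted(unknown)}")
    keep = [f for f in table.features if f not in drop]
    if keep:
        g = table.table.groupby(keep, observed=True, sort=False)[["accidents", "workers"]].sum().reset_index()
    else:
        g = table.table[["accidents", "workers"]].sum().to_frame().T
    return _finalize(table.scheme, tuple(keep), g)
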
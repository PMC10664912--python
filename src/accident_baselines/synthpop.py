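"""Synthetic worker population over the full Cartesian product of categories.

The calibrated weights describe the joint distribution of worker
characteristics; multiplying each cell's total weight mass by the worker
population size yields the expected number of workers per cell. Cell masses
are integerized by largest-remainder apportionment so the integer counts
conserve the population total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harmonize import SurveySample
from .scheme import FeatureScheme
from .weighting import WeightVector


@dataclass
class CombinationSet:
    """Ordered enumeration of all category combinations (lexicographic by
    feature order then category order)."""

    scheme: FeatureScheme
    combinations: list[tuple[str, ...]]

    @classmethod
    def from_scheme(cls, scheme: FeatureScheme) -> "CombinationSet":
        return cls(scheme=scheme, combinations=list(scheme.iter_cells()))

    @property
    def L(self) -> int:
        return len(self.combinations)

    def index(self) -> dict[tuple[str, ...], int]:
        return {c: l for l, c in enumerate(self.combinations)}


@dataclass
class SyntheticPopulation:
    """Integer worker counts per cell plus the raw (pre-apportionment) masses.

    ``table`` has one row per combination: the category labels, the integer
    count ``m`` and the raw mass ``raw_mass``; integer counts sum to n_pop
    exactly.
    """

    scheme: FeatureScheme
    table: pd.DataFrame
    n_pop: int

    def __post_init__(self) -> None:
        assert int(self.table["m"].sum()) == self.n_pop

    @property
    def L(self) -> int:
        return len(self.table)

    def counts(self, raw: bool = False) -> pd.Series:
        """Per-cell worker counts indexed by category tuples."""
        idx = pd.MultiIndex.from_frame(self.table[list(self.scheme.features)])
        return pd.Series(
            self.table["raw_mass" if raw else "m"].to_numpy(), index=idx
        )


def largest_remainder(masses: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to nonnegative masses.

    Each cell gets the floor of its proportional share; leftover units go to
    the largest fractional remainders, ties broken by cell order. Every count
    lands within one unit of the exact proportional share.
    """
    masses = np.asarray(masses, float)
    if (masses < 0).any():
        raise ValueError("masses must be nonnegative")
    msum = masses.sum()
    if msum <= 0:
        raise ValueError("total mass must be positive")
    quota = masses * (total / msum)
    base = np.floor(quota).astype(np.int64)
    short = total - int(base.sum())
    if short:
        frac = quota - base
        # stable sort descending on remainder => earliest cell wins ties
        order = np.argsort(-frac, kind="stable")[:short]
        base[order] += 1
    return base


def weights_to_population(
    sample: SurveySample,
    w: WeightVector | np.ndarray,
    scheme: FeatureScheme,
    n_pop: int,
) -> SyntheticPopulation:
    """Expand calibrated weights into integer worker counts per cell.

    The raw mass of cell l is n_pop times the summed weight of the sample
    instances falling in l; cells with no sample instance get zero. Masses
    are normalized to sum to n_pop before apportionment, so weights rounded
    for publication (which may miss the simplex by a little) do not skew the
    allocation. ``w`` may be a solved :class:`WeightVector` or a plain
    nonnegative array of per-instance weights.
    """
    wv = np.asarray(getattr(w, "w", w), float)
    if n_pop <= 0:
        raise ValueError("n_pop must be positive")
    if (wv < 0).any():
        raise ValueError("weights must be nonnegative")
    if wv.size != sample.S:
        raise ValueError("weight vector length does not match sample size")
    combos = CombinationSet.from_scheme(scheme)
    cell_of = combos.index()
    mass = np.zeros(combos.L)
    labels = sample.cell_labels().to_numpy()
    for s, cell in enumerate(labels):
        mass[cell_of[tuple(cell)]] += wv[s]
    raw = mass * n_pop
    m = largest_remainder(mass, n_pop)
    table = pd.DataFrame(combos.combinations, columns=list(scheme.features))
    table["m"] = m
    table["raw_mass"] = raw
    return SyntheticPopulation(scheme=scheme, table=table, n_pop=int(n_pop))


def population_marginals(pop: SyntheticPopulation, raw: bool = False) -> dict[str, dict[str, float]]:
    """Per-feature category proportions of the (integerized or raw)
    population — for reporting residual distortion against the targets."""
    col = "raw_mass" if raw else "m"
    total = pop.table[col].sum()
    out: dict[str, dict[str, float]] = {}
    for f in pop.scheme.features:
        g = pop.table.groupby(f, observed=True)[col].sum()
        out[f] = {c: float(g.get(c, 0) / total) for c in pop.scheme.categories[f]}
    return out
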
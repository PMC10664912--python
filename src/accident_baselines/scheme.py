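"""Categorical feature scheme shared by the survey, the marginals and the register.

Every downstream object — indicator matrices, synthetic-population cells,
ratio tables — is indexed by the same ordered list of categorical
characteristics (age block, sex, autonomous community, activity block in the
default Spanish configuration). The scheme fixes the feature order, the
category order within each feature, and the flattened index ``k`` used by the
calibration constraints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


AGE_BLOCKS = ["<35", "35–49", "≥50"]
SEXES = ["F", "M"]
ACTIVITY_BLOCKS = [str(b) for b in range(10)]

#: 17 autonomous communities plus the merged autonomous cities.
COMMUNITIES = [
    "Andalucía",
    "Aragón",
    "Principado de Asturias",
    "Illes Balears",
    "Canarias",
    "Cantabria",
    "Castilla y León",
    "Castilla-La Mancha",
    "Cataluña",
    "Comunitat Valenciana",
    "Extremadura",
    "Galicia",
    "Comunidad de Madrid",
    "Región de Murcia",
    "Comunidad Foral de Navarra",
    "País Vasco",
    "La Rioja",
    "Ceuta y Melilla",
]


def normalize_label(label: str) -> str:
    """Canonicalize a category label: strip surrounding whitespace, collapse
    internal runs of whitespace. Case is preserved (community names are proper
    nouns); comparisons elsewhere case-fold."""
    return " ".join(str(label).split())


@dataclass(frozen=True)
class FeatureScheme:
    """Ordered categorical characteristics and their category sets.

    Parameters
    ----------
    features : ordered characteristic names (length ``I``).
    categories : for each feature, its ordered category labels (length ``J_i``).

    The flattened constraint index ``k`` runs over ``(feature, category)``
    pairs in feature order then category order; ``K = sum(J_i)``.
    """

    features: tuple[str, ...]
    categories: dict[str, tuple[str, ...]] = field(hash=False)

    def __post_init__(self) -> None:
        if set(self.features) != set(self.categories):
            raise ValueError("categories must be keyed exactly by the features")
        for f in self.features:
            cats = self.categories[f]
            if len(cats) < 2:
                raise ValueError(f"feature {f!r} needs at least 2 categories")
            if len(set(cats)) != len(cats):
                raise ValueError(f"duplicate category labels in feature {f!r}")

    @classmethod
    def make(cls, categories: dict[str, list[str]]) -> "FeatureScheme":
        return cls(
            features=tuple(categories),
            categories={f: tuple(normalize_label(c) for c in cats) for f, cats in categories.items()},
        )

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def K(self) -> int:
        """Total number of (feature, category) pairs."""
        return sum(len(self.categories[f]) for f in self.features)

    @property
    def n_cells(self) -> int:
        """Size of the full Cartesian product of categories."""
        out = 1
        for f in self.features:
            out *= len(self.categories[f])
        return out

    def category_index(self, feature: str, category: str) -> int:
        """Position of ``category`` within its feature's ordered list."""
        try:
            return self.categories[feature].index(normalize_label(category))
        except ValueError:
            raise KeyError(f"{category!r} is not a category of feature {feature!r}") from None

    def flat_index(self, feature: str, category: str) -> int:
        """Flattened constraint index k of a (feature, category) pair."""
        k = 0
        for f in self.features:
            if f == feature:
                return k + self.category_index(feature, category)
            k += len(self.categories[f])
        raise KeyError(f"unknown feature {feature!r}")

    def flat_pairs(self) -> list[tuple[str, str]]:
        """All (feature, category) pairs in flattened order."""
        return [(f, c) for f in self.features for c in self.categories[f]]

    def iter_cells(self) -> "itertools.product":
        """Enumerate the Cartesian product of categories, lexicographic by
        feature order then category order."""
        return itertools.product(*(self.categories[f] for f in self.features))

    def validate_row(self, values: dict[str, str]) -> None:
        for f in self.features:
            if normalize_label(values[f]) not in self.categories[f]:
                raise ValueError(f"{values[f]!r} is not a valid category of {f!r}")


def read_cell_table(path, scheme: FeatureScheme, **kwargs):
    """Read a delimited cell table keeping every feature column as strings
    (activity block labels are digits and must not decay to integers)."""
    import pandas as pd

    return pd.read_csv(path, dtype={f: str for f in scheme.features}, **kwargs)


def default_scheme(communities: list[str] | None = None) -> FeatureScheme:
    """The Spanish four-characteristic scheme: 3 age blocks x 2 sexes x
    autonomous communities x 10 activity blocks."""
    return FeatureScheme.make(
        {
            "age": list(AGE_BLOCKS),
            "sex": list(SEXES),
            "community": list(communities if communities is not None else COMMUNITIES),
            "activity": list(ACTIVITY_BLOCKS),
        }
    )
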
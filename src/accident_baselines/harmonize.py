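"""Map raw survey / register / marginal tables onto the common scheme.

The three Spanish sources (labour-force survey microdata, Social-Security
affiliation summaries, the occupational-accident register) code the same
characteristics differently: ages in years vs 5-year blocks, activity as CNAE
divisions vs 10 aggregate blocks, geography as provinces vs autonomous
communities. This module owns those mappings and the record filters (working
respondents only, non-blank province, no relapses, no commuting accidents).

All mapping helpers are idempotent: a value that is already a valid category
label passes through unchanged, so harmonizing a harmonized table is the
identity.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scheme import ACTIVITY_BLOCKS, AGE_BLOCKS, FeatureScheme, normalize_label


class DataError(Exception):
    """Base for record-level harmonization failures."""


class InvalidRecordError(DataError):
    pass


class UnmappedCodeError(DataError):
    pass


# ---------------------------------------------------------------------------
# value-level mappings

def age_to_block(age) -> str:
    """Age in years -> one of the three age blocks.

    Under-20s fold into the first block and over-64s into the third, so the
    blocks partition all working ages. Block labels pass through unchanged.
    """
    if isinstance(age, str) and normalize_label(age) in AGE_BLOCKS:
        return normalize_label(age)
    a = float(age)
    if not np.isfinite(a) or a < 0:
        raise InvalidRecordError(f"invalid age {age!r}")
    if a < 35:
        return AGE_BLOCKS[0]
    if a < 50:
        return AGE_BLOCKS[1]
    return AGE_BLOCKS[2]


def _build_cnae_table() -> dict[int, str]:
    blocks: dict[str, list[int]] = {
        "0": [1, 2, 3],
        "1": list(range(10, 19)),
        "2": list(range(5, 10)) + list(range(19, 26)) + [35] + list(range(36, 40)),
        "3": list(range(26, 34)),
        "4": list(range(41, 44)),
        "5": [45, 46, 47, 55, 56],
        "6": list(range(49, 54)) + list(range(58, 64)),
        "7": [64, 65, 66, 68] + list(range(69, 76)) + list(range(77, 83)),
        "8": [84, 85, 86, 87, 88],
        "9": list(range(90, 94)) + list(range(94, 97)) + [97, 99],
    }
    table: dict[int, str] = {}
    for block, divisions in blocks.items():
        for d in divisions:
            table[d] = block
    return table


_CNAE_TO_BLOCK = _build_cnae_table()


def cnae_to_activity_block(cnae_division) -> str:
    """CNAE-2009 division (2-digit) -> 10-block activity code '0'..'9'.

    Divisions absent from the block definition (e.g. 34, 40, 44, 48, 54, 57,
    67, 76, 83, 89, 98 — codes with no active content in the classification)
    raise :class:`UnmappedCodeError` rather than being bucketed silently.
    """
    if isinstance(cnae_division, str) and normalize_label(cnae_division) in ACTIVITY_BLOCKS and len(normalize_label(cnae_division)) == 1:
        return normalize_label(cnae_division)
    try:
        d = int(cnae_division)
    except (TypeError, ValueError):
        raise UnmappedCodeError(f"not a CNAE division: {cnae_division!r}") from None
    if not 1 <= d <= 99:
        raise UnmappedCodeError(f"not a CNAE division: {cnae_division!r}")
    try:
        return _CNAE_TO_BLOCK[d]
    except KeyError:
        raise UnmappedCodeError(f"CNAE division {d:02d} has no activity block") from None


def load_province_table(path=None) -> dict[str, str]:
    """Province code -> autonomous community lookup.

    Ships with the Spanish table (50 provinces + Ceuta/Melilla merged); pass
    ``path`` to substitute another administrative scheme.
    """
    if path is None:
        ref = importlib.resources.files("accident_baselines").joinpath("data/provinces_es.csv")
        with ref.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    return {normalize_label(c): normalize_label(m) for c, m in zip(df["code"], df["community"])}


def province_to_community(province_code, table: dict[str, str] | None = None) -> str:
    """Province code (e.g. '08') -> autonomous community label.

    Ceuta and Melilla map to the merged 'Ceuta y Melilla' label. Community
    labels pass through unchanged.
    """
    if table is None:
        table = load_province_table()
    code = normalize_label(province_code)
    communities = set(table.values())
    if code in communities:
        return code
    if code.isdigit():
        code = f"{int(code):02d}"
    try:
        return table[code]
    except KeyError:
        raise UnmappedCodeError(f"unknown province code {province_code!r}") from None


# ---------------------------------------------------------------------------
# containers

@dataclass
class FilterReport:
    """Per-rule accounting of dropped records; rows_in = retained + dropped."""

    rows_in: int
    retained: int
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.rows_in == self.retained + sum(self.dropped.values())

    def to_dict(self) -> dict:
        return {"rows_in": self.rows_in, "retained": self.retained, "dropped": dict(self.dropped)}


@dataclass
class SurveySample:
    """Harmonized survey microdata: one row per respondent, one column per
    scheme feature, every value a valid category label."""

    scheme: FeatureScheme
    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [f for f in self.scheme.features if f not in self.values.columns]
        if missing:
            raise ValueError(f"sample is missing feature columns {missing}")

    @property
    def S(self) -> int:
        return len(self.values)

    def cell_labels(self) -> pd.Series:
        """Tuple of category labels per instance (the cell it falls in)."""
        return pd.Series(
            list(zip(*(self.values[f] for f in self.scheme.features))),
            index=self.values.index,
        )


@dataclass
class AccidentRegister:
    """Retained, harmonized accident records (relapses and commuting
    accidents already removed)."""

    scheme: FeatureScheme
    records: pd.DataFrame

    @property
    def M(self) -> int:
        return len(self.records)

    def cell_counts(self) -> pd.Series:
        return self.records.groupby(list(self.scheme.features), observed=True).size()


@dataclass
class MarginalTargets:
    """Desired per-category population proportions p_k and the worker total.

    ``proportions`` maps feature -> {category: share}; within each feature the
    shares must sum to 1 (they are a distribution over that characteristic).
    """

    proportions: dict[str, dict[str, float]]
    n_pop: int

    def __post_init__(self) -> None:
        if not (self.n_pop > 0 and float(self.n_pop).is_integer()):
            raise ValueError("n_pop must be a positive integer")
        for f, cats in self.proportions.items():
            vals = np.asarray(list(cats.values()), float)
            if (vals < 0).any():
                raise ValueError(f"negative proportion in feature {f!r}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"proportions of feature {f!r} sum to {vals.sum()}, not 1")

    def as_vector(self, scheme: FeatureScheme) -> np.ndarray:
        """Flattened target vector p_k in the scheme's (feature, category) order."""
        p = np.empty(scheme.K)
        for k, (f, c) in enumerate(scheme.flat_pairs()):
            try:
                p[k] = self.proportions[f][c]
            except KeyError:
                raise KeyError(f"no target proportion for ({f!r}, {c!r})") from None
        return p

    def implied_scheme(self) -> FeatureScheme:
        """The Spanish default scheme restricted to the communities this
        marginal summary actually covers (regional subsets are common in
        simulation and partial analyses)."""
        from .scheme import default_scheme

        communities = list(self.proportions.get("community", {}))
        return default_scheme(communities=communities or None)

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalTargets":
        d = dict(d)
        n_pop = int(d.pop("N_pop"))
        props = {
            f: {normalize_label(c): float(v) for c, v in cats.items()}
            for f, cats in d.items()
        }
        return cls(proportions=props, n_pop=n_pop)


# ---------------------------------------------------------------------------
# record filters

_SURVEY_COLS = {"work_status": "work_status", "age": "age", "sex": "sex",
                "activity": "activity", "province": "province"}
_REGISTER_COLS = {"type": "type", "sex": "sex", "cnae": "cnae",
                  "province": "province", "place": "place", "age": "age"}

_SEX_CODES = {"m": "M", "f": "F", "male": "M", "female": "F", "1": "M", "2": "F", "6": "F"}


def _map_sex(value) -> str:
    v = normalize_label(value).lower()
    try:
        return _SEX_CODES[v]
    except KeyError:
        raise UnmappedCodeError(f"unknown sex code {value!r}") from None


def _is_blank(value) -> bool:
    return pd.isna(value) or normalize_label(value) == ""


def filter_survey(
    raw: pd.DataFrame,
    scheme: FeatureScheme,
    colmap: dict[str, str] | None = None,
    strict: bool = True,
    province_table: dict[str, str] | None = None,
) -> tuple[SurveySample, FilterReport]:
    """Apply the survey filters and harmonize the retained rows.

    Rules, in order: respondents not working in the reference week are
    released (``not_working``); a blank province means work outside the
    country and the row is released (``blank_province``); rows missing age,
    sex or activity are released and counted (``missing_value``). Remaining
    rows are mapped through the age/activity/province harmonizers; unmapped
    codes raise in strict mode, otherwise drop under ``unmapped_code``.
    """
    cols = {**_SURVEY_COLS, **(colmap or {})}
    for role, col in cols.items():
        if col not in raw.columns:
            raise InvalidRecordError(f"survey table lacks a {role!r} column ({col!r})")
    if province_table is None:
        province_table = load_province_table()

    dropped = {"not_working": 0, "blank_province": 0, "missing_value": 0, "unmapped_code": 0}
    out: list[dict[str, str]] = []
    for idx, row in raw.iterrows():
        ws = row[cols["work_status"]]
        if _is_blank(ws):
            raise InvalidRecordError(f"row {idx}: missing work status")
        if str(ws).strip() not in {"1", "working", "True", "true"}:
            dropped["not_working"] += 1
            continue
        if _is_blank(row[cols["province"]]):
            dropped["blank_province"] += 1
            continue
        if any(_is_blank(row[cols[r]]) for r in ("age", "sex", "activity")):
            dropped["missing_value"] += 1
            continue
        try:
            out.append(
                {
                    "age": age_to_block(row[cols["age"]]),
                    "sex": _map_sex(row[cols["sex"]]),
                    "community": province_to_community(row[cols["province"]], province_table),
                    "activity": cnae_to_activity_block(row[cols["activity"]]),
                }
            )
        except UnmappedCodeError:
            if strict:
                raise
            dropped["unmapped_code"] += 1

    values = pd.DataFrame(out, columns=["age", "sex", "community", "activity"])
    values = values[[f for f in scheme.features]]
    sample = SurveySample(scheme=scheme, values=values.reset_index(drop=True))
    for _, r in sample.values.iterrows():
        scheme.validate_row(dict(r))
    report = FilterReport(rows_in=len(raw), retained=sample.S,
                          dropped={k: v for k, v in dropped.items() if v})
    return sample, report


RELAPSE_CODE = "2"
IN_ITINERE_CODE = "3"


def filter_accidents(
    raw: pd.DataFrame,
    scheme: FeatureScheme,
    colmap: dict[str, str] | None = None,
    strict: bool = True,
    province_table: dict[str, str] | None = None,
) -> tuple[AccidentRegister, FilterReport]:
    """Apply the register filters and harmonize the retained accidents.

    Relapses (type-of-accident code 2) re-report a prior accident and are
    discarded; commuting ('in itinere', place-of-accident code 3) accidents
    are discarded per the official reporting convention. Remaining rows are
    harmonized: CNAE division -> activity block, province -> community, age in
    years -> age block.
    """
    cols = {**_REGISTER_COLS, **(colmap or {})}
    for role, col in cols.items():
        if col not in raw.columns:
            raise InvalidRecordError(f"register table lacks a {role!r} column ({col!r})")
    if province_table is None:
        province_table = load_province_table()

    dropped = {"relapse": 0, "in_itinere": 0, "missing_value": 0, "unmapped_code": 0}
    out: list[dict[str, str]] = []
    for idx, row in raw.iterrows():
        if normalize_label(row[cols["type"]]) == RELAPSE_CODE:
            dropped["relapse"] += 1
            continue
        if normalize_label(row[cols["place"]]) == IN_ITINERE_CODE:
            dropped["in_itinere"] += 1
            continue
        if any(_is_blank(row[cols[r]]) for r in ("age", "sex", "cnae", "province")):
            dropped["missing_value"] += 1
            continue
        try:
            out.append(
                {
                    "age": age_to_block(row[cols["age"]]),
                    "sex": _map_sex(row[cols["sex"]]),
                    "community": province_to_community(row[cols["province"]], province_table),
                    "activity": cnae_to_activity_block(row[cols["cnae"]]),
                }
            )
        except UnmappedCodeError:
            if strict:
                raise
            dropped["unmapped_code"] += 1

    records = pd.DataFrame(out, columns=["age", "sex", "community", "activity"])
    records = records[[f for f in scheme.features]]
    register = AccidentRegister(scheme=scheme, records=records.reset_index(drop=True))
    report = FilterReport(rows_in=len(raw), retained=register.M,
                          dropped={k: v for k, v in dropped.items() if v})
    return register, report
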
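"""Mapping condition codes to the eight adverse liver-condition categories.

Categories are not mutually exclusive: a participant coded with both SLD and
MASH counts in both. The any-adverse flag is the union of the eight flags,
and the ordinal outcome used by the proportional-odds model is the number of
distinct categories, capped as 0 / 1 / 2 / 3plus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

log = logging.getLogger(__name__)

CONDITION_CATEGORIES = (
    "SLD",
    "MASH",
    "ALD",
    "cirrhosis",
    "HCC",
    "chronic_HBV",
    "chronic_HCV",
    "hepatic_failure",
)

COUNT_LEVELS = ("0", "1", "2", "3plus")

__all__ = [
    "CONDITION_CATEGORIES",
    "COUNT_LEVELS",
    "ConditionMap",
    "OutcomeRecord",
    "map_conditions",
    "apply_outcomes",
    "synthetic_condition_map",
]


class ConditionMap:
    """Lookup from condition code to one of the eight liver categories.

    A code maps to at most one category; the category set is closed.
    """

    def __init__(self, mapping: dict[str, str]):
        bad = sorted(set(mapping.values()) - set(CONDITION_CATEGORIES))
        if bad:
            raise ValueError(f"unknown condition categories: {bad}")
        self._map = dict(mapping)

    def __len__(self) -> int:
        return len(self._map)

    def category(self, code: str) -> str | None:
        return self._map.get(code)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConditionMap":
        """Read a two-column ``code,category`` mapping table."""
        df = pd.read_csv(path, dtype=str)
        if not {"code", "category"} <= set(df.columns):
            raise ValueError("mapping CSV needs columns 'code' and 'category'")
        if df["code"].duplicated().any():
            dupes = df.loc[df["code"].duplicated(), "code"].tolist()
            raise ValueError(f"codes mapped more than once: {sorted(set(dupes))}")
        return cls(dict(zip(df["code"], df["category"])))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self._map.items()), columns=["code", "category"]
        ).to_csv(path, index=False)


def synthetic_condition_map() -> ConditionMap:
    """The synthetic test mapping shipped with the package.

    Placeholder codes (``SYN-<category>-<i>``) standing in for the real,
    access-restricted concept-code lists; the generator emits these codes.
    """
    ref = resources.files("sddscore") / "data" / "synthetic_condition_map.csv"
    df = pd.read_csv(ref.open(), dtype=str)
    return ConditionMap(dict(zip(df["code"], df["category"])))


@dataclass
class OutcomeRecord:
    flags: dict[str, bool]
    any_adverse: bool
    count_category: str

    def as_row(self) -> dict:
        row = {f"cond_{c}": self.flags[c] for c in CONDITION_CATEGORIES}
        row["any_adverse"] = self.any_adverse
        row["count_category"] = self.count_category
        return row


def _count_level(n: int) -> str:
    return "3plus" if n >= 3 else str(n)


def map_conditions(codes: Iterable[str], cmap: ConditionMap) -> OutcomeRecord:
    """Resolve one participant's condition codes into category flags.

    Duplicate codes are idempotent; unmapped codes (non-liver diagnoses in
    an EHR extract) are ignored.
    """
    cats = set()
    unmapped = 0
    for code in codes:
        cat = cmap.category(code)
        if cat is None:
            unmapped += 1
        else:
            cats.add(cat)
    if unmapped:
        log.debug("ignored %d unmapped condition codes", unmapped)
    flags = {c: c in cats for c in CONDITION_CATEGORIES}
    return OutcomeRecord(
        flags=flags, any_adverse=bool(cats), count_category=_count_level(len(cats))
    )


def apply_outcomes(
    cohort: pd.DataFrame,
    cmap: ConditionMap,
    codes_column: str = "condition_codes",
    sep: str = ";",
) -> pd.DataFrame:
    """Append the eight category flags, any-adverse and count category.

    ``codes_column`` holds each participant's condition codes as a
    ``sep``-joined string (empty or NaN for none).
    """
    if codes_column not in cohort.columns:
        raise KeyError(f"cohort lacks column {codes_column!r}")
    rows = []
    for raw in cohort[codes_column]:
        codes = [] if pd.isna(raw) or raw == "" else str(raw).split(sep)
        rows.append(map_conditions(codes, cmap).as_row())
    return pd.DataFrame(rows, index=cohort.index)
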
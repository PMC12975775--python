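"""Codebook: the scoring contract for SDOH survey items.

A codebook declares, for every survey item, which of the five HHS SDOH
domains it belongs to, how its raw responses are ordered or bounded, and
whether the underlying instrument scores advantage high (``reverse``).
Scoring (see :mod:`sddscore.scoring`) maps every item onto a common unit
scale where 0 is the most advantaged response and 1 the most disadvantaged.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

DOMAINS = (
    "economic_stability",
    "education",
    "healthcare_access_quality",
    "neighborhood_built_environment",
    "social_community_context",
)

Domain = Literal[
    "economic_stability",
    "education",
    "healthcare_access_quality",
    "neighborhood_built_environment",
    "social_community_context",
]


class ItemDefinition(BaseModel):
    """Scoring contract for a single survey item.

    Parameters
    ----------
    name : str
        Unique item identifier; must match the cohort CSV column name.
    domain : str
        One of the five SDOH domains.
    kind : {"ordered_categorical", "continuous"}
        Response type. Ordered-categorical items list their categories from
        most advantaged to most disadvantaged; continuous items declare the
        instrument's theoretical bounds.
    categories : list of str, optional
        Ordered category labels (ordered_categorical only, >= 2 entries).
    scale_min, scale_max : float, optional
        Instrument bounds (continuous only, ``scale_min < scale_max``).
    reverse : bool
        True when the raw instrument scores advantage high (e.g. neighborhood
        safety, social cohesion): the unit score is then flipped.
    missing_codes : list of str
        Raw response values treated as missing (e.g. ``"Unavailable"``).
    """

    name: str
    domain: Domain
    kind: Literal["ordered_categorical", "continuous"]
    categories: Optional[list[str]] = None
    scale_min: Optional[float] = None
    scale_max: Optional[float] = None
    reverse: bool = False
    missing_codes: list[str] = Field(default_factory=lambda: ["Unavailable"])

    @model_validator(mode="after")
    def _check_kind(self) -> "ItemDefinition":
        if self.kind == "ordered_categorical":
            if not self.categories or len(self.categories) < 2:
                raise ValueError(
                    f"item {self.name!r}: ordered_categorical needs >= 2 categories"
                )
            if self.scale_min is not None or self.scale_max is not None:
                raise ValueError(
                    f"item {self.name!r}: categorical items take no scale bounds"
                )
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"item {self.name!r}: duplicate categories")
        else:
            if self.categories is not None:
                raise ValueError(
                    f"item {self.name!r}: continuous items take no category list"
                )
            if self.scale_min is None or self.scale_max is None:
                raise ValueError(f"item {self.name!r}: continuous needs scale bounds")
            if not self.scale_min < self.scale_max:
                raise ValueError(
                    f"item {self.name!r}: scale_min must be < scale_max"
                )
        return self

    @property
    def n_categories(self) -> int:
        if self.kind != "ordered_categorical":
            raise AttributeError(f"item {self.name!r} is continuous")
        return len(self.categories)


class Codebook(BaseModel):
    """Ordered collection of :class:`ItemDefinition` covering all five domains."""

    items: list[ItemDefinition]
    version: str = "0"

    @field_validator("items")
    @classmethod
    def _unique_names(cls, v: list[ItemDefinition]) -> list[ItemDefinition]:
        names = [it.name for it in v]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate item names: {dupes}")
        return v

    @model_validator(mode="after")
    def _all_domains(self) -> "Codebook":
        present = {it.domain for it in self.items}
        missing = [d for d in DOMAINS if d not in present]
        if missing:
            raise ValueError(f"codebook missing domains: {missing}")
        return self

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    def __getitem__(self, name: str) -> ItemDefinition:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.items)

    def domain_items(self, domain: str) -> list[ItemDefinition]:
        return [it for it in self.items if it.domain == domain]

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "Codebook":
        """Load a codebook from a YAML or JSON document."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.model_dump(exclude_none=True)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))


def default_codebook() -> Codebook:
    """The 17-item default codebook shipped with the package.

    Reconstructs the published inventory: five economic-stability items
    (7-level income, employment, 3-level home ownership, food insecurity,
    housing quality problem), a 4-level education item, two healthcare
    items (insurance, discrimination in health care), four neighborhood
    items (physical/social disorder, walkability, safety) and five
    social/community items (cohesion, support, loneliness, perceived
    discrimination, perceived stress).
    """
    ref = resources.files("sddscore") / "data" / "default_codebook.yaml"
    return Codebook.model_validate(yaml.safe_load(ref.read_text()))
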
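"""Unit-scale scoring of SDOH items, domain scores, total SDDS, quintiles.

Every survey item is standardized to the unit interval where 0 is the most
advantaged response and 1 the most disadvantaged: ordered categories receive
equally spaced scores ``k/(K-1)``; bounded continuous instruments are
rescaled affinely to [0, 1] on their theoretical bounds (flipped when the
instrument scores advantage high). Domain scores are means of the domain's
observed item scores. The total SDDS is the mean of all item scores
(``item_mean`` mode, the default) or the mean of the five domain scores
(``domain_mean`` mode), computed under two missing-data policies:
``available`` averages whatever is observed, ``complete`` is missing as soon
as any item is missing.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .codebook import DOMAINS, Codebook, ItemDefinition, default_codebook

__all__ = [
    "UnknownResponseError",
    "OutOfRangeError",
    "InsufficientDataError",
    "standardize_categorical",
    "standardize_continuous",
    "standardize_column",
    "domain_score",
    "total_sdds",
    "quintile_assign",
    "score_cohort",
    "SDDSScorer",
]


class UnknownResponseError(ValueError):
    """A categorical response is neither a declared category nor a missing code."""


class OutOfRangeError(ValueError):
    """A continuous value falls outside the instrument's declared bounds."""


class InsufficientDataError(ValueError):
    """Too few non-missing scores for the requested cohort operation."""


def standardize_categorical(item: ItemDefinition, response) -> float:
    """Score one ordered-categorical response on the unit disadvantage scale.

    The category at ordered index ``k`` of ``K`` receives ``k/(K-1)``, so the
    most advantaged category scores 0 and the most disadvantaged scores 1.
    Declared missing codes (and NaN/None) map to ``nan``.
    """
    if item.kind != "ordered_categorical":
        raise ValueError(f"item {item.name!r} is not ordered_categorical")
    if response is None or (isinstance(response, float) and np.isnan(response)):
        return float("nan")
    if response in item.missing_codes:
        return float("nan")
    try:
        k = item.categories.index(response)
    except ValueError:
        raise UnknownResponseError(
            f"item {item.name!r}: unknown response {response!r}"
        ) from None
    return k / (len(item.categories) - 1)


def standardize_continuous(item: ItemDefinition, value) -> float:
    """Rescale one continuous response to [0, 1] on the instrument bounds.

    Reverse-coded instruments (advantage scored high) are flipped so that 1
    is always the most disadvantaged end. Values outside the declared bounds
    raise :class:`OutOfRangeError`; there is no silent clamping.
    """
    if item.kind != "continuous":
        raise ValueError(f"item {item.name!r} is not continuous")
    if value is None:
        return float("nan")
    if isinstance(value, str):
        if value in item.missing_codes:
            return float("nan")
        value = float(value)
    value = float(value)
    if np.isnan(value):
        return float("nan")
    if not (item.scale_min <= value <= item.scale_max):
        raise OutOfRangeError(
            f"item {item.name!r}: value {value} outside "
            f"[{item.scale_min}, {item.scale_max}]"
        )
    u = (value - item.scale_min) / (item.scale_max - item.scale_min)
    return 1.0 - u if item.reverse else u


def standardize_column(item: ItemDefinition, raw: pd.Series) -> pd.Series:
    """Vectorized unit scoring of one cohort column of raw responses."""
    if item.kind == "ordered_categorical":
        k = len(item.categories)
        mapping = {c: i / (k - 1) for i, c in enumerate(item.categories)}
        mapping.update({m: np.nan for m in item.missing_codes})
        as_str = raw.astype("object")
        scored = as_str.map(mapping)
        bad = scored.isna() & raw.notna() & ~as_str.isin(item.missing_codes)
        if bad.any():
            raise UnknownResponseError(
                f"item {item.name!r}: unknown response "
                f"{raw[bad].iloc[0]!r} (and {int(bad.sum()) - 1} more)"
            )
        return scored.astype(float)
    vals = raw.mask(raw.astype("object").isin(item.missing_codes))
    vals = pd.to_numeric(vals, errors="raise").astype(float)
    obs = vals.dropna()
    out_of_range = (obs < item.scale_min) | (obs > item.scale_max)
    if out_of_range.any():
        raise OutOfRangeError(
            f"item {item.name!r}: {int(out_of_range.sum())} values outside "
            f"[{item.scale_min}, {item.scale_max}] "
            f"(first: {obs[out_of_range].iloc[0]})"
        )
    u = (vals - item.scale_min) / (item.scale_max - item.scale_min)
    return 1.0 - u if item.reverse else u


def domain_score(scores: Sequence[float]) -> float:
    """Mean of the non-missing unit scores; ``nan`` iff all are missing."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("domain_score requires at least one item score")
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def total_sdds(
    item_scores: Sequence[float],
    policy: str = "available",
    codebook: Optional[Codebook] = None,
    mode: str = "item_mean",
) -> float:
    """Total SDDS for one participant under a missing-data policy.

    policy="available" averages observed scores (missing iff none observed);
    policy="complete" is missing as soon as any item score is missing.
    mode="domain_mean" averages the five domain means instead of the raw
    items and requires the codebook to group scores by domain.
    """
    if policy not in ("available", "complete"):
        raise ValueError(f"unknown policy {policy!r}")
    arr = np.asarray(list(item_scores), dtype=float)
    if codebook is not None and arr.size != len(codebook):
        raise ValueError(
            f"{arr.size} scores for a {len(codebook)}-item codebook"
        )
    if policy == "complete" and np.isnan(arr).any():
        return float("nan")
    if np.all(np.isnan(arr)):
        return float("nan")
    if mode == "item_mean":
        return float(np.nanmean(arr))
    if mode != "domain_mean":
        raise ValueError(f"unknown mode {mode!r}")
    if codebook is None:
        raise ValueError("mode='domain_mean' requires a codebook")
    by_name = dict(zip(codebook.item_names, arr))
    means = []
    for dom in DOMAINS:
        vals = [by_name[it.name] for it in codebook.domain_items(dom)]
        if not np.all(np.isnan(vals)):
            means.append(np.nanmean(vals))
    return float(np.mean(means))


def quintile_assign(scores) -> np.ndarray:
    """Partition a cohort's scores into five equal-count rank groups.

    Non-missing scores are ranked (stable tie-break by input order) and split
    into five contiguous groups; when the count is not divisible by 5 the
    remainder is given one-each to the most-advantaged (lowest-score) groups,
    so group sizes differ by at most 1. Returns a float array with labels
    1..5 and ``nan`` where the score is missing.
    """
    arr = np.asarray(scores, dtype=float)
    out = np.full(arr.shape, np.nan)
    obs_idx = np.flatnonzero(~np.isnan(arr))
    n = obs_idx.size
    if n < 5:
        raise InsufficientDataError(
            f"quintile assignment needs >= 5 non-missing scores, got {n}"
        )
    order = obs_idx[np.argsort(arr[obs_idx], kind="stable")]
    base, r = divmod(n, 5)
    sizes = [base + 1] * r + [base] * (5 - r)
    start = 0
    for q, size in enumerate(sizes, start=1):
        out[order[start : start + size]] = q
        start += size
    return out


def score_cohort(
    raw: pd.DataFrame,
    codebook: Optional[Codebook] = None,
    mode: str = "item_mean",
    assign_quintiles: bool = True,
) -> pd.DataFrame:
    """Score a cohort table of raw item responses.

    Returns a frame indexed like ``raw`` with one ``score_<item>`` column per
    codebook item, one ``domain_<domain>`` column per domain, the total SDDS
    under both missing policies (``sdds_available``, ``sdds_complete``),
    ``n_items_observed`` and, optionally, rank quintiles of
    ``sdds_available`` over this cohort.
    """
    codebook = codebook or default_codebook()
    missing_cols = [n for n in codebook.item_names if n not in raw.columns]
    if missing_cols:
        raise KeyError(f"cohort table lacks item columns: {missing_cols}")

    unit = pd.DataFrame(index=raw.index)
    for item in codebook.items:
        unit[item.name] = standardize_column(item, raw[item.name])

    out = unit.add_prefix("score_")
    for dom in DOMAINS:
        names = [it.name for it in codebook.domain_items(dom)]
        out[f"domain_{dom}"] = unit[names].mean(axis=1)

    if mode == "item_mean":
        available = unit.mean(axis=1)
    elif mode == "domain_mean":
        dom_cols = [f"domain_{d}" for d in DOMAINS]
        available = out[dom_cols].mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    any_missing = unit.isna().any(axis=1)
    out["sdds_available"] = available
    out["sdds_complete"] = available.mask(any_missing)
    out["n_items_observed"] = unit.notna().sum(axis=1)
    if assign_quintiles:
        out["quintile"] = quintile_assign(out["sdds_available"].to_numpy())
    return out


class SDDSScorer(TransformerMixin, BaseEstimator):
    """Transformer that scores raw SDOH survey responses into the SDDS.

    A thin estimator wrapper around :func:`score_cohort`: ``fit`` validates
    the codebook against the columns of ``X`` and ``transform`` returns the
    scored frame. Quintiles are rank-based within the transformed cohort.

    Parameters
    ----------
    codebook : Codebook, optional
        Defaults to the shipped 17-item codebook.
    mode : {"item_mean", "domain_mean"}
        Total-SDDS aggregation: mean of all item scores, or mean of the
        five domain scores.
    assign_quintiles : bool
        Whether ``transform`` appends a cohort-rank quintile column.
    """

    def __init__(
        self,
        codebook: Optional[Codebook] = None,
        mode: str = "item_mean",
        assign_quintiles: bool = True,
    ):
        self.codebook = codebook
        self.mode = mode
        self.assign_quintiles = assign_quintiles

    def fit(self, X: pd.DataFrame, y=None) -> "SDDSScorer":
        cb = self.codebook or default_codebook()
        missing = [n for n in cb.item_names if n not in X.columns]
        if missing:
            raise KeyError(f"cohort table lacks item columns: {missing}")
        if self.mode not in ("item_mean", "domain_mean"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.codebook_ = cb
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "codebook_"):
            self.fit(X)
        return score_cohort(
            X, self.codebook_, mode=self.mode, assign_quintiles=self.assign_quintiles
        )
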
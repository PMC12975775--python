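"""Synthetic EHR-style cohort generator.

Emulates the structure the analysis assumes in a large all-comers research
cohort: ~17 SDOH survey items spanning five domains whose responses are
correlated through a single latent standard-normal disadvantage factor;
demographic and lifestyle covariates whose distributions shift with
disadvantage (age inversely); item missingness that is MAR given the latent
factor (more disadvantage, more missingness); and eight non-mutually-
exclusive liver-condition indicators drawn from logistic models with
configurable true per-10% odds ratios on the participant's true disadvantage
score, co-occurring through a shared liability term. Per-condition intercepts
are calibrated at generation time so the union prevalence of the eight
categories hits a configurable target.

The generator's truth (latent factor, true score, planted odds ratios) is
exposed for parameter-recovery testing via ``true_*`` columns and
:func:`truth_report`.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .codebook import Codebook, ItemDefinition, default_codebook
from .outcomes import CONDITION_CATEGORIES

__all__ = [
    "ConfigError",
    "CovariateSpec",
    "ConditionModel",
    "GeneratorConfig",
    "generate_cohort",
    "truth_report",
]


class ConfigError(ValueError):
    """The generator configuration is internally infeasible."""


# plausibility defaults: single-factor loadings of each item's disadvantage
# propensity on the latent factor (economic items load hardest, access and
# walkability weakly)
DEFAULT_LOADINGS: dict[str, float] = {
    "annual_income": 0.75,
    "employed_for_wages": 0.20,
    "home_ownership": 0.65,
    "food_insecurity": 0.60,
    "housing_quality_problem": 0.55,
    "education_years": 0.55,
    "health_insurance": 0.30,
    "discrimination_in_health": 0.45,
    "neighborhood_physical_disorder": 0.55,
    "neighborhood_social_disorder": 0.60,
    "neighborhood_walkability": 0.30,
    "neighborhood_safety": 0.55,
    "social_cohesion": 0.50,
    "social_support": 0.50,
    "loneliness": 0.45,
    "perceived_discrimination": 0.50,
    "perceived_stress": 0.35,
}

# per-10% odds ratios planted by default for the eight conditions
DEFAULT_CONDITION_ORS: dict[str, float] = {
    "SLD": 1.25,
    "MASH": 1.27,
    "ALD": 1.15,
    "cirrhosis": 1.31,
    "HCC": 1.35,
    "chronic_HBV": 1.24,
    "chronic_HCV": 1.40,
    "hepatic_failure": 1.35,
}

# relative marginal prevalence of each condition (printed case counts over
# the cohort size); rescaled jointly so the eight-category union hits the
# target any-condition prevalence
DEFAULT_CONDITION_WEIGHTS: dict[str, float] = {
    "SLD": 4622 / 117783,
    "MASH": 718 / 117783,
    "ALD": 152 / 117783,
    "cirrhosis": 1024 / 117783,
    "HCC": 110 / 117783,
    "chronic_HBV": 424 / 117783,
    "chronic_HCV": 1011 / 117783,
    "hepatic_failure": 243 / 117783,
}

# synthetic code emitted for each flagged category (two aliases each, to
# exercise dedup in the mapping step)
CATEGORY_CODES: dict[str, tuple[str, str]] = {
    "SLD": ("SYN-SLD-1", "SYN-SLD-2"),
    "MASH": ("SYN-MASH-1", "SYN-MASH-2"),
    "ALD": ("SYN-ALD-1", "SYN-ALD-2"),
    "cirrhosis": ("SYN-CIRR-1", "SYN-CIRR-2"),
    "HCC": ("SYN-HCC-1", "SYN-HCC-2"),
    "chronic_HBV": ("SYN-HBV-1", "SYN-HBV-2"),
    "chronic_HCV": ("SYN-HCV-1", "SYN-HCV-2"),
    "hepatic_failure": ("SYN-HF-1", "SYN-HF-2"),
}


class CovariateSpec(BaseModel):
    """A categorical covariate drawn from a latent-shifted multinomial.

    Category probabilities are ``softmax(log(base_probs) + latent_shift * z)``
    so positive shifts make a category more likely for disadvantaged
    participants.
    """

    name: str
    categories: list[str]
    base_probs: list[float]
    latent_shifts: list[float]

    @model_validator(mode="after")
    def _check(self) -> "CovariateSpec":
        k = len(self.categories)
        if len(self.base_probs) != k or len(self.latent_shifts) != k:
            raise ValueError(f"covariate {self.name!r}: length mismatch")
        if any(p <= 0 for p in self.base_probs):
            raise ValueError(f"covariate {self.name!r}: base_probs must be > 0")
        return self


def default_covariates() -> list[CovariateSpec]:
    """Covariate models shaped after the study cohort's marginal tables:
    more female, Black/African-American, Hispanic, unmarried and smoking
    participants — and less frequent alcohol use — at higher disadvantage."""
    return [
        CovariateSpec(
            name="sex_at_birth",
            categories=["Male", "Female", "Other or unavailable"],
            base_probs=[0.36, 0.61, 0.03],
            latent_shifts=[0.0, 0.25, 0.0],
        ),
        CovariateSpec(
            name="race",
            categories=[
                "White",
                "Black or African American",
                "Asian",
                "Other or unavailable",
            ],
            base_probs=[0.76, 0.06, 0.027, 0.153],
            latent_shifts=[0.0, 0.9, -0.1, 0.35],
        ),
        CovariateSpec(
            name="ethnicity",
            categories=[
                "Not Hispanic or Latino",
                "Hispanic or Latino",
                "Other or unavailable",
            ],
            base_probs=[0.87, 0.086, 0.044],
            latent_shifts=[0.0, 0.6, 0.0],
        ),
        CovariateSpec(
            name="birthplace",
            categories=["USA", "Other", "Unavailable"],
            base_probs=[0.879, 0.097, 0.024],
            latent_shifts=[0.0, 0.15, 0.0],
        ),
        CovariateSpec(
            name="marital_status",
            categories=[
                "Married",
                "Living with partner",
                "Never married",
                "Divorced",
                "Separated",
                "Widowed",
                "Unavailable",
            ],
            base_probs=[0.547, 0.057, 0.164, 0.131, 0.016, 0.055, 0.03],
            latent_shifts=[-0.55, 0.15, 0.45, 0.3, 0.7, 0.1, 0.0],
        ),
        CovariateSpec(
            name="smoking",
            categories=["No", "Yes", "Unavailable"],
            base_probs=[0.619, 0.364, 0.017],
            latent_shifts=[0.0, 0.35, 0.1],
        ),
        CovariateSpec(
            name="alcohol",
            categories=[
                "Never",
                "Monthly or less",
                "2 to 4 per month",
                "2 to 3 per week",
                "4 or more per week",
                "Unavailable",
            ],
            base_probs=[0.151, 0.287, 0.201, 0.15, 0.152, 0.057],
            latent_shifts=[0.35, 0.2, 0.0, -0.25, -0.45, 0.3],
        ),
    ]


class ConditionModel(BaseModel):
    """Planted outcome model for one condition category."""

    or_per10: float = Field(gt=0)
    prevalence_weight: float = Field(gt=0, lt=1)


class GeneratorConfig(BaseModel):
    """Full parameterization of the synthetic cohort.

    The seed fully determines the output table. ``target_any_prevalence``
    rescales the per-condition prevalence weights jointly (preserving their
    ratios) so the empirical union prevalence of the eight categories matches
    the target in expectation; set it to ``None`` to use the weights as
    absolute marginal prevalences.
    """

    model_config = {"arbitrary_types_allowed": True}

    n: int = Field(gt=0)
    seed: int = 0
    codebook: Optional[Codebook] = None
    latent_loadings: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_LOADINGS)
    )
    covariates: list[CovariateSpec] = Field(default_factory=default_covariates)
    age_mean: float = 58.0
    age_sd: float = 15.0
    age_latent_slope: float = -2.5  # years per latent SD: disadvantage is younger
    age_bounds: tuple[float, float] = (18.0, 95.0)
    t2dm_base_prev: float = 0.107
    obesity_base_prev: float = 0.172
    comorbidity_latent_slope: float = 0.35
    missing_base_rate: float = 0.03
    missing_latent_slope: float = 0.7
    missing_rate_overrides: dict[str, float] = Field(default_factory=dict)
    conditions: dict[str, ConditionModel] = Field(
        default_factory=lambda: {
            c: ConditionModel(
                or_per10=DEFAULT_CONDITION_ORS[c],
                prevalence_weight=DEFAULT_CONDITION_WEIGHTS[c],
            )
            for c in CONDITION_CATEGORIES
        }
    )
    target_any_prevalence: Optional[float] = 0.0917
    liability_sd: float = 0.8
    unrelated_code_rate: float = 0.15  # rate of benign non-liver codes

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        cb = self.codebook or default_codebook()
        unknown = set(self.latent_loadings) - set(cb.item_names)
        if unknown:
            raise ConfigError(f"latent_loadings for unknown items: {sorted(unknown)}")
        for name, lam in self.latent_loadings.items():
            if not 0.0 <= lam <= 1.0:
                raise ConfigError(f"loading for {name!r} must be in [0, 1]")
        bad_cond = set(self.conditions) - set(CONDITION_CATEGORIES)
        if bad_cond:
            raise ConfigError(f"unknown condition categories: {sorted(bad_cond)}")
        if not self.conditions:
            raise ConfigError("at least one condition model is required")
        if not 0.0 <= self.missing_base_rate < 1.0:
            raise ConfigError("missing_base_rate must be in [0, 1)")
        if self.target_any_prevalence is not None and not (
            0.0 < self.target_any_prevalence < 1.0
        ):
            raise ConfigError("target_any_prevalence must be in (0, 1)")
        if self.liability_sd < 0:
            raise ConfigError("liability_sd must be >= 0")
        return self

    def resolved_codebook(self) -> Codebook:
        return self.codebook or default_codebook()

    def loading(self, item: str) -> float:
        return self.latent_loadings.get(item, 0.5)


def _draw_item(
    item: ItemDefinition, z: np.ndarray, rng: np.random.Generator, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw raw responses and their true unit scores for one item.

    The disadvantage propensity is standard normal: ``lam*z`` plus
    independent noise. Ordered categories are cut at equal-probability
    normal quantiles; continuous instruments take the propensity's normal
    CDF mapped affinely onto their range.
    """
    n = z.shape[0]
    noise = rng.standard_normal(n)
    prop = lam * z + math.sqrt(max(0.0, 1.0 - lam * lam)) * noise
    if item.kind == "ordered_categorical":
        k = len(item.categories)
        cuts = norm.ppf(np.arange(1, k) / k)
        idx = np.searchsorted(cuts, prop)
        raw = np.asarray(item.categories, dtype=object)[idx]
        unit = idx / (k - 1)
        return raw, unit
    unit = norm.cdf(prop)
    width = item.scale_max - item.scale_min
    raw = (
        item.scale_max - width * unit
        if item.reverse
        else item.scale_min + width * unit
    )
    return raw, unit


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + eta)) = target."""

    def f(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - target

    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise ConfigError(f"cannot calibrate intercept for prevalence {target}")
    return brentq(f, lo, hi, xtol=1e-10)


def _calibrated_probs(
    config: GeneratorConfig, eta: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Per-condition event probabilities, union-calibrated if requested."""
    weights = {c: m.prevalence_weight for c, m in config.conditions.items()}

    def probs_for(scale: float) -> dict[str, np.ndarray]:
        out = {}
        for c, w in weights.items():
            target = scale * w
            if not 0.0 < target < 1.0:
                raise ConfigError(
                    f"scaled prevalence {target:.4g} for {c!r} is infeasible"
                )
            b0 = _solve_intercept(eta[c], target)
            out[c] = expit(b0 + eta[c])
        return out

    if config.target_any_prevalence is None:
        return probs_for(1.0)

    def union_gap(scale: float) -> float:
        p = probs_for(scale)
        none = np.ones_like(next(iter(p.values())))
        for arr in p.values():
            none = none * (1.0 - arr)
        return float(np.mean(1.0 - none)) - config.target_any_prevalence

    max_scale = 0.999 / max(weights.values())
    lo = 1e-6
    if union_gap(max_scale) < 0:
        raise ConfigError(
            "target_any_prevalence unreachable with the given prevalence weights"
        )
    if union_gap(lo) > 0:
        raise ConfigError("target_any_prevalence below the feasible range")
    scale = brentq(union_gap, lo, max_scale, xtol=1e-8)
    return probs_for(scale)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one synthetic cohort table.

    One row per participant: raw item responses (with injected missing
    codes), covariates, comorbidity flags, a semicolon-joined
    ``condition_codes`` column consumable by the outcome mapper, and the
    simulation truth columns ``true_latent`` and ``true_sdds``.
    Regenerating with the same config (including seed) is bit-identical.
    """
    cb = config.resolved_codebook()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n

    z = rng.standard_normal(n)
    df = pd.DataFrame({"participant_id": [f"P{i:07d}" for i in range(n)]})

    # items: raw responses + true unit scores (pre-missingness)
    unit = np.empty((n, len(cb)), dtype=float)
    raw_cols: dict[str, np.ndarray] = {}
    for j, item in enumerate(cb.items):
        raw, u = _draw_item(item, z, rng, config.loading(item.name))
        raw_cols[item.name] = raw
        unit[:, j] = u
    true_sdds = unit.mean(axis=1)

    # missingness: MAR given the latent factor
    missing_mask = np.zeros((n, len(cb)), dtype=bool)
    for j, item in enumerate(cb.items):
        base = config.missing_rate_overrides.get(item.name, config.missing_base_rate)
        if base <= 0:
            continue
        p_miss = expit(logit(base) + config.missing_latent_slope * z)
        missing_mask[:, j] = rng.random(n) < p_miss

    for j, item in enumerate(cb.items):
        col = raw_cols[item.name]
        if item.kind == "ordered_categorical":
            col = col.copy()
            col[missing_mask[:, j]] = item.missing_codes[0]
            df[item.name] = col
        else:
            col = col.astype(float).copy()
            col[missing_mask[:, j]] = np.nan
            df[item.name] = col

    # covariates
    age = (
        config.age_mean
        + config.age_latent_slope * z
        + config.age_sd * rng.standard_normal(n)
    )
    df["age"] = np.clip(np.round(age, 1), *config.age_bounds)
    for spec in config.covariates:
        logits = np.log(np.asarray(spec.base_probs)) + np.outer(
            z, np.asarray(spec.latent_shifts)
        )
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        df[spec.name] = np.asarray(spec.categories, dtype=object)[idx]
    for flag, base in (
        ("t2dm", config.t2dm_base_prev),
        ("obesity", config.obesity_base_prev),
    ):
        p = expit(logit(base) + config.comorbidity_latent_slope * z)
        df[flag] = (rng.random(n) < p).astype(int)

    # outcomes: logistic per condition with shared liability for co-occurrence
    liability = config.liability_sd * rng.standard_normal(n)
    eta = {
        c: math.log(m.or_per10) * (true_sdds / 0.1) + liability
        for c, m in config.conditions.items()
    }
    probs = _calibrated_probs(config, eta)
    flags = {c: rng.random(n) < probs[c] for c in config.conditions}

    codes = []
    alias_pick = rng.integers(0, 2, size=(n, len(config.conditions)))
    unrelated = rng.random(n) < config.unrelated_code_rate
    cond_names = list(config.conditions)
    for i in range(n):
        row = [
            CATEGORY_CODES[c][alias_pick[i, k]]
            for k, c in enumerate(cond_names)
            if flags[c][i]
        ]
        if unrelated[i]:
            row.append("SYN-UNRELATED-1")
        codes.append(";".join(row))
    df["condition_codes"] = codes

    df["true_latent"] = z
    df["true_sdds"] = true_sdds
    return df


def truth_report(config: GeneratorConfig) -> dict:
    """Machine-readable record of the planted simulation parameters."""
    return {
        "n": config.n,
        "seed": config.seed,
        "conditions": {
            c: {
                "or_per10": m.or_per10,
                "prevalence_weight": m.prevalence_weight,
            }
            for c, m in config.conditions.items()
        },
        "target_any_prevalence": config.target_any_prevalence,
        "liability_sd": config.liability_sd,
        "latent_loadings": dict(config.latent_loadings),
        "missingness": {
            "base_rate": config.missing_base_rate,
            "latent_slope": config.missing_latent_slope,
            "overrides": dict(config.missing_rate_overrides),
        },
        "age": {
            "mean": config.age_mean,
            "sd": config.age_sd,
            "latent_slope": config.age_latent_slope,
        },
    }
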
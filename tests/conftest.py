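import numpy as np
import pandas as pd
import pytest

from sddscore import (
    GeneratorConfig,
    default_codebook,
    generate_cohort,
    score_cohort,
)
from sddscore.outcomes import apply_outcomes, synthetic_condition_map


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-config synthetic cohort, n=4000, reused across read-only tests."""
    return generate_cohort(GeneratorConfig(n=4000, seed=11))


@pytest.fixture(scope="session")
def scored_cohort(small_cohort, codebook):
    """Small cohort with unit scores, SDDS columns and outcome flags."""
    scored = score_cohort(small_cohort, codebook)
    flags = apply_outcomes(small_cohort, synthetic_condition_map())
    return pd.concat([small_cohort, scored, flags], axis=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def make_clean_config(n: int, seed: int, or_per10: float = 1.25,
                      prevalence: float = 0.15) -> GeneratorConfig:
    """Single-condition generator config for parameter-recovery checks:
    no missingness and no shared liability, so the fitted exposure equals
    the true score and the planted odds ratio is the estimand."""
    return GeneratorConfig(
        n=n,
        seed=seed,
        missing_base_rate=0.0,
        liability_sd=0.0,
        target_any_prevalence=None,
        conditions={
            "SLD": {"or_per10": or_per10, "prevalence_weight": prevalence}
        },
    )
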
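"""Association battery: logistic and proportional-odds models for the SDDS.

Three nested adjustment levels are used throughout: Model 1 is unadjusted;
Model 2 adjusts for age, sex at birth, race, ethnicity, birthplace, marital
status, smoking and alcohol intake; Model 3 further adjusts for type 2
diabetes and obesity. Exposures come in three forms: cohort quintiles of the
score (Q1, most advantaged, as reference), a continuous per-10% form
(odds ratio per 0.1 absolute increase of the [0,1] score, ``exp(0.1*beta)``),
and quintiles-plus-missing-indicator, where quintiles are cut among
complete-score participants and everyone with any missing item forms an
explicit sixth "Missing" category.

All confidence intervals are 95% Wald intervals on the log-odds scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .codebook import DOMAINS, Codebook, default_codebook
from .outcomes import CONDITION_CATEGORIES, COUNT_LEVELS
from .scoring import quintile_assign

log = logging.getLogger(__name__)

__all__ = [
    "FitFailureError",
    "ModelSpec",
    "MODEL2_COVARIATES",
    "MODEL3_COVARIATES",
    "DEFAULT_REFERENCES",
    "fit_logistic",
    "fit_ordinal",
    "run_battery",
    "descriptive_tables",
]


class FitFailureError(RuntimeError):
    """Model fit did not converge or the design is degenerate."""


MODEL2_COVARIATES: tuple[str, ...] = (
    "age",
    "sex_at_birth",
    "race",
    "ethnicity",
    "birthplace",
    "marital_status",
    "smoking",
    "alcohol",
)
MODEL3_COVARIATES: tuple[str, ...] = MODEL2_COVARIATES + ("t2dm", "obesity")

# reference level per categorical covariate: the most prevalent advantaged
# level, fixed for reproducibility
DEFAULT_REFERENCES: dict[str, str] = {
    "sex_at_birth": "Male",
    "race": "White",
    "ethnicity": "Not Hispanic or Latino",
    "birthplace": "USA",
    "marital_status": "Married",
    "smoking": "No",
    "alcohol": "Never",
}

_CONTINUOUS_COVARIATES = {"age", "t2dm", "obesity"}


@dataclass
class ModelSpec:
    """One cell of the association battery.

    level 1/2/3 picks the covariate set; ``extra_adjustment`` appends
    further columns (e.g. HBV/HCV flags for the HCC model);
    ``exposure_form`` is ``quintile``, ``per_10pct`` or
    ``quintile_with_missing``; ``stratum`` optionally restricts to
    ``age_lt65`` / ``age_ge65`` / ``female`` / ``male``.
    """

    level: int = 1
    exposure_form: str = "per_10pct"
    outcome: str = "any_adverse"
    extra_adjustment: list[str] = field(default_factory=list)
    stratum: Optional[str] = None

    def covariates(self) -> list[str]:
        if self.level == 1:
            base: tuple[str, ...] = ()
        elif self.level == 2:
            base = MODEL2_COVARIATES
        elif self.level == 3:
            base = MODEL3_COVARIATES
        else:
            raise ValueError(f"model level must be 1, 2 or 3, got {self.level}")
        return list(base) + list(self.extra_adjustment)


def _apply_stratum(data: pd.DataFrame, stratum: Optional[str]) -> pd.DataFrame:
    if stratum is None:
        return data
    if stratum == "age_lt65":
        return data[data["age"] < 65]
    if stratum == "age_ge65":
        return data[data["age"] >= 65]
    if stratum == "female":
        return data[data["sex_at_birth"] == "Female"]
    if stratum == "male":
        return data[data["sex_at_birth"] == "Male"]
    raise ValueError(f"unknown stratum {stratum!r}")


def _covariate_design(data: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Dummy-coded covariate block; 'Unavailable' levels are retained as
    explicit categories, rows with missing continuous covariates are the
    caller's to drop."""
    blocks = []
    for cov in covariates:
        if cov not in data.columns:
            raise KeyError(f"covariate {cov!r} not in data")
        if cov in _CONTINUOUS_COVARIATES or pd.api.types.is_numeric_dtype(data[cov]):
            blocks.append(data[[cov]].astype(float))
        else:
            col = data[cov].astype("object").fillna("Unavailable")
            ref = DEFAULT_REFERENCES.get(cov)
            levels = [l for l in pd.unique(col) if l != ref]
            levels.sort(key=str)
            dummies = pd.DataFrame(
                {f"{cov}[{l}]": (col == l).astype(float) for l in levels},
                index=data.index,
            )
            blocks.append(dummies)
    if not blocks:
        return pd.DataFrame(index=data.index)
    return pd.concat(blocks, axis=1)


def _exposure_design(
    data: pd.DataFrame,
    spec: ModelSpec,
    score_col: str,
    quintile_col: Optional[str],
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """Exposure block, ordered contrast labels, and the rows it defines."""
    if spec.exposure_form == "per_10pct":
        s = data[score_col]
        block = pd.DataFrame({"sdds_per10": s / 0.1})
        return block, ["per_10pct"], s.notna()
    if spec.exposure_form in ("quintile", "quintile_with_missing"):
        if quintile_col is not None and quintile_col in data.columns:
            q = data[quintile_col]
        else:
            q = pd.Series(quintile_assign(data[score_col].to_numpy()), index=data.index)
        labels = [f"Q{int(i)}" for i in (2, 3, 4, 5)]
        block = pd.DataFrame(
            {f"quintile[Q{k}]": (q == k).astype(float) for k in (2, 3, 4, 5)},
            index=data.index,
        )
        contrasts = ["Q1"] + labels
        if spec.exposure_form == "quintile_with_missing":
            miss = q.isna().astype(float)
            if miss.sum() == 0:
                # nobody is missing: the indicator would be a constant-zero
                # column, so the table collapses to the plain quintile form
                return block, contrasts, q.notna()
            block["quintile[Missing]"] = miss
            return block, contrasts + ["Missing"], pd.Series(True, index=data.index)
        return block, contrasts, q.notna()
    raise ValueError(f"unknown exposure_form {spec.exposure_form!r}")


def _check_binary(y: pd.Series) -> np.ndarray:
    vals = y.astype(float).to_numpy()
    uniq = np.unique(vals[~np.isnan(vals)])
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValueError(f"outcome is not binary: levels {uniq}")
    return vals


def _fit_ml_logit(y: np.ndarray, X: pd.DataFrame):
    events = int(np.sum(y))
    if events == 0 or events == len(y):
        raise FitFailureError(
            f"outcome is constant ({events} events in {len(y)} rows)"
        )
    model = sm.Logit(y, X)
    res = model.fit(disp=0, maxiter=200, method="newton", warn_convergence=False)
    if not res.mle_retvals.get("converged", False):
        res = model.fit(disp=0, maxiter=500, method="bfgs", warn_convergence=False)
    if not res.mle_retvals.get("converged", False):
        raise FitFailureError(
            "logistic fit did not converge (possible complete separation); "
            f"n={len(y)}, events={int(np.sum(y))}, params={list(X.columns)}"
        )
    if not np.all(np.isfinite(res.bse)):
        raise FitFailureError(
            "non-finite standard errors (complete or quasi-complete separation)"
        )
    return res


def _or_rows_from_fit(
    res,
    contrasts: list[str],
    spec: ModelSpec,
    counts: dict[str, tuple[int, int]],
) -> list[dict]:
    """Translate fitted coefficients into OR rows (reference row included).

    ``counts`` maps each contrast label to its (N, case N) — per exposure
    level for quintile forms, whole analysis sample for the per-10% form.
    """
    rows = []
    for contrast in contrasts:
        n, cases = counts[contrast]
        base = {
            "outcome": spec.outcome,
            "model": spec.level,
            "exposure": spec.exposure_form,
            "stratum": spec.stratum,
            "contrast": contrast,
            "n": n,
            "cases": cases,
        }
        if contrast == "Q1":
            rows.append(
                {**base, "or": 1.0, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
            )
            continue
        col = "sdds_per10" if contrast == "per_10pct" else f"quintile[{contrast}]"
        beta = res.params[col]
        se = res.bse[col]
        rows.append(
            {
                **base,
                "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                "p": float(res.pvalues[col]),
            }
        )
    return rows


def fit_logistic(
    data: pd.DataFrame,
    spec: ModelSpec,
    score_col: str = "sdds_available",
    quintile_col: Optional[str] = None,
) -> pd.DataFrame:
    """Fit one logistic model and return its OR table.

    The per-10% odds ratio is reported as ``exp(0.1*beta)`` for the score on
    its native [0,1] scale (the exposure enters the design pre-scaled by
    0.1, so the coefficient is already per 0.1 units). Quintile exposures
    use Q1 as the reference row with OR fixed at 1.
    """
    data = _apply_stratum(data, spec.stratum)
    y_all = data[spec.outcome]
    exp_block, contrasts, keep = _exposure_design(data, spec, score_col, quintile_col)
    cov_block = _covariate_design(data, spec.covariates())

    X = pd.concat([exp_block, cov_block], axis=1)
    mask = keep & y_all.notna() & X.notna().all(axis=1)
    dropped = int(len(data) - mask.sum())
    if dropped:
        log.debug("fit_logistic: dropped %d rows with missing data", dropped)
    X = X.loc[mask]
    y = _check_binary(y_all.loc[mask])
    ys = pd.Series(y, index=X.index)

    counts: dict[str, tuple[int, int]] = {}
    for contrast in contrasts:
        if contrast == "per_10pct":
            counts[contrast] = (int(mask.sum()), int(ys.sum()))
        elif contrast == "Missing":
            in_level = X["quintile[Missing]"] == 1.0
            counts[contrast] = (int(in_level.sum()), int(ys[in_level].sum()))
        elif contrast == "Q1":
            qcols = [f"quintile[Q{k}]" for k in (2, 3, 4, 5)]
            in_level = (X[qcols] == 0.0).all(axis=1)
            if "quintile[Missing]" in X.columns:
                in_level &= X["quintile[Missing]"] == 0.0
            counts[contrast] = (int(in_level.sum()), int(ys[in_level].sum()))
        else:
            in_level = X[f"quintile[{contrast}]"] == 1.0
            counts[contrast] = (int(in_level.sum()), int(ys[in_level].sum()))

    X = sm.add_constant(X, has_constant="add")
    res = _fit_ml_logit(y, X)
    return pd.DataFrame(_or_rows_from_fit(res, contrasts, spec, counts))


def fit_ordinal(
    data: pd.DataFrame,
    spec: ModelSpec,
    score_col: str = "sdds_available",
) -> pd.DataFrame:
    """Proportional-odds (cumulative logit) fit on the condition-count category.

    Reports the common per-10% odds ratio for more conditions with its
    Wald CI. With only two observed outcome levels this coincides with the
    binary logistic estimate.
    """
    data = _apply_stratum(data, spec.stratum)
    outcome = data[spec.outcome]
    observed_levels = [l for l in COUNT_LEVELS if (outcome == l).any()]
    if len(observed_levels) < 2:
        raise FitFailureError("ordinal outcome has fewer than 2 observed levels")
    y_all = pd.Categorical(outcome, categories=observed_levels, ordered=True)

    exp_block, _, keep = _exposure_design(data, spec, score_col, None)
    cov_block = _covariate_design(data, spec.covariates())
    X = pd.concat([exp_block, cov_block], axis=1)
    mask = (keep & outcome.notna() & X.notna().all(axis=1)).to_numpy()
    X = X.loc[mask]
    y = pd.Series(y_all[mask], index=X.index)

    # unit-variance rescaling of the design (age in years dominates the
    # curvature otherwise); the coefficient is transformed back below
    sds = X.std(ddof=0).replace(0.0, 1.0)
    model = OrderedModel(y, X / sds, distr="logit")
    res = model.fit(method="bfgs", maxiter=500, disp=0)
    if not res.mle_retvals.get("converged", False):
        raise FitFailureError("proportional-odds fit did not converge")
    beta = res.params["sdds_per10"] / sds["sdds_per10"]
    se = res.bse["sdds_per10"] / sds["sdds_per10"]
    return pd.DataFrame(
        [
            {
                "outcome": spec.outcome,
                "model": spec.level,
                "exposure": "per_10pct",
                "stratum": spec.stratum,
                "contrast": "per_10pct",
                "n": int(mask.sum()),
                "cases": int((y != "0").sum()),
                "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                "p": float(res.pvalues["sdds_per10"]),
            }
        ]
    )


def _safe(fit_fn, *args, **kwargs) -> pd.DataFrame:
    """Run one battery cell; on failure emit a marked placeholder row."""
    try:
        return fit_fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - battery must not abort
        spec = kwargs.get("spec") or args[1]
        log.warning("battery cell failed (%s): %s", spec, exc)
        return pd.DataFrame(
            [
                {
                    "outcome": spec.outcome,
                    "model": spec.level,
                    "exposure": spec.exposure_form,
                    "stratum": spec.stratum,
                    "contrast": "FIT_FAILED",
                    "n": np.nan,
                    "cases": np.nan,
                    "or": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                }
            ]
        )


def missing_indicator_quintiles(scores_complete: pd.Series) -> pd.Series:
    """Quintiles cut among complete-score participants; NaN marks 'Missing'."""
    return pd.Series(
        quintile_assign(scores_complete.to_numpy()), index=scores_complete.index
    )


def run_battery(
    data: pd.DataFrame,
    codebook: Optional[Codebook] = None,
    selection=None,
    levels: Sequence[int] = (1, 2, 3),
    stratify: bool = True,
    conditions: Sequence[str] = CONDITION_CATEGORIES,
) -> dict[str, pd.DataFrame]:
    """Run the full association battery on a scored cohort with outcomes.

    Expects the columns produced by scoring (``sdds_available``,
    ``sdds_complete``, ``quintile``, ``score_<item>``) and outcome mapping
    (``cond_<cat>``, ``any_adverse``, ``count_category``), plus covariates.

    Returns a dict of OR tables:

    - ``total`` — any-adverse vs SDDS quintiles and per-10%, for both
      missingness treatments (available-case score, and complete-case score
      with an explicit Missing category), at each model level;
    - ``conditions`` — per-10% ORs for each condition category, both
      treatments, each level;
    - ``selected_variables`` — per-10% ORs per selected item and quintile +
      per-10% ORs of the alternative score (when a selection is supplied);
    - ``ordinal`` — proportional-odds fit on the condition-count category;
    - ``stratified`` — any-adverse per-10% ORs within age and sex strata.

    Individual cell failures are marked (contrast ``FIT_FAILED``), not fatal.
    """
    codebook = codebook or default_codebook()
    data = data.copy()
    if "quintile" not in data.columns:
        data["quintile"] = quintile_assign(data["sdds_available"].to_numpy())
    data["quintile_complete"] = missing_indicator_quintiles(data["sdds_complete"])

    out: dict[str, pd.DataFrame] = {}

    # --- total adverse liver conditions ----------------------------------
    rows = []
    for level in levels:
        for form in ("quintile", "per_10pct"):
            rows.append(
                _safe(
                    fit_logistic,
                    data,
                    ModelSpec(level=level, exposure_form=form),
                    score_col="sdds_available",
                    quintile_col="quintile",
                )
            )
        for form in ("quintile_with_missing", "per_10pct"):
            t = _safe(
                fit_logistic,
                data,
                ModelSpec(level=level, exposure_form=form),
                score_col="sdds_complete",
                quintile_col="quintile_complete",
            )
            t = t.assign(treatment="missing_indicator")
            rows.append(t)
    out["total"] = pd.concat(rows, ignore_index=True)
    out["total"]["treatment"] = out["total"]["treatment"].fillna("available")

    # --- individual conditions -------------------------------------------
    rows = []
    for cond in conditions:
        col = f"cond_{cond}"
        if col not in data.columns:
            continue
        d = data.copy()
        d[col] = d[col].astype(int)
        for level in levels:
            extra = (
                ["cond_chronic_HBV", "cond_chronic_HCV"] if cond == "HCC" else []
            )
            for score_col, treatment in (
                ("sdds_available", "available"),
                ("sdds_complete", "missing_indicator"),
            ):
                spec = ModelSpec(level=level, exposure_form="per_10pct", outcome=col)
                t = _safe(fit_logistic, d, spec, score_col=score_col)
                rows.append(t.assign(treatment=treatment, condition=cond))
                if extra and treatment == "available":
                    spec_adj = ModelSpec(
                        level=level,
                        exposure_form="per_10pct",
                        outcome=col,
                        extra_adjustment=[c for c in extra if c != col],
                    )
                    d2 = d.copy()
                    for e in extra:
                        d2[e] = d2[e].astype(int)
                    t = _safe(fit_logistic, d2, spec_adj, score_col=score_col)
                    rows.append(
                        t.assign(treatment="available_hbv_hcv_adj", condition=cond)
                    )
    out["conditions"] = (
        pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    )

    # --- selected variables and alternative score ------------------------
    if selection is not None and selection.selected_items:
        rows = []
        for item in selection.selected_items:
            col = f"score_{item}"
            for level in levels:
                spec = ModelSpec(level=level, exposure_form="per_10pct")
                t = _safe(fit_logistic, data, spec, score_col=col)
                rows.append(t.assign(variable=item))
        alt = data[[f"score_{i}" for i in selection.selected_items]].mean(axis=1)
        d = data.assign(sdds_alternative=alt)
        for level in levels:
            for form in ("quintile", "per_10pct"):
                spec = ModelSpec(level=level, exposure_form=form)
                t = _safe(fit_logistic, d, spec, score_col="sdds_alternative")
                rows.append(t.assign(variable="sdds_alternative"))
        out["selected_variables"] = pd.concat(rows, ignore_index=True)

    # --- ordinal condition count ------------------------------------------
    rows = []
    for level in levels:
        for score_col, treatment in (
            ("sdds_available", "available"),
            ("sdds_complete", "missing_indicator"),
        ):
            spec = ModelSpec(
                level=level, exposure_form="per_10pct", outcome="count_category"
            )
            t = _safe(fit_ordinal, data, spec, score_col=score_col)
            rows.append(t.assign(treatment=treatment))
    out["ordinal"] = pd.concat(rows, ignore_index=True)

    # --- stratified --------------------------------------------------------
    if stratify:
        rows = []
        for stratum in ("age_lt65", "age_ge65", "female", "male"):
            for level in levels:
                spec = ModelSpec(
                    level=level, exposure_form="per_10pct", stratum=stratum
                )
                rows.append(
                    _safe(fit_logistic, data, spec, score_col="sdds_available")
                )
        out["stratified"] = pd.concat(rows, ignore_index=True)

    return out


def descriptive_tables(
    data: pd.DataFrame, codebook: Optional[Codebook] = None
) -> dict[str, pd.DataFrame]:
    """Cohort characteristics by quintile and domain means by outcome status.

    Returns ``characteristics`` (means/SDs of continuous columns and counts/
    percents of categorical covariates per score quintile) and
    ``domain_comparison`` (per-domain mean scores among participants with vs
    without any adverse condition, with Welch two-sample t-tests).
    """
    codebook = codebook or default_codebook()
    if "quintile" not in data.columns:
        data = data.assign(quintile=quintile_assign(data["sdds_available"].to_numpy()))

    rows = []
    groups = {f"Q{int(q)}": g for q, g in data.groupby("quintile") if not np.isnan(q)}
    order = sorted(groups)
    rows.append({"characteristic": "N", **{q: len(groups[q]) for q in order}})
    cont_cols = [
        c for c in ("sdds_available", "age") if c in data.columns
    ] + [f"domain_{d}" for d in DOMAINS if f"domain_{d}" in data.columns]
    for col in cont_cols:
        cells = {}
        for q in order:
            vals = groups[q][col].dropna()
            sd = vals.std(ddof=1) if len(vals) > 1 else np.nan
            cells[q] = f"{vals.mean():.2f} ({sd:.2f})" if len(vals) else ""
        rows.append({"characteristic": f"{col} (mean (SD))", **cells})
    cat_cols = [c for c in DEFAULT_REFERENCES if c in data.columns] + [
        c for c in ("t2dm", "obesity") if c in data.columns
    ]

    def _as_levels(s: pd.Series) -> pd.Series:
        s = s.astype("object")
        return s.mask(s.isna(), "Unavailable")

    for col in cat_cols:
        levels = pd.unique(_as_levels(data[col]))
        for lev in sorted(levels, key=str):
            cells = {}
            for q in order:
                g = _as_levels(groups[q][col])
                n = int((g == lev).sum())
                cells[q] = f"{n} ({100 * n / len(g):.1f})"
            rows.append({"characteristic": f"{col} = {lev} (N (%))", **cells})
    characteristics = pd.DataFrame(rows)

    comp_rows = []
    has = data["any_adverse"].astype(bool)
    for d in DOMAINS:
        col = f"domain_{d}"
        if col not in data.columns:
            continue
        a = data.loc[has, col].dropna()
        b = data.loc[~has, col].dropna()
        if len(a) > 1 and len(b) > 1 and (a.var() + b.var()) > 0:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        elif len(a) > 0 and len(b) > 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.nan, np.nan
        comp_rows.append(
            {
                "domain": d,
                "mean_with_condition": a.mean() if len(a) else np.nan,
                "sd_with_condition": a.std(ddof=1) if len(a) > 1 else np.nan,
                "mean_without_condition": b.mean() if len(b) else np.nan,
                "sd_without_condition": b.std(ddof=1) if len(b) > 1 else np.nan,
                "t_statistic": float(t),
                "p_value": float(p),
            }
        )
    return {
        "characteristics": characteristics,
        "domain_comparison": pd.DataFrame(comp_rows),
    }
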
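"""Factor-analysis variable reduction and the alternative SDDS.

The reduction step mirrors the construction of composite deprivation indices:
exploratory factor analysis on the unit-scored items (principal-axis
factoring, varimax rotation, Kaiser criterion for the factor count), item
selection by absolute loading > 0.4 on any retained factor, an internal
consistency gate per factor group (Cronbach's alpha > 0.7), and an
alternative disadvantage score defined as the mean of the surviving items.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

__all__ = [
    "DegenerateItemError",
    "UndefinedAlphaError",
    "CannotScoreError",
    "FactorSelection",
    "fit_factor_model",
    "cronbach_alpha",
    "select_variables",
    "alternative_sdds",
    "FactorReducer",
]


class DegenerateItemError(ValueError):
    """An item is constant (zero variance) and cannot enter the factor model."""


class UndefinedAlphaError(ValueError):
    """Cronbach's alpha is undefined (zero total variance)."""


class CannotScoreError(ValueError):
    """Alternative SDDS requested from an empty item selection."""


@dataclass
class FactorSelection:
    """Result of the loading/alpha variable-selection step.

    Attributes
    ----------
    loadings : DataFrame, items x factors.
    n_factors : number of retained factors.
    per_factor_alpha : Cronbach's alpha of each factor's above-threshold
        item group (nan where the group has fewer than two items).
    selected_items : items whose dominant factor group passed the alpha gate.
    alternative_score_name : column name used for the derived score.
    """

    loadings: pd.DataFrame
    n_factors: int
    per_factor_alpha: dict[str, float]
    selected_items: list[str]
    alternative_score_name: str = "sdds_alternative"
    dominant_factor: dict[str, str] = field(default_factory=dict)

    def report(self) -> pd.DataFrame:
        """Item-level selection report (item, dominant factor, loading, selected)."""
        rows = []
        for item in self.loadings.index:
            fac = self.dominant_factor.get(item)
            rows.append(
                {
                    "item": item,
                    "dominant_factor": fac,
                    "loading": (
                        float(self.loadings.loc[item].abs().max())
                        if fac is None
                        else float(self.loadings.loc[item, fac])
                    ),
                    "alpha": self.per_factor_alpha.get(fac, float("nan")),
                    "selected": item in self.selected_items,
                }
            )
        return pd.DataFrame(rows)


def _complete_rows(item_matrix: pd.DataFrame) -> pd.DataFrame:
    complete = item_matrix.dropna()
    dropped = len(item_matrix) - len(complete)
    if dropped:
        log.info("factor analysis: dropped %d incomplete rows", dropped)
    return complete


def _varimax_criterion(lr: np.ndarray) -> float:
    sq = lr**2
    return float((sq**2).mean(axis=0).sum() - (sq.mean(axis=0) ** 2).sum())


def _varimax(loadings: np.ndarray, tol: float = 1e-12, max_iter: int = 100) -> np.ndarray:
    """Orthogonal varimax rotation by pairwise Kaiser sweeps.

    Each sweep rotates every factor pair by its analytically optimal angle;
    sweeps repeat until the varimax criterion stops improving.
    """
    lr = loadings.copy()
    n, k = lr.shape
    if k < 2:
        return lr
    crit = _varimax_criterion(lr)
    for _ in range(max_iter):
        for p in range(k - 1):
            for q in range(p + 1, k):
                a, b = lr[:, p], lr[:, q]
                u = a**2 - b**2
                v = 2.0 * a * b
                num = 2.0 * (u * v).sum() - 2.0 * u.sum() * v.sum() / n
                den = (u**2 - v**2).sum() - (u.sum() ** 2 - v.sum() ** 2) / n
                phi = 0.25 * math.atan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = math.cos(phi), math.sin(phi)
                lr[:, p], lr[:, q] = c * a + s * b, -s * a + c * b
        new_crit = _varimax_criterion(lr)
        if new_crit - crit < tol * max(1.0, abs(crit)):
            break
        crit = new_crit
    return lr


def fit_factor_model(
    item_matrix: pd.DataFrame,
    n_factors: int | str = "auto",
    rotation: str = "varimax",
    max_iter: int = 200,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Principal-axis factoring of the item correlation matrix.

    Rows with any missing item are dropped (complete-case). Communalities
    start at the squared multiple correlations and are iterated to
    convergence on the reduced correlation matrix. With
    ``n_factors="auto"`` the Kaiser criterion (eigenvalue of the
    correlation matrix > 1) sets the factor count. Loadings are varimax-
    rotated by default; the result is deterministic given the data.

    Returns a DataFrame of loadings, items x factors (``F1``, ``F2``, ...).
    """
    x = _complete_rows(item_matrix).astype(float)
    if x.shape[1] < 2:
        raise ValueError("factor analysis needs at least 2 items")
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more complete rows than items")
    stds = x.std(axis=0, ddof=1)
    constant = stds[stds == 0].index.tolist()
    if constant:
        raise DegenerateItemError(f"constant item(s): {constant}")

    corr = np.corrcoef(x.to_numpy(), rowvar=False)
    p = corr.shape[0]
    eigvals = np.linalg.eigvalsh(corr)[::-1]
    if n_factors == "auto":
        m = max(1, int(np.sum(eigvals > 1.0)))
    else:
        m = int(n_factors)
        if not 1 <= m <= p:
            raise ValueError(f"n_factors must be in [1, {p}]")

    # initial communalities: squared multiple correlations, with a ridge
    # fallback when the correlation matrix is (near-)singular
    try:
        inv_diag = np.diag(np.linalg.inv(corr))
        h2 = 1.0 - 1.0 / inv_diag
    except np.linalg.LinAlgError:
        h2 = np.max(np.abs(corr - np.eye(p)), axis=0)
    h2 = np.clip(h2, 0.0, 1.0 - 1e-9)

    loadings = None
    for _ in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h2)
        vals, vecs = np.linalg.eigh(reduced)
        idx = np.argsort(vals)[::-1][:m]
        lam = np.clip(vals[idx], 0.0, None)
        loadings = vecs[:, idx] * np.sqrt(lam)
        h2_new = np.clip((loadings**2).sum(axis=1), 0.0, 1.0 - 1e-9)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new

    if rotation == "varimax" and m > 1:
        loadings = _varimax(loadings)
    elif rotation not in ("varimax", "none", None):
        raise ValueError(f"unknown rotation {rotation!r}")

    # canonical orientation: factors ordered by explained variance, each
    # signed so its largest-magnitude loading is positive
    order = np.argsort(-(loadings**2).sum(axis=0), kind="stable")
    loadings = loadings[:, order]
    for j in range(m):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col

    return pd.DataFrame(
        loadings, index=item_matrix.columns, columns=[f"F{j + 1}" for j in range(m)]
    )


def cronbach_alpha(item_matrix: pd.DataFrame) -> float:
    """Cronbach's alpha: ``(k/(k-1)) * (1 - sum(item var) / var(row sums))``.

    Complete-case rows; sample variances (ddof=1). Raises
    :class:`UndefinedAlphaError` when the row-sum variance is zero.
    """
    x = _complete_rows(pd.DataFrame(item_matrix)).astype(float)
    k = x.shape[1]
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    if x.shape[0] < 3:
        raise ValueError("Cronbach's alpha needs at least 3 complete rows")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedAlphaError("zero variance of the item sum")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def select_variables(
    loadings: pd.DataFrame,
    item_matrix: pd.DataFrame,
    loading_threshold: float = 0.4,
    alpha_threshold: float = 0.7,
) -> FactorSelection:
    """Select items by loading magnitude and per-factor internal consistency.

    Items whose maximum absolute loading exceeds ``loading_threshold`` are
    grouped by their dominant factor; each group is kept only if its
    Cronbach's alpha exceeds ``alpha_threshold`` (single-item groups have no
    alpha and are dropped). The selection is the union of surviving groups;
    an empty selection is a valid result.
    """
    abs_load = loadings.abs()
    dominant = abs_load.idxmax(axis=1)
    passing = abs_load.max(axis=1) > loading_threshold

    groups: dict[str, list[str]] = {}
    for item in loadings.index[passing]:
        groups.setdefault(dominant[item], []).append(item)

    per_factor_alpha: dict[str, float] = {}
    selected: list[str] = []
    for factor in loadings.columns:
        members = groups.get(factor, [])
        if len(members) < 2:
            if members:
                per_factor_alpha[factor] = float("nan")
            continue
        alpha = cronbach_alpha(item_matrix[members])
        per_factor_alpha[factor] = alpha
        if alpha > alpha_threshold:
            selected.extend(members)

    # keep codebook order
    selected = [i for i in loadings.index if i in set(selected)]
    return FactorSelection(
        loadings=loadings,
        n_factors=loadings.shape[1],
        per_factor_alpha=per_factor_alpha,
        selected_items=selected,
        dominant_factor={i: dominant[i] for i in loadings.index[passing]},
    )


def alternative_sdds(unit_scores: pd.DataFrame, selection: FactorSelection) -> pd.Series:
    """Mean of the selected items' unit scores (available-case semantics)."""
    if not selection.selected_items:
        raise CannotScoreError("empty selection cannot be scored")
    return unit_scores[selection.selected_items].mean(axis=1).rename(
        selection.alternative_score_name
    )


class FactorReducer(TransformerMixin, BaseEstimator):
    """Estimator wrapping factor extraction, item selection and rescoring.

    ``fit`` expects a participants x items frame of unit scores (columns are
    item names, values in [0, 1] or NaN), extracts factors by principal-axis
    factoring with varimax rotation, and applies the loading/alpha selection
    rule. ``transform`` returns the alternative SDDS (mean of selected
    items) as a one-column frame.

    Attributes (after fit)
    ----------------------
    loadings_ : DataFrame, items x retained factors.
    n_factors_ : int.
    alphas_ : dict factor -> Cronbach's alpha of its item group.
    selected_items_ : list of selected item names.
    selection_ : full :class:`FactorSelection`.
    n_dropped_rows_ : incomplete rows excluded from the factor fit.
    """

    def __init__(
        self,
        n_factors: int | str = "auto",
        loading_threshold: float = 0.4,
        alpha_threshold: float = 0.7,
        rotation: str = "varimax",
    ):
        self.n_factors = n_factors
        self.loading_threshold = loading_threshold
        self.alpha_threshold = alpha_threshold
        self.rotation = rotation

    def fit(self, X: pd.DataFrame, y=None) -> "FactorReducer":
        X = pd.DataFrame(X)
        self.loadings_ = fit_factor_model(
            X, n_factors=self.n_factors, rotation=self.rotation
        )
        self.selection_ = select_variables(
            self.loadings_,
            X,
            loading_threshold=self.loading_threshold,
            alpha_threshold=self.alpha_threshold,
        )
        self.n_factors_ = self.loadings_.shape[1]
        self.alphas_ = self.selection_.per_factor_alpha
        self.selected_items_ = self.selection_.selected_items
        self.n_dropped_rows_ = int(len(X) - len(X.dropna()))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "selection_"):
            raise RuntimeError("FactorReducer is not fitted")
        return alternative_sdds(pd.DataFrame(X), self.selection_).to_frame()
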
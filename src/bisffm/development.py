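"""Prediction-equation development: stratified split, OLS fits, stepwise AIC.

Reproduces the development pipeline for the empirical FFM equations: the
cohort is split into derivation (~70%) and validation (~30%) sets by a
seeded random number generator stratified by sex, candidate models are fit
by ordinary least squares, and bidirectional stepwise selection (AIC) walks
the candidate covariates.  RMSE is the residual standard error
sqrt(SSE / (n - p - 1)); standardized coefficients are b_j * SD(x_j)/SD(y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionModel",
    "RankDeficiencyError",
    "split_cohort",
    "fit_linear_model",
    "stepwise_select",
    "develop_weight_adjustment",
    "vif_report",
]


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the offending terms."""


@dataclass
class RegressionModel:
    term_names: list[str]
    coefficients: np.ndarray
    intercept: float
    adjusted_r2: float
    rmse_kg: float
    standardized_coefficients: np.ndarray
    n_fit: int
    aic: float
    pvalues: np.ndarray

    def __post_init__(self):
        if self.adjusted_r2 > 1 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed 1")
        if self.rmse_kg < 0:
            raise ValueError("rmse must be non-negative")
        if len(self.term_names) != len(self.coefficients):
            raise ValueError("one coefficient per term required")

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        x = data[self.term_names].to_numpy(dtype=float)
        return self.intercept + x @ self.coefficients


def split_cohort(
    cohort: pd.DataFrame,
    derivation_fraction: float = 0.7,
    seed: int = 0,
    sex_column: str = "sex",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded derivation/validation partition stratified by sex.

    Within each sex stratum, round-half-up(fraction * stratum size) children
    go to the derivation set.  Deterministic given ``seed``; the two frames
    partition the input.
    """
    if not 0 < derivation_fraction <= 1:
        raise ValueError("derivation_fraction must be in (0, 1]")
    sexes = cohort[sex_column].to_numpy()
    for sex in (0, 1):
        if int(np.sum(sexes == sex)) == 0:
            raise ValueError(f"sex stratum {sex} is empty; cannot stratify")
    rng = np.random.default_rng(seed)
    deriv_idx: list[np.ndarray] = []
    for sex in (0, 1):
        stratum = cohort.index[sexes == sex].to_numpy()
        n_take = int(np.floor(derivation_fraction * stratum.size + 0.5))
        perm = rng.permutation(stratum.size)
        deriv_idx.append(stratum[perm[:n_take]])
    chosen = np.concatenate(deriv_idx)
    derivation = cohort.loc[np.sort(chosen)]
    validation = cohort.drop(index=chosen)
    if validation.empty:
        warnings.warn("validation set is empty (derivation_fraction too high)", stacklevel=2)
    return derivation, validation


def _design(data: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    return data[list(terms)].to_numpy(dtype=float)


def fit_linear_model(
    data: pd.DataFrame, response: str, terms: Sequence[str]
) -> RegressionModel:
    """OLS fit of ``response`` on ``terms`` with an intercept."""
    terms = list(terms)
    y = data[response].to_numpy(dtype=float)
    x = _design(data, terms)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    sds = x.std(axis=0, ddof=1)
    zero_var = [t for t, s in zip(terms, sds) if s == 0]
    if zero_var:
        raise RankDeficiencyError(f"zero-variance terms: {zero_var}")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the smallest-singular-vector loadings as the collinear set
        _, _, vt = np.linalg.svd(design)
        loads = np.abs(vt[-1][1:])
        guilty = [t for t, w in zip(terms, loads) if w > 0.1 * loads.max()]
        raise RankDeficiencyError(f"collinear terms: {guilty}")
    fit = sm.OLS(y, design).fit()
    resid = y - fit.fittedvalues
    rmse = float(np.sqrt(np.sum(resid**2) / (n - p - 1)))
    coef = fit.params[1:]
    std_coef = coef * sds / y.std(ddof=1)
    return RegressionModel(
        term_names=terms,
        coefficients=np.asarray(coef, dtype=float),
        intercept=float(fit.params[0]),
        adjusted_r2=float(fit.rsquared_adj),
        rmse_kg=rmse,
        standardized_coefficients=np.asarray(std_coef, dtype=float),
        n_fit=n,
        aic=float(fit.aic),
        pvalues=np.asarray(fit.pvalues[1:], dtype=float),
    )


def stepwise_select(
    data: pd.DataFrame,
    response: str,
    candidate_terms: Sequence[str],
    base_terms: Sequence[str] = (),
) -> RegressionModel:
    """Bidirectional stepwise selection minimising AIC.

    Starting from ``base_terms``, each step considers adding any unused
    candidate and dropping any included non-base term, applies the move with
    the lowest AIC, and stops when no move improves on the current model.
    Deterministic given the data (ties resolved by candidate order).
    """
    base = list(base_terms)
    candidates = [t for t in candidate_terms if t not in base]
    current = list(base)

    def aic_of(terms):
        if not terms:
            y = data[response].to_numpy(dtype=float)
            fit = sm.OLS(y, np.ones((y.size, 1))).fit()
            return float(fit.aic), None
        model = fit_linear_model(data, response, terms)
        return model.aic, model

    current_aic, current_model = aic_of(current)
    while True:
        moves: list[tuple[float, list[str]]] = []
        for t in candidates:
            if t not in current:
                moves.append((aic_of(current + [t])[0], current + [t]))
        for t in current:
            if t not in base:
                trimmed = [u for u in current if u != t]
                moves.append((aic_of(trimmed)[0], trimmed))
        if not moves:
            break
        best_aic, best_terms = min(moves, key=lambda m: m[0])
        if best_aic < current_aic - 1e-9:
            current, current_aic = best_terms, best_aic
        else:
            break
    if current_model is None or current != current_model.term_names:
        current_aic, current_model = aic_of(current)
    if current_model is None:
        raise ValueError("stepwise selection retained no terms and no base model")
    return current_model


def develop_weight_adjustment(
    weight_scale: Sequence[float], weight_dxa: Sequence[float]
) -> tuple[float, float]:
    """(intercept, slope) of the simple OLS of DXA weight on scale weight."""
    ws = np.asarray(weight_scale, dtype=float)
    wd = np.asarray(weight_dxa, dtype=float)
    if ws.size != wd.size or ws.size < 3:
        raise ValueError("need at least 3 paired weights")
    if np.ptp(ws) == 0:
        raise ValueError("scale weight has zero variance")
    slope, intercept = np.polyfit(ws, wd, 1)
    return float(intercept), float(slope)


def vif_report(data: pd.DataFrame, terms: Sequence[str]) -> pd.Series:
    """Variance inflation factors for a candidate term set."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    x = sm.add_constant(_design(data, terms), has_constant="add")
    vifs = [variance_inflation_factor(x, i + 1) for i in range(len(terms))]
    return pd.Series(vifs, index=list(terms), name="vif")
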
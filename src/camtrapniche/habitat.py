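"""Habitat-suitability modelling by AICc-based multi-model inference.

The response is the per-site RAI1 of one species in one season; candidate
predictors are the site covariates that survive a Spearman collinearity
screen. Every subset of the retained predictors (including the intercept-only
model) is fitted as a Gaussian GLM / ordinary least squares, models are
ranked by AICc, and predictor importance is summarised by selection
probabilities and conditional model-averaged coefficients with unconditional
standard errors (Burnham–Anderson).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class PredictorScreenResult:
    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (predictor, correlated_with, rho)


@dataclass
class ModelFitRecord:
    """One fitted predictor subset.

    ``k`` counts the intercept, the slopes and the residual-variance
    parameter, so Gaussian maximum-likelihood fits are AICc-comparable.
    """

    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    loglik: float
    k: int
    n: int
    r2: float
    adj_r2: float
    aicc: float = math.nan
    delta_aicc: float = math.nan
    weight: float = math.nan


@dataclass
class MmiSummary:
    selection_probability: dict[str, float]
    coefficient: dict[str, float]
    std_error: dict[str, float]


def screen_collinearity(
    covariates: pd.DataFrame,
    threshold: float = 0.7,
    drop_preference: list[str] | None = None,
) -> PredictorScreenResult:
    """Greedy removal of predictors until all pairwise |Spearman rho| < threshold.

    At each step the pair with the largest |rho| at or above the threshold is
    resolved by dropping one member: a predictor named in ``drop_preference``
    wins the tie; otherwise the member with the larger mean |rho| against all
    remaining predictors goes. Constant predictors (rho undefined) are dropped
    first and flagged.
    """
    prefer = list(drop_preference or [])
    retained = list(covariates.columns)
    dropped: list[tuple[str, str, float]] = []

    for col in list(retained):
        if covariates[col].nunique() <= 1:
            logger.warning("predictor %s is constant — correlation undefined, dropped", col)
            retained.remove(col)
            dropped.append((col, "", math.nan))

    def spearman_abs(cols: list[str]) -> pd.DataFrame:
        rho = stats.spearmanr(covariates[cols].to_numpy())[0]
        if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, rho], [rho, 1.0]])
        return pd.DataFrame(np.abs(rho), index=cols, columns=cols)

    while len(retained) >= 2:
        rho = spearman_abs(retained)
        np.fill_diagonal(rho.values, 0.0)
        i, j = np.unravel_index(np.argmax(rho.values), rho.shape)
        if rho.iat[i, j] < threshold:
            break
        a, b = rho.index[i], rho.columns[j]
        if a in prefer and b not in prefer:
            victim, keeper = a, b
        elif b in prefer and a not in prefer:
            victim, keeper = b, a
        else:
            mean_a = rho.loc[a].mean()
            mean_b = rho.loc[b].mean()
            victim, keeper = (a, b) if mean_a >= mean_b else (b, a)
        retained.remove(victim)
        dropped.append((victim, keeper, float(rho.iat[i, j])))
    return PredictorScreenResult(retained, dropped)


def gaussian_loglik(residuals: np.ndarray) -> float:
    """Gaussian log-likelihood at the ML variance estimate (sigma² = RSS/n)."""
    n = len(residuals)
    rss = float(np.dot(residuals, residuals))
    if rss <= 0:
        return math.inf
    sigma2 = rss / n
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); infinite when n - k - 1 <= 0,
    excluding the model from ranking.
    """
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_all_subsets(
    response: np.ndarray, predictors: pd.DataFrame
) -> list[ModelFitRecord]:
    """Fit one Gaussian GLM per subset of predictors (2^p models).

    The intercept-only model is included. Singular designs are skipped with a
    warning. Coefficient standard errors are the usual OLS ones.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    names = list(predictors.columns)
    if n <= len(names) + 2:
        logger.warning("n=%d sites is small for p=%d predictors", n, len(names))
    records: list[ModelFitRecord] = []
    for r in range(len(names) + 1):
        if n - (r + 2) - 1 <= 0:
            # AICc undefined (and OLS residual df exhausted): not a candidate
            logger.warning("subsets of size %d skipped: too few sites (n=%d)", r, n)
            break
        for subset in itertools.combinations(names, r):
            X = sm.add_constant(
                predictors[list(subset)].to_numpy(dtype=float), has_constant="add"
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                logger.warning("singular design for subset %s — skipped", subset)
                continue
            fit = sm.OLS(y, X).fit()
            ll = gaussian_loglik(fit.resid)
            k = len(subset) + 2  # intercept + slopes + residual variance
            coef_names = ["(Intercept)"] + list(subset)
            records.append(
                ModelFitRecord(
                    predictors=subset,
                    coefficients=dict(zip(coef_names, fit.params)),
                    std_errors=dict(zip(coef_names, fit.bse)),
                    loglik=ll,
                    k=k,
                    n=n,
                    r2=float(fit.rsquared),
                    adj_r2=float(fit.rsquared_adj) if r > 0 else 0.0,
                    aicc=aicc(ll, k, n),
                )
            )
    return records


def rank_and_weight(models: list[ModelFitRecord]) -> list[ModelFitRecord]:
    """Attach ΔAICc and Akaike weights; return models sorted by AICc.

    The best-model set is the subset with ΔAICc < 2 (leading entries of the
    returned list).
    """
    if not models:
        raise ValueError("empty candidate set")
    finite = [m for m in models if math.isfinite(m.aicc)]
    if not finite:
        raise ValueError("no model with finite AICc")
    best = min(m.aicc for m in finite)
    raw = []
    for m in models:
        m.delta_aicc = m.aicc - best
        raw.append(math.exp(-m.delta_aicc / 2.0) if math.isfinite(m.aicc) else 0.0)
    total = sum(raw)
    for m, w in zip(models, raw):
        m.weight = w / total
    return sorted(models, key=lambda m: m.aicc)


def best_model_set(models: list[ModelFitRecord], delta: float = 2.0) -> list[ModelFitRecord]:
    """Models with ΔAICc below ``delta`` (call after rank_and_weight)."""
    return [m for m in models if m.delta_aicc < delta]


def mmi_summary(models: list[ModelFitRecord]) -> MmiSummary:
    """Predictor selection probabilities and conditional model-averaged coefficients.

    The selection probability of a predictor is the summed Akaike weight of
    all models containing it. The averaged coefficient is the weight-
    renormalised mean over the models containing the predictor (conditional
    averaging); its unconditional standard error folds the between-model
    spread into the within-model sampling variance:

        SE = Σ w'_i sqrt( se_i² + (β_i − β̄)² )
    """
    # zero-weight models (e.g. AICc undefined at k ~ n) cannot contribute
    models = [m for m in models if m.weight > 0 and math.isfinite(m.aicc)]
    all_preds = sorted({p for m in models for p in m.predictors})
    sel: dict[str, float] = {}
    coef: dict[str, float] = {}
    se: dict[str, float] = {}
    for pred in all_preds:
        containing = [m for m in models if pred in m.predictors]
        wsum = sum(m.weight for m in containing)
        sel[pred] = wsum
        if wsum <= 0:
            coef[pred] = math.nan
            se[pred] = math.nan
            continue
        w = np.array([m.weight for m in containing]) / wsum
        b = np.array([m.coefficients[pred] for m in containing])
        s = np.array([m.std_errors[pred] for m in containing])
        bbar = float(np.dot(w, b))
        coef[pred] = bbar
        se[pred] = float(np.dot(w, np.sqrt(s**2 + (b - bbar) ** 2)))
    return MmiSummary(sel, coef, se)


def adjusted_r2(r2: float, n: int, k_slopes: int) -> float:
    """Adjusted coefficient of determination, 1 − (1−R²)(n−1)/(n−k−1)."""
    if n - k_slopes - 1 <= 0:
        raise ValueError("n must exceed the slope count + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k_slopes - 1)


def model_table(models: list[ModelFitRecord], delta: float = 2.0) -> pd.DataFrame:
    """Report table of the best-model set (one row per model, ΔAICc < delta)."""
    rows = []
    for m in best_model_set(models, delta):
        rows.append(
            {
                "predictors": "+".join(m.predictors) if m.predictors else "(intercept)",
                "AICc": round(m.aicc, 3),
                "dAICc": round(m.delta_aicc, 3),
                "wt": round(m.weight, 3),
                "R2": round(m.r2, 3),
                "adjR2": round(m.adj_r2, 3),
            }
        )
    return pd.DataFrame(rows)
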
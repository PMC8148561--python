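"""Stepwise regression and path-coefficient analysis of grain yield.

Forward stepwise selection (with a backward removal check) picks the subset
of screened traits that explains yield; path analysis then solves the
standardized normal equations R_x p = r_xy to split each trait-yield
correlation r_iy into a direct effect p_i and the indirect effects routed
through correlated traits, with

    indirect_i = r_iy - p_i,    R2 = sum_i p_i r_iy,
    residual effect = sqrt(1 - R2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "StepwiseResult",
    "PathDecomposition",
    "stepwise_regression",
    "path_analysis",
    "residual_effect",
]


def residual_effect(r2_total: float) -> float:
    """Residual (noise) path sqrt(1 - R2) of a path diagram."""
    if not 0 <= r2_total <= 1:
        raise ValueError("R2 must lie in [0, 1]")
    return float(np.sqrt(1.0 - r2_total))


@dataclass
class StepwiseResult:
    entered: list[str]  # in entry order
    coefficients: pd.Series  # unstandardized, final model
    intercept: float
    partial_r2: pd.Series  # R2 increment at entry, in entry order
    cumulative_r2: list[float]
    p_values: pd.Series  # final-model coefficient p-values
    r2: float


@dataclass
class PathDecomposition:
    direct: pd.Series  # standardized path coefficients p_i
    indirect: pd.Series  # r_iy - p_i
    correlation: pd.Series  # r_iy
    direct_r2: pd.Series  # p_i^2
    r2_total: float
    r2_direct: float  # sum p_i^2
    r2_indirect: float  # r2_total - r2_direct
    residual_effect: float  # sqrt(1 - r2_total)


def _fit(X: pd.DataFrame, y: pd.Series, cols: list[str]):
    design = sm.add_constant(X[cols], has_constant="add")
    return sm.OLS(np.asarray(y, dtype=float), design).fit()


def stepwise_regression(
    X: pd.DataFrame,
    y: pd.Series,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> StepwiseResult:
    """Forward stepwise OLS with removal check.

    At each step the candidate with the smallest partial-F p-value enters if
    that p-value is below ``alpha_enter``; any entered trait whose final-model
    p-value exceeds ``alpha_remove`` is then dropped. Stops when neither rule
    fires. Partial R2 is the R2 increment at entry, in entry order.
    """
    if alpha_enter > alpha_remove:
        warnings.warn(
            "alpha_enter > alpha_remove can cycle; consider alpha_enter <= alpha_remove",
            stacklevel=2,
        )
    X = X.astype(float)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more rows than candidate traits + 1")
    if not np.isfinite(y).all() or not np.isfinite(X.to_numpy()).all():
        raise ValueError("non-finite values in predictors or response")

    entered: list[str] = []
    partial_r2: dict[str, float] = {}
    cumulative: list[float] = []
    current_r2 = 0.0
    seen_states: set[frozenset] = set()
    while True:
        state = frozenset(entered)
        if state in seen_states:
            warnings.warn("stepwise selection cycled; stopping", stacklevel=2)
            break
        seen_states.add(state)
        if current_r2 >= 1.0 - 1e-12:
            break  # exact fit: nothing left to explain
        changed = False
        candidates = [c for c in X.columns if c not in entered]
        # entry step
        best, best_p, best_r2 = None, np.inf, current_r2
        for cand in candidates:
            model = _fit(X, y, entered + [cand])
            p = model.pvalues[cand]
            if np.isnan(p):
                raise ValueError(
                    f"perfect collinearity when entering trait {cand!r}"
                )
            if p < best_p:
                best, best_p, best_r2 = cand, p, model.rsquared
        if best is not None and best_p < alpha_enter:
            entered.append(best)
            partial_r2[best] = best_r2 - current_r2
            current_r2 = best_r2
            cumulative.append(current_r2)
            logger.info("entered %s (p=%.3g, R2=%.3f)", best, best_p, current_r2)
            changed = True
        # removal step
        if entered:
            model = _fit(X, y, entered)
            pvals = model.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > alpha_remove:
                entered.remove(worst)
                partial_r2.pop(worst, None)
                current_r2 = _fit(X, y, entered).rsquared if entered else 0.0
                cumulative.append(current_r2)
                logger.info("removed %s (p=%.3g)", worst, pvals[worst])
                changed = True
        if not changed:
            break

    if entered:
        final = _fit(X, y, entered)
        coefs = final.params.drop("const")
        intercept = float(final.params["const"])
        pvalues = final.pvalues.drop("const")
        r2 = float(final.rsquared)
    else:
        coefs = pd.Series(dtype=float)
        intercept = float(y.mean())
        pvalues = pd.Series(dtype=float)
        r2 = 0.0
    return StepwiseResult(
        entered=entered,
        coefficients=coefs,
        intercept=intercept,
        partial_r2=pd.Series(partial_r2).reindex(entered),
        cumulative_r2=cumulative,
        p_values=pvalues,
        r2=r2,
    )


def path_analysis(X: pd.DataFrame, y: pd.Series) -> PathDecomposition:
    """Path-coefficient decomposition of trait-yield correlations.

    All variables are standardized; the direct effects solve R_x p = r_xy.
    The identities correlation_i = direct_i + indirect_i and
    R2 = sum_i p_i r_iy hold exactly by construction.
    """
    X = X.astype(float)
    y = np.asarray(y, dtype=float)
    r_x = np.corrcoef(X.to_numpy(), rowvar=False)
    r_x = np.atleast_2d(r_x)
    r_xy = np.array([np.corrcoef(X[c], y)[0, 1] for c in X.columns])
    cond = np.linalg.cond(r_x)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("predictor correlation matrix is singular")
    p = np.linalg.solve(r_x, r_xy)
    r2_total = float(p @ r_xy)
    if r2_total > 1.0:
        warnings.warn(
            f"numerical R2 {r2_total:.6f} > 1 clamped to 1", stacklevel=2
        )
        r2_total = 1.0
    direct = pd.Series(p, index=X.columns, name="direct")
    correlation = pd.Series(r_xy, index=X.columns, name="correlation")
    r2_direct = float((p**2).sum())
    return PathDecomposition(
        direct=direct,
        indirect=correlation - direct,
        correlation=correlation,
        direct_r2=direct**2,
        r2_total=r2_total,
        r2_direct=r2_direct,
        r2_indirect=r2_total - r2_direct,
        residual_effect=float(np.sqrt(max(1.0 - r2_total, 0.0))),
    )
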
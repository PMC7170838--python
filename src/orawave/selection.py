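"""Two-step model selection for the PRAA regression.

Step 1 — screening: fit the full Lasso regularisation path on standardised
predictors and keep the k (default 20) features with the largest absolute
coefficients at the largest penalty admitting at least k active features.

Step 2 — best subset: evaluate *every* subset of the candidates (2^k
models, including the intercept-only model) by the second-order
bias-corrected Akaike information criterion

    AICc = n ln(2 pi RSS / n) + n + 2p + 2p(p + 1)/(n - p - 1),

with p = (number of slopes) + 2 counting the intercept and the residual
variance — the convention of the usual statistical environments, so that
Delta-AICc values agree with log-likelihood comparisons of nested Gaussian
linear models.  The search walks subsets in Gray-code order, toggling one
predictor per step with the sweep operator on the precomputed cross-product
matrix, so each subset costs one O(k^2) rank-one update instead of a full
refit.  The winning subset is refit by ordinary least squares on the raw
columns to report coefficients, standard errors and p-values.

Nested models are compared with the standard F-form of ANOVA:
F = [(RSS_small - RSS_large)/Delta df] / [RSS_large/(n - p_large)].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path

from .errors import DegenerateFitError, SaturationError

logger = logging.getLogger("orawave")

__all__ = [
    "OLSFit", "SelectionResult", "aicc", "ols_fit", "lasso_screen",
    "exhaustive_aicc_search", "univariate_scan", "anova_nested",
]

DEFAULT_SCREEN_K = 20
MAX_SEARCH_PREDICTORS = 24


@dataclass(eq=False)
class OLSFit:
    """An ordinary-least-squares fit of PRAA on one predictor subset."""

    subset: Tuple[str, ...]
    coefficients: Dict[str, float]      # includes "intercept"
    std_errors: Dict[str, float]
    p_values: Dict[str, float]
    rss: float
    loglik: float
    aicc: float
    n: int


def aicc(n: int, rss: float, n_slopes: int) -> float:
    """Second-order bias-corrected AIC of a Gaussian linear model.

    Parameter count p = n_slopes + 2 (intercept + residual variance).

    Raises
    ------
    DegenerateFitError
        If rss <= 0 (saturated/interpolating fit).
    SaturationError
        If n - p - 1 < 1, where the correction term blows up.
    """
    if rss <= 0:
        raise DegenerateFitError("rss must be positive for AICc")
    p = n_slopes + 2
    if n - p - 1 < 1:
        raise SaturationError(f"AICc undefined: n={n}, p={p} leaves n-p-1 < 1")
    return (n * math.log(2.0 * math.pi * rss / n) + n + 2 * p
            + 2.0 * p * (p + 1) / (n - p - 1))


def _gaussian_loglik(n: int, rss: float) -> float:
    return -0.5 * (n * math.log(2.0 * math.pi * rss / n) + n)


def ols_fit(X: pd.DataFrame, y: pd.Series, subset: Sequence[str]) -> OLSFit:
    """OLS with intercept on the raw (unstandardised) columns of ``subset``."""
    subset = tuple(subset)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    A = np.column_stack([np.ones(n)] + [np.asarray(X[c], dtype=float)
                                        for c in subset])
    k = A.shape[1]
    if np.linalg.matrix_rank(A) < k:
        raise DegenerateFitError(f"rank-deficient design for subset {subset}")
    coef, _, _, _ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ coef
    rss = float(resid @ resid)
    dof = n - k
    if dof < 1:
        raise SaturationError(f"no residual degrees of freedom for {subset}")
    if rss <= 0:
        raise DegenerateFitError(f"zero residual sum of squares for {subset}")
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    names = ("intercept",) + subset
    return OLSFit(
        subset=subset,
        coefficients=dict(zip(names, map(float, coef))),
        std_errors=dict(zip(names, map(float, se))),
        p_values=dict(zip(names, map(float, pvals))),
        rss=rss,
        loglik=_gaussian_loglik(n, rss),
        aicc=aicc(n, rss, len(subset)),
        n=n,
    )


# ---------------------------------------------------------------------------
# Step 1: Lasso screening
# ---------------------------------------------------------------------------

def lasso_screen(X: pd.DataFrame, y: pd.Series, k: int = DEFAULT_SCREEN_K,
                 n_alphas: int = 200, eps: float = 1e-4) -> List[str]:
    """Screen to exactly ``k`` candidate predictors via the Lasso path.

    Columns are standardised internally.  The penalty is the largest one at
    which at least ``k`` coefficients are active; features are ranked by
    absolute standardised coefficient there, with ties broken by earlier
    entry along the path and then by column order.  Constant columns are
    dropped with a warning before screening.
    """
    cols = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = [c for c, k_ in zip(cols, keep) if not k_]
        logger.warning("dropping constant columns before screening: %s",
                       ", ".join(dropped))
        cols = [c for c, k_ in zip(cols, keep) if k_]
        Xv, sd = Xv[:, keep], sd[keep]
    if k > len(cols):
        raise ValueError(f"k={k} exceeds the {len(cols)} usable columns")
    if k == len(cols):
        return list(cols)

    Xs = (Xv - Xv.mean(axis=0)) / sd
    yc = np.asarray(y, dtype=float)
    yc = yc - yc.mean()
    n = len(yc)
    alpha_max = np.max(np.abs(Xs.T @ yc)) / n
    grid = alpha_max * np.logspace(0.0, np.log10(eps), n_alphas)
    # The low-penalty tail of the path is only inspected for its active-set
    # size, so full coordinate-descent convergence there is not required.
    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        alphas, coefs, _ = lasso_path(Xs, yc, alphas=grid)
    active = coefs != 0.0                       # (n_features, n_alphas)
    nnz = active.sum(axis=0)
    rich = np.flatnonzero(nnz >= k)
    idx = int(rich[0]) if len(rich) else active.shape[1] - 1

    entry = np.where(active.any(axis=1), active.argmax(axis=1), np.inf)
    chosen = coefs[:, idx]
    order = sorted(range(len(cols)),
                   key=lambda j: (-abs(chosen[j]), entry[j], j))
    return [cols[j] for j in order[:k]]


# ---------------------------------------------------------------------------
# Step 2: exhaustive AICc search via Gray-code sweeps
# ---------------------------------------------------------------------------

def _sweep(A: np.ndarray, j: int) -> None:
    """Goodnight's symmetric sweep of pivot ``j``, in place (self-inverse)."""
    d = A[j, j]
    if abs(d) < 1e-12:
        raise DegenerateFitError(f"near-zero sweep pivot at column {j}; "
                                 "candidate columns are collinear")
    col = A[:, j].copy()
    row = A[j, :].copy()
    A -= np.outer(col, row) / d
    A[j, :] = row / d
    A[:, j] = col / d
    A[j, j] = -1.0 / d


@dataclass(eq=False)
class SelectionResult:
    candidates: List[str]
    best: OLSFit
    aicc_table: pd.DataFrame     # top-K subsets: subset, n_slopes, rss, aicc
    n_models_evaluated: int
    n_skipped: int = 0


def exhaustive_aicc_search(X: pd.DataFrame, y: pd.Series,
                           candidates: Sequence[str],
                           top_k: int = 20) -> SelectionResult:
    """Minimum-AICc subset over all 2^k candidate subsets.

    Subsets whose parameter count would leave fewer than one residual degree
    of freedom beyond the AICc correction (n - p - 1 < 1) are skipped and
    counted.  The winner is refit on the raw columns by :func:`ols_fit`.
    """
    candidates = list(candidates)
    k = len(candidates)
    if k > MAX_SEARCH_PREDICTORS:
        raise ValueError(f"{k} candidates exceed the 2^{MAX_SEARCH_PREDICTORS} "
                         "tractability cap")
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if k == 0:
        rss0 = float(np.sum((yv - yv.mean()) ** 2))
        fit = OLSFit(subset=(), coefficients={"intercept": float(yv.mean())},
                     std_errors={"intercept": float(np.std(yv, ddof=1)
                                                    / math.sqrt(n))},
                     p_values={"intercept": float(2 * stats.t.sf(
                         abs(yv.mean() / (np.std(yv, ddof=1) / math.sqrt(n))),
                         n - 1))},
                     rss=rss0, loglik=_gaussian_loglik(n, rss0),
                     aicc=aicc(n, rss0, 0), n=n)
        table = pd.DataFrame([{"subset": (), "n_slopes": 0, "rss": rss0,
                               "aicc": fit.aicc}])
        return SelectionResult([], fit, table, 1, 0)
    if n <= k + 2:
        raise SaturationError(f"n={n} too small for the full {k}-slope model")

    # Standardise for sweep conditioning; RSS is scale invariant.
    Xv = X[candidates].to_numpy(dtype=float)
    Xc = Xv - Xv.mean(axis=0)
    sd = Xc.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(candidates, sd) if s == 0]
        raise DegenerateFitError(f"constant candidate columns: {bad}")
    Xc /= sd
    yc = yv - yv.mean()
    M = np.column_stack([Xc, yc])
    A = M.T @ M

    n_models = 1 << k
    rss = np.empty(n_models)
    rss[0] = A[k, k]
    for t in range(1, n_models):
        _sweep(A, ((t & -t).bit_length() - 1))
        rss[t] = A[k, k]

    codes = np.arange(n_models, dtype=np.uint32)
    gray = codes ^ (codes >> 1)
    sizes = np.bitwise_count(gray).astype(int)
    p = sizes + 2
    valid = (n - p - 1 >= 1) & (rss > 0)
    n_skipped = int(np.sum(~valid))
    crit = np.full(n_models, np.inf)
    vp, vrss = p[valid], rss[valid]
    crit[valid] = (n * np.log(2.0 * np.pi * vrss / n) + n + 2 * vp
                   + 2.0 * vp * (vp + 1) / (n - vp - 1))

    best_t = int(np.argmin(crit))
    subset = tuple(candidates[j] for j in range(k) if (int(gray[best_t]) >> j) & 1)
    best = ols_fit(X, y, subset)

    top = np.argsort(crit, kind="stable")[:top_k]
    table = pd.DataFrame([
        {"subset": tuple(candidates[j] for j in range(k)
                         if (int(gray[t]) >> j) & 1),
         "n_slopes": int(sizes[t]), "rss": float(rss[t]),
         "aicc": float(crit[t])}
        for t in top if np.isfinite(crit[t])
    ])
    return SelectionResult(candidates, best, table, n_models, n_skipped)


# ---------------------------------------------------------------------------
# Univariate scan and nested-model ANOVA
# ---------------------------------------------------------------------------

def univariate_scan(X: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    """One simple regression of PRAA per column: coefficient, SE, p, AICc."""
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    rows = []
    for col in X.columns:
        if np.std(X[col].to_numpy(dtype=float)) == 0:
            rows.append({"variable": col, "coefficient": np.nan,
                         "std_error": np.nan, "p_value": np.nan,
                         "aicc": np.nan, "flag": "constant"})
            continue
        fit = ols_fit(X, y, [col])
        rows.append({"variable": col,
                     "coefficient": fit.coefficients[col],
                     "std_error": fit.std_errors[col],
                     "p_value": fit.p_values[col],
                     "aicc": fit.aicc, "flag": ""})
    return pd.DataFrame(rows)


def anova_nested(small: OLSFit, large: OLSFit) -> float:
    """F-test p-value comparing nested Gaussian linear models.

    ``small.subset`` must be a proper subset of ``large.subset`` fitted on
    the same response (same n).
    """
    if small.n != large.n:
        raise ValueError("models were fitted on different sample sizes")
    s, l = set(small.subset), set(large.subset)
    if not (s < l):
        raise ValueError("small.subset must be a proper subset of large.subset")
    ddf = len(l) - len(s)
    dof_large = large.n - len(large.subset) - 1
    if dof_large < 1:
        raise ValueError("large model has no residual degrees of freedom")
    f_stat = max(small.rss - large.rss, 0.0) / ddf / (large.rss / dof_large)
    return float(stats.f.sf(f_stat, ddf, dof_large))
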
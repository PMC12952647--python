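"""Logistic rejection models on absolute trait differences.

The rejection model treats each egg-swap experiment as a Bernoulli trial:
the response is whether the experimental egg was rejected, and the
predictors are the absolute differences between the experimental egg and
the mean host egg in the nest, one per trait.  Model selection enumerates
all trait subsets, ranks them by AICc, and picks the simplest model within
2 AICc of the top-ranked one; fit quality is summarised by Nagelkerke's
pseudo-R^2.

Maximum-likelihood fits go through statsmodels' binomial GLM (IRLS).  When
quasi-complete separation is detected (near-perfect discrimination is the
norm for strongly categorical signatures, where almost every
different-category egg is rejected), the model is refit with a tiny ridge
penalty on the slopes and flagged.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RejectionModel",
    "ModelSelectionResult",
    "FitError",
    "fit_logistic",
    "fit_rejection",
    "aicc",
    "select_model",
    "nagelkerke_r2",
    "predict_rejection",
    "correlation_screen",
]

SEPARATION_COEF_LIMIT = 15.0
RIDGE_PENALTY = 1e-6
_LOGLIK_TOL = 1e-8


class FitError(ValueError):
    """Raised when a logistic fit is impossible (e.g. one-class outcome)."""


# --------------------------------------------------------------------------
# Model container
# --------------------------------------------------------------------------

@dataclass
class RejectionModel:
    """Fitted logistic rejection rule.

    ``predict`` maps a dict of absolute trait differences to a rejection
    probability via the inverse logit of ``intercept + sum(coef * diff)``.
    Standard errors come from the observed-information Hessian; ``z`` and
    ``p`` are Wald statistics per coefficient.
    """

    intercept: float
    coefficients: dict[str, float]
    n_obs: int = 0
    log_likelihood: float = 0.0
    trait_subset: tuple[str, ...] = ()
    intercept_se: float = float("nan")
    se: dict[str, float] = field(default_factory=dict)
    z: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    n_dropped: int = 0
    converged: bool = True
    separation: bool = False

    def __post_init__(self) -> None:
        self.trait_subset = tuple(sorted(self.coefficients))

    def linear_predictor(self, abs_diffs: Mapping[str, float],
                         on_missing: str = "error") -> float:
        eta = self.intercept
        for t, beta in self.coefficients.items():
            x = abs_diffs.get(t, None)
            if x is None or (isinstance(x, float) and math.isnan(x)):
                if on_missing == "drop":
                    continue
                raise KeyError(
                    f"abs_diffs is missing required trait {t!r} "
                    f"(model uses {sorted(self.coefficients)})")
            eta += beta * float(x)
        return eta

    def predict(self, abs_diffs: Mapping[str, float],
                on_missing: str = "error") -> float:
        """Rejection probability in [0, 1] for one set of trait differences."""
        eta = self.linear_predictor(abs_diffs, on_missing=on_missing)
        # numerically safe inverse logit (handles +/-inf intercepts)
        if eta >= 0:
            return 1.0 / (1.0 + math.exp(-eta)) if eta < 700 else 1.0
        return math.exp(eta) / (1.0 + math.exp(eta))

    def predict_many(self, diffs: pd.DataFrame) -> np.ndarray:
        """Vectorised predict over a DataFrame of per-trait abs differences."""
        eta = np.full(len(diffs), self.intercept, dtype=float)
        for t, beta in self.coefficients.items():
            col = f"diff_{t}" if f"diff_{t}" in diffs.columns else t
            if col not in diffs.columns:
                raise KeyError(f"no column for model trait {t!r}")
            eta = eta + beta * diffs[col].to_numpy(dtype=float)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


@dataclass
class ModelSelectionResult:
    """All-subsets AICc comparison and the simplest-within-2 winner."""

    candidates: list[tuple[tuple[str, ...], float, int]]
    best: RejectionModel
    delta_table: dict[tuple[str, ...], float]
    nagelkerke_r2: float
    null_log_likelihood: float
    n_obs: int
    excluded: list[tuple[str, ...]] = field(default_factory=list)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def _design(experiments: pd.DataFrame, traits: Sequence[str]):
    """Extract (y, X, n_dropped) with complete-case filtering on ``traits``."""
    if "rejected" not in experiments.columns:
        raise FitError("experiments table lacks a 'rejected' column")
    cols = {}
    for t in traits:
        col = f"diff_{t}" if f"diff_{t}" in experiments.columns else t
        if col not in experiments.columns:
            raise FitError(f"no predictor column for trait {t!r}")
        cols[t] = experiments[col].to_numpy(dtype=float)
    y = experiments["rejected"].to_numpy(dtype=float)
    X = np.column_stack([cols[t] for t in traits]) if traits else \
        np.empty((len(y), 0))
    keep = np.isfinite(y)
    if traits:
        keep &= np.isfinite(X).all(axis=1)
    n_dropped = int((~keep).sum())
    y, X = y[keep], X[keep]
    if len(y) == 0:
        raise FitError("no complete-case rows left after dropping missing")
    for j, t in enumerate(traits):
        if not np.isfinite(X[:, j]).any():
            raise FitError(f"trait {t!r} is entirely missing")
    if y.min() == y.max():
        raise FitError("outcome has a single class; cannot fit")
    return y, X, n_dropped


def _ridge_logistic(y: np.ndarray, X1: np.ndarray, penalty: float,
                    max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Newton solver for logistic regression with an L2 penalty on slopes.

    ``X1`` includes the intercept column (unpenalised).  Used only as the
    separation fallback; the penalty is tiny and serves to bound the MLE.
    """
    n, p = X1.shape
    pen = np.full(p, penalty)
    pen[0] = 0.0
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X1 @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X1.T @ (y - mu) - pen * beta
        hess = X1.T @ (X1 * w[:, None]) + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _binomial_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    eta = np.clip(eta, -30, 30)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def fit_logistic(experiments: pd.DataFrame,
                 traits: Iterable[str] = (),
                 separation_limit: float = SEPARATION_COEF_LIMIT,
                 ) -> RejectionModel:
    """ML logistic fit of rejection on absolute trait differences.

    Rows with a missing predictor are dropped (complete-case analysis); the
    dropped count is recorded on the returned model.  If any slope exceeds
    ``separation_limit`` in magnitude after convergence, the data are
    treated as (quasi-)separated: the model is refit with a ridge penalty
    of ``1e-6`` on the slopes, a warning is issued, and ``separation`` is
    flagged on the result.
    """
    traits = sorted(traits)
    y, X, n_dropped = _design(experiments, traits)
    X1 = sm.add_constant(X, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels perfect-sep warnings
        glm = sm.GLM(y, X1, family=sm.families.Binomial())
        res = glm.fit(maxiter=100, tol=_LOGLIK_TOL)
    params = np.asarray(res.params, dtype=float)
    converged = bool(getattr(res, "converged", True))

    separated = bool(np.any(np.abs(params[1:]) > separation_limit)) \
        if len(params) > 1 else False
    if separated or not np.all(np.isfinite(params)):
        warnings.warn(
            "possible (quasi-)complete separation: refitting with a ridge "
            f"penalty of {RIDGE_PENALTY:g} on the slopes",
            RuntimeWarning, stacklevel=2)
        params = _ridge_logistic(y, X1, RIDGE_PENALTY)
        separated = True
        converged = True

    eta = X1 @ params
    ll = _binomial_loglik(y, eta)
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = mu * (1.0 - mu)
    hess = X1.T @ (X1 * w[:, None])
    try:
        cov = np.linalg.inv(hess)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(len(params), np.nan)

    from scipy.stats import norm as _norm
    zvals = params / ses
    pvals = 2.0 * _norm.sf(np.abs(zvals))
    return RejectionModel(
        intercept=float(params[0]),
        coefficients={t: float(b) for t, b in zip(traits, params[1:])},
        n_obs=len(y),
        log_likelihood=ll,
        intercept_se=float(ses[0]),
        se={t: float(s) for t, s in zip(traits, ses[1:])},
        z={t: float(v) for t, v in zip(traits, zvals[1:])},
        p_values={t: float(v) for t, v in zip(traits, pvals[1:])},
        n_dropped=n_dropped,
        converged=converged,
        separation=separated,
    )


# --------------------------------------------------------------------------
# Information criteria and model selection
# --------------------------------------------------------------------------

def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: -2*logLik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined for n={n}, k={k}: requires n > k + 1")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def select_model(experiments: pd.DataFrame,
                 candidate_traits: Iterable[str],
                 max_subset_size: Optional[int] = None,
                 delta_threshold: float = 2.0,
                 ) -> ModelSelectionResult:
    """All-subsets AICc selection with the simplest-within-2 rule.

    Fits every subset of ``candidate_traits`` up to ``max_subset_size``
    (default: all sizes) on the rows complete for *all* candidate traits,
    so AICc values are comparable, and ranks the subsets by AICc.  The best
    model is the one with the fewest parameters among those within
    ``delta_threshold`` AICc of the minimum; ties on parameter count break
    by lower AICc, then lexicographic subset order.  Subsets that fail to
    fit are excluded and reported.
    """
    candidate_traits = sorted(candidate_traits)
    if len(candidate_traits) > 12:
        raise ValueError("exhaustive enumeration capped at 12 candidate traits")
    # common complete-case rows across all candidates
    cols = []
    for t in candidate_traits:
        col = f"diff_{t}" if f"diff_{t}" in experiments.columns else t
        if col not in experiments.columns:
            raise FitError(f"no predictor column for trait {t!r}")
        cols.append(col)
    mask = experiments["rejected"].notna()
    for col in cols:
        mask &= experiments[col].notna()
    rows = experiments[mask]
    n = len(rows)

    max_size = len(candidate_traits) if max_subset_size is None \
        else min(max_subset_size, len(candidate_traits))
    fits: dict[tuple[str, ...], RejectionModel] = {}
    excluded: list[tuple[str, ...]] = []
    for size in range(0, max_size + 1):
        for subset in itertools.combinations(candidate_traits, size):
            try:
                m = fit_logistic(rows, subset)
            except FitError:
                raise
            if not m.converged:
                excluded.append(subset)
                continue
            fits[subset] = m

    candidates = []
    for subset, m in fits.items():
        k = len(subset) + 1  # slopes + intercept
        candidates.append((subset, aicc(m.log_likelihood, k, n), k))
    candidates.sort(key=lambda c: (c[1], c[2], c[0]))
    a_min = candidates[0][1]
    delta = {subset: a - a_min for subset, a, _ in candidates}
    in_window = [c for c in candidates if c[1] - a_min <= delta_threshold]
    in_window.sort(key=lambda c: (c[2], c[1], c[0]))
    best_subset = in_window[0][0]
    best = fits[best_subset]

    null_ll = fits[()].log_likelihood if () in fits else \
        fit_logistic(rows, ()).log_likelihood
    r2 = nagelkerke_r2(best, null_ll)
    return ModelSelectionResult(
        candidates=candidates,
        best=best,
        delta_table=delta,
        nagelkerke_r2=r2,
        null_log_likelihood=null_ll,
        n_obs=n,
        excluded=excluded,
    )


def nagelkerke_r2(model: RejectionModel, null_log_likelihood: float) -> float:
    """Nagelkerke's pseudo-R^2 against the intercept-only fit.

    ``[1 - exp(2(L0 - L1)/n)] / [1 - exp(2 L0/n)]`` with L1 the model
    log-likelihood, L0 the null log-likelihood on the same rows.
    """
    l0, l1, n = null_log_likelihood, model.log_likelihood, model.n_obs
    if l1 < l0 - 1e-6:
        raise ValueError(
            f"model log-likelihood {l1:.6g} is below the null {l0:.6g}; "
            "the null must be fit on the same rows")
    l1 = max(l1, l0)
    denom = 1.0 - math.exp(2.0 * l0 / n)
    if denom == 0.0:
        return 0.0
    return (1.0 - math.exp(2.0 * (l0 - l1) / n)) / denom


def predict_rejection(model: RejectionModel,
                      abs_diffs: Mapping[str, float]) -> float:
    """Rejection probability for one set of absolute trait differences."""
    return model.predict(abs_diffs)


# --------------------------------------------------------------------------
# Diagnostics and missing-data strategies
# --------------------------------------------------------------------------

def correlation_screen(experiments: pd.DataFrame,
                       traits: Iterable[str],
                       r2_threshold: float = 0.4) -> pd.DataFrame:
    """Pairwise R^2 among candidate predictors, with a collinearity warning.

    Highly correlated predictors make subset selection unstable; pairs above
    the threshold are reported (and warned about) but not excluded
    automatically.
    """
    traits = sorted(traits)
    data = {}
    for t in traits:
        col = f"diff_{t}" if f"diff_{t}" in experiments.columns else t
        data[t] = experiments[col].to_numpy(dtype=float)
    rows = []
    for a, b in itertools.combinations(traits, 2):
        mask = np.isfinite(data[a]) & np.isfinite(data[b])
        r = np.corrcoef(data[a][mask], data[b][mask])[0, 1] \
            if mask.sum() > 2 else np.nan
        rows.append({"trait_a": a, "trait_b": b, "r": r, "r2": r * r})
    table = pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "r2"])
    high = table[table["r2"] > r2_threshold]
    if len(high):
        pairs = ", ".join(f"{r.trait_a}/{r.trait_b} (R^2={r.r2:.2f})"
                          for r in high.itertuples())
        warnings.warn(f"highly correlated predictor pairs: {pairs}",
                      UserWarning, stacklevel=2)
    return table


def fit_rejection(experiments: pd.DataFrame,
                  traits: Iterable[str],
                  missing_strategy: str = "drop",
                  missing_prone: Optional[str] = None,
                  max_subset_size: Optional[int] = None):
    """High-level entry point mirroring the analysis workflow.

    ``missing_strategy='drop'`` runs one all-subsets selection on
    complete-case rows.  ``missing_strategy='two-model'`` mirrors the
    immaculate-egg treatment: one selection on all rows excluding the
    missing-prone trait, and one on complete rows including it; returns a
    dict with keys ``'all_rows'`` and ``'complete_rows'``.
    """
    traits = sorted(traits)
    if missing_strategy == "drop":
        return select_model(experiments, traits, max_subset_size)
    if missing_strategy == "two-model":
        if missing_prone is None:
            raise ValueError("two-model strategy needs missing_prone trait")
        without = [t for t in traits if t != missing_prone]
        return {
            "all_rows": select_model(experiments, without, max_subset_size),
            "complete_rows": select_model(experiments, traits, max_subset_size),
        }
    raise ValueError(f"unknown missing_strategy {missing_strategy!r}")
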
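"""Monte-Carlo error-rate estimation from a fitted rejection model.

Observed error rates from experiments confound a host's discrimination
ability with how well-matched the experimental eggs happened to be.  The
model-substitution estimators here control for that: they recombine
measured phenotypes at random and push the resulting trait differences
through the fitted rejection model.

* Type II (accepting a foreign egg): draw a random host egg to represent
  its clutch, draw a foreign egg (a real parasite egg, or a host egg from
  a *different* clutch as a proxy), and average the model's acceptance
  probability over many such combinations.
* Type I (rejecting an own egg): for each clutch with at least two
  measured eggs, take a random within-clutch pair and evaluate the model
  on their differences.  Where a trait (typically color, measured by
  spectrophotometry indoors) exists only for a subset of clutches, its
  within-clutch differences are pooled and assigned at random -- valid
  only if that trait is uncorrelated with the others, which is checked.

Standard errors: binomial ``sqrt(p(1-p)/n)`` for observed rates, a
subsample bootstrap for the 1,000-combination Type II estimates, and the
direct across-clutch SE for Type I.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ErrorEstimate",
    "observed_rate",
    "estimate_type2",
    "estimate_type1",
    "bootstrap_se",
]

from .synthetic_data import substream


@dataclass
class ErrorEstimate:
    """Point estimate of an error rate with its uncertainty."""

    error_type: str  # "type1" | "type2"
    point: float
    se: float
    method: str  # "observed" | "model_substitution"
    n_units: int
    seed: Optional[int] = None
    values: Optional[np.ndarray] = None  # per-combination / per-clutch
    n_excluded: int = 0

    def __post_init__(self):
        if not 0.0 <= self.point <= 1.0:
            raise ValueError(f"error rate {self.point} outside [0, 1]")


def observed_rate(successes: int, n: int,
                  error_type: str = "type2") -> ErrorEstimate:
    """Observed error frequency with binomial SE sqrt(p(1-p)/n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    p = successes / n
    return ErrorEstimate(error_type=error_type, point=p,
                         se=math.sqrt(p * (1.0 - p) / n),
                         method="observed", n_units=n)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _model_traits(model) -> list[str]:
    return sorted(model.coefficients)


def _check_traits(table: pd.DataFrame, traits: Sequence[str],
                  allow_missing: Sequence[str] = ()) -> None:
    for t in traits:
        if t not in table.columns and t not in allow_missing:
            raise KeyError(f"model trait {t!r} absent from egg table")


def _one_parasite_per_nest(parasites: pd.DataFrame,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Keep one parasite egg per nest when several were laid (seeded pick)."""
    if parasites["clutch_id"].is_unique:
        return parasites
    picks = []
    for _, grp in parasites.groupby("clutch_id", sort=False):
        picks.append(grp.index[rng.integers(0, len(grp))])
    return parasites.loc[picks]


# --------------------------------------------------------------------------
# Type II
# --------------------------------------------------------------------------

def estimate_type2(model,
                   host_eggs: pd.DataFrame,
                   foreign_eggs: Optional[pd.DataFrame] = None,
                   n_combos: int = 1000,
                   seed: int = 0,
                   exhaustive: bool = False) -> ErrorEstimate:
    """Model-substitution Type II error rate (acceptance of foreign eggs).

    ``foreign_eggs=None`` selects proxy mode: foreign eggs are host eggs
    from a different clutch, which equalises mimicry across species by
    assuming parasite phenotypes match the host distribution.  Each
    combination pairs one host egg (the clutch representative) with one
    foreign egg and scores ``1 - P(reject)``; ``exhaustive=True`` replaces
    the Monte-Carlo draw with the average over all valid ordered pairs.
    The SE is the subsample bootstrap of the per-combination values.
    """
    traits = _model_traits(model)
    _check_traits(host_eggs, traits)
    rng = substream(seed, "estimate_type2")

    proxy = foreign_eggs is None
    if proxy:
        if host_eggs["clutch_id"].nunique() < 2:
            raise ValueError("proxy mode needs >= 2 distinct host clutches")
        foreign = host_eggs
    else:
        _check_traits(foreign_eggs, traits)
        foreign = _one_parasite_per_nest(foreign_eggs, rng)

    hv = host_eggs[traits].to_numpy(dtype=float)
    fv = foreign[traits].to_numpy(dtype=float)
    h_clutch = host_eggs["clutch_id"].to_numpy()
    f_clutch = foreign["clutch_id"].to_numpy()
    betas = np.array([model.coefficients[t] for t in traits])

    def accept_prob(hi: np.ndarray, fi: np.ndarray) -> np.ndarray:
        diffs = np.abs(fv[fi] - hv[hi])
        eta = model.intercept + diffs @ betas
        with np.errstate(over="ignore"):
            return 1.0 - 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))

    if exhaustive:
        hi, fi = np.meshgrid(np.arange(len(hv)), np.arange(len(fv)),
                             indexing="ij")
        hi, fi = hi.ravel(), fi.ravel()
        if proxy:
            keep = h_clutch[hi] != f_clutch[fi]
            hi, fi = hi[keep], fi[keep]
        values = accept_prob(hi, fi)
    else:
        hi = rng.integers(0, len(hv), n_combos)
        fi = rng.integers(0, len(fv), n_combos)
        if proxy:
            bad = h_clutch[hi] == f_clutch[fi]
            while bad.any():  # never pair eggs from the same clutch
                fi[bad] = rng.integers(0, len(fv), int(bad.sum()))
                bad = h_clutch[hi] == f_clutch[fi]
        values = accept_prob(hi, fi)

    if np.isnan(values).any():
        raise ValueError("missing trait values in sampled combinations; "
                         "filter the egg tables first")
    point = float(values.mean())
    se = bootstrap_se(values, seed=seed) if len(values) >= 2 else 0.0
    return ErrorEstimate(error_type="type2", point=point, se=se,
                         method="model_substitution", n_units=len(values),
                         seed=seed, values=values)


# --------------------------------------------------------------------------
# Type I
# --------------------------------------------------------------------------

def estimate_type1(model,
                   eggs: pd.DataFrame,
                   color_diff_pool: Optional[Sequence[float]] = None,
                   color_trait: Optional[str] = None,
                   seed: int = 0,
                   r_limit: float = 0.3) -> ErrorEstimate:
    """Model-substitution Type I error rate (rejecting an own egg).

    One estimate per clutch with >= 2 eggs: the model's rejection
    probability for a randomly chosen within-clutch pair.  If the model
    uses ``color_trait`` but per-egg color is only available as a pooled
    set of within-clutch differences (``color_diff_pool``), each pair is
    assigned a pool value at random; pooling is refused with a warning if
    color correlates with any other model trait beyond ``r_limit`` in the
    egg table.  Clutches with a single egg are excluded (count recorded).
    """
    traits = _model_traits(model)
    pooled = color_trait is not None and color_diff_pool is not None
    if pooled and color_trait not in traits:
        pooled = False
    _check_traits(eggs, traits,
                  allow_missing=[color_trait] if pooled else [])
    if pooled and len(color_diff_pool) == 0:
        raise ValueError("color_diff_pool is empty but the model uses "
                         f"{color_trait!r}")
    if pooled and color_trait in eggs.columns:
        others = [t for t in traits if t != color_trait
                  and t in eggs.columns]
        for t in others:
            mask = eggs[[color_trait, t]].notna().all(axis=1)
            if mask.sum() > 2:
                r = np.corrcoef(eggs.loc[mask, color_trait],
                                eggs.loc[mask, t])[0, 1]
                if abs(r) >= r_limit:
                    warnings.warn(
                        f"pooled color differences assume independence, but "
                        f"|r({color_trait}, {t})| = {abs(r):.2f} >= "
                        f"{r_limit}", UserWarning, stacklevel=2)

    rng = substream(seed, "estimate_type1")
    pool = np.asarray(color_diff_pool, dtype=float) if pooled else None
    per_clutch = []
    n_excluded = 0
    for _, grp in eggs.groupby("clutch_id", sort=False):
        if len(grp) < 2:
            n_excluded += 1
            continue
        i, j = rng.choice(len(grp), size=2, replace=False)
        diffs = {}
        for t in traits:
            if pooled and t == color_trait:
                diffs[t] = float(pool[rng.integers(0, len(pool))])
            else:
                diffs[t] = abs(float(grp[t].iloc[i]) - float(grp[t].iloc[j]))
        per_clutch.append(model.predict(diffs))
    if not per_clutch:
        raise ValueError("no clutch has >= 2 eggs")
    vals = np.asarray(per_clutch)
    se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return ErrorEstimate(error_type="type1", point=float(vals.mean()),
                         se=se, method="model_substitution",
                         n_units=len(vals), seed=seed, values=vals,
                         n_excluded=n_excluded)


# --------------------------------------------------------------------------
# Bootstrap SE
# --------------------------------------------------------------------------

def bootstrap_se(combo_values: Sequence[float],
                 subsample: int = 100,
                 reps: int = 100,
                 seed: int = 0) -> float:
    """Subsample-bootstrap SE of a mean error rate.

    Resamples ``subsample`` values with replacement from the
    per-combination values, takes the mean, repeats ``reps`` times, and
    returns the sample SD of the replicate means.
    """
    values = np.asarray(combo_values, dtype=float)
    if len(values) == 0:
        raise ValueError("combo_values is empty")
    if subsample <= 0:
        raise ValueError("subsample must be > 0")
    if reps < 2:
        raise ValueError("reps must be >= 2 (sample SD undefined otherwise)")
    rng = substream(seed, "bootstrap_se")
    idx = rng.integers(0, len(values), (reps, subsample))
    means = values[idx].mean(axis=1)
    return float(means.std(ddof=1))
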
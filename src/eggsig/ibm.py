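"""Individual-based simulation of host-parasite egg rejection.

Each nest holds a host whose clutch phenotypes scatter around the host's
genotypic trait value; with some probability the nest is also parasitized
by a parasite drawn from the *same* genotype distribution as the hosts
(identical model and mimic distributions -- the regime where classical
signal detection theory says no decision rule can beat chance).  The host
accepts any egg whose trait value lies within +/- threshold of its own
genotype.  Outcomes are scored hierarchically:

* an accepted parasitic egg is a Type II error and dooms the whole clutch;
* otherwise each host egg is inspected: a rejected host egg is a Type I
  error, an accepted one survives.

The overall Type II rate is accepted-parasite nests over all nests (so its
ceiling is the parasitism probability); the Type I rate is rejected host
eggs over host eggs in nests not doomed by an accepted parasite (switchable
to an all-eggs denominator -- the two have the same expectation because
within-clutch noise is independent of the parasite draw); the success rate
is surviving host eggs over all host eggs, which is a joint probability and
therefore not constrained to equal 1 - (Type I + Type II).

Genotype distributions are either continuous, Normal(mean, sigma_cont), or
categorical, an equal mixture of peaks spaced around the mean with
within-peak sd sigma_cat; the variance-matching constraint
sigma_cont^2 = d_cat^2 + sigma_cat^2 makes the two shapes comparable.
Closed-form companions (`oracle_type1`, `oracle_type2`) give the exact
expected rates for both shapes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthetic_data import substream

__all__ = [
    "DistributionSpec",
    "SimConfig",
    "SimOutcome",
    "simulate",
    "simulate_category_based",
    "sweep",
    "oracle_type1",
    "oracle_type2",
]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """Genotype distribution shared by hosts and parasites.

    ``continuous``: Normal(mean, sigma_cont).  ``categorical``:
    ``n_categories`` equally frequent normal peaks, sd ``sigma_cat`` each,
    evenly spaced on [mean - d_cat, mean + d_cat] (for two categories:
    peaks at mean +/- d_cat).
    """

    shape: str = "continuous"
    mean: float = 0.5
    sigma_cont: float = 0.25
    d_cat: float = 0.0
    sigma_cat: float = 0.0
    n_categories: int = 2

    def __post_init__(self):
        if self.shape not in ("continuous", "categorical"):
            raise ValueError(f"unknown distribution shape {self.shape!r}")
        if self.shape == "continuous" and not self.sigma_cont > 0:
            raise ValueError("sigma_cont must be > 0")
        if self.shape == "categorical":
            if self.d_cat < 0 or self.sigma_cat < 0:
                raise ValueError("d_cat and sigma_cat must be >= 0")
            if self.n_categories < 2:
                raise ValueError("n_categories must be >= 2")

    @property
    def overall_sd(self) -> float:
        if self.shape == "continuous":
            return self.sigma_cont
        if self.n_categories != 2:
            peaks = self.peak_positions()
            return math.sqrt(self.sigma_cat ** 2 + np.var(peaks))
        return math.sqrt(self.d_cat ** 2 + self.sigma_cat ** 2)

    def peak_positions(self) -> np.ndarray:
        offsets = np.linspace(-1.0, 1.0, self.n_categories)
        return self.mean + self.d_cat * offsets

    @property
    def peak_spacing(self) -> float:
        return 2.0 * self.d_cat / (self.n_categories - 1)

    def matched_continuous(self) -> "DistributionSpec":
        """Variance-matched continuous partner (sigma_cont = overall sd)."""
        if self.shape == "continuous":
            return self
        return DistributionSpec(shape="continuous", mean=self.mean,
                                sigma_cont=self.overall_sd)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.shape == "continuous":
            return rng.normal(self.mean, self.sigma_cont, n)
        peaks = self.peak_positions()
        vals = peaks[rng.integers(0, len(peaks), n)]
        if self.sigma_cat > 0:
            vals = vals + rng.normal(0.0, self.sigma_cat, n)
        return vals


@dataclass(frozen=True)
class SimConfig:
    """All simulation parameters; defaults give 10^6 nesting events."""

    threshold: float = 0.25
    distribution: DistributionSpec = field(default_factory=DistributionSpec)
    n_nest: int = 1000
    n_replicates: int = 1000
    n_egg_host: int = 3
    n_egg_para: int = 1
    p_parasitized: float = 0.5
    sigma_host: float = 0.25
    seed: int = 0
    type1_denominator: str = "conditional"  # or "all"

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if not 0.0 <= self.p_parasitized <= 1.0:
            raise ValueError("p_parasitized must be in [0, 1]")
        if self.sigma_host < 0:
            raise ValueError("sigma_host must be >= 0")
        if min(self.n_nest, self.n_replicates, self.n_egg_host,
               self.n_egg_para) < 1:
            raise ValueError("counts must be >= 1")
        if self.type1_denominator not in ("conditional", "all"):
            raise ValueError("type1_denominator must be 'conditional' or 'all'")


@dataclass
class SimOutcome:
    """Simulation result with per-replicate rates and Monte-Carlo SEs."""

    type1_rate: float
    type2_rate: float
    success_rate: float
    per_replicate: dict[str, np.ndarray]
    mc_se: dict[str, float]
    counters: dict[str, int]
    config: SimConfig


# --------------------------------------------------------------------------
# Simulation core
# --------------------------------------------------------------------------

def _run_replicate(config: SimConfig, rng: np.random.Generator):
    """One replicate of n_nest nests; returns raw counters."""
    n = config.n_nest
    dist = config.distribution
    host_geno = dist.draw(n, rng)
    parasitized = rng.random(n) < config.p_parasitized
    para_geno = dist.draw(n, rng)
    eggs = host_geno[:, None] + (
        rng.normal(0.0, config.sigma_host, (n, config.n_egg_host))
        if config.sigma_host > 0 else 0.0)

    # parasite eggs are the parasite genotype exactly; with n_egg_para > 1
    # the copies are identical, so one acceptance test covers the clutch
    para_accepted = parasitized & (
        np.abs(para_geno - host_geno) <= config.threshold)
    egg_rejected = np.abs(eggs - host_geno[:, None]) > config.threshold

    doomed = para_accepted
    n_doomed = int(doomed.sum())
    ok_nests = ~doomed
    rejected_ok = int(egg_rejected[ok_nests].sum())
    eggs_ok = int(ok_nests.sum()) * config.n_egg_host
    rejected_all = int(egg_rejected.sum())
    surviving = eggs_ok - rejected_ok
    return {
        "nests": n,
        "parasitized": int(parasitized.sum()),
        "doomed": n_doomed,
        "host_eggs": n * config.n_egg_host,
        "host_eggs_evaluated": eggs_ok,
        "host_eggs_rejected_in_ok_nests": rejected_ok,
        "host_eggs_rejected_all": rejected_all,
        "surviving": surviving,
    }


def simulate(config: SimConfig) -> SimOutcome:
    """Run the individual-based simulation; deterministic given config.seed."""
    t1 = np.empty(config.n_replicates)
    t2 = np.empty(config.n_replicates)
    succ = np.empty(config.n_replicates)
    totals: dict[str, int] = {}
    for rep in range(config.n_replicates):
        rng = substream(config.seed, "ibm.simulate", rep)
        c = _run_replicate(config, rng)
        for k, v in c.items():
            totals[k] = totals.get(k, 0) + v
        t2[rep] = c["doomed"] / c["nests"]
        if config.type1_denominator == "conditional":
            t1[rep] = (c["host_eggs_rejected_in_ok_nests"] /
                       c["host_eggs_evaluated"]) \
                if c["host_eggs_evaluated"] else np.nan
        else:
            t1[rep] = c["host_eggs_rejected_all"] / c["host_eggs"]
        succ[rep] = c["surviving"] / c["host_eggs"]

    per = {"type1": t1, "type2": t2, "success": succ}
    mc_se = {k: float(np.nanstd(v, ddof=1) / math.sqrt(len(v)))
             if len(v) > 1 else float("nan") for k, v in per.items()}
    return SimOutcome(
        type1_rate=float(np.nanmean(t1)),
        type2_rate=float(np.mean(t2)),
        success_rate=float(np.mean(succ)),
        per_replicate=per,
        mc_se=mc_se,
        counters=totals,
        config=config,
    )


def simulate_category_based(config: SimConfig,
                            n_categories: int = 2) -> SimOutcome:
    """Category-based rejection: binary/discrete perception of peaks.

    Forces sigma_cat = 0 and sigma_host = 0 so phenotypes are exactly the
    category values; with the threshold strictly between zero and the
    spacing between adjacent peaks, the threshold rule *is* category
    matching: own-category eggs are always accepted (zero Type I errors)
    and other-category eggs always rejected, so the expected overall
    Type II rate is p_parasitized / n_categories.  A threshold outside
    that regime falls back to plain threshold semantics with a warning.
    """
    dist = config.distribution
    d_cat = dist.d_cat if dist.shape == "categorical" and dist.d_cat > 0 \
        else dist.sigma_cont  # variance-matched binary by default
    cat = DistributionSpec(shape="categorical", mean=dist.mean,
                           d_cat=d_cat, sigma_cat=0.0,
                           n_categories=n_categories)
    cfg = replace(config, distribution=cat, sigma_host=0.0)
    if not 0.0 < cfg.threshold < cat.peak_spacing:
        warnings.warn(
            f"threshold {cfg.threshold} is outside the category-based "
            f"regime (0, {cat.peak_spacing:g}); plain threshold semantics "
            "apply", UserWarning, stacklevel=2)
    return simulate(cfg)


def sweep(config_base: SimConfig,
          thresholds: Sequence[float],
          shapes: Optional[Sequence[tuple[float, float]]] = None,
          ) -> pd.DataFrame:
    """Error-rate curves over a threshold grid, per distribution shape.

    ``shapes`` is a list of (d_cat, sigma_cat) pairs; each categorical
    shape is paired with its variance-matched continuous partner
    (sigma_cont^2 = d_cat^2 + sigma_cat^2).  With ``shapes=None`` only the
    base config's distribution is swept.  Returns a long-format table with
    one row per (shape, distribution, threshold).
    """
    thresholds = np.asarray(list(thresholds), dtype=float)
    if np.any(np.diff(thresholds) < 0):
        warnings.warn("threshold grid was not sorted; sorting",
                      UserWarning, stacklevel=2)
        thresholds = np.sort(thresholds)

    runs: list[tuple[str, DistributionSpec]] = []
    if shapes is None:
        runs.append(("base", config_base.distribution))
    else:
        for d_cat, sigma_cat in shapes:
            cat = DistributionSpec(
                shape="categorical", mean=config_base.distribution.mean,
                d_cat=d_cat, sigma_cat=sigma_cat)
            label = f"d={d_cat:g},sd={sigma_cat:g}"
            runs.append((label, cat))
            runs.append((label, cat.matched_continuous()))

    rows = []
    for label, dist in runs:
        for i, thr in enumerate(thresholds):
            cfg = replace(config_base, distribution=dist,
                          threshold=float(thr),
                          seed=int(substream(
                              config_base.seed, "ibm.sweep", label,
                              dist.shape, i).integers(0, 2 ** 31)))
            out = simulate(cfg)
            rows.append({
                "shape": label,
                "distribution": dist.shape,
                "threshold": float(thr),
                "type1": out.type1_rate,
                "type2": out.type2_rate,
                "success": out.success_rate,
                "se_type1": out.mc_se["type1"],
                "se_type2": out.mc_se["type2"],
                "se_success": out.mc_se["success"],
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Closed-form companions
# --------------------------------------------------------------------------

def oracle_type1(threshold: float, sigma_host: float) -> float:
    """Expected Type I rate: P(|Normal(0, sigma_host)| > threshold).

    Host-egg deviations are independent of the genotype, so the Type I
    rate is 2(1 - Phi(threshold / sigma_host)) regardless of the genotype
    distribution's shape.  For sigma_host = 0 the rate is a step: 0 if the
    threshold is positive, else 1 (boundary ties accepted).
    """
    if sigma_host < 0:
        raise ValueError("sigma_host must be >= 0")
    if sigma_host == 0.0:
        return 0.0 if threshold >= 0.0 else 1.0
    return float(2.0 * (1.0 - norm.cdf(threshold / sigma_host)))


def oracle_type2(threshold: float, spec: DistributionSpec,
                 p_parasitized: float) -> float:
    """Expected overall Type II rate: p * P(|P_geno - H_geno| <= threshold).

    The difference of two independent genotype draws is Normal(0,
    sqrt(2) * sigma_cont) in the continuous case; for a two-peak
    categorical distribution it is the equal-weight mixture of
    Normal(0, sqrt(2) sigma_cat) (same peak, prob 1/2) and
    Normal(+/- 2 d_cat, sqrt(2) sigma_cat) (opposite peaks, prob 1/4 each).
    """
    t = threshold
    if spec.shape == "continuous":
        s = math.sqrt(2.0) * spec.sigma_cont
        return float(p_parasitized * (2.0 * norm.cdf(t / s) - 1.0))
    if spec.n_categories != 2:
        # general K equal peaks: difference is a mixture over peak pairs
        peaks = spec.peak_positions()
        k = len(peaks)
        s = math.sqrt(2.0) * spec.sigma_cat
        acc = 0.0
        for a in peaks:
            for b in peaks:
                delta = a - b
                if s > 0:
                    acc += norm.cdf((t - delta) / s) - norm.cdf((-t - delta) / s)
                else:
                    acc += 1.0 if abs(delta) <= t else 0.0
        return float(p_parasitized * acc / (k * k))
    d, s = spec.d_cat, math.sqrt(2.0) * spec.sigma_cat
    if s == 0.0:
        pr = 0.5 * (1.0 if t >= 0 else 0.0) + 0.5 * (1.0 if t >= 2 * d else 0.0)
        return float(p_parasitized * pr)
    pr = 0.5 * (norm.cdf(t / s) - norm.cdf(-t / s)) \
        + 0.25 * (norm.cdf((t - 2 * d) / s) - norm.cdf((-t - 2 * d) / s)) \
        + 0.25 * (norm.cdf((t + 2 * d) / s) - norm.cdf((-t + 2 * d) / s))
    return float(p_parasitized * pr)
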
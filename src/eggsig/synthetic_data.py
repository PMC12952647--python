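"""Synthetic egg-phenotype generator.

Generates clutch-structured egg trait tables, parasite eggs, and simulated
egg-swap rejection experiments with known ground truth.  The generator
emulates the statistical structure that the downstream analyses assume:

* each clutch (laying female) has one latent genotype per trait, drawn from
  a continuous (normal) or categorical (peak-mixture) population
  distribution;
* egg phenotypes scatter around the clutch genotype with normal
  within-clutch noise (sigma set per trait);
* categorical traits record their ground-truth mixture component, so tests
  can score category matches exactly;
* traits can be structurally missing for whole clutches (e.g. immaculate
  eggs carry no marking traits);
* experiment outcomes are Bernoulli draws from a known logistic rejection
  rule applied to absolute trait differences, with optionally biased
  (non-random) assignment of experimental eggs to host clutches.

All randomness flows from one root seed; every operation draws from its own
substream keyed by a stable operation name, so adding operations never
perturbs existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "ConfigurationError",
    "immaculate_rule",
    "generate_population",
    "generate_parasite_eggs",
    "generate_experiments",
    "substream",
]

_VARIANCE_RTOL = 1e-9


class ConfigurationError(ValueError):
    """Raised when a trait specification violates its invariants."""


def substream(seed: int, *key: object) -> np.random.Generator:
    """Independent RNG substream derived from ``seed`` and a stable key.

    The key (operation name, replicate index, ...) is hashed with CRC32 so
    that substreams do not depend on call order.
    """
    words = [int(seed) & 0x7FFFFFFF]
    for part in key:
        words.append(zlib.crc32(repr(part).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


# --------------------------------------------------------------------------
# Trait specifications
# --------------------------------------------------------------------------

@dataclass
class TraitSpec:
    """Population distribution of one egg trait.

    ``kind`` selects the genotype distribution:

    - ``continuous``: Normal(population_mean, overall_sd).
    - ``categorical2``: equal mixture of Normal(mean - d, s) and
      Normal(mean + d, s) with d = ``peak_half_distance`` and
      s = ``within_peak_sd``; the variance-matching constraint
      s**2 + d**2 == overall_sd**2 must hold, so a categorical trait is
      directly comparable to a continuous one of the same overall spread.
    - ``categoricalK``: ``n_categories`` equally frequent peaks evenly
      spaced on [mean - d, mean + d], each with sd ``within_peak_sd``
      (no variance constraint is imposed for K > 2).

    ``within_clutch_sd`` is the phenotypic scatter of eggs around the
    clutch genotype.  ``missing_rule`` optionally marks whole clutches as
    structurally missing this trait (see :func:`immaculate_rule`).
    """

    name: str
    kind: str = "continuous"
    population_mean: float = 0.5
    overall_sd: float = 0.25
    peak_half_distance: float = 0.0
    within_peak_sd: float = 0.0
    n_categories: int = 2
    within_clutch_sd: float = 0.0
    missing_rule: Optional[Callable[[np.ndarray, np.random.Generator], np.ndarray]] = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def is_categorical(self) -> bool:
        return self.kind in ("categorical2", "categoricalK")

    def validate(self) -> None:
        if self.kind not in ("continuous", "categorical2", "categoricalK"):
            raise ConfigurationError(
                f"trait {self.name!r}: unknown kind {self.kind!r}")
        if not self.overall_sd > 0:
            raise ConfigurationError(
                f"trait {self.name!r}: overall_sd must be > 0")
        if self.within_clutch_sd < 0:
            raise ConfigurationError(
                f"trait {self.name!r}: within_clutch_sd must be >= 0")
        if self.is_categorical:
            if self.peak_half_distance < 0 or self.within_peak_sd < 0:
                raise ConfigurationError(
                    f"trait {self.name!r}: peak_half_distance and "
                    "within_peak_sd must be >= 0")
        if self.kind == "categorical2":
            target = self.overall_sd ** 2
            got = self.within_peak_sd ** 2 + self.peak_half_distance ** 2
            if abs(got - target) > _VARIANCE_RTOL * max(target, 1.0):
                raise ConfigurationError(
                    f"trait {self.name!r}: variance constraint violated: "
                    f"within_peak_sd^2 + peak_half_distance^2 = {got:.12g} "
                    f"but overall_sd^2 = {target:.12g}")
        if self.kind == "categoricalK" and self.n_categories < 2:
            raise ConfigurationError(
                f"trait {self.name!r}: n_categories must be >= 2")

    def peak_positions(self) -> np.ndarray:
        """Genotype peak locations for categorical kinds."""
        if self.kind == "categorical2":
            return np.array([
                self.population_mean - self.peak_half_distance,
                self.population_mean + self.peak_half_distance,
            ])
        if self.kind == "categoricalK":
            k = self.n_categories
            offsets = np.linspace(-1.0, 1.0, k)
            return self.population_mean + self.peak_half_distance * offsets
        raise ConfigurationError(f"trait {self.name!r} is not categorical")

    def draw_genotypes(self, n: int, rng: np.random.Generator):
        """Return (genotypes, categories); categories is None if continuous."""
        if self.kind == "continuous":
            return rng.normal(self.population_mean, self.overall_sd, n), None
        peaks = self.peak_positions()
        cats = rng.integers(0, len(peaks), n)
        geno = peaks[cats] + rng.normal(0.0, self.within_peak_sd, n) \
            if self.within_peak_sd > 0 else peaks[cats].astype(float)
        return geno, cats


def immaculate_rule(fraction: float, tag: str = "immaculate"):
    """Missing rule marking a given fraction of clutches as immaculate.

    Immaculate eggs have no markings, so marking-dependent traits cannot be
    measured for them; the rule fires per clutch (structural missingness),
    deterministically given the generator's substream.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("immaculate fraction must be in [0, 1]")

    def rule(clutch_ids: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return rng.random(len(clutch_ids)) < fraction

    rule.tag = tag  # type: ignore[attr-defined]
    return rule


# --------------------------------------------------------------------------
# Population and parasite generation
# --------------------------------------------------------------------------

def _validate_specs(specs: Sequence[TraitSpec]) -> None:
    if not specs:
        raise ConfigurationError("at least one TraitSpec is required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate trait names in specs: {names}")
    for s in specs:
        s.validate()


def generate_population(
    specs: Sequence[TraitSpec],
    n_clutches: int,
    eggs_per_clutch: int,
    seed: int,
) -> pd.DataFrame:
    """Generate a host egg table with clutch structure.

    Each clutch gets one latent genotype per trait from the spec's
    population distribution; each egg's trait value is the genotype plus
    Normal(0, within_clutch_sd) noise.  Structural missingness is applied
    after the noise layer.  Returns one row per egg with columns
    ``clutch_id, egg_id, role, category_<trait> (categorical traits only),
    <trait> ...``; the run is bit-reproducible given ``seed``.
    """
    if n_clutches < 1 or eggs_per_clutch < 1:
        raise ConfigurationError("n_clutches and eggs_per_clutch must be >= 1")
    _validate_specs(specs)

    clutch_ids = np.array([f"C{i:05d}" for i in range(n_clutches)])
    n_eggs = n_clutches * eggs_per_clutch
    out = pd.DataFrame({
        "clutch_id": np.repeat(clutch_ids, eggs_per_clutch),
        "egg_id": [f"C{i:05d}-E{j}" for i in range(n_clutches)
                   for j in range(eggs_per_clutch)],
        "role": "host",
    })

    for spec in specs:
        rng = substream(seed, "generate_population", spec.name)
        geno, cats = spec.draw_genotypes(n_clutches, rng)
        values = np.repeat(geno, eggs_per_clutch)
        if spec.within_clutch_sd > 0:
            values = values + rng.normal(0.0, spec.within_clutch_sd, n_eggs)
        cat_col = None
        if cats is not None:
            cat_col = np.repeat(cats, eggs_per_clutch).astype(float)
        if spec.missing_rule is not None:
            miss_rng = substream(seed, "missing_rule", spec.name)
            clutch_missing = np.asarray(
                spec.missing_rule(clutch_ids, miss_rng), dtype=bool)
            egg_missing = np.repeat(clutch_missing, eggs_per_clutch)
            values = np.where(egg_missing, np.nan, values)
            if cat_col is not None:
                cat_col = np.where(egg_missing, np.nan, cat_col)
        if cat_col is not None:
            out[f"category_{spec.name}"] = cat_col
        out[spec.name] = values
    return out


def generate_parasite_eggs(
    specs: Sequence[TraitSpec],
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Generate parasite eggs: one egg per parasite, phenotype == genotype.

    Parasites share the host genotype distribution but have no within-clutch
    layer (each lays a single egg per nest in this framework).
    """
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    _validate_specs(specs)
    out = pd.DataFrame({
        "clutch_id": [f"P{i:05d}" for i in range(n)],
        "egg_id": [f"P{i:05d}-E0" for i in range(n)],
        "role": "parasite",
    })
    for spec in specs:
        rng = substream(seed, "generate_parasite_eggs", spec.name)
        geno, cats = spec.draw_genotypes(n, rng)
        if cats is not None:
            out[f"category_{spec.name}"] = cats.astype(float)
        out[spec.name] = geno
    return out


# --------------------------------------------------------------------------
# Simulated rejection experiments
# --------------------------------------------------------------------------

def _trait_columns(population: pd.DataFrame) -> list[str]:
    skip = {"clutch_id", "egg_id", "role"}
    return [c for c in population.columns
            if c not in skip and not c.startswith("category_")]


def _predict(model, abs_diffs: Mapping[str, float]) -> float:
    """Rejection probability from a fitted model or a plain callable."""
    if callable(model) and not hasattr(model, "predict"):
        return float(model(abs_diffs))
    return float(model.predict(abs_diffs, on_missing="drop"))


def generate_experiments(
    population: pd.DataFrame,
    true_model,
    assignment: str = "random",
    p_match: float = 0.5,
    match_trait: Optional[str] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one egg-swap experiment per host clutch.

    For each clutch, an experimental egg is drawn from a *different* clutch
    and its rejection is a Bernoulli draw with probability given by
    ``true_model`` applied to the absolute differences between the
    experimental egg and the host clutch mean.  ``assignment`` is
    ``"random"`` or ``"category_biased"``; under the biased scheme the donor
    matches the host's ground-truth category on ``match_trait`` (default:
    the first categorical trait) with probability ``p_match``, emulating the
    non-randomness that arises in the field when donor eggs are whatever
    clutches happen to be active.

    ``true_model`` is anything with a ``predict(abs_diffs, on_missing=...)``
    method (e.g. a fitted rejection model) or a plain callable mapping an
    abs-diff dict to a probability.
    """
    if assignment not in ("random", "category_biased"):
        raise ConfigurationError(f"unknown assignment scheme {assignment!r}")
    if assignment == "category_biased" and not 0.0 <= p_match <= 1.0:
        raise ConfigurationError("p_match must be in [0, 1]")
    clutches = population["clutch_id"].unique()
    if len(clutches) < 2:
        raise ConfigurationError(
            "need >= 2 clutches to draw foreign experimental eggs")
    traits = _trait_columns(population)

    cat_cols = [c for c in population.columns if c.startswith("category_")]
    if assignment == "category_biased":
        if match_trait is None:
            if not cat_cols:
                raise ConfigurationError(
                    "category_biased assignment requires a categorical trait")
            match_trait = cat_cols[0].removeprefix("category_")
        if f"category_{match_trait}" not in population.columns:
            raise ConfigurationError(
                f"no ground-truth category column for trait {match_trait!r}")

    hosts = population[population["role"] == "host"].reset_index(drop=True)
    clutch_ids = hosts["clutch_id"].unique()
    nc = len(clutch_ids)
    clutch_index = {c: i for i, c in enumerate(clutch_ids)}
    host_ci = hosts["clutch_id"].map(clutch_index).to_numpy()
    egg_values = hosts[traits].to_numpy(dtype=float)
    means = hosts.groupby("clutch_id", sort=False)[traits].mean() \
        .loc[clutch_ids].to_numpy(dtype=float)
    eggs_of = [np.flatnonzero(host_ci == i) for i in range(nc)]

    match_col = None
    if cat_cols:
        first_ct = match_trait if match_trait is not None \
            else cat_cols[0].removeprefix("category_")
        match_col = f"category_{first_ct}"
        clutch_cat = hosts.groupby("clutch_id", sort=False)[match_col] \
            .first().loc[clutch_ids].to_numpy()

    rng = substream(seed, "generate_experiments")
    # donor clutch per host clutch
    donors = np.empty(nc, dtype=int)
    if assignment == "random":
        donors = rng.integers(0, nc, nc)
        clash = donors == np.arange(nc)
        while clash.any():
            donors[clash] = rng.integers(0, nc, int(clash.sum()))
            clash = donors == np.arange(nc)
    else:
        by_cat: dict = {}
        for i, c in enumerate(clutch_cat):
            by_cat.setdefault(c, []).append(i)
        for i in range(nc):
            same = [j for j in by_cat.get(clutch_cat[i], []) if j != i]
            other = [j for j in range(nc)
                     if clutch_cat[j] != clutch_cat[i]]
            want_match = rng.random() < p_match
            pool = same if (want_match and same) else (other or same)
            donors[i] = pool[rng.integers(0, len(pool))]

    egg_rows = np.array([eggs_of[d][rng.integers(0, len(eggs_of[d]))]
                         for d in donors])
    egg_vals = egg_values[egg_rows]
    diffs = np.abs(egg_vals - means)

    if hasattr(true_model, "predict_many") and not np.isnan(diffs).any():
        diff_frame = pd.DataFrame(
            {f"diff_{t}": diffs[:, j] for j, t in enumerate(traits)})
        p_reject = np.asarray(true_model.predict_many(diff_frame))
    else:  # per-row path handles plain callables and missing traits
        p_reject = np.array([
            _predict(true_model, {t: diffs[i, j]
                                  for j, t in enumerate(traits)})
            for i in range(nc)])
    p_reject = np.clip(p_reject, 0.0, 1.0)
    rejected = rng.random(nc) < p_reject

    out = pd.DataFrame({
        "clutch_id": clutch_ids,
        "donor_clutch_id": clutch_ids[donors],
        "rejected": rejected,
    })
    if match_col is not None:
        egg_cat = hosts[match_col].to_numpy()[egg_rows]
        both = np.isfinite(clutch_cat.astype(float)) & \
            np.isfinite(egg_cat.astype(float))
        out["match_category"] = np.where(
            both, (clutch_cat == egg_cat).astype(float), np.nan)
    for j, t in enumerate(traits):
        out[f"host_{t}"] = means[:, j]
        out[f"egg_{t}"] = egg_vals[:, j]
        out[f"diff_{t}"] = diffs[:, j]
    return out
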
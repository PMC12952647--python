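# Methods

This note documents the models implemented in `eggsig`, the choices made
where the design was genuinely open, and what the synthetic-data-driven
test suite does and does not demonstrate.

## The recognition problem

A host inspecting its clutch faces a one-dimensional discrimination task
per trait: accept an egg if it is "its own", reject otherwise. Two error
rates summarise performance: Type I (rejecting an own egg) and Type II
(accepting a parasitic egg). The central question the package supports is
how the shape of the population distribution of a signature trait —
continuous (unimodal normal) versus categorical (a mixture of discrete
peaks) — changes the jointly achievable error rates, when hosts and
parasites draw from the *same* distribution (the worst case for classical
signal detection, where no likelihood-ratio rule beats chance at the
population level, but individual hosts still know their own phenotype).

## Synthetic data generator

The generator is the package's study population, not a fixture. Each
clutch (female) receives one latent genotype per trait:

* `continuous`: Normal(μ, σ);
* `categorical2`: equal mixture of Normal(μ − d, s) and Normal(μ + d, s)
  under the variance-matching constraint s² + d² = σ², enforced to 1e-9
  relative tolerance, so shape comparisons never confound overall
  variance;
* `categoricalK`: K equally frequent peaks evenly spaced on [μ − d, μ + d]
  (no variance constraint is imposed for K > 2; the K-category case is
  used for category-match accounting, e.g. the 1/6 match probability of
  six equal categories).

Egg phenotypes add Normal(0, σ_within-clutch) noise to the clutch
genotype; parasite eggs are their genotype exactly (one egg per nest, so
a within-clutch layer would be unidentifiable). The latent mixture
component is recorded as a ground-truth category column so tests can
score category matches exactly rather than re-inferring them from
phenotype.

Structural missingness is modelled per clutch: a missing rule (the
bundled preset marks a configurable fraction of clutches as
"immaculate", i.e. unmarked) removes a trait from every egg of the
affected clutches after the noise layer and touches nothing else. The
immaculate fraction has no authoritative empirical value; the preset
default used in tests (0.3–0.4) was chosen once as a plausible minority
fraction and is a free parameter.

Simulated egg-swap experiments replace one egg per host clutch with an
egg from a different clutch and draw the rejection outcome from a known
logistic rule applied to |experimental − clutch mean| per trait. Donor
assignment is uniform by default; the `category_biased` scheme matches
the host's category on a chosen trait with probability `p_match`,
emulating the documented non-randomness of field assignments (donor eggs
are whatever clutches are active that day), which inflates observed
acceptance rates relative to truly random recombination.

All randomness flows from one root seed through named substreams (CRC32
of the operation name mixed into a `SeedSequence`), so adding an
operation never perturbs another's draws and identical seeds give
bit-identical tables.

## Rejection models

`fit_logistic` is a maximum-likelihood binomial GLM (statsmodels IRLS,
relative log-likelihood tolerance 1e-8, 100 iterations) of rejection on
absolute trait differences, complete-case on the requested traits with
the dropped-row count reported. Standard errors come from the
observed-information Hessian; Wald z and p values are reported per
coefficient.

Quasi-complete separation is expected rather than exotic here: a
strongly categorical host that rejects nearly every different-category
egg yields data that an unpenalised logistic fit sends to infinity. Any
slope exceeding 15 in magnitude after convergence triggers a refit by a
small in-package Newton solver with an L2 penalty of 1e-6 on the slopes
(intercept unpenalised); the result is flagged `separation=True` and its
log-likelihood is the unpenalised value at the penalised estimate.

`select_model` fits every subset of up to 12 candidate traits on the
rows complete for *all* candidates (so AICc values are comparable),
ranks by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), and picks the simplest model
within 2 AICc of the minimum; ties on parameter count break by lower
AICc, then lexicographic subset order. Ambiguity in whether the
within-2 rule should use AIC or AICc deltas is resolved in favour of
AICc throughout. Fit quality is Nagelkerke's
R² = [1 − exp(2(L₀−L₁)/n)] / [1 − exp(2L₀/n)]. A correlation screen
reports pairwise predictor R² and warns above 0.4 without excluding
anything (exclusion is an analyst decision).

Missing-prone traits support two strategies mirroring how immaculate
clutches are handled: drop incomplete rows, or run two selections (all
rows without the missing-prone trait; complete rows with it).

## Categoricality battery

Traits are tested one at a time; the upstream correlation screen is the
justification for univariate analysis.

**Clustering.** PAM (k-medoids) on the absolute-difference
dissimilarity, BUILD initialisation plus first-descent SWAP to a local
optimum — deterministic given input order. The average silhouette width
selects k in [2, k_max=10]; because silhouette cannot score k = 1, the
Duda–Hart test on the 2-cluster split arbitrates homogeneity at
α = 0.05 (p > α reports one cluster). The Duda–Hart statistic is
Je(2)/Je(1) with the one-dimensional normal approximation
z = [1 − Je(2)/Je(1) − 2/π] / √(2(1 − 8/π²)/n), one-sided p = 1 − Φ(z).

**Dip test.** The dip is min over unimodal CDFs G (convex up to the
mode, concave after; a jump permitted only at the mode) of
sup|F̂ₙ − G|. It is computed exactly by bisection on the sup-norm radius
ε: a radius is feasible iff some convex-then-concave CDF threads the
tube [i/n − ε, (i−1)/n + ε] around the ECDF, checked by an incremental
convex-hull scan over every candidate mode atom plus a convexity-chain
bound coupling the two sides at the mode. The implementation was
verified against an independent linear-programming oracle (direct
minimax fit per candidate mode, including grid positions inside gaps) on
hundreds of randomized cases including heavy ties, with exact agreement;
a trimmed oracle ships in the test suite. p-values are Monte-Carlo: the
fraction of `n_null` = 2000 uniform(0,1) samples of the same n with dip
at least the observed (p-value SE ≤ 0.011), rather than interpolation
tables; the null sample is cached per (n, n_null, seed). The dip is
exactly invariant to increasing affine transforms, but *not* to general
monotone transforms (they change the convexity structure of the ECDF),
so the test suite asserts affine invariance.

**Silverman's test.** The critical bandwidth h_crit(k) is the smallest
Gaussian-KDE bandwidth with at most k modes, found by bisection to
relative tolerance 1e-4 (valid because the Gaussian-kernel mode count is
non-increasing in bandwidth; the neighborhood of the solution is
re-checked and a diagnostic is raised on violations, which would
indicate grid artifacts). Modes are counted on a bandwidth-adaptive grid
(spacing ≈ h/4, 512–8192 points). The p-value is the variance-rescaled
smoothed bootstrap: resample, add kernel noise at the test bandwidth,
rescale to the sample variance, and count the KDE's modes at that same
bandwidth; p is the fraction of 100 bootstrap replicates with more than
k modes. For the one-mode null the test bandwidth is λ(α)·h_crit with
the Hall–York multiplicative calibration, implemented as a rational
approximation to the calibration curve (λ(0.05) ≈ 1.095); a Monte-Carlo
calibration utility (`hall_york_factor_mc`) reproduces the simulation
route to the factor and serves as a cross-check. With this calibration
the measured rejection rate on unimodal normal samples (n = 200) sits
near the nominal 5% (the uncalibrated test is conservative).

## Error-rate estimators

`estimate_type2` substitutes phenotypes into a fitted model: each
combination pairs a random host egg (the clutch representative) with a
foreign egg — a real parasite egg (one per nest when several exist,
seeded pick) or, in proxy mode, a host egg from a *different* clutch,
which equalises mimetic accuracy across host species by assuming the
parasite matches the host distribution. The estimate is the mean of
1 − P(reject) over 1,000 combinations by default (acceptance
*probabilities* are averaged directly; no 0.5 thresholding is applied,
because the quantity of interest is the expected error rate). An
exhaustive mode averages over all valid ordered pairs and serves as the
oracle in tests. The SE is the subsample bootstrap: 100 means of 100
resampled combinations, reported as their sample SD.

`estimate_type1` produces one estimate per clutch with at least two
measured eggs (single-egg clutches are excluded and counted): the
model's rejection probability for a random within-clutch pair. A trait
measured only on a subset of clutches (color, via spectrophotometry) is
supported by pooling its within-clutch differences and assigning them to
pairs at random; this shortcut is valid only under trait independence,
so the estimator warns when |r| between the pooled trait and any other
model trait reaches 0.3.

`observed_rate` is the plain frequency with SE = √(p(1−p)/n).

## Individual-based simulation

Per nest: a host genotype H, a clutch of 3 host eggs H + Normal(0,
σ_host = 0.25), and with probability p = 0.5 a parasite genotype P from
the same distribution laying one egg equal to P. The host accepts any
egg within the closed interval [H − t, H + t]. Accounting is
hierarchical: an accepted parasitic egg dooms the clutch (Type II, per
nest); otherwise each host egg is inspected (rejected → Type I). The
overall Type II rate is doomed nests over all nests (ceiling p); the
Type I rate divides rejected host eggs by host eggs in non-doomed nests
(the effect-relevant denominator — switchable to all eggs, with
identical expectation since within-clutch noise is independent of the
parasite draw); the success rate is surviving host eggs over all host
eggs, a joint probability deliberately not equal to 1 − (TypeI + TypeII).
Defaults (1,000 replicates × 1,000 nests = 10⁶ nesting events) run in
well under a minute on one CPU; Monte-Carlo SEs are the across-replicate
SD divided by √replicates, with per-replicate seed substreams.

Category-based rejection sets σ_cat = σ_host = 0 so phenotypes are
exactly the category values; with 0 < t < the inter-peak spacing the
threshold rule *is* category matching: Type I is identically zero and
the expected overall Type II rate is p/K. The parasite's category is
uniform (parasites lay at random with respect to host phenotype).
Thresholds are strict (closed interval); boundary ties only matter in
the σ = 0 binary case, where acceptance requires exact category
identity.

Closed-form oracles: Type I = 2(1 − Φ(t/σ_host)) independent of the
genotype distribution's shape (which is why the Type I curves of
categorical and matched continuous populations coincide); Type II =
p · P(|P − H| ≤ t) from the convolution — Normal(0, √2 σ_cont) for the
continuous case, and for a two-peak mixture the equal-weight mixture of
Normal(0, √2 σ_cat) and Normal(±2d, √2 σ_cat) with weights 1/2, 1/4,
1/4. Simulation output is tested against both across threshold grids.

## Numerical and testing choices

* Problem sizes in tests were chosen to make each check sharp but cheap:
  10⁶ nesting events for simulation anchors, 250 replicates per oracle
  grid point, 100–200 replicates for calibration/power studies, n = 500
  datasets for recovery studies. The acceptance script uses the default
  10⁶-event configuration per quantity.
* Stochastic equivalence checks use 3 Monte-Carlo SEs for a single
  quantity; joint checks across a grid widen the per-comparison band to
  3.7 SE (Šidák-style) so the family-wise false-failure rate matches a
  single 3-SE check.
* Degenerate inputs: constant traits report one cluster with a
  degenerate flag; all-tied samples have dip 0 by convention (a point
  mass is unimodal) with a warning; zero-width thresholds and σ_host = 0
  take the documented step-function limits.
* The dip's bisection runs to absolute tolerance 1e-11 and its inner
  kernels are JIT-compiled when numba is available (pure-Python
  fallback otherwise, identical results).

## What the synthetic tests do not show

The generator emulates the statistical structure of egg-signature data —
clutch structure, within-clutch consistency, shape-controlled population
distributions, structural missingness, biased assignment — but not its
measurement process: no spectral or image quantification, no
receptor-noise (JND) scaling, no observer error, no correlated
multi-trait architecture beyond what the user configures, and no
between-year or spatial structure. Passing tests therefore demonstrate
that the estimators and simulations are correct and well-calibrated
under the stated model, not that any particular field system satisfies
that model. Species-level empirical error rates require the deposited
field dataset and are outside the package's scope, as are evolutionary
dynamics (no selection or inheritance: the simulation estimates error
rates, not fitness consequences).
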
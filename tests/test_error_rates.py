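import math

import numpy as np
import pandas as pd
import pytest

from eggsig import (
    RejectionModel,
    TraitSpec,
    bootstrap_se,
    estimate_type1,
    estimate_type2,
    generate_experiments,
    generate_parasite_eggs,
    generate_population,
    observed_rate,
)

REJECT_ALL = RejectionModel(intercept=np.inf, coefficients={"a": 0.0})


def category_model(spacing, trait="t"):
    """Logistic surrogate of 'reject iff category differs': the rejection
    probability is ~0 at zero difference and ~1 beyond half a peak
    spacing."""
    return RejectionModel(intercept=-60.0,
                          coefficients={trait: 120.0 / spacing})


class TestObservedRate:
    def test_field_style_counts(self):
        est = observed_rate(36, 90)
        assert est.point == pytest.approx(0.4)
        assert est.se == pytest.approx(math.sqrt(0.4 * 0.6 / 90), abs=1e-12)

    @pytest.mark.parametrize("s,n,point,se", [
        (0, 50, 0.0, 0.0),
        (50, 100, 0.5, 0.05),
    ])
    def test_edge_and_half(self, s, n, point, se):
        est = observed_rate(s, n)
        assert (est.point, est.se) == (point, se)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            observed_rate(1, 0)
        with pytest.raises(ValueError):
            observed_rate(5, 3)


class TestEstimateType2:
    def test_reject_everything_gives_zero(self, small_population):
        est = estimate_type2(REJECT_ALL, small_population, n_combos=200,
                             seed=1)
        assert est.point == 0.0

    def test_six_categories_acceptance_one_sixth(self):
        spec = TraitSpec(name="t", kind="categoricalK", n_categories=6,
                         population_mean=0.5, overall_sd=0.25,
                         peak_half_distance=0.5, within_peak_sd=0.0,
                         within_clutch_sd=0.0)
        pop = generate_population([spec], 3000, 1, seed=7)
        model = category_model(spec.peak_positions()[1]
                               - spec.peak_positions()[0])
        est = estimate_type2(model, pop, n_combos=6000, seed=8)
        p = 1.0 / 6.0
        se = math.sqrt(p * (1 - p) / 6000)
        assert abs(est.point - p) < 3 * se

    def test_exhaustive_matches_independent_brute_force(
            self, small_population, known_model):
        est = estimate_type2(known_model, small_population, exhaustive=True)
        # independent brute force: plain double loop over ordered pairs
        vals = []
        rows = small_population.to_dict("records")
        for h in rows:
            for f in rows:
                if h["clutch_id"] == f["clutch_id"]:
                    continue
                diff = abs(f["a"] - h["a"])
                vals.append(1 - 1 / (1 + math.exp(
                    -(known_model.intercept
                      + known_model.coefficients["a"] * diff))))
        assert est.point == pytest.approx(np.mean(vals), abs=1e-12)
        assert est.n_units == len(vals)

    def test_monte_carlo_converges_to_exhaustive(
            self, small_population, known_model):
        ex = estimate_type2(known_model, small_population, exhaustive=True)
        mc = estimate_type2(known_model, small_population, n_combos=4000,
                            seed=9)
        sd = np.std(ex.values)
        assert abs(mc.point - ex.point) < 3 * sd / math.sqrt(4000)

    def test_proxy_mode_needs_two_clutches(self, continuous_spec,
                                           known_model):
        pop = generate_population([continuous_spec], 1, 4, seed=2)
        with pytest.raises(ValueError, match="clutches"):
            estimate_type2(known_model, pop, seed=1)

    def test_proxy_equivalence_with_real_parasites(self, continuous_spec,
                                                   known_model):
        # parasites drawn from the host distribution: proxy and parasite
        # modes should agree within combined Monte-Carlo error
        pop = generate_population([continuous_spec], 400, 3, seed=14)
        para = generate_parasite_eggs([continuous_spec], 400, seed=15)
        a = estimate_type2(known_model, pop, n_combos=4000, seed=16)
        b = estimate_type2(known_model, pop, foreign_eggs=para,
                           n_combos=4000, seed=17)
        se = math.hypot(np.std(a.values) / math.sqrt(a.n_units),
                        np.std(b.values) / math.sqrt(b.n_units))
        assert abs(a.point - b.point) < 3 * se

    def test_monotone_in_model_strength(self, small_population):
        weak = RejectionModel(intercept=-1.0, coefficients={"a": 2.0})
        strong = RejectionModel(intercept=-1.0, coefficients={"a": 5.0})
        w = estimate_type2(weak, small_population, exhaustive=True)
        s = estimate_type2(strong, small_population, exhaustive=True)
        assert s.point <= w.point


class TestEstimateType1:
    def test_zero_variation_with_zero_pool(self, known_model):
        spec = TraitSpec(name="a", population_mean=0.5, overall_sd=0.25,
                         within_clutch_sd=0.0)
        pop = generate_population([spec], 30, 3, seed=4)
        est = estimate_type1(known_model, pop, color_diff_pool=[0.0],
                             color_trait="a", seed=5)
        assert est.point == pytest.approx(known_model.predict({"a": 0.0}))

    def test_reject_everything_gives_one_per_clutch(self, small_population):
        est = estimate_type1(REJECT_ALL, small_population, seed=6)
        assert est.point == 1.0
        assert np.all(est.values == 1.0)

    def test_single_egg_clutches_excluded(self, continuous_spec,
                                          known_model):
        pop = generate_population([continuous_spec], 20, 2, seed=7)
        pop = pop.drop(pop[pop["clutch_id"] == pop["clutch_id"].iloc[0]]
                       .index[1:])
        est = estimate_type1(known_model, pop, seed=8)
        assert est.n_excluded == 1
        assert est.n_units == 19

    def test_pooled_color_matches_direct_simulation(self):
        # pooling within-clutch color differences across clutches should
        # reproduce a direct estimate that keeps each clutch's own values
        col = TraitSpec(name="col", population_mean=0.5, overall_sd=0.25,
                        within_clutch_sd=0.08)
        pat = TraitSpec(name="pat", population_mean=0.5, overall_sd=0.25,
                        within_clutch_sd=0.08)
        pop = generate_population([col, pat], 600, 3, seed=9)
        model = RejectionModel(intercept=-2.0,
                               coefficients={"col": 4.0, "pat": 4.0})
        direct = estimate_type1(model, pop, seed=10)
        pool = np.abs(np.random.default_rng(3).normal(
            0, 0.08 * math.sqrt(2), 2000))
        pooled = estimate_type1(model, pop, color_diff_pool=pool,
                                color_trait="col", seed=11)
        se = math.hypot(direct.se, pooled.se)
        assert abs(direct.point - pooled.point) < 3 * se

    def test_pooling_warns_when_traits_correlated(self, rng):
        base = rng.normal(0.5, 0.25, 300)
        pop = pd.DataFrame({
            "clutch_id": np.repeat([f"C{i}" for i in range(150)], 2),
            "egg_id": [f"E{i}" for i in range(300)],
            "role": "host",
            "col": base,
            "pat": base + rng.normal(0, 0.05, 300),
        })
        model = RejectionModel(intercept=-2.0,
                               coefficients={"col": 1.0, "pat": 1.0})
        with pytest.warns(UserWarning, match="independence"):
            estimate_type1(model, pop, color_diff_pool=[0.1],
                           color_trait="col", seed=12)


class TestBootstrapSe:
    def test_constant_values(self):
        assert bootstrap_se(np.full(1000, 0.3), seed=1) == 0.0

    def test_bernoulli_matches_sampling_theory(self):
        rng = np.random.default_rng(13)
        values = rng.integers(0, 2, 1000).astype(float)
        se = bootstrap_se(values, subsample=100, reps=100, seed=2)
        assert abs(se - 0.05) / 0.05 < 0.3

    def test_subsample_larger_than_population_allowed(self):
        assert bootstrap_se([0.0, 1.0], subsample=100, reps=50, seed=3) > 0

    @pytest.mark.parametrize("kwargs", [
        {"reps": 1}, {"subsample": 0},
    ])
    def test_degenerate_parameters_error(self, kwargs):
        with pytest.raises(ValueError):
            bootstrap_se([0.1, 0.2], **{"seed": 1, **kwargs})

    def test_empty_values_error(self):
        with pytest.raises(ValueError):
            bootstrap_se([], seed=1)


class TestAssignmentBias:
    def test_biased_experiments_overestimate_type2(self):
        # matched experimental eggs make the observed acceptance rate
        # exceed the model-substitution estimate under random recombination
        # six equal categories: random recombination accepts ~1/6, while
        # assignments matching the host category 42% of the time inflate
        # the observed acceptance toward 0.42
        spec = TraitSpec(name="t", kind="categoricalK", n_categories=6,
                         population_mean=0.5, overall_sd=0.25,
                         peak_half_distance=0.5, within_peak_sd=0.0,
                         within_clutch_sd=0.0)
        spacing = 2 * 0.5 / 5
        model = category_model(spacing)
        wins = 0
        reps = 30
        for i in range(reps):
            pop = generate_population([spec], 90, 3, seed=100 + i)
            exps = generate_experiments(pop, model,
                                        assignment="category_biased",
                                        p_match=0.42, seed=200 + i)
            observed_acc = observed_rate(
                int((~exps["rejected"]).sum()), len(exps)).point
            est = estimate_type2(model, pop, n_combos=1000, seed=300 + i)
            wins += observed_acc > est.point
        assert wins / reps > 0.9
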
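import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eggsig import (
    RejectionModel,
    TraitSpec,
    aicc,
    correlation_screen,
    fit_logistic,
    fit_rejection,
    generate_experiments,
    generate_population,
    immaculate_rule,
    nagelkerke_r2,
    predict_rejection,
    select_model,
)
from eggsig.rejection_model import FitError


def _logistic_data(rng, n, intercept, coefs, noise_traits=()):
    cols = {f"diff_{t}": rng.random(n) for t in list(coefs) + list(noise_traits)}
    eta = intercept + sum(b * cols[f"diff_{t}"] for t, b in coefs.items())
    cols["rejected"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame(cols)


class TestAicc:
    @pytest.mark.parametrize("ll,k,n,expected", [
        (-5.0, 2, 10, 14 + 12 / 7),        # direct formula evaluation
        (-5.0, 0, 10, 10.0),               # zero-parameter limit: AIC
        (-5.0, 2, 10**9, 14.0 + 1.2e-8),   # large-n limit approaches AIC
    ])
    def test_formula(self, ll, k, n, expected):
        assert aicc(ll, k, n) == pytest.approx(expected, rel=1e-6)

    def test_undefined_below_k_plus_one(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 4, 5)


class TestFitLogistic:
    def test_two_by_two_table_closed_form(self):
        # 40/10 rejected at diff=1, 10/40 at diff=0: slope = log OR = log 16
        rows = ([{"rejected": 1, "diff_a": 1.0}] * 40
                + [{"rejected": 0, "diff_a": 1.0}] * 10
                + [{"rejected": 1, "diff_a": 0.0}] * 10
                + [{"rejected": 0, "diff_a": 0.0}] * 40)
        m = fit_logistic(pd.DataFrame(rows), ["a"])
        assert m.coefficients["a"] == pytest.approx(math.log(16.0), abs=1e-6)
        assert m.intercept == pytest.approx(math.log(10 / 40), abs=1e-6)
        assert m.log_likelihood <= 0

    def test_null_data_gives_null_model(self, rng):
        d = _logistic_data(rng, 4000, 0.0, {"a": 0.0})
        m = fit_logistic(d, ["a"])
        assert abs(m.intercept) < 0.2
        assert abs(m.coefficients["a"]) < 0.35

    def test_parameter_recovery(self):
        spec = TraitSpec(name="a", population_mean=0.5, overall_sd=0.25,
                         within_clutch_sd=0.05)
        pop = generate_population([spec], 2000, 3, seed=3)
        true = RejectionModel(intercept=-2.0, coefficients={"a": 4.0})
        exps = generate_experiments(pop, true, seed=3)
        m = fit_logistic(exps, ["a"])
        assert m.intercept == pytest.approx(-2.0, abs=0.3)
        assert m.coefficients["a"] == pytest.approx(4.0, abs=0.3)

    def test_one_class_outcome_errors(self):
        d = pd.DataFrame({"rejected": [1.0] * 20, "diff_a": range(20)})
        with pytest.raises(FitError, match="single class"):
            fit_logistic(d, ["a"])

    def test_missing_rows_dropped_and_counted(self, rng):
        d = _logistic_data(rng, 200, 0.0, {"a": 1.0})
        d.loc[:19, "diff_a"] = np.nan
        m = fit_logistic(d, ["a"])
        assert m.n_dropped == 20
        assert m.n_obs == 180

    def test_separation_flagged_and_capped(self, rng):
        n = 200
        x = rng.random(n)
        d = pd.DataFrame({"diff_a": x, "rejected": (x > 0.5).astype(float)})
        with pytest.warns(RuntimeWarning, match="separation"):
            m = fit_logistic(d, ["a"])
        assert m.separation
        assert np.isfinite(m.coefficients["a"])
        # still discriminates in the right direction
        assert m.coefficients["a"] > 0
        assert m.predict({"a": 1.0}) > 0.95 > 0.05 > m.predict({"a": 0.0})


class TestPredict:
    def test_point_values(self):
        m = RejectionModel(intercept=0.0, coefficients={"a": 1.0})
        assert m.predict({"a": 0.0}) == pytest.approx(0.5)
        # marking-size scale coefficient from the strongly categorical host
        m2 = RejectionModel(intercept=-2.2, coefficients={"size": 2.22})
        assert m2.predict({"size": 1.0}) == pytest.approx(
            1 / (1 + math.exp(-0.02)), abs=1e-12)

    def test_missing_trait_raises_with_name(self):
        m = RejectionModel(intercept=0.0, coefficients={"a": 1.0, "b": 2.0})
        with pytest.raises(KeyError, match="b"):
            predict_rejection(m, {"a": 0.3})

    @given(diff=st.floats(0, 10), bump=st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_positive_coefficient_diffs(self, diff, bump):
        m = RejectionModel(intercept=-1.0, coefficients={"a": 2.0})
        assert m.predict({"a": diff + bump}) >= m.predict({"a": diff})

    def test_probability_bounds(self):
        m = RejectionModel(intercept=500.0, coefficients={"a": 1000.0})
        assert m.predict({"a": 1e6}) == 1.0
        m2 = RejectionModel(intercept=-500.0, coefficients={"a": -1000.0})
        assert 0.0 <= m2.predict({"a": 1e6}) <= 1e-200


class TestNagelkerke:
    def test_values(self):
        m = RejectionModel(intercept=0, coefficients={}, n_obs=100,
                           log_likelihood=-40.0)
        expected = (1 - math.exp(-0.5862)) / (1 - math.exp(-1.3862))
        assert nagelkerke_r2(m, -69.31) == pytest.approx(expected, abs=1e-3)
        m.log_likelihood = -69.31
        assert nagelkerke_r2(m, -69.31) == 0.0
        m.log_likelihood = -1e-9
        assert nagelkerke_r2(m, -69.31) == pytest.approx(1.0, abs=1e-6)

    def test_likelihood_must_not_decrease(self):
        m = RejectionModel(intercept=0, coefficients={}, n_obs=100,
                           log_likelihood=-80.0)
        with pytest.raises(ValueError):
            nagelkerke_r2(m, -69.31)


class TestSelectModel:
    def test_zero_candidates_returns_intercept_only(self, rng):
        d = _logistic_data(rng, 100, 0.5, {})
        result = select_model(d, [])
        assert result.best.trait_subset == ()
        assert result.nagelkerke_r2 == 0.0

    def test_duplicated_predictor_prefers_single_trait(self, rng):
        d = _logistic_data(rng, 300, -1.0, {"a": 3.0})
        d["diff_b"] = d["diff_a"]
        result = select_model(d, ["a", "b"])
        assert len(result.best.trait_subset) == 1

    def test_simplest_within_two_invariant_holds(self, rng):
        d = _logistic_data(rng, 400, -1.0, {"a": 2.0},
                           noise_traits=["b", "c"])
        result = select_model(d, ["a", "b", "c"])
        best_k = len(result.best.trait_subset) + 1
        assert result.delta_table[result.best.trait_subset] <= 2.0
        for subset, a, k in result.candidates:
            if result.delta_table[subset] <= 2.0:
                assert k >= best_k

    # rescaling a predictor rescales its coefficient, which can trip the
    # scale-dependent separation detector; the refit is benign here
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_aicc_ordering_invariant_to_affine_rescaling(self, rng):
        d = _logistic_data(rng, 300, -1.0, {"a": 2.0}, noise_traits=["b"])
        r1 = select_model(d, ["a", "b"])
        d2 = d.copy()
        d2["diff_a"] = 100.0 * d2["diff_a"] - 3.0
        d2["diff_b"] = 0.01 * d2["diff_b"] + 7.0
        r2 = select_model(d2, ["a", "b"])
        for subset in r1.delta_table:
            assert r1.delta_table[subset] == pytest.approx(
                r2.delta_table[subset], abs=1e-6)


@pytest.fixture(scope="module")
def immaculate_experiments():
    lum = TraitSpec(name="lum", overall_sd=0.25, within_clutch_sd=0.05,
                    missing_rule=immaculate_rule(0.3))
    col = TraitSpec(name="col", overall_sd=0.25, within_clutch_sd=0.05)
    pop = generate_population([lum, col], 300, 3, seed=21)
    true = RejectionModel(intercept=-2.0,
                          coefficients={"lum": 3.0, "col": 3.0})
    return generate_experiments(pop, true, seed=21)


class TestMissingStrategies:
    def test_two_model_strategy_mirrors_immaculate_analysis(
            self, immaculate_experiments):
        out = fit_rejection(immaculate_experiments, ["lum", "col"],
                            missing_strategy="two-model",
                            missing_prone="lum")
        assert set(out) == {"all_rows", "complete_rows"}
        # the all-rows model never sees the missing-prone trait
        assert "lum" not in {t for s, _, _ in out["all_rows"].candidates
                             for t in s}
        # the complete-rows model uses fewer observations
        assert out["complete_rows"].n_obs < out["all_rows"].n_obs

    def test_drop_strategy_reports_complete_cases(
            self, immaculate_experiments):
        result = fit_rejection(immaculate_experiments, ["lum", "col"],
                               missing_strategy="drop")
        n_missing = immaculate_experiments["diff_lum"].isna().sum()
        assert result.n_obs == len(immaculate_experiments) - n_missing


class TestCorrelationScreen:
    def test_warns_on_collinear_pair(self, rng):
        a = rng.random(200)
        d = pd.DataFrame({"diff_a": a, "diff_b": a + rng.normal(0, 0.1, 200),
                          "diff_c": rng.random(200)})
        with pytest.warns(UserWarning, match="correlated"):
            table = correlation_screen(d, ["a", "b", "c"])
        r2 = table.set_index(["trait_a", "trait_b"])["r2"]
        assert r2[("a", "b")] > 0.4
        assert r2[("a", "c")] < 0.4
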
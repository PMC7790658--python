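"""Collinearity pruning, logistic fitting, stepwise selection, AUC, maps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hybridtrace.matrix import RasterGrid
from hybridtrace.sdm import (SeparationError, SpeciesDistributionModel, auc,
                             collinearity_prune, fit_logistic,
                             hindcast_stack)
from hybridtrace.simulate import SimEnvSpec, simulate_env_presence


class TestCollinearityPrune:
    def test_weakly_correlated_variables_all_retained(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame(rng.standard_normal((200, 4)),
                           columns=list("abcd"))
        retained, _ = collinearity_prune(env)
        assert retained == list("abcd")

    def test_duplicated_variable_collapsed_to_one(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        env = pd.DataFrame({"a": x, "b": np.exp(x),  # rank-identical
                            "c": rng.standard_normal(100)})
        retained, _ = collinearity_prune(env)
        assert len(retained) == 2
        assert "c" in retained
        assert len({"a", "b"} & set(retained)) == 1

    def test_planted_three_cluster_structure(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(300)
        z = rng.standard_normal(300)
        env = pd.DataFrame({
            "v1": x, "v2": x + 0.1 * rng.standard_normal(300),  # with v1
            "v3": z,                                            # alone
            "v4": rng.standard_normal(300)})                    # alone
        retained, tree = collinearity_prune(env)
        # hand UPGMA: only (v1, v2) merge below height 0.3
        assert len(retained) == 3
        assert {"v3", "v4"} < set(retained)
        first_merge = tree[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}

    def test_constant_variable_named_in_error(self):
        env = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="'a'"):
            collinearity_prune(env)


class TestFitLogistic:
    def test_labels_independent_of_predictors_give_null_fit(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame({"x": rng.standard_normal(4000)})
        y = np.tile([0, 1], 2000)
        fit = fit_logistic(x, y)
        assert abs(fit.params["const"]) < 0.1
        assert abs(fit.params["x"]) < 0.1

    def test_matches_brute_force_likelihood_grid(self):
        x = pd.DataFrame({"x": [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]})
        y = np.array([0, 0, 1, 0, 1, 1], dtype=float)
        fit = fit_logistic(x, y)

        def loglik(b0, b1):
            eta = b0 + b1 * x["x"].to_numpy()
            p = 1 / (1 + np.exp(-eta))
            return (y * np.log(p) + (1 - y) * np.log(1 - p)).sum()

        # nested grid refinement around the optimum
        centre, width = (0.0, 0.0), 4.0
        for _ in range(8):
            b0s = np.linspace(centre[0] - width, centre[0] + width, 41)
            b1s = np.linspace(centre[1] - width, centre[1] + width, 41)
            best = max(itertools.product(b0s, b1s),
                       key=lambda b: loglik(*b))
            centre, width = best, width / 8
        assert fit.params["const"] == pytest.approx(centre[0], abs=1e-6)
        assert fit.params["x"] == pytest.approx(centre[1], abs=1e-6)

    def test_perfect_separation_raises(self):
        x = pd.DataFrame({"x": [-2.0, -1.0, 1.0, 2.0, 3.0, 4.0]})
        y = np.array([0, 0, 1, 1, 1, 1], dtype=float)
        with pytest.raises(SeparationError):
            fit_logistic(x, y)


class TestStepwise:
    @staticmethod
    def _table(seed, n, noise_vars):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, n)
        p = 1 / (1 + np.exp(-0.156 * x + 7.767))
        df = pd.DataFrame({"bio17": x})
        for i in range(noise_vars):
            df[f"noise{i}"] = rng.standard_normal(n)
        df["species"] = np.where(rng.random(n) < p, "M", "P")
        return df

    def test_planted_signal_always_enters(self):
        for seed in range(10):
            res = SpeciesDistributionModel(self._table(seed, 500, 4)).fit()
            assert "bio17" in res.variables

    def test_single_noise_competitor_rarely_displaces_exact_model(self):
        exact = sum(
            SpeciesDistributionModel(self._table(100 + s, 500, 1)).fit()
            .variables == ["bio17"] for s in range(20))
        assert exact >= 18

    def test_pure_noise_enters_at_nominal_alpha(self):
        """Entry is an alpha=0.05 LR test, so a single noise candidate is
        admitted in about 5% of datasets."""
        entered = 0
        for seed in range(40):
            rng = np.random.default_rng(700 + seed)
            df = pd.DataFrame({"v": rng.standard_normal(200)})
            df["species"] = np.where(rng.random(200) < 0.5, "M", "P")
            res = SpeciesDistributionModel(df).fit()
            entered += len(res.variables) > 0
        assert entered <= 6  # Binomial(40, .05): P(X > 6) < 1%

    def test_trace_is_consistent_with_thresholds(self):
        res = SpeciesDistributionModel(self._table(5, 800, 3)).fit()
        adds = res.trace[res.trace["action"] == "add"]
        assert (adds["p_value"] < 0.05).all()

    def test_empty_model_has_intercept_only(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"v": rng.standard_normal(150)})
        df["species"] = np.where(rng.random(150) < 0.3, "M", "P")
        res = SpeciesDistributionModel(df).fit()
        if not res.variables:
            assert list(res.params.index) == ["const"]
            assert res.auc == 0.5

    def test_printed_equation_convention(self):
        res = SpeciesDistributionModel(self._table(7, 5000, 0)).fit()
        printed = res.printed_coefficients()
        # p_M = 1/(1+exp(a*bio17 + b)): a near -0.156, b near 7.767
        assert printed["bio17"] == pytest.approx(-0.156, rel=0.15)
        assert printed["intercept"] == pytest.approx(7.767, rel=0.15)
        assert "p_M = 1/(1 + exp(" in res.equation()
        assert "AUC" in res.summary()


class TestAuc:
    def test_perfect_separation_gives_one(self):
        a, _ = auc(np.array([1, 2, 3, 10, 11, 12]),
                   np.array([0, 0, 0, 1, 1, 1]))
        assert a == 1.0

    def test_constant_scores_give_half(self):
        a, _ = auc(np.ones(10), np.arange(10) % 2)
        assert a == 0.5

    def test_matches_concordant_pair_enumeration(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.35, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        pairs = [(s1, s0) for s1 in scores[labels] for s0 in scores[~labels]]
        expected = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                            for a, b in pairs])
        a, _ = auc(scores, labels)
        assert a == pytest.approx(expected)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.standard_normal(200)
        labels = rng.random(200) < 0.4
        a1, _ = auc(scores, labels)
        a2, _ = auc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc(np.arange(4), np.ones(4))


class TestHindcast:
    @staticmethod
    def _fitted():
        env = simulate_env_presence(SimEnvSpec(n_localities=2000, seed=9))
        return SpeciesDistributionModel(env).fit()

    def _raster(self, values):
        return RasterGrid(np.asarray(values, dtype=float), 0.0, 0.0, 1.0)

    def test_single_set_cumulative_is_binary(self):
        res = self._fitted()
        rasters = {"bio17": self._raster([[10.0, 90.0], [45.0, 60.0]])}
        _, cumulative = hindcast_stack(res, [rasters])
        assert set(np.unique(cumulative.values)) <= {0.0, 1.0}

    def test_identical_sets_stack_to_all_or_nothing(self):
        res = self._fitted()
        rasters = {"bio17": self._raster([[10.0, 90.0]])}
        _, cumulative = hindcast_stack(res, [rasters] * 3)
        assert set(np.unique(cumulative.values)) <= {0.0, 3.0}

    def test_nodata_propagates(self):
        res = self._fitted()
        grid = self._raster([[10.0, -9999.0]])
        probs, cumulative = hindcast_stack(res, [{"bio17": grid}])
        assert probs[0].values[0, 1] == -9999.0
        assert cumulative.values[0, 1] == -9999.0

    def test_missing_variable_errors(self):
        res = self._fitted()
        with pytest.raises(ValueError, match="lacks"):
            hindcast_stack(res, [{"bio01": self._raster([[1.0]])}])

    def test_misaligned_grids_error(self):
        res = self._fitted()
        env = simulate_env_presence(SimEnvSpec(
            n_localities=2000, seed=10, nuisance={"bio01": 0.2}))
        model = SpeciesDistributionModel(env, candidates=["bio17", "bio01"])
        fitted = model.fit()
        if len(fitted.variables) >= 2:
            sets = {"bio17": self._raster([[1.0]]),
                    "bio01": RasterGrid(np.ones((2, 2)), 0.0, 0.0, 1.0)}
            with pytest.raises(ValueError, match="aligned"):
                hindcast_stack(fitted, [sets])
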
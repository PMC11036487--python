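"""Permutation importance, exact Shapley values, expansion suggestions."""

import numpy as np
import pandas as pd
import pytest

from dbtlopt.attribution import (
    permutation_importance,
    shapley_values,
    shapley_values_sampled,
    suggest_expansion,
    summarize_shapley,
)
from dbtlopt.datasets import assign_strata, collapse_replicates
from dbtlopt.design_space import encode_designs, encoding_columns, enumerate_designs
from dbtlopt.landscape import ScreenConfig, sample_landscape, simulate_screen
from dbtlopt.models import ModelSpec, fit

from conftest import make_dataset, toy_library


def linear_fn(columns, weights, intercept=0.0):
    """Prediction callable: weighted sum of one-hot columns."""
    w = np.array([weights.get(pair, 0.0) for pair in columns])

    def predict(X):
        return X @ w + intercept

    return predict


def rf_model(library, seed=0, n=40):
    rng = np.random.default_rng(seed)
    designs = enumerate_designs(library)
    idx = rng.choice(len(designs), size=min(n, len(designs)), replace=False)
    sub = [designs[i] for i in idx]
    X, _ = encode_designs(sub, library)
    y = rng.uniform(0, 0.3, len(sub))
    return fit(
        ModelSpec("random_forest", {"n_estimators": 30}),
        make_dataset_from(library, sub, y),
    )


def make_dataset_from(library, designs, titers):
    from dbtlopt.datasets import DesignDataset

    rows = [
        {**d.as_dict(), "mean_titer": float(t), "n_replicates": 1,
         "producer": float(t) >= 0.05}
        for d, t in zip(designs, titers)
    ]
    return DesignDataset(pd.DataFrame(rows), library, "complete", 0.05)


class TestShapleyAxioms:
    @pytest.mark.parametrize("seed", range(4))
    def test_efficiency_on_random_fitted_models(self, seed):
        # sum of phi equals prediction minus background mean, to 1e-9
        rng = np.random.default_rng(seed)
        lib = toy_library((3, 2, 4, 2, 3)[: 3 + seed % 3])
        model = rf_model(lib, seed=seed)
        designs = enumerate_designs(lib)
        background = make_dataset_from(
            lib, designs[:10], rng.uniform(0, 0.3, 10)
        )
        instance = designs[rng.integers(len(designs))]
        res = shapley_values(model, instance, background, lib)
        assert res.efficiency_gap < 1e-9 * max(1.0, abs(res.prediction))

    def test_symmetry_identical_factors(self):
        # two factors with identical roles and identical instance levels
        lib = toy_library((2, 2))
        cols = encoding_columns(lib)
        fn = linear_fn(cols, {("fA", "fA_L0"): 0.3, ("fB", "fB_L0"): 0.3})
        designs = enumerate_designs(lib)
        background = designs  # symmetric background (full space)
        instance = designs[0]  # (fA_L0, fB_L0)
        res = shapley_values(fn, instance, background, lib)
        assert res.phi["fA"] == pytest.approx(res.phi["fB"], abs=1e-12)

    def test_null_player_gets_zero(self):
        lib = toy_library((3, 3, 2))
        cols = encoding_columns(lib)
        # model provably ignores fC
        fn = linear_fn(cols, {("fA", "fA_L1"): 0.5, ("fB", "fB_L2"): -0.2})
        designs = enumerate_designs(lib)
        res = shapley_values(fn, designs[7], designs[:6], lib)
        assert abs(res.phi["fC"]) < 1e-9

    def test_additive_model_matches_closed_form(self):
        # for an additive value function, phi_f is the instance's effect
        # minus the background-mean effect of that factor
        lib = toy_library((3, 2, 2))
        cols = encoding_columns(lib)
        rng = np.random.default_rng(1)
        weights = {pair: float(rng.normal(0, 0.1)) for pair in cols}
        fn = linear_fn(cols, weights, intercept=0.05)
        designs = enumerate_designs(lib)
        background = designs[:5]
        instance = designs[-1]
        res = shapley_values(fn, instance, background, lib)
        for fid in lib.factor_ids:
            inst_eff = weights[(fid, instance.level(fid))]
            bg_eff = np.mean([weights[(fid, b.level(fid))] for b in background])
            assert res.phi[fid] == pytest.approx(inst_eff - bg_eff, abs=1e-9)

    def test_single_factor_game(self):
        lib = toy_library((3,))
        cols = encoding_columns(lib)
        fn = linear_fn(cols, {("fA", "fA_L2"): 0.4})
        designs = enumerate_designs(lib)
        res = shapley_values(fn, designs[2], designs[:2], lib)
        assert res.phi["fA"] == pytest.approx(res.prediction - res.background_value)

    def test_factor_bound_enforced(self):
        lib = toy_library((2,) * 17)
        designs_iter = None
        with pytest.raises(ValueError, match="sampling|sampled"):
            shapley_values(lambda X: X.sum(axis=1), None, [], lib)


class TestShapleySampling:
    def test_sampler_agrees_with_exact_within_3_se(self):
        lib = toy_library((3, 2, 2, 3, 2, 2))  # six factors
        model = rf_model(lib, seed=2, n=30)
        designs = enumerate_designs(lib)
        background = designs[:20]
        instance = designs[-1]
        exact = shapley_values(model, instance, background, lib)
        sampled = shapley_values_sampled(
            model, instance, background, lib, n_permutations=150, seed=0
        )
        for fid in lib.factor_ids:
            se = max(sampled.standard_error[fid], 1e-12)
            assert abs(sampled.phi[fid] - exact.phi[fid]) < 3 * se + 1e-9


class TestPermutationImportance:
    def _screen_dataset(self, lib, m, n=200, seed=0):
        table = simulate_screen(
            m, lib, ScreenConfig(n_colonies=n, correct_fraction=1.0,
                                 replicate_noise_sd=0.0, seed=seed)
        )
        return collapse_replicates(table, lib)

    def test_only_active_factor_matters(self):
        lib = toy_library((3, 3, 3))
        effects = {("fA", lv.id): 0.1 * j
                   for j, lv in enumerate(lib.factor("fA").levels)}
        from dbtlopt.landscape import LandscapeModel

        m = LandscapeModel(lib, 0.1, effects, {}, 0.0)
        ds = self._screen_dataset(lib, m)
        spec = fit(ModelSpec("linear"), ds)
        imp = permutation_importance(spec, ds, n_repeats=10, seed=0)
        assert imp.importance("fA") > 0.2
        assert abs(imp.importance("fB")) < 0.05
        assert abs(imp.importance("fC")) < 0.05

    def test_single_level_factor_importance_exactly_zero(self):
        lib = toy_library((3, 1))
        m = sample_landscape(lib, noise_sd=0.0, seed=0)
        ds = self._screen_dataset(lib, m)
        spec = fit(ModelSpec("linear"), ds)
        imp = permutation_importance(spec, ds, n_repeats=5, seed=0)
        assert imp.importance("fB") == 0.0

    def test_invariant_to_level_relabeling(self):
        lib = toy_library((3, 3))
        m = sample_landscape(lib, noise_sd=0.0, seed=4)
        ds = self._screen_dataset(lib, m)
        spec = fit(ModelSpec("linear"), ds)
        imp1 = permutation_importance(spec, ds, n_repeats=8, seed=3)
        # relabel: rename level ids consistently everywhere
        from dbtlopt.design_space import Factor, Level, LibrarySpec
        from dbtlopt.datasets import DesignDataset

        renamed = LibrarySpec(
            "renamed",
            tuple(
                Factor(f.id, f.position, tuple(
                    Level("x_" + lv.id, lv.promoter, lv.orf, lv.strength)
                    for lv in f.levels
                ))
                for f in lib.ordered_factors
            ),
        )
        frame = ds.frame.copy()
        for fid in lib.factor_ids:
            frame[fid] = "x_" + frame[fid]
        ds2 = DesignDataset(frame, renamed, "complete", 0.05)
        spec2 = fit(ModelSpec("linear"), ds2)
        imp2 = permutation_importance(spec2, ds2, n_repeats=8, seed=3)
        for fid in lib.factor_ids:
            assert imp1.importance(fid) == pytest.approx(imp2.importance(fid))

    def test_unfitted_model_rejected(self):
        lib = toy_library((2, 2))
        ds = make_dataset(lib, [0.1, 0.2, 0.05, 0.0])
        with pytest.raises(ValueError):
            permutation_importance(ModelSpec("linear"), ds)


class TestSummarizeShapley:
    def test_strongest_effect_level_has_most_positive_mean_phi(self):
        lib = toy_library((3, 3))
        cols = encoding_columns(lib)
        weights = {pair: 0.0 for pair in cols}
        weights[("fA", "fA_L0")] = 0.3  # the strong-promoter level
        fn = linear_fn(cols, weights)
        designs = enumerate_designs(lib)
        results = [shapley_values(fn, d, designs, lib) for d in designs]
        summary = summarize_shapley(results)
        best = summary.loc[summary["mean_phi"].idxmax()]
        assert (best["factor"], best["level"]) == ("fA", "fA_L0")

    def test_absent_level_not_in_summary(self):
        lib = toy_library((3, 2))
        cols = encoding_columns(lib)
        fn = linear_fn(cols, {("fA", "fA_L0"): 0.2})
        designs = enumerate_designs(lib)
        results = [shapley_values(fn, d, designs, lib) for d in designs[:2]]
        summary = summarize_shapley(results)
        assert "fA_L2" not in set(summary["level"])

    def test_efficiency_aggregates_over_instances(self):
        lib = toy_library((2, 3))
        model = rf_model(lib, seed=5, n=6)
        designs = enumerate_designs(lib)
        results = [shapley_values(model, d, designs, lib) for d in designs]
        total_phi = np.mean([sum(r.phi.values()) for r in results])
        X, _ = encode_designs(designs, lib)
        mean_pred = model.predict(X).mean()
        assert total_phi == pytest.approx(mean_pred - results[0].background_value,
                                          abs=1e-9)


class TestSuggestExpansion:
    def _importance(self, lib, values):
        from dbtlopt.attribution import PermutationImportance

        frame = pd.DataFrame(
            [{"factor": fid, "importance_mean": v, "importance_sd": 0.0}
             for fid, v in values.items()]
        )
        return PermutationImportance(frame, baseline_r2=0.9, n_repeats=1)

    def _summary(self, rows):
        return pd.DataFrame(
            [{"factor": f, "level": l, "n": 5, "mean_phi": phi,
              "q25_phi": phi, "q75_phi": phi, "positive_fraction": 1.0}
             for f, l, phi in rows]
        )

    def test_boundary_factor_flagged_expand_upward(self):
        lib = toy_library((3, 3))  # level 0 is the strong promoter
        imp = self._importance(lib, {"fA": 0.5, "fB": 0.05})
        summary = self._summary(
            [("fA", "fA_L0", 0.1), ("fA", "fA_L2", -0.1), ("fB", "fB_L1", 0.01)]
        )
        report = suggest_expansion(imp, summary, lib)
        assert report.expand_upward == ["fA"]

    def test_interior_optimum_not_flagged(self):
        lib = toy_library((3, 3))
        imp = self._importance(lib, {"fA": 0.5, "fB": 0.05})
        summary = self._summary(
            [("fA", "fA_L1", 0.1), ("fA", "fA_L0", -0.1)]  # medium level best
        )
        report = suggest_expansion(imp, summary, lib)
        assert report.expand_upward == []
        row = report.frame.set_index("factor").loc["fA"]
        assert row["suggestion"] == "keep"

    def test_all_zero_attributions_no_suggestions(self):
        lib = toy_library((3, 3))
        imp = self._importance(lib, {"fA": 0.0, "fB": 0.0})
        report = suggest_expansion(imp, self._summary([]), lib)
        assert report.expand_upward == []
        assert (report.frame["suggestion"] == "neutral").all()

    def test_strongest_available_counts_when_strong_excluded(self):
        # mirror of the reduced library: the factor's strongest buildable
        # promoter is "medium", and an optimum there is still a boundary
        from dbtlopt.design_space import LibrarySpec

        base = toy_library((3, 3))
        lib = LibrarySpec("toy", base.factors, frozenset({("fA", "fA_L0")}))
        imp = self._importance(lib, {"fA": 0.5, "fB": 0.05})
        summary = self._summary([("fA", "fA_L1", 0.1)])
        report = suggest_expansion(imp, summary, lib)
        assert report.expand_upward == ["fA"]
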
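"""Ensemble training strategies, top-N frequency ranking, BMP evaluation."""

import numpy as np
import pandas as pd
import pytest

from dbtlopt.datasets import StratificationScheme, assign_strata, collapse_replicates
from dbtlopt.design_space import enumerate_designs
from dbtlopt.landscape import (
    ScreenConfig,
    sample_landscape,
    simulate_screen,
    true_titers,
)
from dbtlopt.recommend import (
    EnsemblePredictions,
    evaluate_ranking,
    predicted_improvement,
    rank_designs,
    topk_membership,
    train_one_time,
    train_recurrent,
)
from dbtlopt.study import simulate_study

from conftest import make_dataset, toy_library

FAST_GRIDS = {
    "kernel_ridge": {"alpha": [0.01, 0.1], "gamma": [0.1, 1.0]},
}


def fake_preds(values_by_family, library=None, designs=None, kind="complete",
               strategy="one_time"):
    if designs is None:
        designs = enumerate_designs(library)
    return EnsemblePredictions(
        strategy=strategy,
        dataset_kind=kind,
        designs=list(designs),
        predictions={k: np.atleast_2d(v) for k, v in values_by_family.items()},
    )


def brute_force_frequencies(preds, k):
    """Independent recount of top-k membership frequencies."""
    n = len(preds.designs)
    total = np.zeros(n)
    for mat in preds.predictions.values():
        fam = np.zeros(n)
        for row in mat:
            order = sorted(range(n), key=lambda i: (-row[i], i))
            for i in order[:k]:
                fam[i] += 1
        total += fam / mat.shape[0]
    return total / len(preds.predictions)


class TestTopKMembership:
    def test_counts_are_exactly_k(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.random(50)
            for k in (1, 5, 10):
                assert topk_membership(v, k).sum() == k

    def test_ties_resolved_by_enumeration_order(self):
        v = np.array([1.0, 2.0, 2.0, 0.5])
        mask = topk_membership(v, 2)
        assert list(np.flatnonzero(mask)) == [1, 2]
        mask1 = topk_membership(v, 1)
        assert list(np.flatnonzero(mask1)) == [1]


class TestTrainingStrategies:
    def test_one_time_recovers_argmax_on_noiseless_additive(self):
        lib = toy_library((3, 3, 2))
        m = sample_landscape(lib, interaction_density=0.0, noise_sd=0.0, seed=5)
        table = simulate_screen(
            m, lib, ScreenConfig(n_colonies=150, correct_fraction=1.0,
                                 replicate_noise_sd=0.0, seed=0)
        )
        ds = assign_strata(collapse_replicates(table, lib))
        preds = train_one_time(ds, families=["linear"], seed=0)
        space = enumerate_designs(lib)
        truth = true_titers(m, space)
        assert int(np.argmax(preds.ensemble_mean())) == int(np.argmax(truth))

    def test_constant_titers_tie_break_by_enumeration_order(self, toy2x3):
        ds = assign_strata(make_dataset(toy2x3, [0.2] * 6), StratificationScheme(1))
        preds = train_one_time(ds, families=["linear"], seed=0)
        ranking = rank_designs(preds)
        assert list(ranking.frame["design_index"][:3]) == [0, 1, 2]

    def test_one_time_reproducible(self):
        sd = simulate_study(0)
        a = train_one_time(sd.complete, ["linear", "kernel_ridge"],
                           seed=3, grids=FAST_GRIDS)
        b = train_one_time(sd.complete, ["linear", "kernel_ridge"],
                          seed=3, grids=FAST_GRIDS)
        for fam in a.predictions:
            assert np.array_equal(a.predictions[fam], b.predictions[fam])

    def test_recurrent_shapes_and_determinism(self):
        sd = simulate_study(0)
        a = train_recurrent(sd.complete, ["linear"], n_resamples=5, seed=1)
        assert a.predictions["linear"].shape == (5, 672)
        b = train_recurrent(sd.complete, ["linear"], n_resamples=5, seed=1)
        assert np.array_equal(a.predictions["linear"], b.predictions["linear"])

    def test_recurrent_sd_vanishes_as_keep_fraction_grows(self):
        lib = toy_library((3, 3))
        m = sample_landscape(lib, interaction_density=0.0, noise_sd=0.0, seed=6)
        table = simulate_screen(
            m, lib, ScreenConfig(n_colonies=60, correct_fraction=1.0,
                                 replicate_noise_sd=0.0, seed=0)
        )
        ds = assign_strata(collapse_replicates(table, lib))
        wide = train_recurrent(ds, ["linear"], n_resamples=50,
                               keep_fraction=0.6, seed=0)
        tight = train_recurrent(ds, ["linear"], n_resamples=50,
                                keep_fraction=0.99, seed=0)
        assert tight.ensemble_sd().mean() < wide.ensemble_sd().mean()
        assert tight.ensemble_sd().mean() < 1e-6

    def test_single_resample_matches_one_time_structure(self):
        sd = simulate_study(0)
        preds = train_recurrent(sd.complete, ["linear"], n_resamples=1, seed=0)
        assert preds.predictions["linear"].shape[0] == 1
        assert preds.label == "CR"

    def test_labels(self):
        sd = simulate_study(0)
        one = train_one_time(sd.producers, ["linear"], seed=0)
        assert one.label == "PO"


class TestRankDesigns:
    def test_single_model_top1_frequency(self):
        lib = toy_library((2, 3))
        v = np.array([0.1, 0.5, 0.2, 0.05, 0.3, 0.0])
        preds = fake_preds({"linear": v}, library=lib)
        ranking = rank_designs(preds)
        top = ranking.frame.iloc[0]
        assert top["design_index"] == 1
        assert top["freq_top1"] == 1.0
        assert (ranking.frame["freq_top1"][1:] == 0).all()

    def test_disagreeing_models_hand_computed_frequencies(self):
        # two models share the same top-5 set but disagree on the top-1
        lib = toy_library((2, 3))
        a = np.array([0.9, 0.8, 0.3, 0.2, 0.1, 0.0])
        b = np.array([0.8, 0.9, 0.3, 0.2, 0.1, 0.0])
        preds = fake_preds({"m1": a, "m2": b}, library=lib)
        ranking = rank_designs(preds, top_ns=(1, 5, 10))
        f = ranking.frame.set_index("design_index")
        assert f.loc[0, "freq_top1"] == 0.5 and f.loc[1, "freq_top1"] == 0.5
        assert f.loc[0, "freq_top5"] == 1.0 and f.loc[1, "freq_top5"] == 1.0
        # frequency tie broken by mean prediction: both means are 0.85
        # so enumeration order decides
        assert list(ranking.frame["design_index"][:2]) == [0, 1]

    def test_frequency_monotonicity(self):
        rng = np.random.default_rng(2)
        lib = toy_library((4, 5, 3))
        for _ in range(5):
            preds = fake_preds(
                {"m1": rng.random(60), "m2": rng.random((3, 60))},
                library=lib, strategy="recurrent",
            )
            f = rank_designs(preds).frame
            assert (f["freq_top1"] <= f["freq_top5"] + 1e-12).all()
            assert (f["freq_top5"] <= f["freq_top10"] + 1e-12).all()

    def test_matches_brute_force_recount_on_random_ensembles(self):
        # oracle equivalence on 50 random toy ensembles, spaces <= 200
        rng = np.random.default_rng(7)
        for trial in range(50):
            n_designs = int(rng.integers(12, 201))
            designs = list(range(n_designs))  # identity stand-ins
            n_models = int(rng.integers(1, 4))
            values = {
                f"m{j}": rng.random((int(rng.integers(1, 6)), n_designs))
                for j in range(n_models)
            }
            preds = EnsemblePredictions(
                strategy="recurrent", dataset_kind="complete",
                designs=designs, predictions=values,
            )
            ranking = rank_designs(preds)
            f = ranking.frame.sort_values("design_index")
            for k in (1, 5, 10):
                expected = brute_force_frequencies(preds, k)
                assert np.allclose(f[f"freq_top{k}"].to_numpy(), expected)

    def test_ranking_order_consistent_with_composite(self):
        rng = np.random.default_rng(8)
        lib = toy_library((4, 5, 3))
        preds = fake_preds({"m": rng.random((4, 60))}, library=lib,
                           strategy="recurrent")
        f = rank_designs(preds).frame
        keys = list(
            zip(-f["freq_top1"], -f["freq_top5"], -f["freq_top10"],
                -f["mean_pred"], f["design_index"])
        )
        assert keys == sorted(keys)


class TestEvaluateRanking:
    def _titer_ranking(self, ds, reverse=False):
        space = enumerate_designs(ds.library)
        titers = {str(d): t for d, t in zip(ds.designs, ds.titers)}
        v = np.array([titers.get(str(d), -1.0) for d in space])
        if reverse:
            v = -v
        return rank_designs(fake_preds({"m": v}, designs=space)), space

    def test_perfect_ranking_puts_bmp_first(self):
        lib = toy_library((2, 3))
        ds = make_dataset(lib, [0.1, 0.3, 0.05, 0.2, 0.0, 0.15])
        ranking, _ = self._titer_ranking(ds)
        rep = evaluate_ranking(ranking, ds)
        assert rep.bmp_rank == 1 and rep.bmp_in_top10

    def test_reversed_ranking_puts_bmp_last(self):
        lib = toy_library((2, 3))
        ds = make_dataset(lib, [0.1, 0.3, 0.05, 0.2, 0.04, 0.15])
        ranking, space = self._titer_ranking(ds, reverse=True)
        rep = evaluate_ranking(ranking, ds)
        assert rep.bmp_rank == len(space)
        assert rep.nonproducer_median_rank < rep.bmp_rank

    def test_five_bmp_ranks_reported(self):
        lib = toy_library((3, 3))
        ds = make_dataset(lib, np.linspace(0.0, 0.2, 9))
        ranking, _ = self._titer_ranking(ds)
        rep = evaluate_ranking(ranking, ds)
        assert rep.five_bmp_ranks == [1, 2, 3, 4, 5]


class TestPredictedImprovement:
    def test_bmp_itself_has_zero_improvement(self):
        lib = toy_library((2, 3))
        ds = make_dataset(lib, [0.1, 0.3, 0.05, 0.2, 0.0, 0.15])
        space = enumerate_designs(lib)
        v = np.array([0.1, 0.3, 0.05, 0.2, 0.0, 0.15])
        preds = fake_preds({"m": v}, designs=space)
        ranking = rank_designs(preds)
        table = predicted_improvement(ranking, preds, ds, top_n=3)
        bmp_row = table.loc[table["is_bmp"]]
        assert bmp_row["improvement_mean_pct"].iloc[0] == pytest.approx(0.0)

    def test_twenty_percent_better_design(self):
        lib = toy_library((2, 3))
        # measured data misses the true optimum, predicted 20% above BMP
        ds = make_dataset(lib, [0.10, 0.30, 0.05, 0.20, 0.0])
        space = enumerate_designs(lib)
        v = np.array([0.10, 0.30, 0.05, 0.20, 0.0, 0.36])
        preds = fake_preds({"m": v}, designs=space)
        ranking = rank_designs(preds)
        table = predicted_improvement(ranking, preds, ds, top_n=1)
        assert table["improvement_mean_pct"].iloc[0] == pytest.approx(20.0)

    def test_hand_computed_summary_on_fixture(self):
        lib = toy_library((2, 5))
        ds = make_dataset(lib, [0.2])  # single measured design = BMP
        space = enumerate_designs(lib)
        v = np.linspace(0.1, 0.28, 10)  # BMP is design 0 -> pred 0.1
        preds = fake_preds({"m": v}, designs=space)
        ranking = rank_designs(preds)
        table = predicted_improvement(ranking, preds, ds, top_n=10)
        expected = 100.0 * (v[::-1] - 0.1) / 0.1
        assert np.allclose(table["improvement_mean_pct"], expected)

    def test_zero_bmp_reference_rejected(self):
        lib = toy_library((2, 3))
        ds = make_dataset(lib, [0.0, 0.0])
        space = enumerate_designs(lib)
        v = np.zeros(6)
        preds = fake_preds({"m": v}, designs=space)
        ranking = rank_designs(preds)
        with pytest.raises(ZeroDivisionError):
            predicted_improvement(ranking, preds, ds)


class TestTopKProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=1, max_size=60,
        ),
        k=st.integers(min_value=1, max_value=10),
    )
    def test_membership_count_is_min_k_n(self, values, k):
        v = np.asarray(values)
        assert topk_membership(v, k).sum() == min(k, len(v))
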
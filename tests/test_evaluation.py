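"""Entropy-threshold sweep and statistics against hand/loop oracles."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaseg.evaluation import (EntropyThresholdGrid, aggregate_sweep,
                              masked_dice, pairwise_wilcoxon, pearson_tradeoff,
                              percent_removed, retained_pixels, threshold_sweep,
                              wilcoxon_paired)
from gaseg.inference import entropy_map


class TestRetainedAndRemoved:
    def test_threshold_one_retains_everything(self, rng):
        e = entropy_map(rng.random((8, 8)))
        assert retained_pixels(e, 1.0).all()
        assert percent_removed(e, 1.0) == 0.0

    def test_zero_entropy_all_retained_at_any_threshold(self):
        e = np.zeros((4, 4))
        assert retained_pixels(e, 0.01).all()

    def test_three_pixel_example(self):
        e = np.array([0.05, 0.5, 0.95])
        keep = retained_pixels(e, 0.10)
        np.testing.assert_array_equal(keep, [True, False, False])

    def test_four_pixel_percent(self):
        e = np.array([0.0, 0.2, 0.6, 1.0])
        assert percent_removed(e, 0.5) == pytest.approx(50.0)

    def test_uniform_half_entropy_removed_at_low_threshold(self):
        assert percent_removed(np.full((4, 4), 0.5), 0.10) == 100.0

    def test_monotone_non_increasing_in_threshold(self, rng):
        e = rng.random((16, 16))
        vals = [percent_removed(e, t) for t in EntropyThresholdGrid().thresholds]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            retained_pixels(np.zeros((2, 2)), 0.0)
        with pytest.raises(ValueError):
            percent_removed(np.zeros((2, 2)), 1.5)


class TestMaskedDice:
    def test_perfect_prediction(self):
        g = np.array([[1, 0], [1, 0]])
        assert masked_dice(g.astype(float), g, np.ones((2, 2), bool)) == 1.0

    def test_disjoint_prediction(self):
        p = np.array([[1.0, 1.0], [0.0, 0.0]])
        g = np.array([[0, 0], [1, 1]])
        assert masked_dice(p, g, np.ones((2, 2), bool)) == 0.0

    def test_four_pixel_hand_case(self):
        # P = {1,1,0,0}, G = {1,0,1,0} -> 2*1/(2+2) = 0.5
        p = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([1, 0, 1, 0])
        assert masked_dice(p, g, np.ones(4, bool)) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        assert masked_dice(np.zeros(4), np.zeros(4, int), np.ones(4, bool)) == 1.0

    def test_empty_retention_is_undefined(self):
        assert np.isnan(masked_dice(np.ones(4), np.ones(4, int),
                                    np.zeros(4, bool)))


# ------------------------------------------------- sweep vs loop oracle
def _oracle_record(p, e, g1, g2, thr, cut=0.5):
    """Spreadsheet-style re-computation with explicit loops."""
    size = p.size
    removed = sum(1 for v in e.ravel() if v > thr)

    def dice_of(g):
        inter = npred = nref = 0
        any_kept = False
        for pij, eij, gij in zip(p.ravel(), e.ravel(), g.ravel()):
            if eij <= thr:
                any_kept = True
                pred = pij >= cut
                ref = gij > 0
                inter += pred and ref
                npred += pred
                nref += ref
        if not any_kept:
            return float("nan")
        return 1.0 if npred + nref == 0 else 2.0 * inter / (npred + nref)

    d1, d2 = dice_of(g1), dice_of(g2)
    return d1, d2, 100.0 * removed / size


@pytest.fixture(scope="module")
def hand_fixture():
    rng = np.random.default_rng(42)
    prob_maps, ent_maps, graders = {}, {}, {}
    for model in ("m1", "m2"):
        prob_maps[model], ent_maps[model] = {}, {}
        for sid in ("a", "b"):
            p = rng.choice([0.02, 0.2, 0.45, 0.55, 0.8, 0.98], size=(8, 8))
            prob_maps[model][sid] = p
            ent_maps[model][sid] = entropy_map(p)
    for sid in ("a", "b"):
        graders[sid] = ((rng.random((8, 8)) < 0.4).astype(np.uint8),
                        (rng.random((8, 8)) < 0.4).astype(np.uint8))
    return prob_maps, ent_maps, graders


class TestThresholdSweep:
    def test_matches_loop_oracle_bit_for_bit(self, hand_fixture):
        prob_maps, ent_maps, graders = hand_fixture
        grid = EntropyThresholdGrid()
        table = threshold_sweep(prob_maps, ent_maps, graders, grid)
        assert len(table) == 2 * 2 * len(grid.thresholds)
        for _, row in table.iterrows():
            p = prob_maps[row.model_id][row.sample_id]
            e = ent_maps[row.model_id][row.sample_id].values
            g1, g2 = graders[row.sample_id]
            d1, d2, pct = _oracle_record(p, e, g1, g2, row.threshold)
            assert row.dice_vs_grader1 == d1 or (np.isnan(d1) and np.isnan(row.dice_vs_grader1))
            assert row.dice_vs_grader2 == d2 or (np.isnan(d2) and np.isnan(row.dice_vs_grader2))
            assert row.percent_removed == pct
            if row.defined:
                assert row.dice_mean == (d1 + d2) / 2.0

    def test_perfect_prediction_scores_one_everywhere(self):
        truth = np.zeros((8, 8), np.uint8)
        truth[2:6, 2:6] = 1
        p = truth.astype(float)  # entropy 0 everywhere
        table = threshold_sweep({"m": {"s": p}},
                                {"m": {"s": entropy_map(p)}},
                                {"s": (truth, truth)})
        assert (table["dice_mean"] == 1.0).all()
        assert (table["percent_removed"] == 0.0).all()

    def test_percent_removed_monotone_per_group(self, hand_fixture):
        table = threshold_sweep(*hand_fixture)
        for _, grp in table.groupby(["model_id", "sample_id"]):
            vals = grp.sort_values("threshold")["percent_removed"].to_numpy()
            assert (np.diff(vals) <= 0).all()

    def test_misaligned_ids_rejected(self, hand_fixture):
        prob_maps, ent_maps, graders = hand_fixture
        with pytest.raises(ValueError, match="grader"):
            threshold_sweep(prob_maps, ent_maps, {"a": graders["a"]})

    def test_aggregate_reports_undefined_counts(self, hand_fixture):
        table = threshold_sweep(*hand_fixture)
        agg = aggregate_sweep(table, n_boot=50, seed=0)
        assert {"dice_mean", "dice_ci_lo", "dice_ci_hi",
                "percent_removed", "n_undefined"} <= set(agg.columns)
        assert (agg["n_samples"] == 2).all()


# ------------------------------------------------------------- wilcoxon
def _brute_force_wilcoxon(a, b):
    """Exhaustive sign-pattern enumeration of the two-sided exact test."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    npat = 0
    for signs in product([0, 1], repeat=len(d)):
        rp = sum(r for r, s in zip(ranks, signs) if s)
        if min(rp, total - rp) <= w_obs + 1e-9:
            count += 1
        npat += 1
    return w_obs, count / npat


class TestWilcoxon:
    def test_identical_scores_are_degenerate(self):
        a = np.linspace(0.5, 0.9, 8)
        res = wilcoxon_paired(a, a.copy())
        assert res.all_zero and res.p_value == 1.0
        assert not res.significant_after_bonferroni

    def test_uniform_shift_gives_zero_statistic(self):
        b = np.linspace(0.5, 0.7, 20)
        res = wilcoxon_paired(b + 0.1, b)
        assert res.statistic == 0.0
        assert res.p_value < 0.001

    def test_six_pair_hand_example_exact(self):
        a = np.array([0.80, 0.82, 0.75, 0.90, 0.85, 0.60])
        b = np.array([0.78, 0.85, 0.70, 0.80, 0.86, 0.50])
        w, p = _brute_force_wilcoxon(a, b)
        res = wilcoxon_paired(a, b)
        assert res.method == "exact"
        assert res.statistic == w
        assert res.p_value == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        a = rng.random(n)
        b = np.clip(a + rng.normal(0, 0.1, n), 0, 1)
        w, p = _brute_force_wilcoxon(a, b)
        res = wilcoxon_paired(a, b)
        assert res.statistic == w
        assert res.p_value == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("n", [12, 20])
    def test_agrees_with_library_exact_on_tie_free_data(self, n):
        rng = np.random.default_rng(11)
        a = rng.random(n)
        b = rng.random(n)
        res = wilcoxon_paired(a, b)
        ref = stats.wilcoxon(a, b, zero_method="wilcox", method="exact")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_bonferroni_adjustment(self):
        b = np.linspace(0.5, 0.7, 12)
        strong = wilcoxon_paired(b + 0.1, b, n_comparisons=1)
        assert strong.significant_after_bonferroni
        # same data, absurd correction burden -> not significant
        weak = wilcoxon_paired(b + 0.1, b, n_comparisons=10_000)
        assert not weak.significant_after_bonferroni

    def test_requires_five_pairs(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1, 2, 3], [3, 2, 1])

    def test_pairwise_table_counts_comparisons(self):
        rng = np.random.default_rng(5)
        scores = {m: rng.random(8) for m in ("x", "y", "z")}
        tab = pairwise_wilcoxon(scores)
        assert len(tab) == 3


class TestPearson:
    @staticmethod
    def _agg(dice, removed, model="m"):
        return pd.DataFrame({"model_id": model, "threshold":
                             np.linspace(0.1, 1, len(dice)),
                             "dice_mean": dice, "percent_removed": removed})

    def test_affine_relation_is_perfect(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = pearson_tradeoff(self._agg(2 * x + 1, x), "m")
        assert res.rho == pytest.approx(1.0)

    def test_constant_dice_flagged_undefined(self):
        res = pearson_tradeoff(self._agg(np.full(5, 0.8), np.arange(5.0)), "m")
        assert not res.defined and np.isnan(res.rho)

    def test_hand_vectors(self):
        res = pearson_tradeoff(self._agg([2.0, 4, 5, 4, 5], [1.0, 2, 3, 4, 5]), "m")
        assert res.rho == pytest.approx(0.7745966692414834, abs=1e-12)

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            pearson_tradeoff(self._agg([1.0, 2], [1.0, 2]), "m")
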
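"""Score calculus: selectivity, screen efficiencies, thresholds, corrected
scores, quadrants."""

import numpy as np
import pandas as pd
import pytest

from cleavekit.scoring import (
    ScreenMeasurement, call_cleaved, classify_cleaved, corrected_efficiency,
    corrected_selectivity, efficiency_from_screen, fit_cleavage_thresholds,
    quadrant_assign, reduce_kinetics, selectivity_score,
)


class TestSelectivity:
    def test_uniform_profile_scores_zero(self):
        assert selectivity_score(np.full(18, 1.7), 3) == pytest.approx(0.0)

    def test_lone_signal(self):
        prof = np.zeros(18)
        prof[5] = 2.0
        assert selectivity_score(prof, 5) == pytest.approx(2.0)

    def test_matches_mean_subtract_oracle(self, rng):
        prof = rng.normal(size=18)
        for m in range(18):
            others = np.delete(prof, m)
            assert selectivity_score(prof, m) == pytest.approx(
                prof[m] - others.mean(), abs=1e-12)

    def test_translation_covariance_in_target(self, rng):
        prof = rng.normal(size=6)
        base = selectivity_score(prof, 2)
        shifted = prof.copy()
        shifted[2] += 0.7
        assert selectivity_score(shifted, 2) == pytest.approx(base + 0.7, abs=1e-12)

    def test_matrix_input(self, rng):
        mat = rng.normal(size=(10, 5))
        got = selectivity_score(mat, 1)
        for i in range(10):
            assert got[i] == pytest.approx(selectivity_score(mat[i], 1), abs=1e-12)

    def test_single_protease_rejected(self):
        with pytest.raises(ValueError):
            selectivity_score(np.array([1.0]), 0)


class TestScreenMeasurement:
    def test_time_must_increase(self):
        with pytest.raises(ValueError):
            ScreenMeasurement("s", "p", "1", [0, 10, 5], [1, 2, 3])

    def test_fold_change_and_rate(self):
        m = ScreenMeasurement("s", "p", "1", [0, 30, 60], [100, 200, 400])
        assert m.fold_change() == pytest.approx(4.0)
        assert m.rate() == pytest.approx(5.0)  # least-squares slope of 100,200,400


def _toy_kinetics():
    rows = []
    # substrate A strongly cleaved, B mildly, C flat
    for sub, slope in (("A", 30.0), ("B", 6.0), ("C", 0.0)):
        for rep in (1, 2):
            for t in (0, 30, 60):
                rows.append({"substrate": sub, "protease": "MMP13",
                             "replicate": rep, "time_min": t,
                             "fluorescence": 100 + slope * t})
    return pd.DataFrame(rows)


class TestEfficiency:
    def test_replicates_averaged_then_called(self):
        signals = call_cleaved(reduce_kinetics(_toy_kinetics()))
        by_sub = signals.set_index("substrate")
        assert bool(by_sub.loc["A", "cleaved"]) is True
        assert bool(by_sub.loc["C", "cleaved"]) is False

    def test_top_substrate_gets_exactly_one(self):
        signals = call_cleaved(reduce_kinetics(_toy_kinetics()))
        eff = efficiency_from_screen(signals).set_index("substrate")
        assert eff.loc["A", "efficiency"] == pytest.approx(1.0)

    def test_noncleaved_is_zero_regardless_of_signal(self):
        signals = pd.DataFrame({
            "substrate": ["x", "y"], "protease": ["p", "p"],
            "signal": [5.0, 3.0], "cleaved": [True, False]})
        eff = efficiency_from_screen(signals).set_index("substrate")
        assert eff.loc["y", "efficiency"] == 0.0

    def test_hand_arithmetic_three_substrates(self):
        # FC values 10, 4 cleaved; 1.1 non-cleaved -> FC_minbar = 1.1
        signals = pd.DataFrame({
            "substrate": ["a", "b", "c"], "protease": ["p"] * 3,
            "signal": [10.0, 4.0, 1.1], "cleaved": [True, True, False]})
        eff = efficiency_from_screen(signals).set_index("substrate")["efficiency"]
        assert eff["a"] == pytest.approx(1.0)
        assert eff["b"] == pytest.approx(4.0 / (10.0 - 1.1))
        assert eff["c"] == 0.0

    def test_no_cleaved_warns_all_zero(self):
        signals = pd.DataFrame({
            "substrate": ["a"], "protease": ["p"],
            "signal": [1.0], "cleaved": [False]})
        with pytest.warns(UserWarning):
            eff = efficiency_from_screen(signals)
        assert (eff["efficiency"] == 0).all()


class TestThresholds:
    def test_separable_scores_gap_midpoint(self):
        scores = np.array([0.0, 1.0, 3.0, 4.0])[:, None]
        labels = np.array([0, 0, 1, 1], dtype=float)[:, None]
        table = fit_cleavage_thresholds(scores, labels, ["p"])
        assert table.thresholds["p"] == pytest.approx(2.0)
        assert table.youden_j["p"] == pytest.approx(1.0)

    def test_matches_bruteforce_scan(self, rng):
        scores = rng.normal(size=40)
        labels = (scores + rng.normal(0, 0.8, 40)) > 0
        table = fit_cleavage_thresholds(scores[:, None],
                                        labels.astype(float)[:, None], ["p"])
        # brute force over a fine grid of cuts
        best_j = -np.inf
        for t in np.linspace(scores.min() - 1, scores.max() + 1, 20001):
            pred = scores > t
            tp = (pred & labels).sum()
            fp = (pred & ~labels).sum()
            j = tp / labels.sum() - fp / (~labels).sum()
            best_j = max(best_j, j)
        assert table.youden_j["p"] == pytest.approx(best_j, abs=1e-9)

    def test_uninformative_labels_warn(self, rng):
        scores = rng.normal(size=200)
        labels = np.array([1, 0] * 100, dtype=float)  # independent of scores
        with pytest.warns(UserWarning):
            fit_cleavage_thresholds(np.column_stack([scores, scores]),
                                    np.column_stack([labels, np.full(200, np.nan)]),
                                    ["a", "b"])

    def test_imputed_equals_mean_of_fitted(self, rng):
        M = 6
        scores = rng.normal(size=(50, M))
        labels = np.full((50, M), np.nan)
        for j in range(4):   # only 4 proteases screened
            labels[:, j] = (scores[:, j] + rng.normal(0, 0.5, 50) > 0).astype(float)
        table = fit_cleavage_thresholds(scores, labels,
                                        [f"p{j}" for j in range(M)])
        fitted = [table.thresholds[f"p{j}"] for j in range(4)]
        for j in (4, 5):
            assert table.imputed[f"p{j}"]
            assert table.thresholds[f"p{j}"] == pytest.approx(np.mean(fitted))


class TestClassification:
    def test_boundary_is_not_cleaved(self):
        out = classify_cleaved(np.array([[1.0]]), np.array([1.0]))
        assert not out["calls"][0, 0]

    def test_all_positive_predictions(self):
        zhat = np.array([[2.0], [3.0]])
        out = classify_cleaved(zhat, np.array([0.0]),
                               labels=np.array([[True], [False]]))
        assert out["sensitivity"] == 1.0
        assert out["specificity"] == 0.0

    def test_hand_counted_confusion_table(self):
        zhat = np.array([2, 2, 2, 0, 0, 0, 2, 0, 2, 0], dtype=float)[:, None]
        labels = np.array([1, 1, 0, 0, 0, 1, 1, 0, 0, 1], dtype=bool)[:, None]
        out = classify_cleaved(zhat, np.array([1.0]), labels=labels)
        # calls: TP=3 (rows 0,1,6), FP=2 (2,8), TN=3 (3,4,7), FN=2 (5,9)
        assert out["sensitivity"] == pytest.approx(3 / 5)
        assert out["specificity"] == pytest.approx(3 / 5)
        assert out["accuracy"] == pytest.approx(6 / 10)

    def test_monotone_in_zhat(self):
        t = np.array([0.5])
        low = classify_cleaved(np.array([[0.4]]), t)["calls"]
        high = classify_cleaved(np.array([[0.6]]), t)["calls"]
        assert not low[0, 0] and high[0, 0]


class TestCorrectedScores:
    def test_boundary_zero_and_max_one(self, rng):
        zhat = rng.normal(size=(20, 5))
        thr = rng.normal(0, 0.3, size=5)
        eff = corrected_efficiency(zhat, thr)
        for j in range(5):
            cleaved = zhat[:, j] > thr[j]
            if cleaved.any():
                assert eff[:, j].max() == pytest.approx(1.0)
            assert (eff[~cleaved, j] == 0).all()

    def test_exact_threshold_not_cleaved(self):
        eff = corrected_efficiency(np.array([[1.0], [2.0]]), np.array([1.0]))
        assert eff[0, 0] == 0.0
        assert eff[1, 0] == pytest.approx(1.0)

    def test_elementwise_bruteforce(self, rng):
        zhat = rng.normal(size=(20, 5))
        thr = rng.normal(size=5)
        eff = corrected_efficiency(zhat, thr)
        for j in range(5):
            adj = zhat[:, j] - thr[j]
            mx = adj[adj > 0].max() if (adj > 0).any() else None
            for i in range(20):
                expected = adj[i] / mx if adj[i] > 0 else 0.0
                assert eff[i, j] == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance_within_column(self, rng):
        zhat = rng.normal(size=(15, 3))
        thr = np.zeros(3)
        base = corrected_efficiency(zhat, thr)
        scaled = corrected_efficiency(zhat * 3.7, thr)  # common positive scaling
        np.testing.assert_allclose(base, scaled, atol=1e-12)

    def test_corrected_selectivity_extremes_and_oracle(self, rng):
        eff = np.zeros((1, 18))
        eff[0, 4] = 1.0
        assert corrected_selectivity(eff, 4)[0] == pytest.approx(1.0)
        assert corrected_selectivity(np.full((1, 6), 0.5), 2)[0] == pytest.approx(0.0)
        mat = rng.uniform(size=(30, 8))
        got = corrected_selectivity(mat, 3)
        expected = mat[:, 3] - np.delete(mat, 3, axis=1).mean(axis=1)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert (got >= -1 - 1e-12).all() and (got <= 1 + 1e-12).all()


class TestQuadrants:
    def test_high_high(self):
        assert quadrant_assign(0.5, 3.0) == "high-efficiency/high-selectivity"

    def test_boundary_is_low(self):
        assert quadrant_assign(0.4, 2.4) == "low-efficiency/low-selectivity"

    def test_counts_match_hand_tally(self):
        E = np.array([0.1, 0.5, 0.9, 0.2, 0.41])
        S = np.array([0.0, 3.0, 1.0, 2.5, 2.41])
        labels = quadrant_assign(E, S)
        from collections import Counter
        counts = Counter(labels)
        assert counts["low-efficiency/low-selectivity"] == 1
        assert counts["high-efficiency/high-selectivity"] == 2
        assert counts["high-efficiency/low-selectivity"] == 1
        assert counts["low-efficiency/high-selectivity"] == 1
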
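"""Discrimination, decision-curve, reclassification and multiplicity
statistics, checked against printed clinical-table values and brute-force
oracles."""

import numpy as np
import pandas as pd
import pytest

from btiradiomics.evaluation import (
    ConfusionMatrix,
    bh_adjust,
    compare_models,
    confusion_metrics,
    decision_curve,
    delong_ci,
    pr_auc,
    printed,
    reclassification,
    roc_auc,
    round_half_up,
)

from . import oracles

# printed diagnostic-performance rows: (TN, FP, FN, TP) -> printed rates
TABLE_ROWS = [
    ((255, 68, 13, 68), dict(sensitivity="0.84", specificity="0.789",
                             accuracy="0.8", PPV="0.5", NPV="0.951")),
    ((248, 72, 43, 41), dict(sensitivity="0.488", specificity="0.775",
                             accuracy="0.715", PPV="0.363", NPV="0.852")),
    ((253, 70, 13, 68), dict(sensitivity="0.84", specificity="0.783",
                             accuracy="0.795", PPV="0.493", NPV="0.951")),
    ((64, 13, 4, 20), dict(sensitivity="0.833", specificity="0.831",
                           accuracy="0.832", PPV="0.606", NPV="0.941")),
    ((64, 16, 15, 6), dict(sensitivity="0.286", specificity="0.8",
                           accuracy="0.693", PPV="0.273", NPV="0.81")),
    ((64, 13, 5, 19), dict(sensitivity="0.792", specificity="0.831",
                           accuracy="0.822", PPV="0.594", NPV="0.928")),
    ((124, 41, 7, 42), dict(sensitivity="0.857", specificity="0.752",
                            accuracy="0.776", PPV="0.506", NPV="0.947")),
    ((140, 25, 30, 19), dict(sensitivity="0.388", specificity="0.848",
                             accuracy="0.743", PPV="0.432", NPV="0.824")),
    ((131, 34, 10, 39), dict(sensitivity="0.796", specificity="0.794",
                             accuracy="0.794", PPV="0.534", NPV="0.929")),
]


class TestConfusionMetrics:
    @pytest.mark.parametrize("quad,expected", TABLE_ROWS)
    def test_printed_clinical_rows_reproduced(self, quad, expected):
        cm = ConfusionMatrix(*quad)
        out = confusion_metrics(cm)
        for key, val in expected.items():
            assert out["printed"][key] == val, (quad, key)

    def test_all_correct_matrix(self):
        out = confusion_metrics(ConfusionMatrix(TN=10, FP=0, FN=0, TP=5))
        for k in ("sensitivity", "specificity", "accuracy", "PPV", "NPV"):
            assert out[k] == 1.0

    def test_zero_denominator_flagged(self):
        out = confusion_metrics(ConfusionMatrix(TN=10, FP=0, FN=0, TP=0))
        assert np.isnan(out["sensitivity"]) and "sensitivity" in out["flags"]

    def test_accuracy_ci_is_exact_binomial(self):
        out = confusion_metrics(ConfusionMatrix(255, 68, 13, 68))
        lo, hi = out["accuracy_ci"]
        # printed interval for this row: (0.757, 0.837)
        assert round_half_up(lo) == 0.757 and round_half_up(hi) == 0.837

    def test_from_predictions_at_cutoff(self):
        p = np.array([0.1, 0.25, 0.19, 0.8])
        y = np.array([0, 1, 1, 1])
        cm = ConfusionMatrix.from_predictions(p, y, threshold=0.20)
        assert (cm.TN, cm.FP, cm.FN, cm.TP) == (1, 0, 1, 2)

    def test_rounding_half_up_and_trimming(self):
        assert round_half_up(0.8005) == 0.801  # bankers' rounding would give 0.8
        assert printed(0.7995) == "0.8"
        assert printed(0.5) == "0.5"
        assert printed(0.9514925) == "0.951"


class TestRocAuc:
    def test_matches_pair_enumeration_on_small_toys(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            p = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert roc_auc(p, y) == pytest.approx(
                oracles.brute_auc(p, y), abs=1e-12
            )

    def test_perfect_ranking_and_degenerate_ci(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        res = delong_ci(p, y)
        assert res["auc"] == 1.0 and res["degenerate"]
        assert res["ci"] == (1.0, 1.0)

    def test_label_flip_symmetry(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        p = rng.random(40)
        assert roc_auc(p, y) == pytest.approx(1.0 - roc_auc(p, 1 - y))

    def test_delong_ci_covers_reasonably(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
        res = delong_ci(x, y)
        assert res["ci"][0] < res["auc"] < res["ci"][1]
        assert 0.0 < res["se"] < 0.1


class TestPrAuc:
    def test_perfect_ranking_is_one(self):
        assert pr_auc([0.1, 0.2, 0.9, 0.8], [0, 0, 1, 1]) == 1.0

    def test_matches_threshold_sweep_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 15))
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                y[0] = 1
            p = np.round(rng.random(n), 1)
            assert pr_auc(p, y) == pytest.approx(
                oracles.brute_pr_auc(list(p), list(y)), abs=1e-12
            )

    def test_random_scores_approach_prevalence(self, rng):
        n = 4000
        prev = 0.25
        y = (rng.random(n) < prev).astype(int)
        p = rng.random(n)
        assert pr_auc(p, y) == pytest.approx(y.mean(), abs=0.05)


class TestDecisionCurve:
    def test_treat_all_limit_is_prevalence(self, rng):
        y = rng.integers(0, 2, 50)
        curve = decision_curve(rng.random(50), y, thresholds=[0.01, 0.2, 0.5])
        assert curve.treat_all[0] == pytest.approx(
            y.mean() - (1 - y.mean()) * 0.01 / 0.99
        )
        assert np.all(curve.treat_none == 0.0)

    def test_hand_computed_ten_subject_example(self):
        p = [0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95]
        y = [0, 0, 0, 1, 0, 1, 0, 1, 1, 1]
        curve = decision_curve(np.array(p), np.array(y), thresholds=[0.2, 0.4])
        for pt, nb in zip(curve.thresholds, curve.model):
            assert nb == pytest.approx(oracles.brute_net_benefit(p, y, pt))
        # by hand at pt=0.2: TP=5, FP=3 -> 0.5 - 0.3*0.25 = 0.425
        assert curve.model[0] == pytest.approx(0.425)

    def test_constant_probability_model_never_beats_references(self, rng):
        y = rng.integers(0, 2, 200)
        curve = decision_curve(np.full(200, 0.5), y)
        best_ref = np.maximum(curve.treat_all, 0.0)
        assert (curve.model <= best_ref + 1e-12).all()

    def test_threshold_grid_validated(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=[0.0, 0.5])


class TestReclassification:
    def test_identical_probabilities_all_zero(self, rng):
        p = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        rep = reclassification(p, p, y, n_boot=50, seed=0)
        assert rep.nri_categorical == 0.0
        assert rep.nri_continuous == 0.0
        assert rep.idi == 0.0

    def test_eight_subject_hand_example(self):
        p_ref = np.array([0.1, 0.1, 0.3, 0.3, 0.1, 0.3, 0.1, 0.3])
        p_new = np.array([0.3, 0.1, 0.1, 0.3, 0.3, 0.1, 0.1, 0.3])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        rep = reclassification(p_ref, p_new, y, cut_points=(0.20,), n_boot=50,
                               seed=1)
        assert rep.nri_categorical == pytest.approx(
            oracles.brute_nri_categorical(p_ref, p_new, y, 0.20)
        )
        # by hand: events up 1, down 1 -> 0; non-events up 1, down 1 -> 0
        assert rep.nri_categorical == 0.0
        assert rep.idi == pytest.approx(oracles.brute_idi(p_ref, p_new, y))

    def test_idi_is_discrimination_slope_difference(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        p_ref, p_new = rng.random(60), rng.random(60)
        rep = reclassification(p_ref, p_new, y, n_boot=50, seed=2)
        assert rep.idi == pytest.approx(oracles.brute_idi(p_ref, p_new, y),
                                        abs=1e-12)

    def test_added_noise_does_not_improve_idi(self):
        rng_ = np.random.default_rng(8)
        n = 300
        x = rng_.normal(size=n)
        y = (rng_.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
        p_ref = 1 / (1 + np.exp(-2 * x))
        idis = []
        for b in range(40):
            noise = rng_.normal(scale=0.3, size=n)
            p_new = np.clip(p_ref + noise, 0.001, 0.999)
            idis.append(oracles.brute_idi(p_ref, p_new, y))
        assert np.mean(idis) <= 0.01

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self, rng):
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        p_ref, p_new = rng.random(80), rng.random(80)
        a = reclassification(p_ref, p_new, y, n_boot=200, seed=5)
        b = reclassification(p_ref, p_new, y, n_boot=200, seed=5)
        assert a.idi_ci == b.idi_ci
        assert a.idi_ci[0] <= a.idi <= a.idi_ci[1]


class TestMultiplicity:
    def test_bh_hand_worked_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_stepup_oracle(self, rng):
        p = rng.random(15)
        np.testing.assert_allclose(bh_adjust(p), oracles.bh_stepup(list(p)),
                                   atol=1e-12)

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.031]), [0.031])

    def test_adjusted_monotone_and_not_below_raw(self, rng):
        p = rng.random(12)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_identical_distributions_give_p_one(self, rng):
        base = rng.normal(0.8, 0.02, size=30)
        table = pd.DataFrame({"a": base, "b": base.copy(), "c": base + 0.05})
        out = compare_models(table)
        row_ab = out[(out.model_a == "a") & (out.model_b == "b")].iloc[0]
        assert row_ab.p == 1.0
        assert (out.p_adjusted >= out.p - 1e-15).all()

    def test_fdr_controlled_on_null_simulation(self):
        """10,000 replicates of m=9 null tests: observed FDR under BH stays
        within nominal + 2 SE."""
        rng_ = np.random.default_rng(123)
        m, alpha, reps = 9, 0.05, 10_000
        false_discoveries = 0
        p = rng_.random((reps, m))
        ranked = np.sort(p, axis=1)
        ks = np.arange(1, m + 1)
        rejected_any = (ranked <= alpha * ks / m).any(axis=1)
        # under the complete null every rejection is false: FDR = P(any)
        fdr_hat = rejected_any.mean()
        se = np.sqrt(fdr_hat * (1 - fdr_hat) / reps)
        assert fdr_hat <= alpha + 2 * se + 1e-12
        # and the vectorized rule agrees with the implementation on a sample
        for row in p[:50]:
            assert (bh_adjust(row) <= alpha).any() == bool(
                (np.sort(row) <= alpha * ks / m).any()
            )
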
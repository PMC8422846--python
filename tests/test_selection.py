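"""ICC filter, Spearman redundancy filter, LASSO screen and varimax PCA."""

import numpy as np
import pandas as pd
import pytest

from btiradiomics.selection import (
    SelectionConfig,
    icc_2_1,
    icc_filter,
    lasso_screen,
    pca_varimax,
    spearman_filter,
    varimax,
)

from .oracles import anova_icc21, soft_threshold


class TestIcc:
    def test_identical_raters_icc_one(self):
        y = np.column_stack([np.arange(6.0), np.arange(6.0)])
        assert icc_2_1(y) == pytest.approx(1.0)

    def test_matches_anova_sums_oracle(self, rng):
        for _ in range(10):
            y = rng.normal(size=(6, 2)) + rng.normal(size=(6, 1)) * 2.0
            assert icc_2_1(y) == pytest.approx(anova_icc21(y), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        y = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1)) * 1.5
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 2),
            "rater": np.tile(["a", "b"], 8),
            "score": y.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        # two-way random, absolute agreement, single rater
        icc2 = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert icc_2_1(y) == pytest.approx(icc2, abs=1e-8)

    def test_filter_keeps_reproducible_drops_noise(self, rng):
        n = 40
        signal = rng.normal(size=n)
        r1 = pd.DataFrame({
            "stable": signal + 0.05 * rng.normal(size=n),
            "noisy": rng.normal(size=n),
        })
        r2 = pd.DataFrame({
            "stable": signal + 0.05 * rng.normal(size=n),
            "noisy": rng.normal(size=n),
        })
        keep, iccs = icc_filter(r1, r2, icc_min=0.8)
        assert keep == ["stable"]
        assert iccs["stable"] >= 0.8 and not iccs["noisy"] >= 0.8

    def test_zero_variance_feature_dropped_with_nan(self):
        r1 = pd.DataFrame({"flat": np.ones(6)})
        r2 = pd.DataFrame({"flat": np.ones(6)})
        keep, iccs = icc_filter(r1, r2)
        assert keep == [] and np.isnan(iccs["flat"])


class TestSpearmanFilter:
    def test_duplicated_column_removed_once(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        y = (x + rng.normal(size=30) > 0).astype(int)
        kept = spearman_filter(df, y, 0.9)
        assert sorted(kept) in (["a", "c"], ["b", "c"])
        assert len(kept) == 2

    def test_three_mutually_correlated_one_survivor(self, rng):
        base = rng.normal(size=50)
        df = pd.DataFrame({
            "f1": base + 0.01 * rng.normal(size=50),
            "f2": base + 0.01 * rng.normal(size=50),
            "f3": base + 0.01 * rng.normal(size=50),
        })
        y = (base > 0).astype(int)
        kept = spearman_filter(df, y, 0.9)
        assert len(kept) == 1

    def test_independent_features_all_survive(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 5)),
                          columns=[f"f{i}" for i in range(5)])
        y = rng.integers(0, 2, 60)
        assert len(spearman_filter(df, y, 0.9)) == 5

    def test_priority_keeps_label_associated_feature(self, rng):
        y = rng.integers(0, 2, 80)
        informative = y + 0.2 * rng.normal(size=80)
        degraded = informative + 0.35 * rng.normal(size=80)  # weaker association
        df = pd.DataFrame({"aaa_weak": degraded, "zzz_strong": informative})
        kept = spearman_filter(df, y, 0.8)
        # despite losing the lexicographic tie-break, the label-stronger
        # feature survives the redundant pair
        assert kept == ["zzz_strong"]


class TestLassoScreen:
    def test_orthonormal_design_soft_threshold_closed_form(self, rng):
        """Squared-error lasso on an orthonormal design equals
        soft-thresholding of the least-squares estimates."""
        n, p = 64, 8
        q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = q  # X^T X = I
        beta = np.array([3.0, -2.0, 1.5, 0.8, 0.4, 0.1, 0.0, 0.0])
        y = X @ beta + 0.05 * rng.normal(size=n)
        alpha = 0.01
        res = lasso_screen(pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]),
                           y, objective="linear", alpha=alpha)
        ols = X.T @ y
        expected = soft_threshold(ols, n * alpha)
        np.testing.assert_allclose(res.coefficients.to_numpy(), expected,
                                   atol=1e-6)

    def test_all_zero_solution_triggers_flagged_fallback(self, rng):
        """A penalty strong enough to zero every coefficient flags the
        result and retries along the path for the weakest-penalty model
        with an active feature."""
        cfg = SelectionConfig(lasso_folds=5, seed=1)
        yy = np.array([0, 1] * 20)
        # near-degenerate features: the CV optimum keeps nothing
        res = lasso_screen(pd.DataFrame(rng.normal(scale=1e-6, size=(40, 4)),
                                        columns=list("abcd")), yy, cfg)
        assert res.fallback
        # weak but real signal: the fallback recovers an active set
        x = yy + 3.0 * rng.normal(size=40)
        res2 = lasso_screen(pd.DataFrame({"s": x * 1e-3}), yy, cfg)
        if res2.fallback:
            assert len(res2.ranked) >= 1

    def test_epv_presets_nine_and_three(self, rng):
        """105 events cap the screen at 9 features, 49 events at 3."""
        def cohort(n, events, seed):
            r = np.random.default_rng(seed)
            y = np.zeros(n, dtype=int)
            y[:events] = 1
            X = r.normal(size=(n, 20))
            X[:, :12] += y[:, None] * r.uniform(0.8, 1.6, 12)  # 12 real signals
            cols = [f"f{i:02d}" for i in range(20)]
            return pd.DataFrame(X, columns=cols), y

        X1, y1 = cohort(505, 105, 0)
        res1 = lasso_screen(X1, y1, SelectionConfig(k_features=9, seed=0))
        assert len(res1.selected) == 9
        X2, y2 = cohort(214, 49, 1)
        res2 = lasso_screen(X2, y2, SelectionConfig(k_features=3, seed=1))
        assert len(res2.selected) == 3
        # selection is the |coefficient| ranking prefix
        assert res1.selected == res1.ranked[:9]

    def test_both_classes_required(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            lasso_screen(X, np.zeros(10, dtype=int))


class TestVarimaxPca:
    def test_communalities_preserved(self, rng):
        A = rng.normal(size=(12, 4))
        A_rot, R = varimax(A)
        np.testing.assert_allclose(R @ R.T, np.eye(4), atol=1e-10)
        np.testing.assert_allclose((A_rot**2).sum(axis=1), (A**2).sum(axis=1),
                                   atol=1e-8)

    def test_already_optimal_loadings_unchanged(self):
        """Perfect simple structure is a varimax fixed point."""
        A = np.zeros((10, 2))
        A[:5, 0] = 0.9
        A[5:, 1] = 0.8
        A_rot, R = varimax(A)
        np.testing.assert_allclose(np.abs(R), np.eye(2), atol=1e-8)

    def test_two_factor_recovery_of_planted_sparsity(self, rng):
        """Rotated loadings recover which variables load on which factor."""
        n = 400
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        X = np.column_stack(
            [f1 + 0.1 * rng.normal(size=n) for _ in range(4)]
            + [f2 + 0.1 * rng.normal(size=n) for _ in range(4)]
        )
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(8)])
        model = pca_varimax(df, n_components=2)
        L = np.abs(model.rotated_loadings)
        group1 = L[:4].argmax(axis=1)
        group2 = L[4:].argmax(axis=1)
        assert len(set(group1)) == 1 and len(set(group2)) == 1
        assert group1[0] != group2[0]
        # simple structure: cross-loadings are small
        for i in range(8):
            assert L[i].min() < 0.35 < L[i].max()

    def test_kaiser_rule_and_override(self, rng):
        n = 200
        f = rng.normal(size=n)
        X = np.column_stack([f + 0.3 * rng.normal(size=n) for _ in range(3)]
                            + [rng.normal(size=n) for _ in range(3)])
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(6)])
        auto = pca_varimax(df)
        assert 1 <= auto.n_components < 6
        forced = pca_varimax(df, n_components=5)
        assert forced.n_components == 5
        assert forced.component_names == [f"PC{i}" for i in range(1, 6)]

    def test_scores_unit_variance_and_projection_consistency(self, rng):
        df = pd.DataFrame(rng.normal(size=(120, 6)),
                          columns=[f"v{i}" for i in range(6)])
        model = pca_varimax(df, n_components=3)
        np.testing.assert_allclose(model.scores.std(ddof=1), 1.0, atol=1e-8)
        again = model.transform(df)
        np.testing.assert_allclose(again.to_numpy(), model.scores.to_numpy(),
                                   atol=1e-10)

    def test_sign_convention_largest_loading_positive(self, rng):
        df = pd.DataFrame(rng.normal(size=(80, 5)),
                          columns=[f"v{i}" for i in range(5)])
        model = pca_varimax(df, n_components=3)
        L = model.rotated_loadings
        for j in range(3):
            assert L[np.abs(L[:, j]).argmax(), j] > 0


class TestEndToEndEnrichment:
    def test_selected_features_come_from_the_invasion_shell_roi(self):
        """When shell-ROI (BTI4) and tumor-only (WT) features compete in one
        screen, the selected set is enriched for the shell ROI's features
        (permutation p < 0.05) — the invasion signal lives at the interface."""
        from btiradiomics.feature_extraction import minmax_scale
        from btiradiomics.pipeline import extract_cohort_features
        from btiradiomics.synthetic_cohort import PhantomConfig, generate_cohort

        from scipy import stats as sstats

        cfg = PhantomConfig(n_subjects=150, seed=77, second_rater=False)
        subjects = generate_cohort(cfg)
        y = np.array([s.record.invasion for s in subjects])
        tabs = extract_cohort_features(subjects, rois=["BTI4mm", "WT"])
        pooled = pd.concat(
            [tabs["BTI4mm"].add_prefix("BTI4mm."), tabs["WT"].add_prefix("WT.")],
            axis=1,
        )
        scaled, _ = minmax_scale(pooled)
        # the chain's own priority measure: |Spearman rho| with the label
        assoc = {
            c: abs(sstats.spearmanr(scaled[c].to_numpy(), y).statistic)
            for c in scaled.columns
        }
        top10 = sorted(assoc, key=assoc.get, reverse=True)[:10]
        from_shell = np.array([c.startswith("BTI4mm.") for c in scaled.columns])
        obs = np.mean([c.startswith("BTI4mm.") for c in top10])
        rng_ = np.random.default_rng(0)
        null = [
            from_shell[rng_.choice(len(from_shell), size=10, replace=False)].mean()
            for _ in range(2000)
        ]
        p = (np.sum(np.asarray(null) >= obs) + 1) / 2001
        assert p < 0.05
        # and the screen's strongest coefficient sits on a shell-ROI feature
        res = lasso_screen(scaled, y, SelectionConfig(lasso_folds=5, seed=2))
        assert res.ranked[0].startswith("BTI4mm.")
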
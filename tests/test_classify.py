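import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.svm import SVC

from enoselab.classify import (
    ClassifierConfig,
    EvalResult,
    _svm_cv_predict_precomputed,
    cv_splits,
    da_classify,
    evaluate,
    greedy_svm_selection,
    nested_greedy_svm_eval,
    pca_project,
    sigma_to_gamma,
    stepwise_da,
    stepwise_select,
    svm_grid_search,
)


def feature_frame(X, y, prefix="f"):
    df = pd.DataFrame(X, columns=[f"{prefix}{i:02d}" for i in range(X.shape[1])])
    df.insert(0, "group", y)
    df.insert(0, "subject_id", [f"s{i}" for i in range(len(y))])
    return df


def two_groups(n_per=20):
    return np.array(["A"] * n_per + ["B"] * n_per)


class TestEvalResult:
    @given(
        tp=st.integers(0, 50), tn=st.integers(0, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_identities(self, tp, tn, fp, fn):
        r = EvalResult(tp=tp, tn=tn, fp=fp, fn=fn)
        if tp + fn:
            assert r.sensitivity == tp / (tp + fn)
        if tn + fp:
            assert r.specificity == tn / (tn + fp)
        if r.total:
            assert r.accuracy == (tp + tn) / r.total

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="tp"):
            EvalResult(tp=-1, tn=0, fp=0, fn=0)


class TestEvaluate:
    def test_all_correct(self):
        y = two_groups(5)
        r = evaluate(y, y, positive="B")
        assert (r.sensitivity, r.specificity, r.accuracy) == (1.0, 1.0, 1.0)

    def test_printed_triple_at_20_plus_20(self):
        # TP=19, FN=1, TN=18, FP=2 -> 95% / 90% / 92.5%
        y_true = two_groups(20)
        y_pred = y_true.copy()
        y_pred[20] = "A"  # one missed positive
        y_pred[[0, 1]] = "B"  # two false alarms
        r = evaluate(y_true, y_pred, positive="B")
        assert (r.tp, r.fn, r.tn, r.fp) == (19, 1, 18, 2)
        assert r.sensitivity == pytest.approx(0.95)
        assert r.specificity == pytest.approx(0.90)
        assert r.accuracy == pytest.approx(0.925)

    def test_single_class_predictions(self):
        y = two_groups(4)
        r = evaluate(y, np.array(["B"] * 8), positive="B")
        assert r.specificity == 0.0 and r.sensitivity == 1.0

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError, match="unseen"):
            evaluate(["A", "B"], ["A", "C"], positive="B")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            evaluate(["A", "B"], ["A"], positive="B")

    def test_absent_positive_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            evaluate(["A", "A"], ["A", "A"], positive="B")


class TestConfig:
    def test_defaults(self):
        cfg = ClassifierConfig()
        assert cfg.max_indices == 10
        assert min(cfg.C_grid) == pytest.approx(1.0)
        assert max(cfg.C_grid) == pytest.approx(1000.0)
        assert min(cfg.sigma_grid) == pytest.approx(0.1)
        assert max(cfg.sigma_grid) == pytest.approx(50.0)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"method": "E"}, "method"),
            ({"C_grid": ()}, "C_grid"),
            ({"C_grid": (0.0, 1.0)}, "C_grid"),
            ({"sigma_grid": (-1.0,)}, "sigma_grid"),
            ({"max_indices": 0}, "max_indices"),
        ],
    )
    def test_validation(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            ClassifierConfig(**kwargs)

    def test_sigma_gamma_conversion(self):
        assert sigma_to_gamma(20.0) == pytest.approx(1.0 / 800.0)


class TestCvSplits:
    def test_loo(self):
        splits = cv_splits(two_groups(3), "loo")
        assert len(splits) == 6
        assert all(te.size == 1 for _, te in splits)

    def test_stratified_balance(self):
        splits = cv_splits(two_groups(10), ("stratified", 5), seed=0)
        for tr, te in splits:
            y = two_groups(10)
            assert (y[te] == "B").sum() == 2

    def test_seed_reproducible(self):
        a = cv_splits(two_groups(10), ("stratified", 5), seed=3)
        b = cv_splits(two_groups(10), ("stratified", 5), seed=3)
        for (tra, _), (trb, _) in zip(a, b):
            np.testing.assert_array_equal(tra, trb)

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="cv scheme"):
            cv_splits(two_groups(3), "bootstrap")


class TestPCA:
    def test_line_in_3d(self):
        t = np.linspace(0, 1, 30)
        X = np.outer(t, [1.0, 2.0, -1.0])
        scores, evr = pca_project(X, 1)
        assert evr[0] == pytest.approx(1.0)

    def test_isotropic_cloud_equal_shares(self):
        # eigenvalues of the sample covariance of an isotropic Gaussian
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20000, 3))
        _, evr = pca_project(X, 3)
        np.testing.assert_allclose(evr, 1 / 3, atol=0.02)

    def test_duplicated_column_rank_deficiency(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(15, 2))
        X = np.column_stack([base, base[:, 0]])  # rank 2 in 3 columns
        scores, evr = pca_project(X, 2)
        assert scores.shape == (15, 2)
        with pytest.raises(ValueError, match="rank"):
            pca_project(X, 3)


class TestDaClassify:
    def test_separated_clouds_perfect(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 2))
        X[20:] += 10.0
        r = da_classify(X, two_groups(20), kind="linear", cv="loo")
        assert r.accuracy == 1.0

    def test_qda_separated(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        X[20:] += 8.0
        r = da_classify(X, two_groups(20), kind="quadratic", cv=("stratified", 5))
        assert r.accuracy == 1.0

    def test_permutation_null(self):
        # label permutation: mean CV accuracy within the binomial 95% band
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        accs = []
        for _ in range(100):
            y = np.array(["A"] * 10 + ["B"] * 10)
            rng.shuffle(y)
            accs.append(da_classify(X, y, cv=("stratified", 2), seed=0).accuracy)
        n_total = 100 * 20
        band = 1.96 * np.sqrt(0.25 / n_total)
        # fold-correlation inflates the variance; allow 2x the iid band
        assert abs(np.mean(accs) - 0.5) < 2 * band

    def test_lda_qda_agree_with_bayes_equal_covariance(self):
        # equal-covariance Gaussians: Bayes rule is linear, both DAs converge to it
        rng = np.random.default_rng(3)
        n = 4000
        mu = 1.2
        Xa = rng.normal(size=(n, 2))
        Xb = rng.normal(size=(n, 2)) + mu
        X = np.vstack([Xa, Xb])
        y = np.array(["A"] * n + ["B"] * n)
        from enoselab.classify import _fit_da

        lda = _fit_da(X, y, "linear")
        qda = _fit_da(X, y, "quadratic")
        grid = rng.normal(size=(2000, 2)) + mu / 2
        bayes = np.where(grid.sum(axis=1) > mu, "B", "A")
        assert np.mean(lda.predict(grid) == qda.predict(grid)) > 0.97
        assert np.mean(lda.predict(grid) == bayes) > 0.97

    def test_singular_covariance_fallback(self):
        # a constant column makes the covariance singular; shrinkage kicks in
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.normal(size=40), np.ones(40)])
        X[20:, 0] += 5.0
        r = da_classify(X, two_groups(20), kind="quadratic", cv=("stratified", 5))
        assert r.accuracy > 0.9


class TestStepwise:
    def test_informative_feature_selected_first(self):
        # one shifted feature among pure noise: picked first >= 95% of runs
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 20))
            y = two_groups(20)
            X[20:, 7] += 3.0  # effect size 3 on feature f07
            names = [f"f{i:02d}" for i in range(20)]
            sel = stepwise_select(X, y, names)
            if sel and sel[0] == "f07":
                hits += 1
        assert hits / n_runs >= 0.95

    def test_identical_features_one_entered(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=40)
        col[20:] += 3.0
        X = np.column_stack([col] * 4)
        sel = stepwise_select(X, two_groups(20), list("abcd"))
        assert len(sel) == 1

    def test_no_feature_entered_gives_chance_result(self, caplog):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2)) * 1e-6
        y = two_groups(15)
        # entry alpha of 0 blocks everything
        df = feature_frame(X, y)
        cfg = ClassifierConfig(sda_entry_alpha=1e-12, cv=("stratified", 3))
        sel, result = stepwise_da(df, cfg)
        assert sel == []
        assert 0.3 < result.accuracy < 0.7

    def test_two_group_requirement(self):
        with pytest.raises(ValueError, match="2 groups"):
            stepwise_select(np.zeros((4, 2)), np.array(["A"] * 4), ["a", "b"])

    def test_stepwise_da_end_to_end(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 10))
        X[20:, 3] += 3.0
        df = feature_frame(X, two_groups(20))
        sel, result = stepwise_da(df, ClassifierConfig(cv="loo"))
        assert "f03" in sel
        assert result.accuracy > 0.85


class TestGridSearch:
    def test_separable_reaches_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2)) * 0.1
        X[15:] += 5.0
        df = feature_frame(X, two_groups(15))
        cfg = ClassifierConfig(C_grid=(1.0, 10.0), sigma_grid=(0.5, 2.0, 10.0))
        C, sigma, acc = svm_grid_search(df, cfg)
        assert acc == 1.0

    def test_tiny_sigma_overfits_detected_by_cv(self):
        # sigma -> 0: every training point memorized, CV near chance
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = two_groups(15)
        df = feature_frame(X, y)
        Xz = (X - X.mean(0)) / X.std(0)
        clf = SVC(C=10.0, gamma=sigma_to_gamma(0.01)).fit(Xz, y)
        assert clf.score(Xz, y) == 1.0  # resubstitution is perfect
        cfg = ClassifierConfig(C_grid=(10.0,), sigma_grid=(0.01,))
        _, _, acc = svm_grid_search(df, cfg)
        assert acc < 0.65

    def test_tie_breaks_to_smaller_c_then_sigma(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 2)) * 0.1
        X[10:] += 5.0
        df = feature_frame(X, two_groups(10))
        cfg = ClassifierConfig(C_grid=(100.0, 1.0, 10.0), sigma_grid=(5.0, 1.0))
        C, sigma, acc = svm_grid_search(df, cfg)
        assert acc == 1.0
        assert C == 1.0 and sigma == 1.0


class TestFastSvmPath:
    def test_fast_path_matches_public_svc(self):
        # dual-route check for the libsvm shortcut used throughout selection
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = 24
            X = rng.normal(size=(n, 3))
            y = np.array(["A", "B"] * (n // 2))
            X[y == "B"] += rng.uniform(0.0, 2.0)
            D = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
            K = np.exp(-D / (2.0 * 3.0**2))
            splits = cv_splits(y, "loo")
            fast = _svm_cv_predict_precomputed(K, y, 10.0, splits)
            ref = np.empty(n, dtype=y.dtype)
            for tr, te in splits:
                clf = SVC(C=10.0, kernel="precomputed")
                clf.fit(K[np.ix_(tr, tr)], y[tr])
                ref[te] = clf.predict(K[np.ix_(te, tr)])
            np.testing.assert_array_equal(fast, ref)


class TestGreedySelection:
    def make_features(self, seed=0, n_per=10, n_feat=6, effect=3.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(2 * n_per, n_feat))
        X[n_per:, 2] += effect
        return feature_frame(X, two_groups(n_per))

    def test_requires_preset_c_sigma(self):
        with pytest.raises(ValueError, match="preset C and sigma"):
            greedy_svm_selection(self.make_features(), ClassifierConfig())

    def test_trace_length_bookkeeping(self):
        df = self.make_features(n_feat=4)
        cfg = ClassifierConfig(C=10.0, sigma=5.0, max_indices=10)
        trace = greedy_svm_selection(df, cfg)
        assert len(trace.steps) == 4  # min(max_indices, n_candidates)
        assert len(set(trace.names)) == 4  # no index chosen twice

    def test_informative_feature_first(self):
        trace = greedy_svm_selection(
            self.make_features(effect=4.0),
            ClassifierConfig(C=10.0, sigma=5.0, max_indices=2),
        )
        assert trace.names[0] == "f02"
        assert trace.steps[0][1].accuracy > 0.9

    def test_reproducibility(self):
        df = self.make_features(seed=3)
        cfg = ClassifierConfig(C=10.0, sigma=5.0, max_indices=3, cv=("stratified", 5), seed=11)
        a = greedy_svm_selection(df, cfg)
        b = greedy_svm_selection(df, cfg)
        assert a.names == b.names
        assert [r.to_dict() for _, r in a.steps] == [r.to_dict() for _, r in b.steps]

    def test_matches_bruteforce_first_two_steps(self):
        # quick version of the oracle-equivalence acceptance criterion
        for seed in (0, 1, 2):
            df = self.make_features(seed=seed, n_per=8, n_feat=5, effect=float(seed))
            cfg = ClassifierConfig(C=10.0, sigma=5.0, max_indices=2, cv="loo")
            trace = greedy_svm_selection(df, cfg)
            names = [c for c in df.columns if c not in ("subject_id", "group")]
            X = df[names].to_numpy(float)
            y = df["group"].to_numpy()
            Xz = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)

            def loo_acc(cols):
                correct = 0
                for i in range(len(y)):
                    tr = np.delete(np.arange(len(y)), i)
                    clf = SVC(C=10.0, gamma=sigma_to_gamma(5.0))
                    clf.fit(Xz[tr][:, cols], y[tr])
                    correct += clf.predict(Xz[i : i + 1, cols])[0] == y[i]
                return correct / len(y)

            best1 = max(
                ((n, loo_acc([names.index(n)])) for n in sorted(names)),
                key=lambda t: t[1],
            )
            # max() keeps the first of equal values = lexicographic tie rule
            assert trace.names[0] == best1[0]
            j1 = names.index(best1[0])
            best2 = max(
                ((n, loo_acc([j1, names.index(n)])) for n in sorted(names) if n != best1[0]),
                key=lambda t: t[1],
            )
            assert trace.names[1] == best2[0]

    def test_monotone_effect_response(self):
        # expected step-1 CV accuracy non-decreasing in injected effect size
        from enoselab import CohortSpec, generate_cohort, representative_curves
        from enoselab.features_time import extract_time_features

        n_seeds = 50
        mean_acc = []
        for effect in (0.0, 1.0, 2.0, 3.0):
            accs = []
            for seed in range(n_seeds):
                spec = CohortSpec(
                    n_per_group=10, n_sweeps=4, layers=1, temp_step_c=2.0,
                    effect_layer=1, effect_window=(90.0, 100.0),
                    effect_size=effect, seed=seed,
                )
                curves = representative_curves(generate_cohort(spec), spec.grid())
                ft = extract_time_features(curves)
                # sigma matched to single-index z-scored distances; sigma=20
                # underfits a one-feature kernel at this C
                cfg = ClassifierConfig(
                    C=10.0, sigma=2.0, max_indices=1, cv=("stratified", 4), seed=seed
                )
                trace = greedy_svm_selection(ft, cfg)
                accs.append(trace.steps[0][1].accuracy)
            mean_acc.append(np.mean(accs))
        for lo, hi in zip(mean_acc, mean_acc[1:]):
            assert hi >= lo - 0.03  # Monte-Carlo slack on a non-decreasing mean
        assert mean_acc[-1] > mean_acc[0] + 0.2

    def test_nested_eval_runs(self):
        df = self.make_features(effect=4.0)
        cfg = ClassifierConfig(C=10.0, sigma=5.0, max_indices=2, cv=("stratified", 5))
        r = nested_greedy_svm_eval(df, cfg)
        assert r.accuracy > 0.8

    def test_trace_frame_schema(self):
        trace = greedy_svm_selection(
            self.make_features(), ClassifierConfig(C=10.0, sigma=5.0, max_indices=2)
        )
        frame = trace.to_frame()
        assert list(frame.columns) == [
            "step", "index_name", "sensitivity", "specificity", "accuracy",
        ]
        assert list(frame["step"]) == [1, 2]
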
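"""Classifier-pipeline behavior: scaling, selection, scoring, patterns."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from itpcdecode import (
    PipelineConfig,
    decode_over_time,
    haufe_patterns,
    roc_auc,
    select_features_l1,
    standardize,
)
from itpcdecode.decoding import (
    _fit_fold,
    _fit_logistic,
    decode_matrix,
    stratified_folds,
)

from conftest import toy_dataset


class TestStandardize:
    def test_two_point_column(self):
        tr, te = standardize(np.array([[1.0], [3.0]]), np.array([[2.0]]))
        assert np.allclose(tr.ravel(), [-1.0, 1.0])  # population SD convention
        assert te[0, 0] == pytest.approx(0.0)

    def test_constant_column_maps_to_zero(self):
        tr, te = standardize(np.full((3, 1), 4.0), np.array([[9.0]]))
        assert np.all(tr == 0) and np.all(te == 0)

    def test_test_set_uses_train_statistics(self):
        tr, te = standardize(np.array([[0.0], [2.0]]), np.array([[4.0]]))
        assert te[0, 0] == pytest.approx(3.0)  # (4 - 1) / 1


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 1.0),
            ([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1], 0.0),
            ([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1], 0.5),
        ],
    )
    def test_reference_cases(self, scores, labels, expected):
        assert roc_auc(np.array(scores), np.array(labels)) == expected

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            scores = np.round(rng.standard_normal(n), 1)  # provoke ties
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            pos = scores[labels == 1][:, None]
            neg = scores[labels == 0][None, :]
            oracle = ((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (
                pos.shape[0] * neg.shape[1]
            )
            assert roc_auc(scores, labels) == pytest.approx(oracle, abs=1e-12)
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_large_input_rank_path_agrees(self, rng):
        scores = np.round(rng.standard_normal(200), 1)
        labels = rng.integers(0, 2, 200)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestStratifiedFolds:
    @pytest.mark.parametrize("ratio", [(17, 17), (51, 17)])
    def test_fold_ratios_match_dataset(self, ratio):
        y = np.r_[np.ones(ratio[0], int), np.zeros(ratio[1], int)]
        folds = stratified_folds(y, 5, seed=0)
        overall = ratio[0] / sum(ratio)
        test_sets = []
        for tr, te in folds:
            frac = y[te].mean()
            assert abs(frac - overall) <= 1.0 / len(te)
            test_sets.append(te)
        covered = np.sort(np.concatenate(test_sets))
        assert np.array_equal(covered, np.arange(sum(ratio)))

    def test_deterministic_given_seed(self):
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        a = stratified_folds(y, 4, seed=5)
        b = stratified_folds(y, 4, seed=5)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)

    def test_too_few_samples_rejected(self):
        y = np.array([1, 1, 1, 0, 0])
        with pytest.raises(ValueError, match="at least one per"):
            stratified_folds(y, 3, seed=0)


class TestFeatureSelection:
    def test_informative_feature_found_reliably(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((40, 50))
            y = np.r_[np.ones(20, int), np.zeros(20, int)]
            X[:, 7] = y * 2.0 + 0.1 * r.standard_normal(40)  # separates classes
            mask = select_features_l1(X, y, seed=seed)
            hits += bool(mask[7])
        assert hits >= 19  # >= 95% of seeded reruns

    def test_all_noise_engages_single_feature_fallback(self):
        X = np.zeros((20, 10))
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        mask = select_features_l1(X, y, seed=0)
        assert mask.sum() == 1

    def test_duplicated_informative_feature_retained(self, rng):
        X = rng.standard_normal((40, 20))
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        signal = y * 2.0 + 0.1 * rng.standard_normal(40)
        X[:, 3] = signal
        X[:, 11] = signal
        mask = select_features_l1(X, y, seed=1)
        assert mask[3] or mask[11]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            select_features_l1(np.zeros((5, 3)), np.ones(5, int))

    def test_engines_agree(self, rng):
        for seed in range(8):
            r = np.random.default_rng(100 + seed)
            X = r.standard_normal((27, 8))
            y = r.integers(0, 2, 27)
            if np.bincount(y, minlength=2).min() < 4:
                continue
            fast = select_features_l1(X, y, seed=seed, n_alphas=10, engine="fast")
            skl = select_features_l1(X, y, seed=seed, n_alphas=10, engine="sklearn")
            assert np.array_equal(fast, skl)


class TestLogisticEngines:
    def test_weights_agree_with_sklearn(self, rng):
        worst = 0.0
        for _ in range(10):
            X = rng.standard_normal((25, 4))
            y = rng.integers(0, 2, 25)
            if len(np.unique(y)) < 2:
                continue
            wf, bf = _fit_logistic(X, y, 1.0, "fast")
            ws, bs = _fit_logistic(X, y, 1.0, "sklearn")
            worst = max(worst, float(np.abs(wf - ws).max()), abs(bf - bs))
        assert worst < 1e-6


class TestDecodeOverTime:
    def test_null_features_score_near_chance(self, rng):
        ds = toy_dataset(rng, n_subjects=17, n_features=6, n_times=12)
        res = decode_over_time(ds, PipelineConfig(n_alphas=10, seed=0))
        assert 0.4 < res.mean_auc.mean() < 0.6

    def test_injected_effect_recovered_in_window(self, rng):
        ds = toy_dataset(
            rng,
            n_subjects=17,
            n_features=8,
            n_times=8,
            effect=2.5,
            effect_times=slice(3, 6),
        )
        res = decode_over_time(ds, PipelineConfig(n_alphas=10, seed=0))
        assert res.mean_auc[3:6].min() > 0.9
        assert res.mean_auc[[0, 1, 7]].max() < 0.75

    def test_feature_scaling_invariance(self, rng):
        ds = toy_dataset(rng, n_subjects=12, n_features=5, n_times=4, effect=1.0)
        res1 = decode_over_time(ds, PipelineConfig(n_alphas=8, seed=3))
        ds.X = ds.X * 7.0
        res2 = decode_over_time(ds, PipelineConfig(n_alphas=8, seed=3))
        assert np.allclose(res1.fold_aucs, res2.fold_aucs)

    def test_deterministic_given_seed(self, rng):
        ds = toy_dataset(rng, n_subjects=10, n_features=5, n_times=3)
        a = decode_over_time(ds, PipelineConfig(n_alphas=8, seed=4))
        b = decode_over_time(ds, PipelineConfig(n_alphas=8, seed=4))
        assert np.array_equal(a.fold_aucs, b.fold_aucs)
        for ma, mb in zip(a.selected, b.selected):
            for fa, fb in zip(ma, mb):
                assert np.array_equal(fa, fb)

    def test_train_score_dominates_test_score(self, rng):
        """Anti-leakage sanity: in-sample AUC should beat out-of-sample."""
        ds = toy_dataset(rng, n_subjects=14, n_features=10, n_times=6, effect=0.8)
        cfg = PipelineConfig(n_alphas=8, seed=0)
        folds = stratified_folds(ds.y, cfg.outer_folds, cfg.seed)
        train_aucs, test_aucs = [], []
        for ti in range(ds.n_times):
            X = ds.X[:, :, ti]
            for tr, te in folds:
                auc, mask, w_full, train_z = _fit_fold(
                    X, ds.y, tr, te, cfg, collect_model=True
                )
                train_scores = train_z[:, mask] @ w_full[mask]
                train_aucs.append(roc_auc(train_scores, ds.y[tr]))
                test_aucs.append(auc)
        assert np.mean(train_aucs) >= np.mean(test_aucs)

    def test_engines_give_close_scores(self, rng):
        ds = toy_dataset(rng, n_subjects=12, n_features=6, n_times=5, effect=1.2)
        fast = decode_over_time(ds, PipelineConfig(n_alphas=10, seed=2, engine="fast"))
        skl = decode_over_time(ds, PipelineConfig(n_alphas=10, seed=2, engine="sklearn"))
        assert np.abs(fast.fold_aucs - skl.fold_aucs).max() < 0.05
        assert np.abs(fast.mean_auc - skl.mean_auc).mean() < 0.01

    def test_too_few_rows_for_folds(self, rng):
        ds = toy_dataset(rng, n_subjects=3, n_features=4, n_times=2)
        with pytest.raises(ValueError, match="at least one per"):
            decode_over_time(ds, PipelineConfig(seed=0))


class TestHaufePatterns:
    def test_identity_covariance_pattern_proportional_to_weights(self, rng):
        # whiten exactly: orthonormalize centered columns => sample cov = I
        n = 50
        a = rng.standard_normal((n, 3))
        a -= a.mean(0)
        X = np.linalg.qr(a)[0] * np.sqrt(n - 1)
        w = np.array([1.5, -0.5, 0.2])
        pm = haufe_patterns(w, X)
        cov = np.cov(X, rowvar=False)
        expected = cov @ w / (w @ cov @ w)
        assert np.allclose(pm.pattern, expected, atol=1e-10)

    def test_hand_computed_two_feature_case(self, rng):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        # build a matrix with exactly this sample covariance
        n = 40
        a = rng.standard_normal((n, 2))
        a -= a.mean(0)
        z = np.linalg.qr(a)[0] * np.sqrt(n - 1)
        X = z @ np.linalg.cholesky(C).T
        w = np.array([1.0, 0.0])
        pm = haufe_patterns(w, X)
        ratio = pm.pattern / pm.pattern[0]
        assert np.allclose(ratio, [1.0, 0.5], atol=1e-8)

    def test_informative_feature_has_peak_pattern(self, rng):
        n = 60
        y = np.r_[np.ones(30), -np.ones(30)]
        X = rng.standard_normal((n, 12))
        X[:, 4] += 2.0 * y
        w, b = _fit_logistic(X, (y > 0).astype(int), 1.0, "fast")
        pm = haufe_patterns(w, X)
        assert np.argmax(np.abs(pm.pattern)) == 4
        assert pm.top_mask.sum() == 1  # 5% of 12 rounds to at least one

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            haufe_patterns(np.zeros(3), np.random.default_rng(0).standard_normal((10, 3)))
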
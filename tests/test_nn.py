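import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dualrisk.cohort import Cohort, FeatureSpec
from dualrisk.nn import (
    EarlyStopper,
    MetricsReport,
    NetConfig,
    ResNetClassifier,
    TrainConfig,
    _bce,
    _Core,
    auc_confidence_interval,
    build_network,
    evaluate,
    split_data,
    train,
    undersample,
)


def gaussian_cloud_cohort(n=2000, gap=4.0, seed=0, extra_feature=False):
    """Two well-separated Gaussian clouds -> a nearly separable problem."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x1 = rng.normal(gap * y, 1.0)
    x2 = rng.normal(-gap * y, 1.0)
    feats = {"x1": x1, "x2": x2}
    specs = [
        FeatureSpec("x1", "continuous", perturbation_unit=1.0),
        FeatureSpec("x2", "continuous", perturbation_unit=1.0),
    ]
    if extra_feature:
        feats["x3"] = rng.normal(1.5 * y, 1.0)
        specs.append(FeatureSpec("x3", "continuous", perturbation_unit=1.0))
    y = y.astype(np.int64)
    return Cohort(
        features=pd.DataFrame(feats),
        y=y, y_documented=y, y_coded=np.zeros_like(y),
        feature_specs=specs, seed=seed,
    )


class TestArchitecture:
    def test_parameter_count_matches_layer_arithmetic(self):
        d, h, blocks = 20, 32, 2
        # stem d*h+h; per block two linears (h^2+h) and two layer norms (2h)
        expected = d * h + h + blocks * (2 * (h * h + h) + 2 * 2 * h) + h + 1
        core = _Core(NetConfig(d, h, blocks, 0.25), seed=0)
        assert core.param_count() == expected

    def test_zeroed_weights_predict_one_half(self):
        core = _Core(NetConfig(4, 8, 2, 0.0), seed=0)
        for k in core.params:
            core.params[k][...] = 0.0
        prob, _ = core.forward(np.random.default_rng(0).normal(size=(5, 4)))
        assert np.allclose(prob, 0.5)

    def test_initialisation_is_seed_reproducible(self):
        X = np.random.default_rng(1).normal(size=(3, 6))
        a, _ = _Core(NetConfig(6, 16), seed=42).forward(X)
        b, _ = _Core(NetConfig(6, 16), seed=42).forward(X)
        c, _ = _Core(NetConfig(6, 16), seed=43).forward(X)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_inference_mode_is_deterministic_despite_dropout(self):
        core = _Core(NetConfig(6, 16, 2, 0.5), seed=0)
        X = np.random.default_rng(1).normal(size=(10, 6))
        p1, _ = core.forward(X, training=False)
        p2, _ = core.forward(X, training=False)
        assert np.array_equal(p1, p2)

    def test_backward_matches_finite_differences(self):
        cfg = NetConfig(5, 8, 2, 0.0)
        core = _Core(cfg, seed=3)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 5))
        y = rng.integers(0, 2, 7).astype(float)
        prob, cache = core.forward(X)
        grads = core.backward(cache, (prob - y) / len(y))
        eps = 1e-6
        for key, value in core.params.items():
            flat_idx = rng.integers(0, value.size, size=3)
            for fi in flat_idx:
                ix = np.unravel_index(fi, value.shape)
                old = value[ix]
                value[ix] = old + eps
                lp, _ = core.forward(X)
                value[ix] = old - eps
                lm, _ = core.forward(X)
                value[ix] = old
                numeric = (_bce(lp, y) - _bce(lm, y)) / (2 * eps)
                assert grads[key][ix] == pytest.approx(numeric, rel=1e-4, abs=1e-9)


class TestSplit:
    def test_ratio_sizes(self):
        s = split_data(1000, (0.64, 0.16, 0.20), seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (640, 160, 200)

    def test_partition_and_determinism(self):
        s1 = split_data(1003, seed=5)
        s2 = split_data(1003, seed=5)
        union = np.concatenate([s1.train, s1.validation, s1.test])
        assert np.array_equal(np.sort(union), np.arange(1003))
        for a, b in zip((s1.train, s1.validation, s1.test),
                        (s2.train, s2.validation, s2.test)):
            assert np.array_equal(a, b)

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            split_data(10, (0.999, 0.0005, 0.0005), seed=0)

    def test_holdout_prevalence_unchanged(self, cohort_20k):
        s = split_data(cohort_20k, seed=3)
        overall = cohort_20k.y.mean()
        assert abs(cohort_20k.y[s.validation].mean() - overall) < 0.01
        assert abs(cohort_20k.y[s.test].mean() - overall) < 0.01


class TestUndersample:
    def test_keeps_all_minority_and_balances(self):
        labels = np.r_[np.ones(100), np.zeros(1000)].astype(int)
        idx = undersample(labels, np.arange(1100), seed=0)
        assert len(idx) == 200
        assert labels[idx].sum() == 100
        assert set(np.flatnonzero(labels == 1)) <= set(idx)

    def test_balanced_input_is_noop(self):
        labels = np.r_[np.ones(50), np.zeros(50)].astype(int)
        idx = undersample(labels, np.arange(100), seed=0)
        assert np.array_equal(idx, np.arange(100))

    def test_seed_reproducible(self):
        labels = (np.random.default_rng(0).random(500) < 0.2).astype(int)
        a = undersample(labels, np.arange(500), seed=9)
        b = undersample(labels, np.arange(500), seed=9)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            undersample(np.ones(10, dtype=int), np.arange(10), seed=0)


class TestEarlyStopping:
    def test_patience_one_stops_on_second_stale_epoch(self):
        stopper = EarlyStopper(patience=1)
        assert not stopper.update(0, 0.5)
        assert stopper.update(1, 0.4)  # stops at the second epoch
        assert stopper.best_epoch == 0

    def test_running_max_requires_strict_improvement(self):
        stopper = EarlyStopper(patience=2)
        stopper.update(0, 0.5)
        stopper.update(1, 0.5)  # tie does not reset patience
        assert stopper.update(2, 0.5)
        assert stopper.best_epoch == 0


class TestTraining:
    def test_separable_toy_reaches_high_f1(self):
        cohort = gaussian_cloud_cohort(n=2000, seed=1)
        splits = split_data(cohort, seed=2)
        net = build_network(NetConfig(2, 16), seed=3, feature_specs=cohort.feature_specs)
        net = train(net, cohort, splits, TrainConfig(max_epochs=60, seed=4))
        assert net.best_val_f1 >= 0.95

    def test_restored_weights_reproduce_best_validation_f1(self):
        from sklearn.metrics import f1_score

        cohort = gaussian_cloud_cohort(n=1200, gap=2.0, seed=5)
        splits = split_data(cohort, seed=6)
        net = build_network(NetConfig(2, 16), seed=7, feature_specs=cohort.feature_specs)
        net = train(
            net, cohort, splits,
            TrainConfig(max_epochs=30, restore_best=True, seed=8),
        )
        prob = net.predict_proba(cohort.features.iloc[splits.validation])
        f1 = f1_score(cohort.y[splits.validation], (prob >= 0.5).astype(int))
        assert f1 == pytest.approx(net.best_val_f1, abs=1e-12)
        assert net.history["val_f1"].max() == pytest.approx(net.best_val_f1)

    def test_informative_feature_never_hurts_over_seeds(self):
        # adding a strictly informative feature should not decrease the
        # achievable validation F1 beyond seed noise
        f1_base, f1_extra = [], []
        for seed in range(5):
            for extra, sink in ((False, f1_base), (True, f1_extra)):
                cohort = gaussian_cloud_cohort(
                    n=1500, gap=1.0, seed=100 + seed, extra_feature=extra
                )
                splits = split_data(cohort, seed=seed)
                net = build_network(
                    NetConfig(3 if extra else 2, 16), seed=seed,
                    feature_specs=cohort.feature_specs,
                )
                net = train(net, cohort, splits, TrainConfig(max_epochs=30, seed=seed))
                sink.append(net.best_val_f1)
        assert np.mean(f1_extra) >= np.mean(f1_base) - 0.02


class TestEvaluate:
    @staticmethod
    def _cohort_with_scores(scores, labels):
        class Fixed:
            def __init__(self, p):
                self.p = np.asarray(p, dtype=float)

            def predict_proba(self, features):
                return self.p[features.index.to_numpy()]

        y = np.asarray(labels, dtype=np.int64)
        cohort = Cohort(
            features=pd.DataFrame({"f": np.zeros(len(y), dtype=np.int64)}),
            y=y, y_documented=y, y_coded=np.zeros_like(y),
            feature_specs=[FeatureSpec("f", "binary")],
        )
        return Fixed(scores), cohort

    def test_perfect_predictor_scores_one(self):
        model, cohort = self._cohort_with_scores(
            [0.9, 0.8, 0.95, 0.1, 0.2, 0.05], [1, 1, 1, 0, 0, 0]
        )
        rep = evaluate(model, cohort, np.arange(6))
        assert (rep.f1, rep.accuracy, rep.precision, rep.recall, rep.auc) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_uninformative_predictor_has_half_auc(self):
        model, cohort = self._cohort_with_scores([0.5] * 6, [1, 0, 1, 0, 1, 0])
        rep = evaluate(model, cohort, np.arange(6))
        assert rep.auc == pytest.approx(0.5)

    def test_hand_computed_confusion_matrix(self):
        # scores .9 .7 .6 .4 .3 .1 / labels 1 0 1 1 0 0, threshold .5:
        # TP=2 FP=1 FN=1 TN=2 -> precision 2/3, recall 2/3, acc 4/6
        model, cohort = self._cohort_with_scores(
            [0.9, 0.7, 0.6, 0.4, 0.3, 0.1], [1, 0, 1, 1, 0, 0]
        )
        rep = evaluate(model, cohort, np.arange(6))
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(4 / 6)
        assert rep.f1 == pytest.approx(2 / 3)
        # pairwise AUC: 7 of 9 positive-negative pairs correctly ordered
        assert rep.auc == pytest.approx(7 / 9)

    def test_auc_equals_pairwise_comparison(self):
        rng = np.random.default_rng(4)
        scores = np.round(rng.random(300), 2)  # induce ties
        labels = (rng.random(300) < 0.4).astype(int)
        model, cohort = self._cohort_with_scores(scores, labels)
        rep = evaluate(model, cohort, np.arange(300))
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert rep.auc == pytest.approx(brute, abs=1e-12)

    def test_single_class_reports_auc_not_available(self):
        model, cohort = self._cohort_with_scores([0.9, 0.2, 0.7], [1, 1, 1])
        rep = evaluate(model, cohort, np.arange(3))
        assert rep.auc is None and rep.auc_ci is None
        assert rep.recall == pytest.approx(2 / 3)


class TestAucConfidenceInterval:
    def test_published_testset_interval(self):
        low, high = auc_confidence_interval(0.782, 29_338, 141_922, 0.95)
        assert round(low, 3) == 0.779
        assert round(high, 3) == 0.785

    def test_width_shrinks_with_sample_size(self):
        w = []
        for n in (100, 10_000, 1_000_000):
            low, high = auc_confidence_interval(0.8, n, n)
            w.append(high - low)
        assert w[0] > w[1] > w[2]
        # SE ~ 1/sqrt(n+ n-): width falls by ~10x per 100x in n
        assert w[2] < w[0] / 50

    def test_symmetric_about_one_half(self):
        low, high = auc_confidence_interval(0.5, 500, 500)
        assert low + high == pytest.approx(1.0)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            auc_confidence_interval(0.8, 10, 10, level=1.5)
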
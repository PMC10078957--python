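"""Classifier training, the kernel-scale heuristic, and leave-one-out CV."""

import numpy as np
import pytest

from serpbci.classify import (
    ChannelDataset,
    ClassifierSpec,
    DegenerateDataError,
    confusion_table,
    kernel_scale_heuristic,
    loo_crossval,
    predict,
    train,
)
from conftest import make_dataset


class TestKernelScaleHeuristic:
    def test_two_points_give_their_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert kernel_scale_heuristic(X) == pytest.approx(5.0)

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 4))
        assert kernel_scale_heuristic(7.0 * X) == pytest.approx(
            7.0 * kernel_scale_heuristic(X)
        )

    def test_matches_exhaustive_pairs_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 6))
        dists = [
            np.linalg.norm(X[i] - X[j])
            for i in range(10) for j in range(i + 1, 10)
        ]
        assert len(dists) == 45
        assert kernel_scale_heuristic(X, subsample=100) == pytest.approx(
            float(np.median(dists))
        )

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kernel_scale_heuristic(np.ones((5, 3)))

    def test_subsample_is_seeded(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 3))
        a = kernel_scale_heuristic(X, subsample=20, seed=5)
        b = kernel_scale_heuristic(X, subsample=20, seed=5)
        assert a == b


class TestTrain:
    @pytest.mark.parametrize("kind", ["SVM", "LDA"])
    def test_separable_1d_classes(self, kind):
        X = np.array([[-1.0], [-1.1], [-0.9], [1.0], [1.1], [0.9]])
        y = np.array(["AD", "AD", "AD", "AV", "AV", "AV"])
        model = train(ClassifierSpec(kind=kind), X, y)
        assert np.all(predict(model, X) == y)

    def test_lda_matches_closed_form_discriminant(self):
        """With equal priors, LDA predicts by the sign of the closed-form
        discriminant w.x + b, w = S^-1 (mu1 - mu0), b = -w.(mu0 + mu1)/2,
        computed here from sample moments independently of the fit."""
        rng = np.random.default_rng(3)
        mu = np.array([1.0, -0.5, 2.0])
        X = np.vstack([
            -mu + 0.3 * rng.standard_normal((40, 3)),
            mu + 0.3 * rng.standard_normal((40, 3)),
        ])
        y = np.array(["AD"] * 40 + ["AV"] * 40)
        model = train(ClassifierSpec(kind="LDA"), X, y)
        mu0, mu1 = X[:40].mean(axis=0), X[40:].mean(axis=0)
        pooled = 0.5 * (np.cov(X[:40].T, bias=True) + np.cov(X[40:].T, bias=True))
        w = np.linalg.solve(pooled, mu1 - mu0)
        b = -0.5 * w @ (mu0 + mu1)
        probes = rng.standard_normal((200, 3))
        d = probes @ w + b
        probes, d = probes[np.abs(d) > 1e-6], d[np.abs(d) > 1e-6]
        expected = np.where(d > 0, "AV", "AD")
        assert np.all(predict(model, probes) == expected)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            train(ClassifierSpec(), np.zeros((4, 2)), np.array(["AD"] * 4))

    def test_null_training_accuracy_near_chance_on_holdout(self):
        """Identical class distributions: held-out accuracy hovers at 50%."""
        rng = np.random.default_rng(4)
        accs = []
        for _ in range(20):
            X = rng.standard_normal((40, 10))
            y = np.array(["AD"] * 20 + ["AV"] * 20)
            model = train(ClassifierSpec(kind="LDA"), X, y)
            probe = rng.standard_normal((50, 10))
            truth = rng.choice(["AD", "AV"], 50)
            accs.append(np.mean(predict(model, probe) == truth))
        assert abs(np.mean(accs) - 0.5) < 0.05


class TestLooCrossval:
    def test_fold_count_and_each_example_tested_once(self):
        ds = make_dataset(np.random.default_rng(0), m=6)
        res = loo_crossval(ds, "F1")
        assert len(res.predictions) == 12
        assert sorted(f.held_out for f in res.folds) == list(range(12))

    @pytest.mark.parametrize("kind", ["SVM", "LDA"])
    def test_noise_free_strong_effect_is_perfect(self, kind):
        ds = make_dataset(np.random.default_rng(1), m=8, shift=3.0, noise=0.05)
        res = loo_crossval(ds, "F2", ClassifierSpec(kind=kind))
        assert res.accuracy_pct == 100.0

    def test_accuracy_equals_tp_sum(self):
        ds = make_dataset(np.random.default_rng(2), m=8, shift=0.8, noise=1.0)
        res = loo_crossval(ds, "F1")
        conf = res.confusion_pct
        assert res.accuracy_pct == pytest.approx(conf["TP_D"] + conf["TP_V"])
        assert sum(conf.values()) == pytest.approx(100.0)

    def test_fs_selection_recorded_per_fold(self):
        ds = make_dataset(np.random.default_rng(3), m=6, shift=2.0, noise=0.3)
        res = loo_crossval(ds, "FS2", selection=0.5)
        for fold in res.folds:
            assert fold.threshold_uV is not None
            assert fold.selected_indexes

    def test_too_few_examples_raises(self):
        ds = make_dataset(np.random.default_rng(4), m=1)
        with pytest.raises(ValueError):
            loo_crossval(ds, "F1")

    def test_no_leakage_mutating_held_out_example(self):
        """Changing the held-out example must not change the training-fold
        feature selection or the fitted model of its own fold."""
        rng = np.random.default_rng(5)
        ds = make_dataset(rng, m=6, shift=1.5, noise=0.5)
        res = loo_crossval(ds, "FS2", selection="inner", keep_models=True)
        mutated = {k: v.copy() for k, v in ds.serps.items()}
        mutated["ADSD"][0] += 100.0  # corrupt AD example 0 only
        mutated["ADSV"][0] -= 50.0
        ds2 = ChannelDataset(ds.channel, mutated, ds.n_avg)
        res2 = loo_crossval(ds2, "FS2", selection="inner", keep_models=True)
        f1, f2 = res.folds[0], res2.folds[0]  # fold holding out AD example 0
        assert f1.threshold_uV == f2.threshold_uV
        assert f1.selected_indexes == f2.selected_indexes
        np.testing.assert_array_equal(f1.model_signature, f2.model_signature)

    @pytest.mark.parametrize("pair", [("FS1", "F1"), ("FS2", "F2")])
    def test_threshold_zero_degenerates_to_base_method(self, pair):
        fs, base = pair
        ds = make_dataset(np.random.default_rng(6), m=8, shift=1.0, noise=1.0)
        for kind in ("SVM", "LDA"):
            spec = ClassifierSpec(kind=kind)
            a = loo_crossval(ds, fs, spec, selection=0.0)
            b = loo_crossval(ds, base, spec)
            np.testing.assert_array_equal(a.predictions, b.predictions)


class TestConfusion:
    def _result(self, truths, preds):
        from serpbci.classify import CVResult

        return CVResult("C3", "F1", 10, "SVM", np.array(preds), np.array(truths))

    def test_all_correct_balanced(self):
        res = self._result(["AD", "AD", "AV", "AV"], ["AD", "AD", "AV", "AV"])
        assert confusion_table(res) == {
            "TP_D": 50.0, "FP_D": 0.0, "FP_V": 0.0, "TP_V": 50.0,
        }

    def test_constant_predictor(self):
        res = self._result(["AD", "AD", "AV", "AV"], ["AD"] * 4)
        conf = confusion_table(res)
        assert conf["TP_D"] == 50.0 and conf["FP_V"] == 50.0
        assert conf["TP_V"] == 0.0 and conf["FP_D"] == 0.0

    def test_counting_oracle_on_random_folds(self):
        rng = np.random.default_rng(7)
        truths = rng.choice(["AD", "AV"], 40)
        preds = rng.choice(["AD", "AV"], 40)
        conf = confusion_table(self._result(truths, preds))
        count = lambda t, p: sum(
            1 for a, b in zip(truths, preds) if a == t and b == p
        ) / 40 * 100
        assert conf["TP_D"] == pytest.approx(count("AD", "AD"))
        assert conf["FP_D"] == pytest.approx(count("AD", "AV"))
        assert conf["FP_V"] == pytest.approx(count("AV", "AD"))
        assert conf["TP_V"] == pytest.approx(count("AV", "AV"))
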
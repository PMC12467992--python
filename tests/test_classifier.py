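"""Preprocessing, fold construction, network mechanics and metrics."""

import numpy as np
import pytest

from flowconn.classifier import (CONCUSSED, CONTROL, ConcNetClassifier,
                                 ModelConfig, confusion_counts, evaluate,
                                 make_folds, metrics_from_cm,
                                 predict_participant, RealizationResult,
                                 trapezoidal_auc)
from flowconn.nn import build_concnet, cross_entropy, softmax
from flowconn.preprocess import (RawRecording, preprocess_recording,
                                 segment_epochs)


def make_recording(duration, fs, n_channels=64, seed=0):
    rng = np.random.default_rng(seed)
    return RawRecording(signal=rng.standard_normal(
        (n_channels, int(duration * fs))), fs=fs, participant_id="p0",
        label=CONTROL)


class TestPreprocess:
    def test_trim_resample_shape(self):
        rec = preprocess_recording(make_recording(300, 500))
        assert rec.fs == 250
        assert rec.signal.shape == (64, 73_000)  # (300 - 8) s * 250 Hz

    def test_native_rate_only_trimmed_and_filtered(self):
        rec = preprocess_recording(make_recording(100, 250))
        assert rec.fs == 250
        assert rec.signal.shape == (64, 92 * 250)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            preprocess_recording(make_recording(7, 250))

    def test_butterworth_attenuation_at_1p2x_cutoff(self):
        """A 5th-order Butterworth attenuates a tone at 1.2x its cutoff by
        ~8.6 dB = 10*log10(1 + 1.2^10).  Checked with cutoff << Nyquist,
        where the digital design tracks the analog magnitude curve."""
        fs = 250.0
        t = np.arange(int(fs * 60)) / fs
        tone = np.sin(2 * np.pi * 12.0 * t)
        rec = RawRecording(signal=np.tile(tone, (64, 1)), fs=fs)
        out = preprocess_recording(rec, trim_s=4.0, cutoff_hz=10.0)
        seg = out.signal[0, 5000:]  # steady state of the causal filter
        att_db = -20 * np.log10(np.sqrt(2) * seg.std())
        expected = 10 * np.log10(1 + 1.2 ** 10)
        assert att_db == pytest.approx(expected, abs=0.4)

    def test_default_chain_suppresses_120hz(self):
        """At the study settings (100 Hz cutoff, fs 250) a 120 Hz tone is
        attenuated at least as much as the analog curve predicts."""
        fs = 250.0
        t = np.arange(int(fs * 40)) / fs
        rec = RawRecording(signal=np.tile(np.sin(2 * np.pi * 120 * t),
                                          (64, 1)), fs=fs)
        out = preprocess_recording(rec, trim_s=4.0)
        seg = out.signal[0, 2000:]
        att_db = -20 * np.log10(np.sqrt(2) * seg.std() + 1e-12)
        assert att_db >= 10 * np.log10(1 + 1.2 ** 10)

    def test_segment_counts(self):
        rec = make_recording(300, 250)
        assert len(segment_epochs(rec)) == 30
        rec292 = make_recording(292, 250)
        assert len(segment_epochs(rec292)) == 29
        with pytest.warns(RuntimeWarning):
            assert segment_epochs(make_recording(9, 250)) == []

    def test_epochs_shape_and_labels(self):
        eps = segment_epochs(make_recording(35, 250))
        assert all(e.segment.shape == (64, 2500) for e in eps)
        assert all(e.label == CONTROL for e in eps)


class TestFolds:
    @staticmethod
    def study_labels():
        labels = {f"HC_{k:02d}": CONTROL for k in range(1, 16)}
        labels.update({f"CC_{k:02d}": CONCUSSED for k in range(1, 12)})
        return labels

    def test_study_cohort_fold_sizes(self):
        """15 + 11 participants, 6 folds: train 8+8, test 6+2, validation 1+1."""
        plan = make_folds(self.study_labels(), repeats=5, folds=6, seed=0)
        assert len(plan.folds) == 30
        labels = self.study_labels()
        for f in plan.folds:
            train_by = [labels[p] for p in f["train"]]
            test_by = [labels[p] for p in f["test"]]
            val_by = [labels[p] for p in f["val"]]
            assert train_by.count(CONTROL) == train_by.count(CONCUSSED) == 8
            assert test_by.count(CONTROL) == 6
            assert test_by.count(CONCUSSED) == 2
            assert val_by.count(CONTROL) == val_by.count(CONCUSSED) == 1

    def test_no_leakage_any_fold(self):
        plan = make_folds(self.study_labels(), repeats=5, folds=6, seed=3)
        plan.assert_no_leakage()  # hard assertion on every fold
        for f in plan.folds:
            assert not set(f["train"]) & set(f["test"])

    def test_every_participant_tested_each_repeat(self):
        plan = make_folds(self.study_labels(), repeats=5, folds=6, seed=1)
        for rep in range(5):
            tested = set()
            for f in plan.folds[rep * 6:(rep + 1) * 6]:
                tested.update(f["test"])
            assert tested == set(self.study_labels())

    def test_repeats_shuffle_participants(self):
        plan = make_folds(self.study_labels(), repeats=2, folds=6, seed=5)
        assert plan.folds[0]["test"] != plan.folds[6]["test"]

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_folds({"a": CONTROL, "b": CONCUSSED}, folds=6)


class TestNetwork:
    def test_parameter_count_is_31514(self):
        """24-unit bLSTM x2, dense 8 and 2, with 64 input channels."""
        net = build_concnet(n_channels=64)
        assert net.n_params() == 31_514

    def test_softmax_probabilities_sum_to_one(self, rng):
        net = build_concnet(n_channels=5, lstm_units=4, fc_hidden=3, seed=0)
        probs = net.predict_proba(rng.standard_normal((9, 20, 5)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-12)
        assert np.all(probs >= 0)

    def test_gradients_match_numerical(self, rng):
        net = build_concnet(n_channels=3, lstm_units=4, fc_hidden=3, seed=1)
        X = rng.standard_normal((4, 6, 3))
        y = np.eye(2)[rng.integers(0, 2, 4)]
        logits = net.forward(X, train=False)
        d = (softmax(logits) - y) / X.shape[0]
        for layer in reversed(net.layers):
            d = layer.backward(d)
        grads = {k: v.copy() for k, v in net.grads().items()}
        params = net.params()
        eps = 1e-6
        for name, p in params.items():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = cross_entropy(softmax(net.forward(X, train=False)), y)
            p[idx] = orig - eps
            lm = cross_entropy(softmax(net.forward(X, train=False)), y)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_overfits_small_separable_set(self):
        """A tiny separable set is fit to 100% with a gentler learning rate."""
        rng = np.random.default_rng(0)
        t = np.arange(64) / 64.0
        X = np.stack([np.tile(np.sin(2 * np.pi * (4 + 8 * (k % 2)) * t)
                              + 0.1 * rng.standard_normal(64), (6, 1))
                      for k in range(8)])
        y = np.array([CONTROL, CONCUSSED] * 4)
        clf = ConcNetClassifier(lstm_units=8, fc_hidden=4, lr=0.003,
                                epochs=50, dropout=0.1, seed=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_fit_is_seeded_deterministic(self, rng):
        X = rng.standard_normal((10, 4, 30))
        y = np.array([CONTROL, CONCUSSED] * 5)
        p1 = ConcNetClassifier(lstm_units=4, fc_hidden=3, epochs=2,
                               seed=7).fit(X, y).predict_proba(X)
        p2 = ConcNetClassifier(lstm_units=4, fc_hidden=3, epochs=2,
                               seed=7).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_sklearn_params_roundtrip(self):
        clf = ConcNetClassifier()
        params = clf.get_params()
        assert params["lstm_units"] == 24
        assert params["dropout"] == 0.32
        assert params["lr"] == 0.03
        assert params["batch_size"] == 12
        assert params["epochs"] == 5
        clf.set_params(epochs=2)
        assert clf.epochs == 2


class TestPrediction:
    def test_participant_median_rule(self):
        assert predict_participant([0.9, 0.9, 0.9]) == (0.9, CONCUSSED)
        p, lab = predict_participant([0.2, 0.6, 0.4])
        assert p == pytest.approx(0.4)
        assert lab == CONTROL

    def test_boundary_is_strictly_greater(self):
        assert predict_participant([0.5, 0.5])[1] == CONTROL


class TestMetrics:
    def test_confusion_ratio_metrics(self):
        cm = {"TP": 9, "FN": 1, "FP": 2, "TN": 8}
        m = metrics_from_cm(cm)
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["recall"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["precision"] == pytest.approx(100 * 9 / 11)
        f1 = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
        assert m["f1"] == pytest.approx(f1)

    def test_perfect_separation_auc(self):
        y = [CONCUSSED] * 3 + [CONTROL] * 3
        assert trapezoidal_auc(y, [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]) == 1.0

    def test_chance_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        y = [CONCUSSED, CONTROL] * 200
        aucs = [trapezoidal_auc(y, rng.random(400)) for _ in range(50)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = [CONCUSSED] * 10 + [CONTROL] * 10
        s = rng.random(20)
        a1 = trapezoidal_auc(y, s)
        a2 = trapezoidal_auc(y, np.exp(5 * s) + 3)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_truth_gives_nan_auc(self):
        assert np.isnan(trapezoidal_auc([CONCUSSED] * 4, [0.1, 0.2, 0.3, 0.4]))

    def test_evaluate_bookkeeping_conservation(self):
        reals = [
            RealizationResult(["a", "b"], [CONCUSSED, CONTROL],
                              [CONCUSSED, CONCUSSED], [0.9, 0.6], 0, 0),
            RealizationResult(["a", "c"], [CONCUSSED, CONTROL],
                              [CONTROL, CONTROL], [0.4, 0.2], 0, 1),
        ]
        res = evaluate(reals)
        total_errors = sum(v["errors"]
                           for v in res.misclassification.values())
        off_diag = res.total_cm["FP"] + res.total_cm["FN"]
        assert total_errors == off_diag == 2
        assert res.misclassification["a"]["tested"] == 2
        assert res.misclassification["a"]["errors"] == 1
        assert res.summary["accuracy"]["mean"] == pytest.approx(50.0)
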
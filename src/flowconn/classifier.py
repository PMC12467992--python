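"""ConcNet: bidirectional-LSTM classification of raw EEG epochs.

The network stacks two bidirectional LSTM layers of 24 units per direction
(sequence-to-sequence, then final-state), dropout 0.32 after every learned
layer, a ReLU dense layer of 8 units, and a softmax output; training uses
cross-entropy with Adam (lr 0.03), batch size 12 and 5 epochs.

Evaluation is subject-wise: all of a participant's 10 s epochs stay on one
side of every train/test split, folds keep the training classes balanced,
and performance is aggregated over repeats x folds realizations (confusion
matrix, accuracy/recall/specificity/precision/F1, ROC and AUC with 95%
confidence intervals, and a per-participant misclassification table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, build_concnet
from .preprocess import preprocess_recording, segment_epochs

CONCUSSED = "concussed"
CONTROL = "non-concussed"


@dataclass
class ModelConfig:
    """Hyperparameters of the network and the epoch conditioning applied to it.

    ``time_decimation`` subsamples the epoch's time axis by an integer factor
    before the network (1 = full 2500-step sequences); ``zscore`` applies
    per-channel standardization of each epoch, needed for stable training at
    the high 0.03 learning rate.
    """

    lstm_units: int = 24
    dropout: float = 0.32
    fc_hidden: int = 8
    lr: float = 0.03
    batch_size: int = 12
    epochs: int = 5
    clip_norm: float | None = 5.0
    zscore: bool = True
    time_decimation: int = 1
    epoch_len_s: float = 10.0
    seed: int = 0


class ConcNetClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator over EEG epochs.

    ``X`` is ``(n_epochs, n_channels, n_times)``; ``y`` holds class labels
    (any two values; ordered with :attr:`classes_`).  ``predict_proba``
    returns per-epoch class probabilities in ``classes_`` column order.
    """

    def __init__(self, lstm_units: int = 24, dropout: float = 0.32,
                 fc_hidden: int = 8, lr: float = 0.03, batch_size: int = 12,
                 epochs: int = 5, clip_norm: float | None = 5.0,
                 zscore: bool = True, time_decimation: int = 1,
                 seed: int = 0):
        self.lstm_units = lstm_units
        self.dropout = dropout
        self.fc_hidden = fc_hidden
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.clip_norm = clip_norm
        self.zscore = zscore
        self.time_decimation = time_decimation
        self.seed = seed

    def _prepare(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_epochs, n_channels, n_times)")
        if self.time_decimation > 1:
            X = X[:, :, ::self.time_decimation]
        if self.zscore:
            mu = X.mean(axis=2, keepdims=True)
            sd = X.std(axis=2, keepdims=True)
            X = (X - mu) / np.where(sd > 0, sd, 1.0)
        # network wants (batch, time, channels)
        return np.transpose(X, (0, 2, 1))

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("ConcNet is a binary classifier")
        X = self._prepare(X)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        y_idx = np.searchsorted(self.classes_, y)
        onehot = np.eye(2)[y_idx]

        self.net_ = build_concnet(n_channels=X.shape[2],
                                  lstm_units=self.lstm_units,
                                  dropout=self.dropout,
                                  fc_hidden=self.fc_hidden,
                                  seed=self.seed)
        self.n_params_ = self.net_.n_params()
        opt = Adam(self.net_.params(), lr=self.lr)
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        self.history_ = {"loss": [], "val_loss": []}
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for k in range(0, n, self.batch_size):
                idx = order[k:k + self.batch_size]
                losses.append(self.net_.train_step(
                    X[idx], onehot[idx], opt, clip_norm=self.clip_norm))
            self.history_["loss"].append(float(np.mean(losses)))
            if X_val is not None:
                self.history_["val_loss"].append(
                    self._val_loss(X_val, y_val))
        return self

    def _val_loss(self, X_val, y_val) -> float:
        probs = self.predict_proba(X_val)
        y_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        return float(-np.mean(np.log(probs[np.arange(len(y_idx)), y_idx]
                                     + 1e-12)))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(self._prepare(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class FoldPlan:
    """Participant-level train/validation/test splits for every realization."""

    folds: list  # list of dicts with keys train/val/test -> list of ids
    repeats: int
    n_folds: int
    labels: dict

    def assert_no_leakage(self):
        for f in self.folds:
            overlap = set(f["train"]) & set(f["test"])
            if overlap:
                raise AssertionError(f"train/test leakage: {overlap}")
            if set(f["val"]) & set(f["test"]):
                raise AssertionError("validation/test leakage")
            if set(f["val"]) & set(f["train"]):
                raise AssertionError("validation/train leakage")


def make_folds(labels: dict, repeats: int = 5, folds: int = 6,
               seed: int = 0, val_per_class: int = 1) -> FoldPlan:
    """Subject-wise balanced cross-validation plan.

    For each repeat the participants of each class are shuffled; fold ``f``
    tests a cyclic block of each class (block sizes chosen so every
    participant is tested at least once per repeat), holds out one
    validation participant per class, and trains on an equal number of
    participants from each class.  With 15 + 11 participants and 6 folds
    this reproduces the train 8+8 / test 6+2 / validation 1+1 scheme.
    """
    classes = sorted(set(labels.values()))
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    by_class = {c: sorted(p for p, lab in labels.items() if lab == c)
                for c in classes}
    n_minor = min(len(v) for v in by_class.values())
    if n_minor < 2:
        raise ValueError("need at least 2 participants per class")

    test_minor = int(np.ceil(n_minor / folds))
    train_per_class = n_minor - val_per_class - test_minor
    if train_per_class < 1:
        raise ValueError(
            f"cohort too small for {folds}-fold subject-wise CV: "
            f"minority class has {n_minor} participants")
    test_size = {}
    for c, ids in by_class.items():
        size = len(ids) - train_per_class - val_per_class
        if size < 1 or folds * size < len(ids):
            raise ValueError(
                f"class '{c}' cannot be fully tested with {folds} folds")
        test_size[c] = size

    rng = np.random.default_rng(seed)
    plan = []
    for _ in range(repeats):
        shuffled = {c: list(rng.permutation(ids))
                    for c, ids in by_class.items()}
        for f in range(folds):
            test, rest = [], {}
            for c, ids in shuffled.items():
                n_c = len(ids)
                pos = [(f * test_size[c] + k) % n_c
                       for k in range(test_size[c])]
                t = [ids[p] for p in pos]
                test.extend(t)
                rest[c] = [p for p in ids if p not in t]
            val, train = [], []
            for c in classes:
                val.extend(rest[c][:val_per_class])
                train.extend(rest[c][val_per_class:
                                     val_per_class + train_per_class])
            plan.append({"train": train, "val": val, "test": test})
    fp = FoldPlan(folds=plan, repeats=repeats, n_folds=folds, labels=labels)
    fp.assert_no_leakage()
    return fp


def predict_participant(epoch_probs, threshold: float = 0.5):
    """Median-over-epochs participant probability and hard label.

    Concussed iff the median probability strictly exceeds the threshold.
    """
    p = float(np.median(np.asarray(epoch_probs, dtype=float)))
    return p, (CONCUSSED if p > threshold else CONTROL)


def confusion_counts(y_true, y_pred, positive=CONCUSSED) -> dict:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return {"TP": tp, "FN": fn, "FP": fp, "TN": tn}


def metrics_from_cm(cm: dict) -> dict:
    """The five ratio metrics, as percentages; NaN where undefined."""
    tp, fn, fp, tn = cm["TP"], cm["FN"], cm["FP"], cm["TN"]
    total = tp + fn + fp + tn

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    acc = ratio(tp + tn, total)
    rec = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = (2 * prec * rec / (prec + rec)
          if np.isfinite(prec) and np.isfinite(rec) and (prec + rec) > 0
          else float("nan"))
    return {"accuracy": acc, "recall": rec, "specificity": spec,
            "precision": prec, "f1": f1}


def trapezoidal_auc(y_true, scores, positive=CONCUSSED) -> float:
    """AUC by threshold sweep; NaN when only one class is present."""
    y = (np.asarray(y_true) == positive).astype(int)
    if y.min() == y.max():
        return float("nan")
    fpr, tpr, _ = roc_curve(y, scores)
    return float(np.trapezoid(tpr, fpr))


@dataclass
class RealizationResult:
    """Participant-level outcome of one train/test realization."""

    participant_ids: list
    y_true: list
    y_pred: list
    y_score: list  # median epoch P(concussed)
    repeat: int
    fold: int


def _mean_ci(values) -> dict:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {"mean": float("nan"), "ci_low": float("nan"),
                "ci_high": float("nan")}
    mean = float(np.mean(v))
    se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return {"mean": mean, "ci_low": mean - 1.96 * se,
            "ci_high": mean + 1.96 * se}


@dataclass
class ClassifierMetrics:
    """Aggregate over realizations: CM, ratio metrics with 95% CI, ROC/AUC."""

    per_realization: list
    summary: dict
    total_cm: dict
    median_roc: dict
    misclassification: dict


def evaluate(realizations, fpr_grid=None) -> ClassifierMetrics:
    """Aggregate realization results.

    Ratio metrics and AUC are computed per realization, then summarized as
    mean with a normal-approximation 95% CI over realizations.  The median
    ROC is computed pointwise on a common FPR grid across repeats (all
    realizations of a repeat pooled into one ROC).
    """
    if not realizations:
        raise ValueError("no realizations to evaluate")
    if fpr_grid is None:
        fpr_grid = np.linspace(0, 1, 101)

    rows = []
    total = {"TP": 0, "FN": 0, "FP": 0, "TN": 0}
    for r in realizations:
        cm = confusion_counts(r.y_true, r.y_pred)
        for k in total:
            total[k] += cm[k]
        m = metrics_from_cm(cm)
        m["auc"] = trapezoidal_auc(r.y_true, r.y_score)
        m.update(cm)
        rows.append(m)

    summary = {name: _mean_ci([row[name] for row in rows])
               for name in ("accuracy", "recall", "specificity", "precision",
                            "f1", "auc")}

    # median ROC across repeats: pool each repeat's realizations into one ROC
    by_repeat = {}
    for r in realizations:
        by_repeat.setdefault(r.repeat, []).append(r)
    tprs = []
    for reals in by_repeat.values():
        y = np.concatenate([(np.asarray(r.y_true) == CONCUSSED).astype(int)
                            for r in reals])
        s = np.concatenate([np.asarray(r.y_score, dtype=float)
                            for r in reals])
        if y.min() == y.max():
            continue
        fpr, tpr, _ = roc_curve(y, s)
        tprs.append(np.interp(fpr_grid, fpr, tpr))
    median_roc = {"fpr": fpr_grid,
                  "tpr": (np.median(np.stack(tprs), axis=0) if tprs
                          else np.full_like(fpr_grid, np.nan))}

    miscls = {}
    for r in realizations:
        for pid, yt, yp in zip(r.participant_ids, r.y_true, r.y_pred):
            rec = miscls.setdefault(pid, {"label": yt, "tested": 0,
                                          "errors": 0})
            rec["tested"] += 1
            rec["errors"] += int(yt != yp)
    return ClassifierMetrics(per_realization=rows, summary=summary,
                             total_cm=total, median_roc=median_roc,
                             misclassification=miscls)


def epochs_by_participant(cohort, config: ModelConfig,
                          preprocess: bool = True) -> dict:
    """Preprocess + segment every recording; returns id -> (epochs array, label)."""
    out = {}
    for rec in cohort.recordings:
        r = preprocess_recording(rec) if preprocess else rec
        eps = segment_epochs(r, epoch_len_s=config.epoch_len_s)
        if not eps:
            warnings.warn(f"participant {rec.participant_id} yielded no "
                          "epochs; excluded", RuntimeWarning, stacklevel=2)
            continue
        out[rec.participant_id] = (np.stack([e.segment for e in eps]),
                                   rec.label)
    return out


def run_ensemble(cohort, config: ModelConfig | None = None, seed: int = 0,
                 repeats: int = 5, folds: int = 6, preprocess: bool = True,
                 threshold: float = 0.5) -> ClassifierMetrics:
    """End-to-end subject-wise ensemble cross-validation.

    Trains one network per realization (fold) on the training participants'
    epochs, scores the test participants (median epoch probability), and
    aggregates metrics over all repeats x folds realizations.
    """
    if config is None:
        config = ModelConfig(seed=seed)
    data = epochs_by_participant(cohort, config, preprocess=preprocess)
    labels = {pid: lab for pid, (_, lab) in data.items()}
    plan = make_folds(labels, repeats=repeats, folds=folds, seed=seed)

    realizations = []
    for k, fold in enumerate(plan.folds):
        fold_seed = (seed * 100_003 + k * 7919) % (2 ** 31 - 1)
        x_train = np.concatenate([data[p][0] for p in fold["train"]])
        y_train = np.concatenate([[data[p][1]] * len(data[p][0])
                                  for p in fold["train"]])
        clf = ConcNetClassifier(
            lstm_units=config.lstm_units, dropout=config.dropout,
            fc_hidden=config.fc_hidden, lr=config.lr,
            batch_size=config.batch_size, epochs=config.epochs,
            clip_norm=config.clip_norm, zscore=config.zscore,
            time_decimation=config.time_decimation, seed=fold_seed)
        clf.fit(x_train, y_train)
        conc_col = int(np.where(clf.classes_ == CONCUSSED)[0][0])

        ids, y_true, y_pred, y_score = [], [], [], []
        for pid in fold["test"]:
            probs = clf.predict_proba(data[pid][0])[:, conc_col]
            p, lab = predict_participant(probs, threshold=threshold)
            ids.append(pid)
            y_true.append(data[pid][1])
            y_pred.append(lab)
            y_score.append(p)
        realizations.append(RealizationResult(
            participant_ids=ids, y_true=y_true, y_pred=y_pred,
            y_score=y_score, repeat=k // folds, fold=k % folds))
    return evaluate(realizations)
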
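"""Binary tactile-attention classification with leave-one-out cross-validation.

The decoding problem: given one averaged-trial example (an F1 sERP pair or
an F2 difference wave from a single EEG channel), decide which forearm
site the subject attended (class AD vs AV).  Two classifiers are
supported — a Gaussian-kernel SVM whose kernel scale comes from the
median-pairwise-distance heuristic, and LDA with the SVD solver.

Cross-validation holds out one example per fold.  Everything
data-dependent — the grand difference wave diffsERP(ADAV), the selection
threshold for FS1/FS2, the kernel scale — is recomputed from the training
fold only, so each fold is translatable to an online setting where the
held-out example is genuinely unseen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

from .erp import SERP_SAMPLES
from .features import (
    EmptySelectionError,
    apply_selection,
    extract_f1,
    extract_f2,
    select_indexes,
    sweep_selection,
)

CLASS_AD = "AD"
CLASS_AV = "AV"

__all__ = [
    "ClassifierSpec",
    "ChannelDataset",
    "CVResult",
    "FoldDetail",
    "kernel_scale_heuristic",
    "train",
    "predict",
    "loo_crossval",
    "confusion_table",
]


class DegenerateDataError(ValueError):
    """All training points identical; no kernel scale can be derived."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier configuration.

    ``kind`` is "SVM" (Gaussian kernel; ``kernel_scale`` numeric or
    "heuristic") or "LDA" (singular-value-decomposition solver).  The SVM
    box constraint defaults to 1.
    """

    kind: str = "SVM"
    kernel_scale: float | str = "heuristic"
    box_constraint: float = 1.0
    heuristic_subsample: int = 1000
    heuristic_seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("SVM", "LDA"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if isinstance(self.kernel_scale, (int, float)) and self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be > 0")


def kernel_scale_heuristic(
    X: np.ndarray, subsample: int = 1000, seed: int = 0
) -> float:
    """Median pairwise Euclidean distance over a seeded subsample.

    Uses the full set when it is no larger than ``subsample``.  Raises
    :class:`DegenerateDataError` when the median distance is 0.
    """
    X = np.asarray(X, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 training examples")
    if len(X) > subsample:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), size=subsample, replace=False)]
    scale = float(np.median(pdist(X)))
    if scale == 0.0:
        raise DegenerateDataError("median pairwise distance is 0 (identical points)")
    return scale


@dataclass
class Model:
    """A fitted classifier plus the metadata needed to audit it."""

    spec: ClassifierSpec
    estimator: object
    kernel_scale: float | None = None

    def signature(self) -> np.ndarray:
        """Flat parameter vector identifying the fitted decision rule."""
        est = self.estimator
        if isinstance(est, SVC):
            return np.concatenate(
                [est.dual_coef_.ravel(), est.intercept_.ravel(),
                 est.support_vectors_.ravel(), [est._gamma]]
            )
        return np.concatenate([est.coef_.ravel(), est.intercept_.ravel()])


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> Model:
    """Fit the configured classifier; deterministic given fixed inputs."""
    spec.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if spec.kind == "SVM":
        if spec.kernel_scale == "heuristic":
            scale = kernel_scale_heuristic(
                X, spec.heuristic_subsample, spec.heuristic_seed
            )
        else:
            scale = float(spec.kernel_scale)
        est = SVC(C=spec.box_constraint, kernel="rbf", gamma=1.0 / scale**2)
        est.fit(X, y)
        return Model(spec, est, kernel_scale=scale)
    est = LinearDiscriminantAnalysis(solver="svd")
    est.fit(X, y)
    return Model(spec, est)


def predict(model: Model, X: np.ndarray) -> np.ndarray:
    """Predict labels; a decision value of exactly 0 maps to class AD."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = model.estimator.decision_function(X)
    # sklearn orders classes alphabetically: AD (negative side), AV (positive)
    return np.where(d > 0, CLASS_AV, CLASS_AD)


@dataclass
class ChannelDataset:
    """Per-channel grouped sERPs: cluster key -> (m, 60) matrix, row order =
    consecutive-group (acquisition) order."""

    channel: str
    serps: dict[str, np.ndarray]
    n_avg: int

    def __post_init__(self) -> None:
        sizes = {k: len(v) for k, v in self.serps.items()}
        if len(set(sizes.values())) != 1:
            raise ValueError(f"unbalanced clusters: {sizes}")
        self.m = next(iter(sizes.values()))

    @property
    def diffs_AD(self) -> np.ndarray:
        return self.serps["ADSD"] - self.serps["ADSV"]

    @property
    def diffs_AV(self) -> np.ndarray:
        return self.serps["AVSD"] - self.serps["AVSV"]

    def labels(self) -> np.ndarray:
        """Example labels: the m AD examples first, then the m AV examples."""
        return np.array([CLASS_AD] * self.m + [CLASS_AV] * self.m)

    def base_features(self, method: str) -> np.ndarray:
        """(2m, p) base feature matrix for F1 (p=120) or F2 (p=60)."""
        if method in ("F1", "FS1"):
            ad = [extract_f1(i, self.serps, CLASS_AD).values for i in range(self.m)]
            av = [extract_f1(i, self.serps, CLASS_AV).values for i in range(self.m)]
        elif method in ("F2", "FS2"):
            ad = list(self.diffs_AD)
            av = list(self.diffs_AV)
        else:
            raise ValueError(f"unknown method {method!r}")
        return np.asarray(ad + av, dtype=float)


@dataclass
class FoldDetail:
    held_out: int
    threshold_uV: float | None
    selected_indexes: tuple[int, ...] | None
    prediction: str
    truth: str
    model_signature: np.ndarray | None = None


@dataclass
class CVResult:
    channel: str
    method: str
    n_avg: int
    classifier: str
    predictions: np.ndarray
    truths: np.ndarray
    folds: list[FoldDetail] = field(default_factory=list)

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * float(np.mean(self.predictions == self.truths))

    @property
    def confusion_pct(self) -> dict[str, float]:
        return confusion_table(self)

    def to_record(self) -> dict:
        rec = {
            "channel": self.channel,
            "method": self.method,
            "n_avg": self.n_avg,
            "classifier": self.classifier,
            "n_folds": len(self.predictions),
            "accuracy_pct": self.accuracy_pct,
        }
        rec.update(self.confusion_pct)
        return rec


def _apply_indexes(base: np.ndarray, method: str, indexes: tuple[int, ...]) -> np.ndarray:
    """Restrict base F1/F2 features to the selected sample indexes."""
    idx = np.asarray(indexes, dtype=np.intp)
    if method == "FS1":
        return np.concatenate(
            [base[:, :SERP_SAMPLES][:, idx], base[:, SERP_SAMPLES:][:, idx]], axis=1
        )
    if method == "FS2":
        return base[:, idx]
    return base


def _adav_from_training(dataset: ChannelDataset, train_idx: np.ndarray) -> np.ndarray:
    """Grand difference wave from the training fold's examples only."""
    ad_rows = train_idx[train_idx < dataset.m]
    av_rows = train_idx[train_idx >= dataset.m] - dataset.m
    return dataset.diffs_AD[ad_rows].mean(axis=0) - dataset.diffs_AV[av_rows].mean(axis=0)


def _choose_threshold_inner_loo(
    base_train: np.ndarray,
    y_train: np.ndarray,
    method: str,
    adav: np.ndarray,
    spec: ClassifierSpec,
) -> tuple[float, tuple[int, ...]]:
    """Inner LOO on the training fold over the threshold sweep.

    Returns the smallest threshold attaining maximal inner accuracy (ties
    broken toward more features, i.e. the lower threshold).
    """
    sweep = sweep_selection(adav)
    # accuracy depends only on the index set; evaluate each distinct set
    # once, at the smallest threshold that produces it
    distinct: list[tuple[float, tuple[int, ...]]] = []
    for thr, idx in zip(sweep.thresholds, sweep.index_sets):
        if not distinct or distinct[-1][1] != idx:
            distinct.append((float(thr), idx))
    best_thr, best_idx, best_acc = 0.0, sweep.index_sets[0], -1.0
    n = len(base_train)
    for thr, idx in distinct:
        Xt = _apply_indexes(base_train, method, idx)
        correct = 0
        for j in range(n):
            mask = np.arange(n) != j
            if len(np.unique(y_train[mask])) < 2:
                continue
            try:
                m = train(spec, Xt[mask], y_train[mask])
            except DegenerateDataError:
                continue
            correct += int(predict(m, Xt[j : j + 1])[0] == y_train[j])
        acc = correct / n
        if acc > best_acc:  # strictly greater keeps the smallest threshold on ties
            best_thr, best_idx, best_acc = float(thr), idx, acc
    return best_thr, best_idx


def loo_crossval(
    dataset: ChannelDataset,
    method: str,
    spec: ClassifierSpec | None = None,
    selection: str | float = "inner",
    keep_models: bool = False,
) -> CVResult:
    """Leave-one-out cross-validation over the 2m averaged-group examples.

    ``method`` is F1/F2 (fixed features) or FS1/FS2 (per-fold threshold
    selection).  ``selection`` controls the FS threshold: ``"inner"``
    (default) picks it by inner LOO on each training fold; a float fixes
    it; ``"max"`` sweeps fixed thresholds over a whole-dataset ADAV wave
    and reports the best result (sensitivity analysis only — the ADAV wave
    then sees the held-out data, mirroring the literal test-set reading of
    the fine-tuning procedure).
    """
    spec = spec or ClassifierSpec()
    spec.validate()
    if method not in ("F1", "F2", "FS1", "FS2"):
        raise ValueError(f"unknown method {method!r}")
    if dataset.m < 2:
        raise ValueError("need at least 2 examples per class for LOO")

    if method in ("FS1", "FS2") and selection == "max":
        adav = dataset.diffs_AD.mean(axis=0) - dataset.diffs_AV.mean(axis=0)
        sweep = sweep_selection(adav)
        best = None
        for thr in sweep.thresholds:
            res = loo_crossval(dataset, method, spec, selection=float(thr))
            if best is None or res.accuracy_pct > best.accuracy_pct:
                best = res
        return best

    base = dataset.base_features(method)
    y = dataset.labels()
    n = len(y)
    preds = np.empty(n, dtype=object)
    folds: list[FoldDetail] = []
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        thr: float | None = None
        idx: tuple[int, ...] | None = None
        if method in ("FS1", "FS2"):
            adav = _adav_from_training(dataset, train_idx)
            if selection == "inner":
                thr, idx = _choose_threshold_inner_loo(
                    base[train_idx], y[train_idx], method, adav, spec
                )
            else:
                thr = float(selection)
                idx = select_indexes(adav, thr)
                if not idx:  # fall back to threshold 0 = all samples
                    thr, idx = 0.0, select_indexes(adav, 0.0)
            X = _apply_indexes(base, method, idx)
        else:
            X = base
        model = train(spec, X[train_idx], y[train_idx])
        pred = predict(model, X[i : i + 1])[0]
        preds[i] = pred
        folds.append(
            FoldDetail(
                i, thr, idx, pred, y[i],
                model.signature() if keep_models else None,
            )
        )
    return CVResult(
        dataset.channel, method, dataset.n_avg, spec.kind,
        preds.astype(str), y, folds,
    )


def confusion_table(result: CVResult) -> dict[str, float]:
    """2x2 confusion matrix in percent of all folds.

    Class AD corresponds to target D.  ``TP_D``/``TP_V`` are correctly
    classified D/V targets, ``FP_D``/``FP_V`` are D/V targets that were
    misclassified; the four entries sum to 100 and accuracy = TP_D + TP_V.
    """
    n = len(result.predictions)
    if n == 0:
        raise ValueError("no folds")
    t, p = result.truths, result.predictions
    pct = lambda mask: 100.0 * float(np.sum(mask)) / n
    return {
        "TP_D": pct((t == CLASS_AD) & (p == CLASS_AD)),
        "FP_D": pct((t == CLASS_AD) & (p == CLASS_AV)),
        "FP_V": pct((t == CLASS_AV) & (p == CLASS_AD)),
        "TP_V": pct((t == CLASS_AV) & (p == CLASS_AV)),
    }
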
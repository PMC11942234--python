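"""Model selection under adversarial label corruption.

Candidate classifiers are compared on three axes:

* accuracy — F1 (binary F1 on the minority class for two-class tasks, macro
  F1 otherwise) from pooled out-of-fold predictions of a seeded stratified
  5-fold cross-validation, and F'1, the same quantity averaged over repeated
  runs in which 20% of the *training* labels are randomly reassigned;
* classification stability CS = TP − mean(TP'), the drop in pooled true
  positives between the clean run and the corrupted runs (small is better;
  stored on the rate scale, divided by the positive support);
* classification robustness CR = mean(TP') − 80%·TP, the excess of corrupted
  true positives over the naive-loss baseline in which every corrupted
  positive were lost (large is better; raw count scale). The 80% baseline is
  tied to the nominal 20% corruption design, not to the fraction actually
  applied in a given run.

The composite ranking score is alpha·F'1 + beta·CS + gamma·CR with defaults
alpha=2, beta=−1, gamma=0.1. Test folds are never corrupted; evaluation is
always against the true labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core_data import ExpressionDataset, GeneList
from .models import build_model, standardize
from .synthetic import mislabel

__all__ = [
    "ConfusionCounts",
    "ModelMetrics",
    "CVResult",
    "f1_from_counts",
    "cross_validate",
    "adversarial_evaluate",
    "final_score",
    "evaluate_model",
]


@dataclass
class ConfusionCounts:
    """Per-class true-positive / false-positive / false-negative counts."""

    tp: dict[str, int]
    fp: dict[str, int]
    fn: dict[str, int]
    n_samples: int

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]
    ) -> "ConfusionCounts":
        tp, fp, fn = {}, {}, {}
        for c in classes:
            tp[c] = int(np.sum((y_true == c) & (y_pred == c)))
            fp[c] = int(np.sum((y_true != c) & (y_pred == c)))
            fn[c] = int(np.sum((y_true == c) & (y_pred != c)))
        return cls(tp, fp, fn, len(y_true))

    def diagonal(self) -> int:
        return sum(self.tp.values())


def _f1_single(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def f1_from_counts(
    c: ConfusionCounts, averaging: str = "macro", positive: str | None = None
) -> float:
    """F1 from confusion counts: harmonic mean of precision and recall.

    ``binary`` scores the designated positive class; ``macro`` is the
    unweighted mean of per-class F1, with classes at zero precision+recall
    contributing 0.
    """
    if averaging == "binary":
        if positive is None:
            raise ValueError("binary averaging needs a positive class")
        return _f1_single(c.tp[positive], c.fp[positive], c.fn[positive])
    if averaging == "macro":
        return float(np.mean([_f1_single(c.tp[k], c.fp[k], c.fn[k]) for k in c.tp]))
    raise ValueError(f"unknown averaging {averaging!r}")


@dataclass
class CVResult:
    f1: float
    oof_pred: np.ndarray  # pooled out-of-fold predicted labels, sample order
    oof_proba: np.ndarray  # pooled out-of-fold class probabilities
    classes: list[str]
    counts: ConfusionCounts
    positive: str | None  # minority class for binary tasks, else None
    fold_assignment: np.ndarray


@dataclass
class ModelMetrics:
    model: str
    label_task: str
    F1: float
    F1_prime: float
    CS: float  # rate scale: (TP - mean TP') / positive support
    CR: float  # count scale: mean TP' - 0.8 * TP
    final_score: float
    n_reps: int
    mislabel_fraction: float
    TP: int = 0
    CS_count: float = 0.0  # raw-count companion of CS
    CS_f1: float = 0.0  # F1-difference variant of stability
    coefficients: tuple[float, float, float] = (2.0, -1.0, 0.1)


def _make_model(model, seed: int, need_proba: bool):
    if isinstance(model, str):
        return build_model(model, seed, need_proba=need_proba)
    if callable(model):
        return model(seed=seed, need_proba=need_proba)
    raise TypeError("model must be a registry name or a factory callable")


def _task_conventions(classes: list[str], y: np.ndarray):
    """Binary tasks score the minority class; multiclass uses macro/diagonal."""
    if len(classes) == 2:
        counts = {c: int(np.sum(y == c)) for c in classes}
        positive = min(classes, key=lambda c: (counts[c], c))
        return "binary", positive
    return "macro", None


def _tp_and_f1(y_true, y_pred, classes, averaging, positive):
    counts = ConfusionCounts.from_predictions(y_true, y_pred, classes)
    f1 = f1_from_counts(counts, averaging, positive)
    tp = counts.tp[positive] if averaging == "binary" else counts.diagonal()
    return counts, f1, tp


def _fold_plan(y: np.ndarray, n_folds: int, seed: int):
    counts = {c: int(np.sum(y == c)) for c in np.unique(y)}
    small = {c: n for c, n in counts.items() if n < n_folds}
    if small:
        raise ValueError(f"classes smaller than the fold count {n_folds}: {small}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate(
    ds: ExpressionDataset,
    features: GeneList,
    model,
    n_folds: int = 5,
    seed: int = 42,
) -> CVResult:
    """Seeded stratified k-fold CV; pooled out-of-fold F1 and probabilities."""
    idx = ds.gene_index(list(features))
    X_all = np.log2(ds.values[idx, :] + 1.0).T
    y = ds.label_array()
    classes = sorted(np.unique(y).tolist())
    averaging, positive = _task_conventions(classes, y)
    folds = _fold_plan(y, n_folds, seed)

    oof_pred = np.empty(len(y), dtype=object)
    oof_proba = np.zeros((len(y), len(classes)))
    fold_of = np.zeros(len(y), dtype=int)
    for f, (tr, te) in enumerate(folds):
        Xtr, mean, sd = standardize(X_all[tr])
        Xte, _, _ = standardize(X_all[te], mean, sd)
        clf = _make_model(model, seed, need_proba=True)
        clf.fit(Xtr, _encode(y[tr], classes))
        proba = clf.predict_proba(Xte)
        oof_proba[te] = _align_proba(proba, clf.classes_, len(classes))
        oof_pred[te] = [classes[i] for i in np.argmax(oof_proba[te], axis=1)]
        fold_of[te] = f
    oof_pred = oof_pred.astype(str)
    counts, f1, _ = _tp_and_f1(y, oof_pred, classes, averaging, positive)
    return CVResult(f1, oof_pred, oof_proba, classes, counts, positive, fold_of)


def _encode(y: np.ndarray, classes: list[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in y])


def _align_proba(proba: np.ndarray, model_classes, n_classes: int) -> np.ndarray:
    out = np.zeros((proba.shape[0], n_classes))
    for j, c in enumerate(model_classes):
        out[:, int(c)] = proba[:, j]
    return out


def adversarial_evaluate(
    ds: ExpressionDataset,
    features: GeneList,
    model,
    mislabel_fraction: float = 0.2,
    n_reps: int = 100,
    seed: int = 42,
    n_folds: int = 5,
    baseline_fraction: float = 0.2,
    corrupt_side: str = "train",
) -> dict:
    """F'1, CS and CR under repeated random training-label reassignment.

    Per repetition, ``mislabel_fraction`` of each training fold's labels are
    reassigned to a different class (fresh draw each repetition, seeds fanned
    out from ``seed``); the refit model is scored on the untouched test folds
    against true labels. ``corrupt_side='both'`` additionally corrupts the
    test-side labels used for scoring, for sensitivity analysis only.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if corrupt_side not in ("train", "both"):
        raise ValueError("corrupt_side must be 'train' or 'both'")
    idx = ds.gene_index(list(features))
    X_all = np.log2(ds.values[idx, :] + 1.0).T
    y = ds.label_array()
    classes = sorted(np.unique(y).tolist())
    averaging, positive = _task_conventions(classes, y)
    folds = _fold_plan(y, n_folds, seed)

    # clean reference run on the same folds
    clean_pred = np.empty(len(y), dtype=object)
    scalers = []
    for tr, te in folds:
        Xtr, mean, sd = standardize(X_all[tr])
        scalers.append((mean, sd))
        Xte, _, _ = standardize(X_all[te], mean, sd)
        clf = _make_model(model, seed, need_proba=False)
        clf.fit(Xtr, _encode(y[tr], classes))
        clean_pred[te] = [classes[i] for i in np.atleast_1d(clf.predict(Xte))]
    clean_pred = clean_pred.astype(str)
    _, f1_clean, tp_clean = _tp_and_f1(y, clean_pred, classes, averaging, positive)

    tp_primes, f1_primes = [], []
    for rep in range(n_reps):
        rep_rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        y_eval = y
        if corrupt_side == "both":
            y_eval = _mislabel_array(y, mislabel_fraction, rep_rng)
        pred = np.empty(len(y), dtype=object)
        for (tr, te), (mean, sd) in zip(folds, scalers):
            y_tr = _mislabel_array(y[tr], mislabel_fraction, rep_rng)
            Xtr, _, _ = standardize(X_all[tr], mean, sd)
            Xte, _, _ = standardize(X_all[te], mean, sd)
            clf = _make_model(model, seed, need_proba=False)
            clf.fit(Xtr, _encode(y_tr, classes))
            pred[te] = [classes[i] for i in np.atleast_1d(clf.predict(Xte))]
        pred = pred.astype(str)
        _, f1_r, tp_r = _tp_and_f1(y_eval, pred, classes, averaging, positive)
        tp_primes.append(tp_r)
        f1_primes.append(f1_r)

    mean_tp_prime = float(np.mean(tp_primes))
    positives = (
        int(np.sum(y == positive)) if averaging == "binary" else len(y)
    )
    cs_count = tp_clean - mean_tp_prime
    return {
        "F1": f1_clean,
        "F1_prime": float(np.mean(f1_primes)),
        "CS": cs_count / positives,
        "CS_count": cs_count,
        "CS_f1": f1_clean - float(np.mean(f1_primes)),
        "CR": mean_tp_prime - (1.0 - baseline_fraction) * tp_clean,
        "TP": tp_clean,
        "TP_prime_trace": [float(t) for t in tp_primes],
        "F1_prime_trace": [float(f) for f in f1_primes],
    }


def _mislabel_array(y: np.ndarray, fraction: float, rng) -> np.ndarray:
    if fraction == 0:
        return y.copy()
    as_map = {str(i): v for i, v in enumerate(y)}
    flipped = mislabel(as_map, fraction, rng)
    return np.array([flipped[str(i)] for i in range(len(y))])


def final_score(
    F1_prime: float,
    CS: float,
    CR: float,
    alpha: float = 2.0,
    beta: float = -1.0,
    gamma: float = 0.1,
) -> float:
    """Composite ranking score alpha·F'1 + beta·CS + gamma·CR."""
    return alpha * F1_prime + beta * CS + gamma * CR


def evaluate_model(
    ds: ExpressionDataset,
    features: GeneList,
    model,
    model_name: str | None = None,
    label_task: str = "task",
    mislabel_fraction: float = 0.2,
    n_reps: int = 100,
    seed: int = 42,
    n_folds: int = 5,
    alpha: float = 2.0,
    beta: float = -1.0,
    gamma: float = 0.1,
) -> tuple[ModelMetrics, CVResult]:
    """Full evaluation of one model: clean CV plus adversarial metrics."""
    name = model_name or (model if isinstance(model, str) else type(model).__name__)
    cv = cross_validate(ds, features, model, n_folds=n_folds, seed=seed)
    adv = adversarial_evaluate(
        ds,
        features,
        model,
        mislabel_fraction=mislabel_fraction,
        n_reps=n_reps,
        seed=seed,
        n_folds=n_folds,
    )
    score = final_score(adv["F1_prime"], adv["CS"], adv["CR"], alpha, beta, gamma)
    metrics = ModelMetrics(
        model=name,
        label_task=label_task,
        F1=cv.f1,
        F1_prime=adv["F1_prime"],
        CS=adv["CS"],
        CR=adv["CR"],
        final_score=score,
        n_reps=n_reps,
        mislabel_fraction=mislabel_fraction,
        TP=adv["TP"],
        CS_count=adv["CS_count"],
        CS_f1=adv["CS_f1"],
        coefficients=(alpha, beta, gamma),
    )
    return metrics, cv
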
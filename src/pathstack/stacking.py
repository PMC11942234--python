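"""Softmax-weighted two-level stacking meta-classifier.

Level one: each base classifier i gets a scalar quality score
Score_i = F'1_i + CS_i + CR_i from model selection, converted to a weight by a
softmax, w_i = exp(Score_i) / Σ_j exp(Score_j). Level two: the out-of-fold
class-probability columns of every base model, multiplied by that model's
weight, are concatenated into meta-features on which a gradient-boosted-tree
meta-learner is trained against the true labels. Prediction applies the same
weighting to base-model probabilities on new samples before the meta-learner
votes.

Out-of-fold (never in-fold) probabilities feed the meta-learner, the standard
leakage-free stacking contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .core_data import ExpressionDataset, GeneList
from .model_selection import ModelMetrics, _align_proba, _encode
from .models import MODEL_NAMES, build_model, standardize

__all__ = [
    "StackingEnsemble",
    "classifier_scores",
    "softmax_weights",
    "fit_stacking",
    "predict",
    "WeightedStackingClassifier",
    "stacking_factory",
]


def classifier_scores(metrics: list[ModelMetrics]) -> dict[str, float]:
    """Score_i = F'1_i + CS_i + CR_i per base model (unweighted sum).

    Note the deliberate asymmetry with the ranking composite, which weights CS
    negatively: both definitions are implemented verbatim — the sum feeds the
    softmax weights, the weighted composite ranks models.
    """
    by_model = {m.model: m for m in metrics}
    if len(by_model) != len(metrics):
        raise ValueError("duplicate model entries in metrics")
    return {name: m.F1_prime + m.CS + m.CR for name, m in by_model.items()}


def softmax_weights(scores: dict[str, float]) -> dict[str, float]:
    """Numerically stable softmax over classifier scores; weights sum to 1."""
    if not scores:
        raise ValueError("no scores given")
    vals = np.array(list(scores.values()), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite classifier score")
    shifted = np.exp(vals - vals.max())
    w = shifted / shifted.sum()
    return dict(zip(scores.keys(), w.tolist()))


@dataclass
class StackingEnsemble:
    base_models: list[str]
    scores: dict[str, float]
    weights: dict[str, float]
    meta_learner: GradientBoostingClassifier
    feature_genes: GeneList
    classes: list[str]
    fitted_base: dict[str, object] = field(default_factory=dict)
    scaler: tuple[np.ndarray, np.ndarray] | None = None
    seed: int = 42


def _meta_features(
    weights: dict[str, float], probas: dict[str, np.ndarray], order: list[str]
) -> np.ndarray:
    return np.hstack([weights[m] * probas[m] for m in order])


def fit_stacking(
    ds: ExpressionDataset,
    features: GeneList,
    metrics: list[ModelMetrics],
    oof_probas: dict[str, np.ndarray],
    seed: int = 42,
) -> StackingEnsemble:
    """Fit the meta-learner on weighted out-of-fold base probabilities.

    ``oof_probas`` maps each base model to its out-of-fold class-probability
    matrix in dataset sample order (as returned by
    ``model_selection.cross_validate``).
    """
    order = [m.model for m in metrics]
    missing = [m for m in order if m not in oof_probas]
    if missing:
        raise ValueError(f"missing out-of-fold probabilities for: {missing}")
    n = ds.n_samples
    for m in order:
        if oof_probas[m].shape[0] != n:
            raise ValueError(
                f"out-of-fold matrix for {m!r} has {oof_probas[m].shape[0]} rows; "
                f"dataset has {n} samples (sample-order mismatch?)"
            )
    scores = classifier_scores(metrics)
    weights = softmax_weights(scores)
    y = ds.label_array()
    classes = sorted(np.unique(y).tolist())

    meta_X = _meta_features(weights, oof_probas, order)
    meta = GradientBoostingClassifier(
        n_estimators=100, max_depth=3, learning_rate=0.1, random_state=seed
    )
    meta.fit(meta_X, _encode(y, classes))

    # refit the base models on all samples for the prediction path
    idx = ds.gene_index(list(features))
    X = np.log2(ds.values[idx, :] + 1.0).T
    Xs, mean, sd = standardize(X)
    fitted = {}
    for m in order:
        clf = build_model(m, seed, need_proba=True)
        clf.fit(Xs, _encode(y, classes))
        fitted[m] = clf
    return StackingEnsemble(
        base_models=order,
        scores=scores,
        weights=weights,
        meta_learner=meta,
        feature_genes=features,
        classes=classes,
        fitted_base=fitted,
        scaler=(mean, sd),
        seed=seed,
    )


def predict(
    ensemble: StackingEnsemble, ds: ExpressionDataset
) -> tuple[list[str], np.ndarray]:
    """Predicted labels and class probabilities for new samples."""
    missing = [g for g in ensemble.feature_genes if g not in set(ds.genes)]
    if missing:
        raise KeyError(f"feature genes absent from dataset: {missing[:5]}")
    idx = ds.gene_index(list(ensemble.feature_genes))
    X = np.log2(ds.values[idx, :] + 1.0).T
    mean, sd = ensemble.scaler
    Xs, _, _ = standardize(X, mean, sd)
    n_classes = len(ensemble.classes)
    probas = {
        m: _align_proba(clf.predict_proba(Xs), clf.classes_, n_classes)
        for m, clf in ensemble.fitted_base.items()
    }
    meta_X = _meta_features(ensemble.weights, probas, ensemble.base_models)
    proba = ensemble.meta_learner.predict_proba(meta_X)
    proba = _align_proba(proba, ensemble.meta_learner.classes_, n_classes)
    labels = [ensemble.classes[i] for i in np.argmax(proba, axis=1)]
    return labels, proba


class WeightedStackingClassifier:
    """Self-contained stacking estimator for the evaluation harness.

    Given fixed softmax weights (from model selection), ``fit`` builds inner
    out-of-fold probabilities for each base model on the training data, trains
    the gradient-boosted meta-learner on the weighted concatenation, and
    refits the base models on the full training data. This lets the ensemble
    run through exactly the same cross-validation / adversarial-corruption
    harness as any base model.
    """

    def __init__(
        self,
        weights: dict[str, float],
        base_models: list[str] | None = None,
        n_inner_folds: int = 5,
        seed: int = 42,
        need_proba: bool = True,
    ):
        self.weights = dict(weights)
        self.base_models = list(base_models or MODEL_NAMES)
        self.n_inner_folds = n_inner_folds
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n_classes = len(self.classes_)
        n_folds = min(self.n_inner_folds, int(np.min(np.bincount(_as_int(y)))))
        n_folds = max(2, n_folds)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.seed)
        oof = {m: np.zeros((len(y), n_classes)) for m in self.base_models}
        for tr, te in skf.split(X, y):
            for m in self.base_models:
                clf = build_model(m, self.seed, need_proba=True)
                clf.fit(X[tr], _as_int(y[tr], self.classes_))
                oof[m][te] = _align_proba(clf.predict_proba(X[te]), clf.classes_, n_classes)
        meta_X = _meta_features(self.weights, oof, self.base_models)
        self._meta = GradientBoostingClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1, random_state=self.seed
        )
        self._meta.fit(meta_X, _as_int(y, self.classes_))
        self._fitted = {}
        for m in self.base_models:
            clf = build_model(m, self.seed, need_proba=True)
            clf.fit(X, _as_int(y, self.classes_))
            self._fitted[m] = clf
        return self

    def _base_meta_features(self, X: np.ndarray) -> np.ndarray:
        n_classes = len(self.classes_)
        probas = {
            m: _align_proba(self._fitted[m].predict_proba(X), self._fitted[m].classes_, n_classes)
            for m in self.base_models
        }
        return _meta_features(self.weights, probas, self.base_models)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        proba = self._meta.predict_proba(self._base_meta_features(X))
        return _align_proba(proba, self._meta.classes_, len(self.classes_))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _as_int(y: np.ndarray, classes: np.ndarray | None = None) -> np.ndarray:
    if classes is None:
        classes = np.unique(y)
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in y])


def stacking_factory(
    weights: dict[str, float],
    base_models: list[str] | None = None,
    n_inner_folds: int = 5,
):
    """Factory usable wherever the harness accepts a base-model name."""

    def make(seed: int, need_proba: bool = True):
        return WeightedStackingClassifier(
            weights, base_models, n_inner_folds=n_inner_folds, seed=seed
        )

    return make
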
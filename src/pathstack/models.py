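"""Registry of the five base classifier families and their importance scores.

The panel is LR (logistic regression), SVM (linear-kernel support vector
machine), RF (random forest), XGB (gradient-boosted trees, xgboost) and LGBM
(gradient-boosted trees, lightgbm). All models are fitted on standardized
log2(TPM+1) features so that linear coefficients are comparable across genes.

Two configurations exist per family:

* ``build_model`` — the classification configuration used for
  cross-validation, adversarial evaluation and stacking; standard defaults
  aimed at accuracy.
* ``build_importance_model`` — the capacity-limited configuration used for
  gene-importance scoring and the adversarial-permutation retention filter.
  Flexible models fit label noise almost as well as signal, so their raw
  importance magnitudes do not drop under label corruption; strong
  regularisation (linear models) and forced feature rotation with shallow
  trees (ensembles) make each gene's score track its own discriminative
  signal instead of an arbitrary allocation among correlated genes.

Importance conventions: absolute coefficient magnitude for the linear models
(maximum over decision rows in the multiclass case), raw — unnormalized —
total split gain for the tree ensembles.
"""

from __future__ import annotations

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

MODEL_NAMES = ["LR", "SVM", "RF", "XGB", "LGBM"]

__all__ = [
    "MODEL_NAMES",
    "build_model",
    "build_importance_model",
    "raw_importances",
    "standardize",
]


def build_model(name: str, seed: int, need_proba: bool = False):
    """Instantiate a fresh, unfitted classifier for ``name`` with a fixed seed."""
    if name == "LR":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if name == "SVM":
        svc = SVC(kernel="linear", random_state=seed)
        if need_proba:
            # sigmoid-calibrated probabilities for the stacking path
            return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)
        return svc
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "XGB":
        return XGBClassifier(
            n_estimators=100,
            max_depth=3,
            learning_rate=0.1,
            random_state=seed,
            verbosity=0,
            n_jobs=1,
            eval_metric="logloss",
        )
    if name == "LGBM":
        return LGBMClassifier(
            n_estimators=100,
            learning_rate=0.1,
            random_state=seed,
            verbose=-1,
            n_jobs=1,
        )
    raise ValueError(f"unknown model {name!r}; choose one of {MODEL_NAMES}")


def build_importance_model(name: str, seed: int):
    """Capacity-limited configuration for importance scoring (see module docs)."""
    if name == "LR":
        # near the heavy-shrinkage limit |coef| tracks per-gene covariance
        # with the label rather than a collinear allocation
        return LogisticRegression(C=0.01, max_iter=5000, random_state=seed)
    if name == "SVM":
        return SVC(kernel="linear", C=0.01, random_state=seed)
    if name == "RF":
        # max_features=1 rotates every gene through split candidacy; shallow
        # depth keeps impurity decrease tied to class structure, not overfit
        return RandomForestClassifier(
            n_estimators=200, max_features=1, max_depth=5, random_state=seed, n_jobs=1
        )
    if name == "XGB":
        return XGBClassifier(
            n_estimators=200,
            max_depth=1,
            learning_rate=0.1,
            colsample_bytree=0.1,
            random_state=seed,
            verbosity=0,
            n_jobs=1,
            eval_metric="logloss",
        )
    if name == "LGBM":
        return LGBMClassifier(
            n_estimators=200,
            max_depth=1,
            learning_rate=0.1,
            colsample_bytree=0.1,
            random_state=seed,
            verbose=-1,
            n_jobs=1,
        )
    raise ValueError(f"unknown model {name!r}; choose one of {MODEL_NAMES}")


def standardize(X: np.ndarray, mean=None, sd=None):
    """Column-standardize; constant columns are left centred (sd treated as 1)."""
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd


def raw_importances(fitted, name: str, n_features: int) -> np.ndarray:
    """Unnormalized per-feature importance of a fitted model.

    |coefficient| (max over rows) for LR/SVM; raw total split gain (not the
    share-normalized attribute) for RF/XGB/LGBM, so that a global loss of
    discriminative signal is visible in every gene's score.
    """
    if name in ("LR", "SVM"):
        coef = np.atleast_2d(fitted.coef_)
        return np.abs(coef).max(axis=0)
    if name == "RF":
        return np.mean(
            [
                t.tree_.compute_feature_importances(normalize=False)
                for t in fitted.estimators_
            ],
            axis=0,
        )
    if name == "XGB":
        score = fitted.get_booster().get_score(importance_type="total_gain")
        out = np.zeros(n_features)
        for key, val in score.items():
            out[int(key[1:])] = val
        return out
    if name == "LGBM":
        return np.asarray(
            fitted.booster_.feature_importance(importance_type="gain"), dtype=float
        )
    raise ValueError(f"unknown model {name!r}")
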
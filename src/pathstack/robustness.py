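"""Stage 4 of feature selection: adversarial-sample gene filtering.

A gene earns its place in the final feature set only if its model importance
under the true labels beats its importance under label-permuted refits almost
always. Concretely: 100 times, the labels of a random subset S' of samples
(by default S' = S, the full cohort) are permuted among themselves, the model
is refit, and the gene's importance recomputed. A gene is retained when its
permuted importance fell strictly below its true-label importance in at least
95 of the 100 iterations, and the final set is the strict majority vote of
that decision across the five base models.

Two deliberate choices make the rule discriminating:

* The comparison uses raw (unnormalized) importances — absolute coefficient
  or total split gain itself — because the filter detects the drop in a
  gene's absolute discriminative contribution; share-normalising would cancel
  a uniform drop across an informative panel.
* Importances come from the capacity-limited model configurations
  (``models.build_importance_model``): a flexible model fits permuted labels
  almost as well as true ones, so its importance magnitudes carry no signal
  about label structure.
"""

from __future__ import annotations

import math
from collections.abc import Callable
from dataclasses import dataclass

import numpy as np

from .core_data import ExpressionDataset, GeneList
from .models import MODEL_NAMES, build_importance_model, raw_importances, standardize

__all__ = [
    "ImportanceScore",
    "RobustnessProfile",
    "importance_scores",
    "permutation_profile",
    "majority_vote_retention",
]


@dataclass
class ImportanceScore:
    gene: str
    model: str
    value: float


@dataclass
class RobustnessProfile:
    gene: str
    model: str
    true_importance: float
    permuted_importances: list[float]
    n_below: int
    retained: bool


def _features(ds: ExpressionDataset, genes: GeneList):
    idx = ds.gene_index(list(genes))
    X = np.log2(ds.values[idx, :] + 1.0).T  # samples × genes
    X, _, _ = standardize(X)
    labels = ds.label_array()
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to score importance")
    return X, y


def _fit_importances(X, y, model_name: str, seed: int) -> np.ndarray:
    model = build_importance_model(model_name, seed)
    model.fit(X, y)
    return raw_importances(model, model_name, X.shape[1])


def importance_scores(
    ds: ExpressionDataset,
    genes: GeneList,
    model: str,
    seed: int = 42,
    normalize: bool = True,
) -> list[ImportanceScore]:
    """Per-gene importance under one model, optionally share-normalized to sum 1."""
    X, y = _features(ds, genes)
    imp = _fit_importances(X, y, model, seed)
    if normalize:
        total = imp.sum()
        if total > 0:
            imp = imp / total
    return [ImportanceScore(g, model, float(v)) for g, v in zip(genes, imp)]


def permutation_profile(
    ds: ExpressionDataset,
    genes: GeneList,
    model: str,
    subset_fraction: float = 1.0,
    n_permutations: int = 100,
    seed: int = 42,
    retention_quantile: float = 0.95,
    score_fn: Callable[[np.ndarray, np.ndarray, int], np.ndarray] | None = None,
) -> list[RobustnessProfile]:
    """Adversarial-permutation importance profile for every gene under one model.

    Each iteration draws a fresh uniformly random subset S' of
    round(subset_fraction · n) samples and permutes the labels within S'
    (labels outside S' are untouched; ``subset_fraction=1`` permutes the whole
    label vector), refits the model with the same model seed, and records each
    gene's raw importance. ``n_below`` counts iterations with permuted
    importance strictly below the true-label importance; retention requires
    n_below ≥ ceil(retention_quantile · n_permutations).

    ``score_fn(X, y, iteration)`` replaces the model-fit importance
    computation when given — the hook used for null calibration of the rule.
    """
    if not (0.0 < subset_fraction <= 1.0):
        raise ValueError("subset_fraction must be in (0, 1]")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X, y = _features(ds, genes)
    n = X.shape[0]
    rng = np.random.default_rng(seed)

    def scores(y_vec, iteration):
        if score_fn is not None:
            return np.asarray(score_fn(X, y_vec, iteration), dtype=float)
        return _fit_importances(X, y_vec, model, seed)

    true_imp = scores(y, -1)
    subset_size = int(round(subset_fraction * n))
    n_below = np.zeros(len(true_imp), dtype=int)
    perms = np.empty((n_permutations, len(true_imp)))
    for i in range(n_permutations):
        y_perm = y.copy()
        if subset_size > 0:
            subset = rng.choice(n, size=subset_size, replace=False)
            y_perm[subset] = y_perm[subset][rng.permutation(subset_size)]
        imp = scores(y_perm, i)
        perms[i] = imp
        n_below += imp < true_imp

    threshold = math.ceil(retention_quantile * n_permutations)
    return [
        RobustnessProfile(
            gene=g,
            model=model,
            true_importance=float(true_imp[j]),
            permuted_importances=perms[:, j].tolist(),
            n_below=int(n_below[j]),
            retained=bool(n_below[j] >= threshold),
        )
        for j, g in enumerate(genes)
    ]


def majority_vote_retention(
    profiles: dict[str, list[RobustnessProfile]],
    models: list[str] | None = None,
) -> GeneList:
    """Genes retained by strictly more than half of the models.

    A tie at exactly half (possible with an even panel) drops the gene.
    """
    if models is None:
        models = [m for m in MODEL_NAMES if m in profiles] or list(profiles)
    missing = [m for m in models if m not in profiles]
    if missing:
        raise ValueError(f"no profiles for models: {missing}")
    gene_order = [p.gene for p in profiles[models[0]]]
    universe = set(gene_order)
    flags: dict[str, dict[str, bool]] = {}
    for m in models:
        flags[m] = {p.gene: p.retained for p in profiles[m]}
        if set(flags[m]) != universe:
            raise ValueError(f"model {m!r} scored a different gene universe")
    kept = [
        g for g in gene_order if sum(flags[m][g] for m in models) > len(models) / 2
    ]
    return GeneList(kept)
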
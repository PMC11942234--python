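"""Stage 1 of feature selection: differential expression on log2(TPM+1).

Each class is contrasted one-vs-rest. Per gene the log2 fold change is the
difference of group means of log2(TPM+1) and the p-value comes from a
two-sided Welch (unequal-variance) t-test on the same transformed values, with
Benjamini–Hochberg adjustment across all tested genes. Genes pass the filter
when |log2FC| ≥ log2(1.5) and adjusted p < 0.05, the thresholds the pipeline
was designed around.

The test backend is deliberately pluggable (a single function boundary):
inputs here are TPM, so a count-based negative-binomial backend can be
substituted when raw counts are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import ExpressionDataset, GeneList

__all__ = ["DEResult", "de_test", "de_filter", "de_test_all_contrasts", "union_deg_list"]


@dataclass
class DEResult:
    gene: str
    log2_fold_change: float
    p_value: float
    adj_p_value: float
    contrast: tuple[str, str]  # (label, "rest")


def de_test(ds: ExpressionDataset, label: str) -> list[DEResult]:
    """One-vs-rest differential expression for ``label`` against all other classes.

    Genes with zero variance in both groups (including the all-constant case)
    get log2FC equal to the mean difference (0 when means tie) and p = 1.
    """
    y = ds.label_array()
    in_group = y == label
    n1, n2 = int(in_group.sum()), int((~in_group).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"degenerate contrast for label {label!r}: {n1} vs {n2} samples "
            "(need >= 2 on each side)"
        )
    logx = np.log2(ds.values + 1.0)
    a = logx[:, in_group]
    b = logx[:, ~in_group]
    lfc = a.mean(axis=1) - b.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # Welch df is undefined when both groups are constant; no evidence either way
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    pvals = np.where(degenerate, 1.0, pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)

    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    contrast = (label, "rest")
    return [
        DEResult(g, float(lfc[i]), float(pvals[i]), float(adj[i]), contrast)
        for i, g in enumerate(ds.genes)
    ]


def de_filter(
    results: list[DEResult], fc_threshold: float = 1.5, alpha: float = 0.05
) -> GeneList:
    """Keep genes with |FC| ≥ ``fc_threshold`` (linear scale) and adj p < ``alpha``."""
    log_thr = np.log2(fc_threshold)
    kept = [
        r.gene
        for r in results
        if abs(r.log2_fold_change) >= log_thr and r.adj_p_value < alpha
    ]
    return GeneList(kept)


def de_test_all_contrasts(ds: ExpressionDataset) -> dict[str, list[DEResult]]:
    """Run one-vs-rest contrasts for every class label, in sorted label order."""
    return {label: de_test(ds, label) for label in sorted(set(ds.label_array()))}


def union_deg_list(
    per_contrast: dict[str, list[DEResult]],
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> GeneList:
    """Union of per-contrast DEG lists, preserving first-seen gene order."""
    out: list[str] = []
    for label in per_contrast:
        out.extend(de_filter(per_contrast[label], fc_threshold, alpha))
    return GeneList(out)
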
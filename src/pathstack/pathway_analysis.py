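"""Stages 2–3 of feature selection: enrichment, PC1-variance pathway gating,
parent–child pruning, and loading-based representative-gene selection.

A pathway is treated as interpretable signal when (a) it is over-represented
among the differentially expressed genes (one-sided hypergeometric test, BH
adjusted), and (b) its expression submatrix is close to one-dimensional: the
fraction of total variance captured by the first principal component, V, must
exceed 0.7 both raw and after the size normalisation

    V' = V * (km / k) ** alpha,     alpha = 0.5,

where k is the pathway size and km the median size among pathways passing the
raw gate. The normalisation compensates for V's systematic decrease with
pathway size. Finally each surviving pathway is collapsed to the smallest set
of genes whose absolute PC1 loadings strictly exceed 95% of the total loading
mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import ExpressionDataset, GeneList, GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "PathwayScore",
    "LoadingVector",
    "enrich",
    "pathway_covariance",
    "pc1_variance_fraction",
    "normalize_variance",
    "select_pathways",
    "prune_parent_pathways",
    "select_representative_genes",
]


@dataclass
class EnrichmentResult:
    pathway: str
    overlap: int
    pathway_size_in_universe: int
    p_value: float
    adj_p_value: float


@dataclass
class PathwayScore:
    pathway: str
    k: int
    V: float
    V_prime: float
    passes: bool


@dataclass
class LoadingVector:
    pathway: str
    entries: list[tuple[str, float]]  # (gene, signed PC1 loading)


def enrich(
    deg: GeneList,
    universe: GeneList,
    sets: GeneSetCollection,
    min_size: int = 5,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of DEGs in each gene set.

    Population = the gene universe (the expression-measured feature space),
    successes = the DEGs, draws = the pathway's genes present in the universe.
    Pathways with fewer than ``min_size`` universe genes are not tested.
    Returns pathways significant at BH-adjusted p < ``alpha``.
    """
    uni = universe.as_set()
    degs = deg.as_set()
    stray = degs - uni
    if stray:
        raise ValueError(f"DEGs not contained in the universe: {sorted(stray)[:5]}")

    names, pvals, overlaps, sizes = [], [], [], []
    M, n_deg = len(uni), len(degs)
    for name, members in sets.sets.items():
        in_uni = members & uni
        if len(in_uni) < min_size:
            continue
        ov = len(in_uni & degs)
        # upper tail: P(X >= ov) with X ~ Hypergeom(M, n_deg, |in_uni|)
        p = float(stats.hypergeom.sf(ov - 1, M, n_deg, len(in_uni)))
        names.append(name)
        pvals.append(min(p, 1.0))
        overlaps.append(ov)
        sizes.append(len(in_uni))
    if not names:
        return []
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        EnrichmentResult(names[i], overlaps[i], sizes[i], pvals[i], float(adj[i]))
        for i in range(len(names))
        if adj[i] < alpha
    ]


def pathway_covariance(ds: ExpressionDataset, pathway_genes: list[str]) -> np.ndarray:
    """Sample covariance (divisor n−1) of the samples × genes pathway submatrix."""
    idx = ds.gene_index(pathway_genes)  # raises on missing genes
    X = ds.values[idx, :].T  # samples × genes
    if X.shape[0] < 2:
        raise ValueError("covariance requires at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    return (Xc.T @ Xc) / (X.shape[0] - 1)


def pc1_variance_fraction(
    ds: ExpressionDataset, pathway_genes: list[str], standardize: bool = True
) -> tuple[float, LoadingVector]:
    """Fraction of total variance on PC1 of the pathway submatrix, with loadings.

    With ``standardize`` the eigendecomposition is of the gene–gene correlation
    matrix, so V is invariant to per-gene affine rescaling and no single
    high-expression gene can dominate; zero-variance genes are dropped first
    (they carry no correlation information). The loading vector is the unit
    leading eigenvector, sign-fixed so its largest-magnitude entry is positive.
    """
    if len(pathway_genes) < 2:
        raise ValueError("need at least 2 pathway genes")
    cov = pathway_covariance(ds, pathway_genes)
    sd = np.sqrt(np.diag(cov))
    genes = list(pathway_genes)
    if standardize:
        keep = sd > 0
        if not np.any(keep):
            raise ValueError("all pathway genes are constant across samples")
        if keep.sum() < 2:
            raise ValueError("fewer than 2 non-constant pathway genes")
        cov = cov[np.ix_(keep, keep)]
        sd = sd[keep]
        genes = [g for g, k in zip(genes, keep) if k]
        mat = cov / np.outer(sd, sd)
    else:
        if np.trace(cov) == 0:
            raise ValueError("all pathway genes are constant across samples")
        mat = cov
    evals, evecs = np.linalg.eigh(mat)
    v = float(evals[-1] / evals.sum())
    vec = evecs[:, -1]
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    return v, LoadingVector("", list(zip(genes, vec.tolist())))


def normalize_variance(V: float, k: int, km: float, alpha: float = 0.5) -> float:
    """Size-normalised PC1 variance fraction V' = V * (km/k)^alpha."""
    if k <= 0 or km <= 0:
        raise ValueError("pathway sizes must be positive")
    return V * (km / k) ** alpha


def select_pathways(
    scores: list[tuple[str, int, float]],
    v_threshold: float = 0.7,
    alpha: float = 0.5,
) -> list[PathwayScore]:
    """Apply the raw and size-normalised PC1-variance gates.

    ``scores`` holds (pathway, k, V) triples with k ≥ 5. km is the median size
    among pathways clearing the raw gate V > ``v_threshold``; each pathway then
    passes iff V > v_threshold and V' ≥ v_threshold.
    """
    for name, k, _ in scores:
        if k < 5:
            raise ValueError(f"pathway {name!r} has k={k} < 5; filter upstream")
    high = [k for _, k, v in scores if v > v_threshold]
    if not high:
        raise ValueError(
            f"no pathway has V > {v_threshold}; review the variance threshold "
            "or the enrichment stage"
        )
    km = float(np.median(high))
    out = []
    for name, k, v in scores:
        vp = normalize_variance(v, k, km, alpha)
        out.append(PathwayScore(name, k, v, vp, bool(v > v_threshold and vp >= v_threshold)))
    return out


def prune_parent_pathways(
    selected: set[str], sets: GeneSetCollection
) -> set[str]:
    """Drop parent pathways in favour of their more specific selected children.

    With an explicit hierarchy, any selected pathway that is an ancestor of
    another selected pathway is removed. Without one, a pathway whose gene set
    strictly contains another selected pathway's set is treated as the parent;
    identical gene sets keep only the lexicographically first identifier.
    """
    selected = set(selected)
    if sets.hierarchy:
        g = nx.DiGraph()
        g.add_nodes_from(sets.names())
        g.add_edges_from(sets.hierarchy)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"pathway hierarchy contains a cycle: {cycle}")
        drop = {
            p
            for p in selected
            if any(c in nx.descendants(g, p) for c in selected - {p})
        }
        return selected - drop
    drop: set[str] = set()
    for p in selected:
        for q in selected:
            if p == q:
                continue
            sp, sq = sets.sets[p], sets.sets[q]
            if sp > sq:  # strict superset => p is the less specific parent
                drop.add(p)
            elif sp == sq and p > q:
                drop.add(p)
    return selected - drop


def select_representative_genes(lv: LoadingVector, coverage: float = 0.95) -> GeneList:
    """Smallest loading-ranked gene prefix strictly exceeding the coverage mass.

    Genes are sorted by |loading| descending (ties broken by identifier); the
    returned prefix is the shortest whose summed |loading| is strictly greater
    than ``coverage`` times the total.
    """
    if not lv.entries:
        raise ValueError("empty loading vector")
    mags = [abs(v) for _, v in lv.entries]
    total = math.fsum(mags)
    if total == 0:
        raise ValueError("all PC1 loadings are zero")
    ranked = sorted(lv.entries, key=lambda e: (-abs(e[1]), e[0]))
    # compensated prefix sums keep the strict ">" honest at exact boundaries
    chosen: list[str] = []
    for s in range(1, len(ranked) + 1):
        chosen.append(ranked[s - 1][0])
        if math.fsum(abs(v) for _, v in ranked[:s]) > coverage * total:
            return GeneList(chosen)
    return GeneList(chosen)
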
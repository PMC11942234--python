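import math

import numpy as np
import pytest

from pathstack.core_data import GeneList, GeneSetCollection
from pathstack.pathway_analysis import (
    LoadingVector,
    enrich,
    normalize_variance,
    pathway_covariance,
    pc1_variance_fraction,
    prune_parent_pathways,
    select_pathways,
    select_representative_genes,
)

from conftest import make_dataset


def hypergeom_tail_oracle(overlap, universe, n_deg, n_path):
    """P(X >= overlap) by direct pmf enumeration with binomial coefficients."""
    total = 0.0
    for x in range(overlap, min(n_deg, n_path) + 1):
        total += (
            math.comb(n_deg, x)
            * math.comb(universe - n_deg, n_path - x)
            / math.comb(universe, n_path)
        )
    return total


class TestEnrichment:
    def _fixture(self, overlap, universe=20, n_deg=5, n_path=4):
        uni = [f"g{i}" for i in range(universe)]
        deg = uni[:n_deg]
        members = set(deg[:overlap]) | set(uni[n_deg : n_deg + (n_path - overlap)])
        sets = GeneSetCollection({"P": members})
        return GeneList(deg), GeneList(uni), sets

    def test_worked_hypergeometric_example(self):
        """Universe 20, 5 DEGs, 4-gene pathway, overlap 3 -> p ~ 0.03199."""
        deg, uni, sets = self._fixture(overlap=3)
        (r,) = enrich(deg, uni, sets, min_size=4, alpha=1.0)
        expected = hypergeom_tail_oracle(3, 20, 5, 4)
        assert expected == pytest.approx(0.031991744, abs=1e-8)
        assert r.p_value == pytest.approx(expected, abs=1e-12)
        assert r.overlap == 3 and r.pathway_size_in_universe == 4

    def test_zero_overlap_gives_p_one(self):
        deg, uni, sets = self._fixture(overlap=0)
        (r,) = enrich(deg, uni, sets, min_size=4, alpha=1.1)
        assert r.p_value == pytest.approx(1.0)

    def test_small_pathway_not_tested(self):
        deg, uni, sets = self._fixture(overlap=3)
        assert enrich(deg, uni, sets, min_size=5, alpha=1.0) == []

    def test_deg_outside_universe_raises(self):
        deg, uni, sets = self._fixture(overlap=2)
        bad_deg = GeneList(list(deg) + ["not_in_universe"])
        with pytest.raises(ValueError, match="not contained"):
            enrich(bad_deg, uni, sets)

    def test_matches_enumeration_on_random_small_universes(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            universe = int(rng.integers(10, 31))
            n_deg = int(rng.integers(2, universe // 2))
            n_path = int(rng.integers(2, universe // 2))
            uni = [f"g{i}" for i in range(universe)]
            deg = list(rng.choice(uni, n_deg, replace=False))
            members = set(rng.choice(uni, n_path, replace=False))
            sets = GeneSetCollection({"P": members})
            (r,) = enrich(GeneList(deg), GeneList(uni), sets, min_size=1, alpha=1.1)
            expected = hypergeom_tail_oracle(r.overlap, universe, n_deg, n_path)
            assert r.p_value == pytest.approx(expected, abs=1e-10)


class TestCovariance:
    def test_matches_double_loop_on_random_matrix(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 10, size=(3, 6))  # 3 genes x 6 samples
        ds = make_dataset(vals)
        cov = pathway_covariance(ds, ds.genes)
        X = vals.T
        n = X.shape[0]
        for i in range(3):
            for j in range(3):
                manual = sum(
                    (X[s, i] - X[:, i].mean()) * (X[s, j] - X[:, j].mean())
                    for s in range(n)
                ) / (n - 1)
                assert cov[i, j] == pytest.approx(manual, abs=1e-10)

    def test_perfectly_correlated_pair(self):
        base = np.array([1.0, 2, 3, 4, 5])
        ds = make_dataset(np.vstack([base, 3 * base]))
        cov = pathway_covariance(ds, ds.genes)
        assert cov[0, 1] == pytest.approx(np.sqrt(cov[0, 0] * cov[1, 1]), abs=1e-10)

    def test_constant_gene_gives_zero_row(self):
        ds = make_dataset(np.vstack([np.full(4, 7.0), np.arange(4.0)]))
        cov = pathway_covariance(ds, ds.genes)
        np.testing.assert_allclose(cov[0, :], 0.0, atol=1e-12)

    def test_missing_gene_raises(self):
        ds = make_dataset(np.ones((2, 3)))
        with pytest.raises(KeyError, match="absent"):
            pathway_covariance(ds, ["g1", "nope"])


class TestPC1VarianceFraction:
    def test_duplicated_genes_give_v_one(self):
        base = np.array([1.0, 5, 2, 8, 3, 9])
        ds = make_dataset(np.vstack([base, base, base]))
        v, lv = pc1_variance_fraction(ds, ds.genes)
        assert v == pytest.approx(1.0, abs=1e-12)
        assert len(lv.entries) == 3

    def test_matches_explicit_eigendecomposition(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(1, 9, size=(4, 8))
        ds = make_dataset(vals)
        v, lv = pc1_variance_fraction(ds, ds.genes)
        corr = np.corrcoef(vals)
        evals = np.linalg.eigvalsh(corr)
        assert v == pytest.approx(evals[-1] / evals.sum(), abs=1e-12)
        assert sum(x**2 for _, x in lv.entries) == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_limit_approaches_one_over_k(self):
        rng = np.random.default_rng(6)
        ds = make_dataset(rng.normal(100, 1, size=(4, 5000)))
        v, _ = pc1_variance_fraction(ds, ds.genes)
        assert v == pytest.approx(0.25, abs=0.03)

    def test_affine_rescaling_invariance_when_standardized(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(1, 5, size=(5, 30))
        ds = make_dataset(vals)
        scaled = make_dataset(vals * rng.uniform(0.5, 20, size=(5, 1)) + 3.0)
        v1, _ = pc1_variance_fraction(ds, ds.genes)
        v2, _ = pc1_variance_fraction(scaled, scaled.genes)
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(8)
        ds = make_dataset(rng.uniform(0, 10, size=(4, 20)))
        _, lv = pc1_variance_fraction(ds, ds.genes)
        loadings = [x for _, x in lv.entries]
        assert loadings[int(np.argmax(np.abs(loadings)))] > 0

    def test_all_constant_genes_raise(self):
        ds = make_dataset(np.ones((3, 5)))
        with pytest.raises(ValueError, match="constant"):
            pc1_variance_fraction(ds, ds.genes)


class TestNormalizeVariance:
    def test_identity_at_median_size(self):
        assert normalize_variance(0.8, 9, 9.0) == pytest.approx(0.8)

    def test_quarter_size_ratio(self):
        assert normalize_variance(0.7, 36, 9.0) == pytest.approx(0.35)

    def test_can_exceed_one_for_small_pathways(self):
        assert normalize_variance(0.9, 2, 8.0) == pytest.approx(1.8)

    def test_monotone_decreasing_in_k(self):
        vals = [normalize_variance(0.8, k, 10.0) for k in range(5, 40)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_sizes_raise(self):
        with pytest.raises(ValueError):
            normalize_variance(0.5, 0, 9.0)
        with pytest.raises(ValueError):
            normalize_variance(0.5, 5, 0.0)


class TestSelectPathways:
    def test_worked_example_with_three_pathways(self):
        scored = select_pathways([("A", 5, 0.9), ("B", 9, 0.8), ("C", 20, 0.75)])
        by = {s.pathway: s for s in scored}
        assert by["A"].V_prime == pytest.approx(0.9 * (9 / 5) ** 0.5, abs=1e-9)
        assert by["B"].V_prime == pytest.approx(0.8)
        assert by["C"].V_prime == pytest.approx(0.75 * (9 / 20) ** 0.5, abs=1e-9)
        assert (by["A"].passes, by["B"].passes, by["C"].passes) == (True, True, False)

    def test_single_high_pathway_is_its_own_median(self):
        (s,) = select_pathways([("A", 7, 0.85)])
        assert s.V_prime == pytest.approx(0.85) and s.passes

    def test_no_pathway_above_threshold_raises(self):
        with pytest.raises(ValueError, match="V > 0.7"):
            select_pathways([("A", 5, 0.5), ("B", 9, 0.7)])  # 0.7 is not > 0.7

    def test_small_pathway_input_rejected(self):
        with pytest.raises(ValueError, match="k=4"):
            select_pathways([("A", 4, 0.9)])

    def test_median_uses_only_high_v_pathways(self):
        scored = select_pathways(
            [("A", 5, 0.9), ("B", 50, 0.2), ("C", 60, 0.3), ("D", 7, 0.8)]
        )
        by = {s.pathway: s for s in scored}
        km = 6.0  # median of {5, 7}
        assert by["A"].V_prime == pytest.approx(0.9 * (km / 5) ** 0.5, abs=1e-9)


class TestPruning:
    def test_strict_superset_is_dropped(self):
        sets = GeneSetCollection(
            {"A": {f"g{i}" for i in range(5)}, "B": {f"g{i}" for i in range(10)}}
        )
        assert prune_parent_pathways({"A", "B"}, sets) == {"A"}

    def test_disjoint_sets_both_kept(self):
        sets = GeneSetCollection({"A": {"g1", "g2"}, "B": {"g3", "g4"}})
        assert prune_parent_pathways({"A", "B"}, sets) == {"A", "B"}

    def test_identical_sets_keep_lexicographically_first(self):
        sets = GeneSetCollection({"B": {"g1"}, "A": {"g1"}})
        assert prune_parent_pathways({"A", "B"}, sets) == {"A"}

    def test_hierarchy_overrides_set_relations(self):
        sets = GeneSetCollection(
            {"P": {"g1", "g2"}, "C": {"g3", "g4"}},
            hierarchy={("P", "C")},
        )
        assert prune_parent_pathways({"P", "C"}, sets) == {"C"}

    def test_hierarchy_ancestors_removed_transitively(self):
        sets = GeneSetCollection(
            {"A": {"g1"}, "B": {"g2"}, "C": {"g3"}},
            hierarchy={("A", "B"), ("B", "C")},
        )
        assert prune_parent_pathways({"A", "C"}, sets) == {"C"}

    def test_cycle_raises(self):
        sets = GeneSetCollection(
            {"A": {"g1"}, "B": {"g2"}}, hierarchy={("A", "B"), ("B", "A")}
        )
        with pytest.raises(ValueError, match="cycle"):
            prune_parent_pathways({"A"}, sets)

    def test_idempotent(self):
        sets = GeneSetCollection(
            {"A": {f"g{i}" for i in range(5)}, "B": {f"g{i}" for i in range(10)}, "C": {"x"}}
        )
        once = prune_parent_pathways({"A", "B", "C"}, sets)
        assert prune_parent_pathways(once, sets) == once


class TestRepresentativeGenes:
    def _lv(self, loadings):
        return LoadingVector("P", [(f"g{i}", v) for i, v in enumerate(loadings)])

    def test_prefix_scan_example(self):
        out = select_representative_genes(self._lv([0.6, 0.3, 0.06, 0.04]))
        assert list(out) == ["g0", "g1", "g2"]

    def test_single_gene(self):
        assert len(select_representative_genes(self._lv([1.0]))) == 1

    def test_strict_inequality_at_boundary(self):
        """Cumulative 0.95 of total 1.0 at rank 3 is not > 95%, so all four
        genes are needed."""
        out = select_representative_genes(self._lv([0.5, 0.3, 0.15, 0.05]))
        assert len(out) == 4

    def test_signs_are_ignored(self):
        out = select_representative_genes(self._lv([-0.6, 0.3, -0.06, 0.04]))
        assert list(out) == ["g0", "g1", "g2"]

    def test_all_zero_loadings_raise(self):
        with pytest.raises(ValueError, match="zero"):
            select_representative_genes(self._lv([0.0, 0.0]))

    def test_output_size_monotone_in_coverage(self):
        rng = np.random.default_rng(9)
        lv = self._lv(rng.normal(size=12))
        sizes = [
            len(select_representative_genes(lv, c)) for c in np.linspace(0.1, 0.99, 15)
        ]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_matches_exhaustive_minimal_prefix_search(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            loadings = rng.normal(size=int(rng.integers(2, 10)))
            lv = self._lv(loadings)
            got = len(select_representative_genes(lv, 0.95))
            mags = np.sort(np.abs(loadings))[::-1]
            best = next(
                s
                for s in range(1, len(mags) + 1)
                if mags[:s].sum() > 0.95 * mags.sum()
            )
            assert got == best
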
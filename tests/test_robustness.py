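import numpy as np
import pytest

from pathstack.core_data import GeneList
from pathstack.models import MODEL_NAMES
from pathstack.robustness import (
    RobustnessProfile,
    importance_scores,
    majority_vote_retention,
    permutation_profile,
)
from pathstack.synthetic import PlantedPathway, SimulationDesign, simulate

from conftest import make_dataset


def _two_gene_dataset(seed=0, n=60):
    """One perfectly separating gene, one pure-noise gene."""
    rng = np.random.default_rng(seed)
    labels = ["A"] * (n // 2) + ["B"] * (n // 2)
    sep = np.where(np.array(labels) == "A", 10.0, 100.0) + rng.normal(0, 1, n)
    noise = rng.uniform(10, 100, n)
    return make_dataset(np.vstack([np.clip(sep, 0, None), noise]), labels=labels)


class TestImportanceScores:
    @pytest.mark.parametrize("model", MODEL_NAMES)
    def test_separating_gene_outranks_noise(self, model):
        wins = 0
        for seed in range(10):
            ds = _two_gene_dataset(seed)
            scores = importance_scores(ds, GeneList(ds.genes), model, seed=seed)
            wins += scores[0].value > scores[1].value
        assert wins >= 9

    def test_normalized_scores_sum_to_one(self):
        ds = _two_gene_dataset()
        for model in MODEL_NAMES:
            scores = importance_scores(ds, GeneList(ds.genes), model)
            assert sum(s.value for s in scores) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_model_raises(self):
        ds = _two_gene_dataset()
        with pytest.raises(ValueError, match="unknown model"):
            importance_scores(ds, GeneList(ds.genes), "MLP")


class TestPermutationProfile:
    def _profile_with_counts(self, n_below_by_gene, n_permutations=100):
        """Drive the retention rule through a crafted score function."""
        ds = _two_gene_dataset(n=40)
        genes = GeneList(ds.genes)

        def score_fn(X, y, iteration):
            if iteration < 0:  # true-label call
                return np.ones(len(n_below_by_gene))
            return np.array(
                [0.5 if iteration < nb else 2.0 for nb in n_below_by_gene]
            )

        return permutation_profile(
            ds,
            genes,
            "LR",
            n_permutations=n_permutations,
            score_fn=score_fn,
            seed=1,
        )

    def test_retention_boundary_inclusive_at_95(self):
        p95, p94 = self._profile_with_counts([95, 94])
        assert p95.n_below == 95 and p95.retained
        assert p94.n_below == 94 and not p94.retained

    def test_boundary_scales_with_permutation_count(self):
        p19, p18 = self._profile_with_counts([19, 18], n_permutations=20)
        assert p19.retained and not p18.retained  # ceil(0.95 * 20) = 19

    def test_label_independent_scores_are_never_retained(self):
        """A constant-importance score with symmetric refit jitter gives
        n_below ~ Binomial(n_permutations, 0.5); retention at the 95% rule is
        then astronomically unlikely."""
        ds = _two_gene_dataset(n=40)
        rng = np.random.default_rng(123)

        def null_scores(X, y, iteration):
            base = np.ones(X.shape[1])
            if iteration < 0:
                return base
            return base + rng.normal(scale=0.05, size=X.shape[1])

        profiles = permutation_profile(
            ds, GeneList(ds.genes), "LR", n_permutations=100, score_fn=null_scores
        )
        assert not any(p.retained for p in profiles)
        assert all(20 <= p.n_below <= 80 for p in profiles)

    def test_bit_reproducible_from_seed(self):
        ds = _two_gene_dataset()
        a = permutation_profile(ds, GeneList(ds.genes), "LR", n_permutations=5, seed=9)
        b = permutation_profile(ds, GeneList(ds.genes), "LR", n_permutations=5, seed=9)
        assert [p.permuted_importances for p in a] == [p.permuted_importances for p in b]

    def test_separating_gene_retained_noise_gene_not(self):
        ds = _two_gene_dataset(seed=3, n=80)
        profiles = permutation_profile(
            ds, GeneList(ds.genes), "LR", n_permutations=40, seed=2
        )
        assert profiles[0].retained
        assert profiles[0].n_below > profiles[1].n_below

    def test_invalid_arguments_raise(self):
        ds = _two_gene_dataset()
        with pytest.raises(ValueError, match="n_permutations"):
            permutation_profile(ds, GeneList(ds.genes), "LR", n_permutations=0)
        with pytest.raises(ValueError, match="subset_fraction"):
            permutation_profile(ds, GeneList(ds.genes), "LR", subset_fraction=1.5)


class TestMajorityVote:
    def _profiles(self, flags_by_model):
        out = {}
        for model, flags in flags_by_model.items():
            out[model] = [
                RobustnessProfile(f"g{i}", model, 1.0, [], 0, bool(f))
                for i, f in enumerate(flags)
            ]
        return out

    def test_three_of_five_kept_two_of_five_dropped(self):
        profiles = self._profiles(
            {
                "LR": [1, 1],
                "SVM": [1, 1],
                "RF": [1, 0],
                "XGB": [0, 0],
                "LGBM": [0, 0],
            }
        )
        assert list(majority_vote_retention(profiles)) == ["g0"]

    def test_tie_on_even_panel_is_dropped(self):
        profiles = self._profiles({"LR": [1], "SVM": [1], "RF": [0], "XGB": [0]})
        assert list(majority_vote_retention(profiles, ["LR", "SVM", "RF", "XGB"])) == []

    def test_inconsistent_gene_universe_raises(self):
        profiles = self._profiles({"LR": [1, 1], "SVM": [1]})
        with pytest.raises(ValueError, match="universe"):
            majority_vote_retention(profiles, ["LR", "SVM"])

    def test_missing_model_raises(self):
        profiles = self._profiles({"LR": [1]})
        with pytest.raises(ValueError, match="no profiles"):
            majority_vote_retention(profiles, ["LR", "SVM"])


class TestEndToEndRetention:
    def test_planted_genes_survive_majority_vote(self):
        """On a strongly planted design the voted gene set is dominated by
        planted genes under a reduced permutation budget."""
        design = SimulationDesign(
            n_samples_per_class=[60, 40],
            n_background_genes=100,
            planted_pathways=[PlantedPathway(8, 2.0, 0.4)],
            seed=21,
        )
        ds, _, planted = simulate(design)
        candidates = GeneList(list(planted) + [f"BG{j + 1:05d}" for j in range(4)])
        profiles = {
            m: permutation_profile(ds, candidates, m, n_permutations=20, seed=13)
            for m in MODEL_NAMES
        }
        kept = majority_vote_retention(profiles)
        overlap = len(set(kept) & planted.as_set())
        assert overlap >= 0.7 * len(planted)
        assert len(set(kept) - planted.as_set()) <= 1
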
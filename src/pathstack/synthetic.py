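"""Synthetic TPM cohorts with planted pathway-coherent class signal.

The generator emulates the structure the selection pipeline is built for: a
bulk-RNA-seq-like TPM matrix over a modest gene universe in which a handful of
"planted" pathways carry a class-dependent expression shift, the member genes
of each pathway co-vary through a shared latent factor (so the pathway's first
principal component captures the planted axis), and everything else is
heavy-tailed log-normal background noise. Class imbalance and a controllable
fraction of mislabeled ("adversarial") samples complete the picture.

Default design mirrors the melanoma metastasis cohort that motivated the
method: 368 vs 102 samples, an enzyme-gene-sized background universe scaled to
desk size, and five planted pathways of ten genes each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import ExpressionDataset, GeneList, GeneSetCollection, round_half_even

__all__ = ["PlantedPathway", "SimulationDesign", "simulate", "mislabel"]

TPM_TOTAL = 1_000_000.0
_BASELINE_LOG2_MEAN = 4.0  # median background TPM ~16 before renormalisation
_BASELINE_LOG2_SD = 2.0


@dataclass(frozen=True)
class PlantedPathway:
    """One pathway with planted signal.

    size
        Number of member genes, ≥ 5.
    log2_effect
        Class-dependent mean shift of each member gene, in log2-TPM units.
    correlation
        Within-pathway gene–gene correlation ρ ∈ [0, 1), induced by a shared
        latent factor with loading √ρ.
    """

    size: int = 10
    log2_effect: float = 1.5
    correlation: float = 0.6


@dataclass
class SimulationDesign:
    n_samples_per_class: list[int] = field(default_factory=lambda: [368, 102])
    n_background_genes: int = 1000
    planted_pathways: list[PlantedPathway] = field(
        default_factory=lambda: [PlantedPathway() for _ in range(5)]
    )
    label_noise_fraction: float = 0.0
    dispersion: float = 1.0
    seed: int = 42
    n_decoy_sets_per_pathway: int = 3

    def __post_init__(self) -> None:
        if len(self.n_samples_per_class) < 2:
            raise ValueError("need at least 2 classes")
        if any(n < 1 for n in self.n_samples_per_class):
            raise ValueError("every class needs at least 1 sample")
        if self.n_background_genes < 1:
            raise ValueError("n_background_genes must be positive")
        for p in self.planted_pathways:
            if p.size < 5:
                raise ValueError("planted pathways must have size >= 5")
            if not (0.0 <= p.correlation < 1.0):
                raise ValueError("within-pathway correlation must be in [0, 1)")
        if not (0.0 <= self.label_noise_fraction < 1.0):
            raise ValueError("label_noise_fraction must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.planted_pathways and max(p.size for p in self.planted_pathways) > (
            self.n_background_genes
        ):
            raise ValueError(
                "infeasible design: size-matched decoy sets need at least as many "
                "background genes as the largest planted pathway"
            )

    @property
    def n_samples(self) -> int:
        return sum(self.n_samples_per_class)

    @property
    def class_labels(self) -> list[str]:
        return [f"C{i}" for i in range(len(self.n_samples_per_class))]


def simulate(design: SimulationDesign) -> tuple[ExpressionDataset, GeneSetCollection, GeneList]:
    """Draw one cohort from ``design``.

    Returns the labelled TPM dataset (columns sum to 10^6), a gene-set
    collection holding each planted pathway plus size-matched random
    background decoy sets, and the list of planted genes.

    Identical seeds give bit-identical outputs.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_samples
    m = len(design.n_samples_per_class)
    labels_clean = np.repeat(design.class_labels, design.n_samples_per_class)
    samples = [f"S{i + 1:04d}" for i in range(n)]

    planted_genes: list[str] = []
    pathway_members: dict[str, list[str]] = {}
    for p_idx, pw in enumerate(design.planted_pathways, start=1):
        name = f"PLANTED_PWY_{p_idx}"
        members = [f"PW{p_idx}_G{j + 1:02d}" for j in range(pw.size)]
        pathway_members[name] = members
        planted_genes.extend(members)
    background = [f"BG{j + 1:05d}" for j in range(design.n_background_genes)]
    genes = planted_genes + background

    log2x = np.empty((len(genes), n))
    baseline = rng.normal(_BASELINE_LOG2_MEAN, _BASELINE_LOG2_SD, size=len(genes))

    row = 0
    for p_idx, pw in enumerate(design.planted_pathways, start=1):
        # each pathway discriminates one non-reference class, cycling over them
        target_class = design.class_labels[1 + (p_idx - 1) % (m - 1)]
        shift = (labels_clean == target_class).astype(float) * pw.log2_effect
        factor = rng.normal(size=n)  # shared latent axis of the pathway
        for _ in range(pw.size):
            noise = rng.normal(size=n)
            z = (
                baseline[row]
                + design.dispersion
                * (np.sqrt(pw.correlation) * factor + np.sqrt(1.0 - pw.correlation) * noise)
                + shift
            )
            log2x[row] = z
            row += 1
    for _ in background:
        log2x[row] = baseline[row] + design.dispersion * rng.normal(size=n)
        row += 1

    expr = np.exp2(log2x)
    tpm = expr / expr.sum(axis=0, keepdims=True) * TPM_TOTAL

    label_map = dict(zip(samples, labels_clean.tolist()))
    if design.label_noise_fraction > 0:
        label_map = mislabel(label_map, design.label_noise_fraction, rng)

    sets: dict[str, set[str]] = {k: set(v) for k, v in pathway_members.items()}
    descriptions = {
        name: f"planted pathway (k={len(v)})" for name, v in pathway_members.items()
    }
    for p_idx, pw in enumerate(design.planted_pathways, start=1):
        for r in range(design.n_decoy_sets_per_pathway):
            name = f"RANDOM_SET_{p_idx}_{r + 1}"
            members = rng.choice(background, size=pw.size, replace=False)
            sets[name] = set(members.tolist())
            descriptions[name] = "size-matched random background set"

    ds = ExpressionDataset(genes, samples, tpm, label_map)
    return ds, GeneSetCollection(sets, descriptions), GeneList(planted_genes)


def mislabel(
    labels: dict[str, str], fraction: float, rng: np.random.Generator
) -> dict[str, str]:
    """Reassign a random ``fraction`` of samples to a different class.

    Exactly ``round(fraction * n)`` samples (round-half-to-even) are chosen
    uniformly without replacement; each gets a label drawn uniformly from the
    other observed classes. This is label *reassignment* — the corruption used
    for model stability/robustness evaluation — as opposed to the within-subset
    label permutation used by the gene-level robustness filter.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    samples = list(labels.keys())
    n_flip = round_half_even(fraction * len(samples))
    out = dict(labels)
    if n_flip == 0:
        return out
    label_set = sorted(set(labels.values()))
    if len(label_set) < 2:
        raise ValueError("cannot mislabel: only one class present")
    chosen = rng.choice(len(samples), size=n_flip, replace=False)
    for idx in chosen:
        s = samples[idx]
        others = [l for l in label_set if l != labels[s]]
        out[s] = others[rng.integers(len(others))]
    return out
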
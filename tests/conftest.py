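import numpy as np
import pytest

from pathstack.core_data import ExpressionDataset
from pathstack.synthetic import PlantedPathway, SimulationDesign, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """Two-class cohort with two strongly planted pathways, desk-sized."""
    design = SimulationDesign(
        n_samples_per_class=[60, 40],
        n_background_genes=150,
        planted_pathways=[PlantedPathway(8, 1.5, 0.5), PlantedPathway(6, 2.0, 0.5)],
        seed=11,
    )
    return simulate(design)


@pytest.fixture(scope="session")
def separable_cohort():
    """Wide-margin cohort on which a linear model should be perfect."""
    design = SimulationDesign(
        n_samples_per_class=[50, 30],
        n_background_genes=40,
        planted_pathways=[PlantedPathway(6, 6.0, 0.0)],
        seed=5,
    )
    return simulate(design)


def make_dataset(values, labels=None, prefix="g"):
    """Tiny ExpressionDataset from a genes × samples array."""
    values = np.asarray(values, dtype=float)
    genes = [f"{prefix}{i + 1}" for i in range(values.shape[0])]
    samples = [f"s{j + 1}" for j in range(values.shape[1])]
    label_map = None
    if labels is not None:
        label_map = dict(zip(samples, labels))
    return ExpressionDataset(genes, samples, values, label_map)
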
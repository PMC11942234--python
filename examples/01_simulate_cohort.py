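"""Draw a synthetic TPM cohort with planted pathway signal.

Builds a melanoma-metastasis-like two-class cohort (majority:minority 150:50)
in which five 10-gene pathways carry a class-dependent log2 shift of 1.5 and
co-vary through a shared latent factor (rho = 0.6); 1000 background genes are
pure log-normal noise. Prints the cohort dimensions and verifies the TPM
column constraint.
"""

import numpy as np

from pathstack import PlantedPathway, SimulationDesign, simulate

design = SimulationDesign(
    n_samples_per_class=[150, 50],
    n_background_genes=1000,
    planted_pathways=[PlantedPathway(size=10, log2_effect=1.5, correlation=0.6)] * 5,
    seed=1,
)
ds, gene_sets, planted = simulate(design)

print(f"genes x samples: {ds.n_genes} x {ds.n_samples}")
print(f"class counts:    {ds.class_counts()}")
print(f"planted genes:   {len(planted)} across {sum(n.startswith('PLANTED') for n in gene_sets.names())} pathways")
print(f"gene sets:       {len(gene_sets)} (planted + size-matched random decoys)")
print(f"TPM column sums: {ds.values.sum(axis=0).min():.1f} .. {ds.values.sum(axis=0).max():.1f}")
# Every column sums to 10^6 — the TPM unit constraint the pipeline assumes.
assert np.allclose(ds.values.sum(axis=0), 1e6, rtol=1e-6)
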
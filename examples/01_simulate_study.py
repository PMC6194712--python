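"""Generate a small synthetic co-fractionation study with planted ground truth.

The generator plants three kinds of complexes: co-eluting (members share an
elution peak — these behave like complexes that are intact under the
experimental conditions), disrupted (members elute at deliberately separated
positions — intact in the literature, broken in this assay), and neutral
(members elute independently, indistinguishable from chance).
"""

import numpy as np

from cofracbench.simulate import (
    SimulationConfig,
    complex_database,
    generate_datasets,
    generate_truth,
)

config = SimulationConfig(
    n_proteins=200, n_fractions=40, n_complexes=20, complex_size_range=(3, 6),
    frac_coeluting=0.5, frac_disrupted=0.3, seed=42,
)
rng = np.random.default_rng(config.seed)
truth = generate_truth(config, rng)
datasets = generate_datasets(config, truth, rng=rng)
db = complex_database(truth)

print(f"proteins: {config.n_proteins}, fractions: {config.n_fractions}")
for klass in ("coeluting", "disrupted", "neutral"):
    print(f"{klass:>10} complexes: {len(truth.complexes_of_class(klass))}")
for ds in datasets:
    missing = float(ds.data.isna().to_numpy().mean())
    print(f"dataset {ds.dataset_id}: {len(ds.proteins)} profiles, "
          f"{missing:.0%} missing cells")
# Each dataset redraws elution positions, so disrupted/neutral complexes look
# different between replicates while co-eluting complexes stay coherent.
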
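"""Gold-standard choice changes the predicted interactome's size at fixed precision.

A Gaussian Naive Bayes classifier scores every candidate protein pair from
co-elution features (Pearson R, Euclidean distance, co-apex distance,
averaged across datasets). Training labels come from a gold standard: TP =
within-complex pair, FP = pair of gold proteins from different complexes.
Ranking pairs by score and tracking cumulative precision = TP/(TP+FP) over
labeled pairs, the interactome at X% precision is the deepest prefix whose
precision meets X. A clean gold standard (only complexes that truly co-elute)
yields far larger interactomes than size-matched random gold subsets.
"""

import itertools

import numpy as np

from cofracbench.dataio import complex_to_pairs, filter_min_fractions
from cofracbench.predictor import (
    build_features,
    interactome_at_precision,
    label_pairs,
    precision_recall,
    train_score_cv,
)
from cofracbench.simulate import (
    SimulationConfig,
    complex_database,
    generate_datasets,
    generate_truth,
)
from cofracbench.subsets import random_subset

config = SimulationConfig(n_proteins=150, n_fractions=40, n_complexes=20,
                          complex_size_range=(3, 6), frac_coeluting=0.6,
                          frac_disrupted=0.4, seed=23)
rng = np.random.default_rng(config.seed)
truth = generate_truth(config, rng)
datasets = [filter_min_fractions(d, 5)
            for d in generate_datasets(config, truth, rng=rng)]
db = complex_database(truth)

proteins = sorted(set().union(*[set(d.proteins) for d in datasets]))
features = build_features(datasets, list(itertools.combinations(proteins, 2)))
pairs = list(features.index)
all_gold = complex_to_pairs(db)

# clean gold standard: only the complexes that truly co-elute
clean_pairs, clean_proteins = set(), set()
for cid in truth.complexes_of_class("coeluting"):
    members = sorted(truth.complex_members[cid])
    clean_proteins.update(members)
    clean_pairs.update(itertools.combinations(members, 2))


def interactome_sizes(gold_pairs, gold_proteins, seed):
    labels = label_pairs(pairs, gold_pairs, gold_proteins)
    scores = train_score_cv(features, labels, n_folds=5, seed=seed)
    ranked = precision_recall(scores, labels)
    return {p: interactome_at_precision(ranked, p)[1] for p in (0.5, 0.75, 0.9)}


sizes_clean = interactome_sizes(clean_pairs, clean_proteins, 0)
rnd = random_subset(all_gold, len(clean_pairs), seed=1)
sizes_random = interactome_sizes(rnd, None, 0)
sizes_full = interactome_sizes(all_gold, db.protein_universe, 0)

print(f"gold standards: clean = {len(clean_pairs)} pairs (co-eluting "
      f"complexes only), random = {len(rnd)} pairs, full = {len(all_gold)}")
print("\ninteractome size (pairs) at fixed precision:")
print(f"{'precision':>10} {'clean':>8} {'random':>8} {'full':>8}")
for p in (0.5, 0.75, 0.9):
    print(f"{p:>10.0%} {sizes_clean[p]:>8} {sizes_random[p]:>8} {sizes_full[p]:>8}")
# the clean subset dominates: contaminated/random gold standards poison the
# training labels AND deflate the measured precision of good predictions
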
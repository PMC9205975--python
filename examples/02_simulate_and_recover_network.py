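"""Simulate a planted regulatory network and recover it end to end.

Generates a 10-gene, 480-point data set with known directed couplings, runs
the screening pipeline, and scores the ranked edges against the emitted gold
standard.
"""

import numpy as np

from tegrn import (
    PlantedNetwork,
    SamplingDesign,
    all_pairs_te,
    one_way_screen,
    roc_pr_curves,
    simulate,
)

names = tuple(f"G{i}" for i in range(10))
rng = np.random.default_rng(0)
pairs = [(a, b) for a in names for b in names if a != b]
chosen = [pairs[i] for i in rng.choice(len(pairs), size=10, replace=False)]
net = PlantedNetwork(genes=names, edges={p: 0.8 for p in chosen}, mode="nonlinear-lag")

matrix, gold = simulate(net, SamplingDesign(interval_minutes=3, duration_hours=24), seed=0)
print(f"simulated {matrix.shape[0]} genes x {matrix.shape[1]} time points")

te_matrix = all_pairs_te(matrix, n_permutations=100, master_seed=0)
one_way = one_way_screen(te_matrix)
print(f"{len(te_matrix.entries)} ordered pairs -> {len(one_way)} one-way edges")

metrics, _ = roc_pr_curves(te_matrix, gold)
print(f"AUROC vs planted gold standard: {metrics.auroc:.3f}")
print(f"AUPRC vs planted gold standard: {metrics.auprc:.3f}")
# AUROC well above 0.5 means true planted couplings rank above spurious
# pairs; over many seeds the median for coupling 0.8 is above 0.8.
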
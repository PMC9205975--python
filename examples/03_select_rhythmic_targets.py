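"""Select candidate rhythm genes that share a reference expression pattern.

Builds a small panel in which ten genes follow the reference's night-peaked
waveform and twenty follow other phases, clusters the panel with fuzzy
c-means and with cosine agglomerative clustering, and intersects the two
clusters containing the reference.
"""

import numpy as np
import pandas as pd

from tegrn import (
    SamplingDesign,
    cosine_cluster,
    fuzzy_cmeans_cluster,
    make_rhythm_reference,
    select_by_reference,
)

design = SamplingDesign(interval_minutes=6, duration_hours=24)
rng = np.random.default_rng(1)
rows = {"REF": make_rhythm_reference(design, peak_phase_hours=22.0, seed=0)}
for i in range(9):
    rows[f"co{i}"] = make_rhythm_reference(design, peak_phase_hours=22.0, seed=i + 1)
for i in range(20):
    phase = float(rng.uniform(4.0, 16.0))
    rows[f"bg{i}"] = make_rhythm_reference(design, peak_phase_hours=phase, seed=100 + i)
matrix = pd.DataFrame(rows).T

fuzzy = fuzzy_cmeans_cluster(matrix, n_clusters=3, seed=0)
cosine = cosine_cluster(matrix, n_clusters=3)
selected = select_by_reference(fuzzy, cosine, "REF")
print(f"selected {len(selected)} genes sharing the reference pattern:")
print(sorted(selected))
# The planted co-phase genes (co0..co8 plus REF) are recovered; genes with
# other peak phases fall into different clusters and are excluded.
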
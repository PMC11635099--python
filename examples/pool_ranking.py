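"""Common-growth ranking of a small gene-clone pool.

Mimics the pooled growth of 14 gene expression clones over five passages
in three replicate flasks, then ranks clones by their mean relative
frequency change (cycle 5 vs start).
"""

import numpy as np
import pandas as pd

import denovopool as dp

s = np.linspace(0.10, -0.16, 14)  # clone 1 fittest, clone 14 least fit
truth = dp.make_mdng_pool(s, n_replicates=3, n_cycles=5, seed=21)

rng = np.random.default_rng(22)
depth = 300_000
cols, meta = {}, []
for r in range(3):
    for t in (1, 6):
        name = truth.sample_name(r, t - 1)
        cols[name] = pd.Series(rng.multinomial(depth, truth.frequencies(r, t - 1)),
                               index=truth.clone_ids)
        meta.append({"sample": name, "replicate": r + 1, "timepoint": t})
cm = dp.assemble_count_matrix(cols, pd.DataFrame(meta).set_index("sample"))

ranking = dp.rank_pool_growth(cm)
print(ranking[["mean_change", "rank"]].sort_values("rank").to_string())
print("\nmean_change is frequency(cycle 5)/frequency(start) averaged over "
      "the three replicates; rank 1 is the largest relative increase. "
      "With evenly spaced fitness values the recovered ranking follows "
      "the true fitness order.")
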
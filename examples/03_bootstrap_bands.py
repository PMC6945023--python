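"""Bootstrap confidence bands around a fitted demographic history.

Resamples the sites of a simulated SFS, refits each replicate, and
prints the pointwise 5%/50%/95% quantiles of Ne on a log time grid.
"""

import numpy as np

from stepsfs import (
    SimDemography,
    bootstrap_histories,
    quantile_bands,
    simulate_sfs,
)

u = 1e-8
truth = SimDemography(epochs=((0.0, 1_000.0), (500.0, 10_000.0)))
sfs = simulate_sfs(20, truth, u, 10_000_000, seed=4, num_genealogies=5000)

histories, dropped = bootstrap_histories(sfs, u, replicates=100, seed=11)
print(f"fitted {len(histories)} bootstrap replicates ({dropped} dropped)")

grid = np.geomspace(50, 50_000, 8)
bands = quantile_bands(histories, grid)
print(f"\n{'time':>10} {'q05':>10} {'median':>10} {'q95':>10}")
for t, lo, md, hi in zip(grid, bands["quantiles"][0.05],
                         bands["quantiles"][0.5], bands["quantiles"][0.95]):
    print(f"{t:10.0f} {lo:10.0f} {md:10.0f} {hi:10.0f}")
print("\nthe 5-95% band should contain the true Ne (1000 recently,")
print("10000 in the deep past) at the corresponding times.")
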
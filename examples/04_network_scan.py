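"""Interactome connectivity scan over a ranked gene list.

A 15-gene module is planted in a 500-node scale-free interactome as a
dense cluster of well-connected proteins.  With that module heading the
ranked gene list, the average degree of the connected top genes exceeds
the empirical null (random gene sets of the same size), and the scan
stops significant almost immediately.
"""

import numpy as np

from triopba import NetworkScanConfig, SimConfig, TruthSet, generate_interactome, scan
from triopba.sim import rng_for

cfg = SimConfig(n_genes=500, n_snps=1500, module_density_multiple=5.0, seed=4)
module = [f"G{i:04d}" for i in range(15)]
inter = generate_interactome(cfg, TruthSet([], [], [], module))
print(f"interactome: {inter.n_nodes} nodes, {inter.n_edges} edges")

rng = rng_for(cfg.seed, "example-ranking")
rest = [g for g in inter.nodes if g not in set(module)]
ranked = module + list(np.asarray(rest)[rng.permutation(len(rest))])

result = scan(ranked, inter,
              NetworkScanConfig(n_start=10, n_max=50, n_null_samples=1000, seed=4))
print(
    f"scan stopped at N = {result.n_final}: "
    f"avg connectivity {result.observed_avg_connectivity:.1f} vs null mean "
    f"{result.null_mean:.1f} (95th pct {result.null_q95:.1f}), "
    f"empirical p = {result.empirical_p:.4g}"
)
print(
    f"subnetwork links {len(result.subnetwork.seeds_linked)} of the top "
    f"{result.n_final} genes through {len(result.subnetwork.intermediates)} "
    "intermediate node(s); p is the add-one upper-tail probability under "
    "1,000 random same-size gene draws."
)
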
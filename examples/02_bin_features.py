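"""Compute per-bin accessibility and motif features around a true binding site.

The genome is tiled into 50-bp bins; every feature is one number per bin.
At a bound site the accessibility statistics and the motif log-probabilities
should all rise above their background levels.
"""

import numpy as np

from tfbind import SimConfig, bin_genome, build_feature_table, generate

data = generate(SimConfig(seed=2, n_chroms=1, chrom_length=80_000, n_sites=15, n_decoys=15))
bins = bin_genome(data.sizes)
ct = data.cell_types[0]

table = build_feature_table(
    bins,
    data.accessibility[ct],
    data.accessibility_peaks[ct],
    data.accessibility_peaks[ct],
    [data.pwm],
    genome=data.genome,
    coverage_by_celltype=data.accessibility,
)
print(f"{table.n_features} features per bin: {table.names}\n")

chrom, site = data.true_sites[ct][0]
site_bin = site // 50
background_bin = site_bin + 100  # 5 kb away

arr = table.data[chrom]
print(f"true site at {chrom}:{site} (bin {site_bin}) vs background bin {background_bin}:")
for j, name in enumerate(table.names):
    print(f"  {name:32s} site={arr[site_bin, j]:9.3f}  background={arr[background_bin, j]:9.3f}")

# the motif's best hit in the site bin should be orders of magnitude more
# probable than anywhere near the background bin
j = table.names.index(f"motif_{data.pwm.name}_max_log_prob")
gap = arr[site_bin, j] - arr[background_bin, j]
print(f"\nmotif max-log-probability gap (site - background): {gap:.2f} nats")
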
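"""Train one two-class exponential-family classifier by discriminative
maximum conditional likelihood and inspect what it learned.

Positives are windows centered at ChIP peak summit bins; negatives come from
the uniform and accessibility-matched sampling schemas.  The classifier is a
product of per-feature components (Gaussian for numeric, Bernoulli for the
peak-overlap indicators) in natural parameterization, so its posterior is a
logistic function of the sufficient statistics.
"""

import numpy as np

from tfbind import SimConfig, bin_genome, generate, train_mcl
from tfbind.features import extract_windows
from tfbind.pipeline import feature_tables
from tfbind.sampling import build_initial_training_set

data = generate(SimConfig(seed=3, n_chroms=2, chrom_length=100_000, n_sites=25, n_decoys=25))
ct = data.cell_types[0]
bins = bin_genome(data.sizes)
table = feature_tables(data)[ct]

ts = build_initial_training_set(
    bins,
    data.chip_conservative[ct],
    data.chip_relaxed[ct],
    data.accessibility[ct],
    np.random.default_rng(0),
    other_conservative={o: data.chip_conservative[o] for o in data.cell_types if o != ct},
)
n_pos = sum(1 for l in ts.labels if l == "B")
print(f"training set: {n_pos} positives, {len(ts) - n_pos} negatives")
for src in ("uniform", "dnase-matched", "cross-celltype"):
    n = sum(1 for p in ts.provenance if p == src)
    w = sum(w for w, p in zip(ts.weights, ts.provenance) if p == src)
    print(f"  {src:15s} n={n:4d}  total weight={w:8.2f}")

W = 7  # adjacent bins per window (350 bp)
X, names, families = extract_windows(table, ts.centers, W)
model = train_mcl(X, ts.labels, ts.weight_array, families, feature_names=names)
print(f"\nfitted in {model.fit_info['n_iter']} iterations, "
      f"|grad| = {model.fit_info['grad_norm']:.2e}")

post = model.posterior(X)
labels = np.asarray(ts.labels)
print(f"mean posterior on positives: {post[labels == 'B'].mean():.3f}")
print(f"mean posterior on negatives: {post[labels == 'U'].mean():.3f}")

# which feature columns separate the classes most (standardized mean gap)?
pos, neg = X[labels == "B"], X[labels == "U"]
scale = X.std(axis=0)
scale[scale == 0] = 1.0
gap = np.abs(pos.mean(axis=0) - neg.mean(axis=0)) / scale
print("\nmost class-separating feature columns (bound vs unbound, in SDs):")
for j in np.argsort(-gap)[:5]:
    print(f"  {names[j]:40s} {gap[j]:.2f}")
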
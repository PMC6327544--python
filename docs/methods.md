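# Methods

## Problem setting

Transcription factor binding is cell type-specific: the same genome yields
different ChIP-seq peak sets in different cell types, largely because
chromatin accessibility gates which motif occurrences are usable.  `tfbind`
casts the prediction task as binary classification of 200-bp genomic windows
(shifted by 50 bp) into *overlapping a ChIP peak* vs not, for a target cell
type in which only accessibility data are available.  Labels for training
come from cell types that do have ChIP-seq: a window is **B** (bound) when it
overlaps a conservative (IDR-thresholded) peak by ≥100 bp, **A** (ambiguous)
when it merely overlaps a relaxed peak by ≥1 bp, and **U** (unbound)
otherwise.  When a factor lacks conservative peaks, relaxed peaks drive the
bound rule too.  Ambiguous windows are excluded from training-time selection
and from every metric.

## Binning and features

All coordinates are 0-based half-open.  Chromosomes are tiled with 50-bp bins
(trailing partial bins dropped, which keeps bin↔coordinate arithmetic exact).
Per-bin features:

| group | features | family |
|---|---|---|
| fold_enrichment | min, max, mean, median of the per-base signal | Gaussian |
| long_range | mean of bin means over ±5 and ±25 bins (clipped at ends) | Gaussian |
| peak | overlap indicator, overlapped fraction, distance to nearest peak (bp), for conservative and relaxed accessibility peaks | Bernoulli / Gaussian |
| variation | population std and coefficient of variation (ε = 10⁻⁶) of the bin mean across cell types; omitted with <2 cell types | Gaussian |
| motif | per PWM: max log-probability in the bin and log of the average probability (stable log-sum-exp) | Gaussian |
| sequence | G/C fraction, CpG frequency (count/49), longest homopolymer run | Gaussian |

Distance features are capped at 10,000 bp so they stay bounded, which suits
Gaussian components.  Motif scanning slides the PWM over both strands at
base-pair resolution; the per-position score is the natural-log probability
of the m-mer, strands combined by the maximum before aggregation (the
aggregation-vs-strand order is a genuinely open choice; joint max is used
here).  PWM columns are floored by mixing with the uniform distribution
(floor 10⁻⁴), so all log scores are finite; non-ACGT bases score as the
column minimum.  Bins too close to the chromosome end to host any motif
start are imputed with the chromosome-wide minimum.  No quantile
normalization is applied across cell types.

The classifier input for candidate summit bin *i* concatenates all per-bin
features over W adjacent bins centered at *i*.  W is the median across cell
types of the per-cell-type median ChIP peak width, divided by 50 bp, rounded
(half up), incremented if even.  Rounding before vs after the medians is
unspecified upstream; rounding once, after the median-of-medians, is the
single consistent choice used here.  Bins referenced beyond chromosome ends
are clamped to the terminal bin (replication padding).

## Model and training

Each class c ∈ {B, U} is a product of independent exponential-family
components with natural parameters: Gaussian (η₁ = μ/σ², η₂ = −1/(2σ²) < 0),
Bernoulli (one logit), and optionally an order-3 homogeneous Markov model
over raw sequence (log-conditional tables; orders 0–2 cover the first three
positions).  The posterior is

P(B|x) = σ( (β_B − β_U) + log f_B(x) − log f_U(x) ).

Because every component is exponential-family, the log-density difference is
linear in the sufficient statistics T(x) (x and x² per Gaussian feature, x
per Bernoulli, k-mer counts for the Markov model).  Training therefore
maximizes the weighted conditional log-likelihood, plus a Gaussian prior, in
the *class-difference* parameterization: an L2-regularized weighted logistic
regression on T(x).  This objective is strictly concave, so the optimum is
unique — random restarts agree to machine precision — and the fit provably
coincides with an independently optimized logistic regression on the same
statistics.  The fitted difference is then split symmetrically into two
normalized class components (Gaussian: η₂ offsets chosen so both classes stay
proper densities; the log-partition terms are absorbed into β_B − β_U), which
leaves the posterior bit-identical.  Placing the prior on class differences
rather than on each class separately is this package's choice; it preserves
concavity, and the posterior — the only quantity the pipeline consumes — has
the same expressive class either way.

Numerical choices: sufficient statistics are z-scored with *weighted* moments
before optimization (so duplicating an example is exactly equivalent to
doubling its weight), and the prior (scale 1.0 by default, configurable)
applies to the standardized-scale coefficients with the bias unpenalized.
The optimizer is L-BFGS with gradient tolerance 10⁻⁶ on the weight-normalized
objective and at most 500 iterations; non-convergence raises an error with
diagnostics.  When the optional sequence component is present, its per-class
table logits are optimized jointly (smooth but no longer concave; the
default pipeline does not use it, matching single-cell-type operation where
only accessibility and motif features are kept).

## Negative sampling

Positives are the windows centered at the bin holding each conservative peak
summit, weight 1.  Negatives, all stratified by chromosome and sampled
without replacement, with center bins never overlapping a relaxed peak:

1. **Uniform** — 10× the chromosome's positive count, weight 1.
2. **Accessibility-matched** — 10× positives drawn from decile strata of the
   eligible bins' median accessibility so the draw distribution matches the
   positives'; each draw from stratum g is down-weighted by
   (N_g/N_neg)/(n_g/n_total), the importance weight that makes the weighted
   sample represent the eligible-negative population (weights reduce to 1
   when the draw distribution equals the population's).  The decile
   construction and the bin-median matching statistic are this package's
   instantiation of an under-specified upstream scheme.  Empty strata hand
   their draws to the nearest non-empty stratum with a warning.
3. **Cross-cell-type** — 4× positives from bins covered by another training
   cell type's conservative peaks but no relaxed peak of the current one;
   uniform weights summing to (eligible bins / all putative-negative bins) ×
   the total weight of schemas 1–2 on that chromosome.  The normalization
   anchor ("rate among all putative negatives" relative to counts or to
   weights) is ambiguous upstream; anchoring to the schema-1–2 weight total
   is the choice here.  Skipped in single-cell-type operation.

## Iterative training and prediction

Five rounds per training cell type.  After round r, all labeled windows on
the selection chromosomes are scored with the average of rounds 1…r window
probabilities; τ is the ⌈0.01·n_B⌉-th smallest bound-window score (an
interpolation-free order statistic), and every unbound window with score
strictly > τ is added as a negative with weight 1.  A window enters the
negative set at most once across rounds (repeat selection does not
accumulate weight); its training example is centered at the bin containing
the window midpoint.  On toy genomes the selection chromosomes default to
all training chromosomes (restricting them is purely a large-genome
economy).

Window probability: S_i = 1 − Π_{ℓ∈C_i}(1 − P_ℓ) with
C_i = {ℓ : the W-bin peak centered at ℓ overlaps the window's 4 bins by ≥2
bins} = [i−h+1, i+h+2], h=(W−1)/2.  Out-of-range bins contribute P = 0; for
the degenerate W = 1 the set is empty and S ≡ 0.  Ensembling is the
arithmetic mean of S per window across the 5·K classifiers.  Peak calling
joins runs with S > t, records the run maximum p, trims flank windows with
S < 0.8·p from the outside in (never removing the maximal window; trimming
only shrinks runs, never splits them), places the summit at the center of
the maximal window (leftmost on ties), and writes score
round(−100·log₁₀(1−p)) with p capped at 1−10⁻⁸ (score ≤ 800, clamped to the
narrowPeak range [0, 1000]) and signalValue = p.

## Evaluation

AUC-PR uses continuous (non-linear) interpolation between operating points:
TP varies linearly between adjacent distinct-score points and FP linearly in
TP, giving precision t/((1+s)t+c) whose integral has a closed form; tied
scores form one operating point and the curve starts at recall 0 with the
top block's precision.  A fine-grid numeric integration of the same
interpolation serves as the test oracle, and the step-wise average-precision
estimate agrees within O(1/n) on large random data.  AUC-ROC is trapezoidal;
recall at FDR f is the maximal recall over thresholds with precision ≥ 1−f
(0 if unattainable).  Peak-list similarity is base-pair Jaccard over merged
intervals (0 for two empty sets).

## Synthetic data

The generator emulates the input bundle at desk scale: 3 × 200-kb
chromosomes of i.i.d. background sequence (GC 0.41), two cell types with 60
true sites each (half shared), a 12-bp consensus-derived PWM (match
probability 0.85) whose instances are embedded at true sites with 5%
per-base mutation and random strand, 60 decoy open regions (accessible,
motif-free, unbound, shared across cell types), conservative ChIP peaks
±150 bp and relaxed ±200 bp around each site summit, and accessibility
tracks built from Gaussian bumps (height ≈ 8-fold, ±40% per site) over
half-normal noise, smoothed with a 150-bp moving average as the real
fold-enrichment tracks are.  Everything is deterministic given the seed,
down to the written bytes.

What the fixture does *not* emulate: read-level noise, fragment-size
artifacts, copy-number and mappability biases, correlated background
(nucleosome positioning, CpG islands), motif clustering in enhancers, and
indirect/tethered binding.  Under the default conditions both accessibility
and motif evidence mark every true site, so the task is strongly separable
and the held-out ranking metrics saturate near 1.0; passing tests therefore
demonstrates mechanical correctness of the pipeline, not expected
performance on real genomes, where reported AUC-PR is far lower.  Harder
variants exercise the failure modes: restricting features to accessibility
only makes the decoys genuine hard negatives (the iterative rounds then add
hundreds of them), and the motif-free variant removes sequence evidence
entirely.

## Scale of the shipped experiments

Tests and the acceptance script run the full pipeline on the default 600-kb,
two-cell-type fixture (about 12,000 bins and 4,000 windows per chromosome,
roughly 1,000 training windows per cell type), chosen so a complete run
takes seconds on one CPU while every code path — all three sampling schemas,
five iterative rounds, 5·K ensembling, both peak-calling thresholds — is
exercised end to end.

## Known limitations

* Only PWM motif models are implemented; the motif interface (log-probability
  of an m-mer) admits dependency-aware models but none ship.
* RNA-seq-, annotation- and DNA-shape-based features are out of scope, as is
  de novo motif discovery; motifs must be supplied (or simulated).
* The accessibility-matched sampler's decile scheme is one reasonable
  instantiation; other matching statistics may behave differently on real
  data.
* bigWig input is optional (pyBigWig); the canonical text format is bedGraph,
  which is impractical at full-genome scale.
* Peak trimming never splits a run; a run containing two well-separated
  summits yields one peak.
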
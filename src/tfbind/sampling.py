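"""Initial training-set construction: positives at peak summits plus three
negative-sampling schemas, all stratified by chromosome.

Positives are the windows centered at the bin containing each conservative
ChIP-seq peak summit (weight 1).  Negatives come from

1. uniform sampling — per chromosome, 10x as many center bins as there are
   positives on it, uniform over bins not covered by a relaxed peak;
2. accessibility-matched sampling — negatives over-sampled so that their
   DNase bin-median distribution matches the positives', then importance
   down-weighted back to the eligible-negative population (decile strata);
3. cross-cell-type sampling — 4x as many center bins from regions that are
   ChIP-positive in another training cell type but relaxed-peak-free in the
   current one, with a total weight matching the rate of such regions among
   all putative negatives (skipped when only one cell type is available).

No sampled negative center bin ever overlaps a relaxed peak of the target
cell type, and all draws are without replacement within a chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .binning import BinIndex
from .io_formats import CoverageTrack, PeakRecord

logger = logging.getLogger(__name__)

UNIFORM_FACTOR = 10  # negatives per positive, schema 1
MATCHED_FACTOR = 10  # negatives per positive, schema 2 (count not fixed upstream)
CROSS_FACTOR = 4  # negatives per positive, schema 3
N_STRATA = 10  # decile strata for accessibility matching


@dataclass
class TrainingSet:
    """Weighted training windows identified by (chrom, center bin)."""

    centers: list[tuple[str, int]] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)  # 'B' or 'U'
    weights: list[float] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def add(self, chrom: str, bin_i: int, label: str, weight: float, source: str) -> None:
        if weight <= 0:
            raise ValueError("example weights must be positive")
        self.centers.append((chrom, bin_i))
        self.labels.append(label)
        self.weights.append(weight)
        self.provenance.append(source)

    def extend(self, other: "TrainingSet") -> None:
        self.centers.extend(other.centers)
        self.labels.extend(other.labels)
        self.weights.extend(other.weights)
        self.provenance.extend(other.provenance)

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)

    def negative_center_set(self) -> set[tuple[str, int]]:
        return {c for c, l in zip(self.centers, self.labels) if l == "U"}


def covered_bins_mask(bins: BinIndex, peaks: list[PeakRecord], chrom: str) -> np.ndarray:
    """Boolean mask over bins of ``chrom``: True if the bin overlaps any peak."""
    n = bins.n_bins(chrom)
    w = bins.bin_width
    mask = np.zeros(n, dtype=bool)
    for p in peaks:
        if p.chrom != chrom:
            continue
        lo = max(0, p.start // w)
        hi = min(n, -(-p.end // w))  # ceil division: bins overlapping [start, end)
        mask[lo:hi] = True
    return mask


def positives_from_peaks(
    bins: BinIndex, conservative: list[PeakRecord]
) -> TrainingSet:
    """One positive window per conservative peak, centered at the summit bin."""
    ts = TrainingSet()
    for p in conservative:
        if p.chrom not in bins.sizes:
            continue
        i = p.summit_pos // bins.bin_width
        if 0 <= i < bins.n_bins(p.chrom):
            ts.add(p.chrom, i, "B", 1.0, "positive")
    return ts


def _positives_per_chrom(positives: TrainingSet) -> dict[str, int]:
    counts: dict[str, int] = {}
    for chrom, _ in positives.centers:
        counts[chrom] = counts.get(chrom, 0) + 1
    return counts


def sample_uniform(
    bins: BinIndex,
    relaxed_peaks: list[PeakRecord],
    positives: TrainingSet,
    rng: np.random.Generator,
    factor: int = UNIFORM_FACTOR,
    chroms: list[str] | None = None,
) -> TrainingSet:
    """Schema 1: per chromosome, ``factor`` x positives uniform negatives."""
    ts = TrainingSet()
    pos_counts = _positives_per_chrom(positives)
    for chrom in chroms or bins.chroms:
        n_pos = pos_counts.get(chrom, 0)
        want = factor * n_pos
        if want == 0:
            continue
        eligible = np.flatnonzero(~covered_bins_mask(bins, relaxed_peaks, chrom))
        if len(eligible) < want:
            logger.warning(
                "%s: only %d eligible bins for %d uniform negatives", chrom, len(eligible), want
            )
            want = len(eligible)
        for i in rng.choice(eligible, size=want, replace=False):
            ts.add(chrom, int(i), "U", 1.0, "uniform")
    return ts


def bin_median_coverage(bins: BinIndex, coverage: CoverageTrack, chrom: str) -> np.ndarray:
    n = bins.n_bins(chrom)
    w = bins.bin_width
    return np.median(coverage[chrom][: n * w].reshape(n, w), axis=1)


def sample_dnase_matched(
    bins: BinIndex,
    relaxed_peaks: list[PeakRecord],
    positives: TrainingSet,
    coverage: CoverageTrack,
    rng: np.random.Generator,
    factor: int = MATCHED_FACTOR,
    chroms: list[str] | None = None,
    n_strata: int = N_STRATA,
) -> TrainingSet:
    """Schema 2: negatives drawn to match the positives' DNase-median deciles.

    Strata are deciles of the eligible negatives' bin-median accessibility; the
    target draw distribution is the positives' distribution over those strata.
    A draw from stratum g receives the importance weight
    ``(N_g / N_neg) / (n_g / n_total)`` so the weighted sample represents the
    eligible-negative population.  Strata without eligible bins hand their
    draws to the nearest non-empty stratum.
    """
    ts = TrainingSet()
    pos_counts = _positives_per_chrom(positives)
    pos_by_chrom: dict[str, list[int]] = {}
    for chrom, i in positives.centers:
        pos_by_chrom.setdefault(chrom, []).append(i)
    for chrom in chroms or bins.chroms:
        n_pos = pos_counts.get(chrom, 0)
        n_draws = factor * n_pos
        if n_draws == 0:
            continue
        medians = bin_median_coverage(bins, coverage, chrom)
        eligible = np.flatnonzero(~covered_bins_mask(bins, relaxed_peaks, chrom))
        if len(eligible) == 0:
            logger.warning("%s: no eligible bins for matched negatives", chrom)
            continue
        med_neg = medians[eligible]
        # decile boundaries over the eligible-negative population
        edges = np.quantile(med_neg, np.linspace(0, 1, n_strata + 1)[1:-1])
        strata_neg = np.searchsorted(edges, med_neg, side="right")
        med_pos = medians[np.asarray(pos_by_chrom[chrom])]
        strata_pos = np.searchsorted(edges, med_pos, side="right")
        pop_frac = np.bincount(strata_neg, minlength=n_strata) / len(eligible)
        target_frac = np.bincount(strata_pos, minlength=n_strata) / len(strata_pos)
        draws = np.floor(target_frac * n_draws).astype(int)
        # distribute the remainder to the largest fractional parts
        rem = n_draws - draws.sum()
        if rem > 0:
            frac = target_frac * n_draws - draws
            draws[np.argsort(-frac)[:rem]] += 1
        nonempty = np.flatnonzero(pop_frac > 0)
        for g in range(n_strata):
            if draws[g] == 0:
                continue
            g_use = g
            if pop_frac[g] == 0:
                g_use = int(nonempty[np.argmin(np.abs(nonempty - g))])
                logger.warning("%s: stratum %d empty; drawing from stratum %d", chrom, g, g_use)
                draws[g_use] += draws[g]
                continue
        for g in range(n_strata):
            n_g = int(draws[g])
            if n_g == 0 or pop_frac[g] == 0:
                continue
            pool = eligible[strata_neg == g]
            if len(pool) < n_g:
                logger.warning("%s: stratum %d has %d bins < %d draws", chrom, g, len(pool), n_g)
                n_g = len(pool)
            weight = float(pop_frac[g] / (draws[g] / n_draws))
            for i in rng.choice(pool, size=n_g, replace=False):
                ts.add(chrom, int(i), "U", weight, "dnase-matched")
    return ts


def sample_cross_celltype(
    bins: BinIndex,
    other_conservative: dict[str, list[PeakRecord]],
    current_relaxed: list[PeakRecord],
    positives: TrainingSet,
    rng: np.random.Generator,
    base_weight_total: float,
    factor: int = CROSS_FACTOR,
    chroms: list[str] | None = None,
) -> TrainingSet:
    """Schema 3: negatives from bins ChIP-positive in another cell type.

    ``other_conservative`` maps the other training cell types to their
    conservative ChIP peaks.  Per chromosome, ``factor`` x positives bins are
    drawn uniformly from bins covered by some other cell type's peak but not
    by a relaxed peak of the current one; their uniform weights sum to
    (eligible bins / all putative-negative bins) x ``base_weight_total``,
    the total weight of the schema 1-2 negatives on that chromosome.
    Returns an empty set when no other cell type is given.
    """
    ts = TrainingSet()
    if not other_conservative:
        return ts
    pos_counts = _positives_per_chrom(positives)
    for chrom in chroms or bins.chroms:
        n_pos = pos_counts.get(chrom, 0)
        want = factor * n_pos
        if want == 0:
            continue
        relaxed_mask = covered_bins_mask(bins, current_relaxed, chrom)
        other_mask = np.zeros(bins.n_bins(chrom), dtype=bool)
        for peaks in other_conservative.values():
            other_mask |= covered_bins_mask(bins, peaks, chrom)
        eligible = np.flatnonzero(other_mask & ~relaxed_mask)
        n_putative = int((~relaxed_mask).sum())
        if len(eligible) == 0 or n_putative == 0:
            logger.warning("%s: no eligible cross-cell-type negatives", chrom)
            continue
        if len(eligible) < want:
            logger.warning(
                "%s: only %d eligible cross-cell-type bins for %d draws",
                chrom, len(eligible), want,
            )
            want = len(eligible)
        rate = len(eligible) / n_putative
        weight = rate * base_weight_total / want
        for i in rng.choice(eligible, size=want, replace=False):
            ts.add(chrom, int(i), "U", weight, "cross-celltype")
    return ts


def build_initial_training_set(
    bins: BinIndex,
    chip_conservative: list[PeakRecord],
    chip_relaxed: list[PeakRecord],
    coverage: CoverageTrack,
    rng: np.random.Generator,
    other_conservative: dict[str, list[PeakRecord]] | None = None,
    chroms: list[str] | None = None,
) -> TrainingSet:
    """All positives plus the three negative-sampling schemas.

    When no conservative peaks exist, relaxed peaks supply the positives.
    ``chroms`` restricts sampling (and positives) to the training chromosomes.
    """
    pos_source = chip_conservative if chip_conservative else chip_relaxed
    positives = positives_from_peaks(bins, pos_source)
    if chroms is not None:
        keep = [k for k, (c, _) in enumerate(positives.centers) if c in chroms]
        filtered = TrainingSet()
        for k in keep:
            filtered.add(*positives.centers[k], "B", 1.0, "positive")
        positives = filtered
    ts = TrainingSet()
    ts.extend(positives)
    uni = sample_uniform(bins, chip_relaxed, positives, rng, chroms=chroms)
    matched = sample_dnase_matched(bins, chip_relaxed, positives, coverage, rng, chroms=chroms)
    ts.extend(uni)
    ts.extend(matched)
    if other_conservative:
        base_total = float(uni.weight_array.sum() + matched.weight_array.sum())
        cross = sample_cross_celltype(
            bins, other_conservative, chip_relaxed, positives, rng,
            base_weight_total=base_total, chroms=chroms,
        )
        ts.extend(cross)
    return ts


def write_training_set(ts: TrainingSet, bins: BinIndex, path) -> None:
    """Audit dump: gzip-able TSV of window coordinates, label, weight, provenance."""
    import gzip as _gzip

    opener = _gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for (chrom, i), label, weight, src in zip(
            ts.centers, ts.labels, ts.weights, ts.provenance
        ):
            start, end = bins.bin_interval(i)
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\t{weight!r}\t{src}\n")
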
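"""Per-bin chromatin-accessibility features.

Four feature groups are computed from DNase-seq (or ATAC-seq) fold-enrichment
coverage and the associated accessibility peak lists:

* ``fold_enrichment``: min / max / mean / median of the per-base signal in
  each bin;
* ``long_range``: the bin-mean signal averaged over broader windows of
  +-r bins around each bin (clipped at chromosome ends);
* ``peak``: overlap indicator, overlapped fraction of the bin, and distance
  (bp, capped) to the nearest accessibility peak, for the conservative and
  relaxed peak flavors;
* ``variation``: population standard deviation and coefficient of variation
  of the per-bin mean signal across cell types (only defined for >= 2 cell
  types; single-cell-type runs omit the group).
"""

from __future__ import annotations

import numpy as np

from .binning import BinIndex
from .io_formats import CoverageTrack, PeakRecord

DISTANCE_CAP = 10_000  # bp; bounds the distance-to-peak features
CV_EPS = 1e-6

LONG_RANGE_RADII = (5, 25)  # bins: 250 bp and 1.25 kb half-windows


def bin_stats(track: CoverageTrack, bins: BinIndex) -> dict[str, dict[str, np.ndarray]]:
    """Aggregate per-base coverage into per-bin min, max, mean and median."""
    out: dict[str, dict[str, np.ndarray]] = {}
    w = bins.bin_width
    for chrom in bins.chroms:
        n = bins.n_bins(chrom)
        values = track[chrom][: n * w].reshape(n, w)
        out[chrom] = {
            "min": values.min(axis=1),
            "max": values.max(axis=1),
            "mean": values.mean(axis=1),
            "median": np.median(values, axis=1),
        }
    return out


def long_range_stats(
    track: CoverageTrack, bins: BinIndex, radii: tuple[int, ...] = LONG_RANGE_RADII
) -> dict[str, dict[str, np.ndarray]]:
    """Mean fold-enrichment over +-r-bin windows centered at each bin.

    The value at bin i is the mean of the per-bin means over bins
    ``[i-r, i+r]`` intersected with the chromosome.
    """
    if any(r < 1 for r in radii):
        raise ValueError("radii must be >= 1")
    out: dict[str, dict[str, np.ndarray]] = {}
    w = bins.bin_width
    for chrom in bins.chroms:
        n = bins.n_bins(chrom)
        means = track[chrom][: n * w].reshape(n, w).mean(axis=1)
        csum = np.concatenate(([0.0], np.cumsum(means)))
        feats: dict[str, np.ndarray] = {}
        idx = np.arange(n)
        for r in radii:
            lo = np.maximum(idx - r, 0)
            hi = np.minimum(idx + r, n - 1) + 1
            feats[f"mean_r{r}"] = (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)
        out[chrom] = feats
    return out


def _merge_intervals(peaks: list[PeakRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not peaks:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ivs = sorted((p.start, p.end) for p in peaks)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _covered_cumulative(starts: np.ndarray, ends: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Total covered bp in [0, x) under the merged intervals, vectorized in x."""
    # cumulative covered length up to each interval start/end
    lengths = ends - starts
    cum = np.concatenate(([0], np.cumsum(lengths)))
    # for position x: intervals fully before it + partial of the one containing it
    k = np.searchsorted(starts, x, side="right")  # intervals with start < x
    full = cum[np.maximum(k - 1, 0)]
    partial = np.where(
        k > 0, np.minimum(x, ends[np.maximum(k - 1, 0)]) - starts[np.maximum(k - 1, 0)], 0
    )
    partial = np.maximum(partial, 0)
    return np.where(k > 0, full + partial, 0)


def peak_features(
    bins: BinIndex,
    conservative: list[PeakRecord],
    relaxed: list[PeakRecord],
    distance_cap: int = DISTANCE_CAP,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-bin peak overlap indicator, overlapped fraction, and distance to peak.

    Distance is 0 inside a peak and capped at ``distance_cap`` (also the value
    on chromosomes with no peak at all).
    """
    flavors = {"cons": conservative, "relax": relaxed}
    out: dict[str, dict[str, np.ndarray]] = {c: {} for c in bins.chroms}
    w = bins.bin_width
    for flavor, peaks in flavors.items():
        by_chrom: dict[str, list[PeakRecord]] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append(p)
        for chrom in bins.chroms:
            n = bins.n_bins(chrom)
            starts, ends = _merge_intervals(by_chrom.get(chrom, []))
            a = np.arange(n, dtype=np.int64) * w
            b = a + w
            if len(starts) == 0:
                frac = np.zeros(n)
                dist = np.full(n, float(distance_cap))
            else:
                ov = _covered_cumulative(starts, ends, b) - _covered_cumulative(
                    starts, ends, a
                )
                frac = ov / w
                # distance: 0 if overlap; else gap to nearest interval
                k = np.searchsorted(starts, b, side="left")  # first interval at/after bin end
                d_next = np.where(k < len(starts), starts[np.minimum(k, len(starts) - 1)] - b, distance_cap)
                j = np.searchsorted(ends, a, side="right") - 1  # last interval ending <= a
                # nearest preceding end: need max end among intervals before; merged => ends sorted
                prev_end = np.where(j >= 0, ends[np.maximum(j, 0)], -distance_cap * 2)
                d_prev = a - prev_end
                dist = np.where(ov > 0, 0, np.minimum(d_next, d_prev))
                dist = np.minimum(np.maximum(dist, 0), distance_cap).astype(np.float64)
            out[chrom][f"{flavor}_indicator"] = (frac > 0).astype(np.float64)
            out[chrom][f"{flavor}_fraction"] = frac.astype(np.float64)
            out[chrom][f"{flavor}_distance"] = dist
    return out


def variation_features(
    tracks: dict[str, CoverageTrack], bins: BinIndex
) -> dict[str, dict[str, np.ndarray]] | None:
    """Cross-cell-type variability of the per-bin mean signal.

    Returns population standard deviation and coefficient of variation
    (std / (mean + eps)) per bin, or ``None`` when fewer than two cell types
    are supplied.
    """
    if len(tracks) < 2:
        return None
    out: dict[str, dict[str, np.ndarray]] = {}
    w = bins.bin_width
    for chrom in bins.chroms:
        n = bins.n_bins(chrom)
        means = np.stack(
            [t[chrom][: n * w].reshape(n, w).mean(axis=1) for t in tracks.values()]
        )
        std = means.std(axis=0)  # population convention
        cv = std / (means.mean(axis=0) + CV_EPS)
        out[chrom] = {"std": std, "cv": cv}
    return out
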
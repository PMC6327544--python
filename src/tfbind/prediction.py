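"""From per-bin summit posteriors to window probabilities and narrowPeak calls.

The classifier yields, per 50-bp bin ``i``, the posterior ``P_i`` that the bin
contains a peak summit.  For a 200-bp window starting at bin ``i`` the
probability ``S_i`` that the window overlaps a predicted peak by at least
100 bp is the complement of the product of the complementary posteriors of
all bins whose W-bin peak would achieve that overlap:

    S_i = 1 - prod_{l in C_i} (1 - P_l),
    C_i = { l : |[l-h, l+h] intersect [i, i+3]| >= 2 bins },  h = (W-1)/2,

which for W = 5 is exactly the center bins i-1 .. i+4.  Out-of-range bins
contribute P = 0.  Predictions from several classifiers (5 training rounds x
K cell types) are combined by averaging S per window.  Peak lists are derived
by joining threshold-exceeding window runs, trimming low ends, and writing
narrowPeak records with score = -100*log10(1-p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .binning import WINDOW_SIZE, WINDOW_STEP
from .io_formats import PeakRecord

WINDOW_BINS = WINDOW_SIZE // WINDOW_STEP  # 4 bins per 200-bp window
PROB_CAP = 1.0 - 1e-8  # keeps -100*log10(1-p) finite (max score 800)


@dataclass
class ProbabilityTrack:
    """Per-chromosome window scores S_i on the 50-bp grid (window start bins)."""

    scores: dict[str, np.ndarray]
    width_bins: int  # W, the odd number of bins a peak spans

    def __post_init__(self) -> None:
        for chrom, s in self.scores.items():
            if np.any((s < 0) | (s > 1)):
                raise ValueError(f"{chrom}: window probabilities outside [0, 1]")


def contributing_range(width_bins: int) -> tuple[int, int]:
    """Offsets (lo, hi) such that C_i = {i+lo, ..., i+hi}.

    A peak centered at bin l spans [l-h, l+h]; it overlaps the window's bins
    [i, i+3] by >= 2 bins iff i-h+1 <= l <= i+h+2 (empty for W = 1, where a
    single-bin peak can never achieve a 100-bp overlap).
    """
    if width_bins % 2 == 0 or width_bins < 1:
        raise ValueError(f"peak width in bins must be odd and >= 1, got {width_bins}")
    h = (width_bins - 1) // 2
    return (-h + 1, h + 2)


def window_probability(posteriors: np.ndarray, width_bins: int) -> np.ndarray:
    """S_i for every window start bin i on one chromosome.

    ``posteriors`` holds P per bin; the result has one entry per 200-bp window
    fully inside the binned region (n_bins - 3 windows).  Bins outside the
    chromosome contribute P = 0.
    """
    lo, hi = contributing_range(width_bins)
    p = np.asarray(posteriors, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("bin posteriors outside [0, 1]")
    n_windows = max(0, len(p) - (WINDOW_BINS - 1))
    if n_windows == 0:
        return np.empty(0)
    if hi < lo:  # degenerate W = 1: no peak can overlap by 100 bp
        return np.zeros(n_windows)
    span = hi - lo + 1
    # pad so window i reads bins i+lo .. i+hi; out-of-range bins are P=0
    pad_left = max(0, -lo)
    pad_right = max(0, (n_windows - 1) + hi - (len(p) - 1))
    padded = np.pad(1.0 - p, (pad_left, pad_right), constant_values=1.0)
    view = np.lib.stride_tricks.sliding_window_view(padded, span)
    start = lo + pad_left
    return 1.0 - view[start : start + n_windows].prod(axis=1)


def predict_window_scores(
    posteriors: dict[str, np.ndarray], width_bins: int
) -> ProbabilityTrack:
    return ProbabilityTrack(
        scores={c: window_probability(p, width_bins) for c, p in posteriors.items()},
        width_bins=width_bins,
    )


def ensemble_average(tracks: list[ProbabilityTrack]) -> ProbabilityTrack:
    """Arithmetic mean of window scores across classifiers (identical grids)."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if set(t.scores) != set(first.scores) or any(
            len(t.scores[c]) != len(first.scores[c]) for c in first.scores
        ):
            raise ValueError("window grids differ between tracks")
    return ProbabilityTrack(
        scores={
            c: np.mean([t.scores[c] for t in tracks], axis=0) for c in first.scores
        },
        width_bins=first.width_bins,
    )


def call_peaks(
    track: ProbabilityTrack, threshold: float, name_prefix: str = "peak"
) -> list[PeakRecord]:
    """Join window runs with S > threshold into narrowPeak records.

    Within each run the maximum probability p is recorded; bordering windows
    with S < 0.8*p are trimmed from both ends (the maximal window is never
    removed).  The summit sits at the center of the maximal window (leftmost
    on ties); score = round(-100*log10(1-p)) with p capped at 1 - 1e-8 and the
    score clamped to [0, 1000]; signalValue = p.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    peaks: list[PeakRecord] = []
    k = 0
    for chrom, s in track.scores.items():
        above = s > threshold
        if not above.any():
            continue
        run_start = None
        bounds = []
        for i, a in enumerate(above):
            if a and run_start is None:
                run_start = i
            elif not a and run_start is not None:
                bounds.append((run_start, i - 1))
                run_start = None
        if run_start is not None:
            bounds.append((run_start, len(above) - 1))
        for lo, hi in bounds:
            run = s[lo : hi + 1]
            p = float(run.max())
            imax = lo + int(np.argmax(run))
            a, b = lo, hi
            while a < imax and s[a] < 0.8 * p:
                a += 1
            while b > imax and s[b] < 0.8 * p:
                b -= 1
            start = a * WINDOW_STEP
            end = b * WINDOW_STEP + WINDOW_SIZE
            summit = imax * WINDOW_STEP + WINDOW_SIZE // 2 - start
            p_capped = min(p, PROB_CAP)
            score = int(min(1000, max(0, round(-100.0 * math.log10(1.0 - p_capped)))))
            k += 1
            peaks.append(
                PeakRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=f"{name_prefix}_{k}",
                    score=score,
                    strand=".",
                    signal_value=p,
                    p_value=-1.0,
                    q_value=-1.0,
                    summit=summit,
                )
            )
    return peaks


def write_score_track(track: ProbabilityTrack, path) -> None:
    """Window scores as bedGraph rows on the 50-bp window-start grid."""
    import gzip as _gzip

    opener = _gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for chrom, s in track.scores.items():
            for i, v in enumerate(s):
                fh.write(f"{chrom}\t{i * WINDOW_STEP}\t{i * WINDOW_STEP + WINDOW_SIZE}\t{float(v):.6g}\n")
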
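"""Genome binning, 200-bp window enumeration, and B/A/U label derivation.

The genome is tiled with non-overlapping fixed-width bins (50 bp by default);
a trailing partial bin is dropped.  Predictions and labels live on 200-bp
windows shifted by 50 bp.  A window is labeled B ("bound") when it overlaps a
conservative ChIP-seq peak by at least 100 bp, A ("ambiguous") when it merely
overlaps a relaxed peak by at least 1 bp, and U ("unbound") otherwise.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import ChromSizes, PeakRecord

WINDOW_SIZE = 200
WINDOW_STEP = 50
BOUND_OVERLAP = 100  # minimum overlap with a conservative peak for label B


@dataclass(frozen=True)
class BinIndex:
    """Partition of each chromosome into fixed-width, genome-tiling bins.

    Bin ``i`` of a chromosome covers ``[i*w, (i+1)*w)``; the trailing partial
    bin is dropped, so each chromosome has ``floor(length / w)`` bins.
    """

    sizes: dict[str, int] = field(default_factory=dict)
    bin_width: int = 50

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError(f"bin_width must be >= 1, got {self.bin_width}")

    def n_bins(self, chrom: str) -> int:
        return self.sizes[chrom] // self.bin_width

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    def bin_of(self, chrom: str, pos: int) -> int:
        """Bin index containing base ``pos`` (must fall in a complete bin)."""
        i = pos // self.bin_width
        if pos < 0 or i >= self.n_bins(chrom):
            raise IndexError(f"{chrom}:{pos} not in a complete bin")
        return i

    def bin_interval(self, i: int) -> tuple[int, int]:
        return i * self.bin_width, (i + 1) * self.bin_width


def bin_genome(sizes: ChromSizes, bin_width: int = 50) -> BinIndex:
    """Tile every chromosome with ``bin_width`` bins (trailing remainder dropped)."""
    return BinIndex(sizes=dict(sizes), bin_width=bin_width)


@dataclass(frozen=True)
class LabeledWindow:
    chrom: str
    start: int  # multiple of WINDOW_STEP
    label: str  # 'B', 'A' or 'U'

    @property
    def end(self) -> int:
        return self.start + WINDOW_SIZE


def enumerate_windows(sizes: ChromSizes) -> dict[str, np.ndarray]:
    """Start coordinates of the 200-bp windows shifted by 50 bp, per chromosome.

    Only windows fully inside the chromosome are enumerated.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, length in sizes.items():
        n = max(0, (length - WINDOW_SIZE) // WINDOW_STEP + 1)
        out[chrom] = np.arange(n, dtype=np.int64) * WINDOW_STEP
    return out


def _max_single_peak_overlap(
    starts: np.ndarray, ends: np.ndarray, win_starts: np.ndarray, win_size: int
) -> np.ndarray:
    """For each window, the largest overlap (bp) with any single interval."""
    best = np.zeros(len(win_starts), dtype=np.int64)
    if len(starts) == 0:
        return best
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    win_ends = win_starts + win_size
    # candidate intervals for window w: those with start < win_end and end > win_start.
    # peaks may overlap each other, so scan the candidate range per window; ranges
    # are short for realistic peak densities.
    lo = np.searchsorted(ends, win_starts, side="right")  # ends sorted? not guaranteed
    # ends are not necessarily sorted when peaks nest; fall back to cumulative max ends
    cummax_end = np.maximum.accumulate(ends)
    hi = np.searchsorted(starts, win_ends, side="left")
    for w in range(len(win_starts)):
        a, b = win_starts[w], win_ends[w]
        j = hi[w] - 1
        m = 0
        while j >= 0 and cummax_end[j] > a:
            ov = min(ends[j], b) - max(starts[j], a)
            if ov > m:
                m = ov
            j -= 1
        best[w] = m
    del lo
    return best


def derive_labels(
    windows: dict[str, np.ndarray],
    conservative: list[PeakRecord],
    relaxed: list[PeakRecord],
) -> list[LabeledWindow]:
    """Assign B/A/U labels to windows from conservative and relaxed peaks.

    B takes precedence over A.  When the conservative list is empty, the
    relaxed peaks also drive the bound rule (the upstream IDR pipeline yields
    no conservative peaks for some factors).
    """
    bound_source = conservative if conservative else relaxed
    out: list[LabeledWindow] = []
    by_chrom_b: dict[str, list[PeakRecord]] = {}
    by_chrom_r: dict[str, list[PeakRecord]] = {}
    for p in bound_source:
        by_chrom_b.setdefault(p.chrom, []).append(p)
    for p in relaxed:
        by_chrom_r.setdefault(p.chrom, []).append(p)
    for chrom, win_starts in windows.items():
        pb = by_chrom_b.get(chrom, [])
        pr = by_chrom_r.get(chrom, [])
        ov_b = _max_single_peak_overlap(
            np.array([p.start for p in pb], dtype=np.int64),
            np.array([p.end for p in pb], dtype=np.int64),
            win_starts,
            WINDOW_SIZE,
        )
        ov_r = _max_single_peak_overlap(
            np.array([p.start for p in pr], dtype=np.int64),
            np.array([p.end for p in pr], dtype=np.int64),
            win_starts,
            WINDOW_SIZE,
        )
        for s, b, r in zip(win_starts, ov_b, ov_r):
            if b >= BOUND_OVERLAP:
                label = "B"
            elif r >= 1:
                label = "A"
            else:
                label = "U"
            out.append(LabeledWindow(chrom, int(s), label))
    return out


def peak_width_bins(
    peak_lists: list[list[PeakRecord]], bin_width: int = 50
) -> int:
    """Typical peak width of a TF, in bins, forced odd.

    Computed as the median across cell types of the per-cell-type median peak
    width, divided by the bin width, rounded, then incremented if even.  This
    is the number W of adjacent bins the classifier sees.
    """
    medians = [
        float(np.median([p.width for p in peaks])) for peaks in peak_lists if peaks
    ]
    if not medians:
        raise ValueError("all peak lists are empty; cannot derive a peak width")
    med = float(np.median(medians))
    w = int(np.floor(med / bin_width + 0.5))  # round half up
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def write_labels(labels: list[LabeledWindow], path: str | Path) -> None:
    """Write labels as gzip-able TSV: chrom, window start, label."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for lw in labels:
            fh.write(f"{lw.chrom}\t{lw.start}\t{lw.label}\n")


def read_labels(path: str | Path) -> list[LabeledWindow]:
    opener = gzip.open if str(path).endswith(".gz") else open
    out: list[LabeledWindow] = []
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 or fields[2] not in "BAU":
                raise ValueError(f"{path}:{ln}: malformed label row")
            out.append(LabeledWindow(fields[0], int(fields[1]), fields[2]))
    return out
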
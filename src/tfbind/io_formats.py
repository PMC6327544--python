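"""Readers and writers for the text formats used throughout the package.

All coordinates are 0-based, half-open (BED convention) everywhere in the
package; any 1-based source would be converted at this boundary.  Supported
formats: ENCODE narrowPeak (10 columns), bedGraph coverage, FASTA, a two-column
chromosome-size TSV, and gzip-compressed variants of each (detected by the
``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: chromosome name -> length in bp
ChromSizes = dict[str, int]

#: chromosome name -> per-base float array (length == chromosome length)
CoverageTrack = dict[str, np.ndarray]


@dataclass
class PeakRecord:
    """One ENCODE narrowPeak record (BED6+4), 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    signal_value: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    summit: int = -1  # offset from start, or -1 if unknown

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.summit != -1 and not 0 <= self.summit < self.end - self.start:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit offset "
                f"{self.summit} outside peak"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def summit_pos(self) -> int:
        """Absolute summit coordinate; peak midpoint when summit is -1."""
        if self.summit == -1:
            return self.start + self.width // 2
        return self.start + self.summit


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column TSV of chromosome name and length."""
    sizes: ChromSizes = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns, got {len(fields)}")
            chrom, length = fields[0], int(fields[1])
            if chrom in sizes:
                raise ValueError(f"{path}:{ln}: duplicate chromosome {chrom!r}")
            if length <= 0:
                raise ValueError(f"{path}:{ln}: non-positive length for {chrom!r}")
            sizes[chrom] = length
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_narrowpeak(path: str | Path) -> list[PeakRecord]:
    """Read an ENCODE narrowPeak file (10 tab-separated columns).

    Records are returned in file order with coordinates preserved exactly.
    Malformed lines raise :class:`ValueError` naming the line number.
    """
    peaks: list[PeakRecord] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(
                    f"{path}:{ln}: narrowPeak needs >=10 columns, got {len(fields)}"
                )
            try:
                peaks.append(
                    PeakRecord(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3],
                        score=int(fields[4]),
                        strand=fields[5],
                        signal_value=float(fields[6]),
                        p_value=float(fields[7]),
                        q_value=float(fields[8]),
                        summit=int(fields[9]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return peaks


def write_narrowpeak(peaks: list[PeakRecord], path: str | Path) -> None:
    """Write peaks as narrowPeak; ``read_narrowpeak`` round-trips exactly."""
    with _open_text(path, "wt") as fh:
        for p in peaks:
            fh.write(
                # repr keeps the shortest decimal that round-trips a float64
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score}\t{p.strand}\t"
                f"{float(p.signal_value)!r}\t{float(p.p_value)!r}\t"
                f"{float(p.q_value)!r}\t{p.summit}\n"
            )


def read_coverage(path: str | Path, sizes: ChromSizes) -> CoverageTrack:
    """Read a bedGraph into dense per-base arrays.

    Bases not covered by any interval are 0.  Overlapping intervals are
    resolved last-written-wins, with a logged warning.
    """
    track: CoverageTrack = {c: np.zeros(n, dtype=np.float64) for c, n in sizes.items()}
    seen_overlap = False
    covered = {c: np.zeros(n, dtype=bool) for c, n in sizes.items()}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{ln}: bedGraph needs 4 columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if chrom not in sizes:
                raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if value < 0:
                raise ValueError(f"{path}:{ln}: negative coverage value {value}")
            if start < 0 or end > sizes[chrom] or start >= end:
                raise ValueError(
                    f"{path}:{ln}: interval [{start},{end}) outside "
                    f"{chrom} (length {sizes[chrom]}) or empty"
                )
            if not seen_overlap and covered[chrom][start:end].any():
                logger.warning("%s:%d: overlapping bedGraph intervals; last wins", path, ln)
                seen_overlap = True
            covered[chrom][start:end] = True
            track[chrom][start:end] = value
    return track


def write_coverage(track: CoverageTrack, path: str | Path, precision: int = 6) -> None:
    """Write a dense track as bedGraph, merging equal-valued runs, omitting zeros."""
    with _open_text(path, "wt") as fh:
        for chrom, values in track.items():
            if len(values) == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{round(float(v), precision):g}\n")


def read_coverage_bigwig(path: str | Path, sizes: ChromSizes) -> CoverageTrack:
    """Read a bigWig file into the same dense representation (optional backend)."""
    import pyBigWig  # optional dependency

    track: CoverageTrack = {}
    with pyBigWig.open(str(path)) as bw:
        for chrom, n in sizes.items():
            vals = np.asarray(bw.values(chrom, 0, n), dtype=np.float64)
            vals[np.isnan(vals)] = 0.0
            if (vals < 0).any():
                raise ValueError(f"{path}: negative coverage on {chrom}")
            track[chrom] = vals
    return track


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into uppercase sequences keyed by record id.

    Any base outside A/C/G/T is mapped to N.
    """
    table = str.maketrans(
        {c: "N" for c in "BDEFHIJKLMOPQRSUVWXYZ"}  # IUPAC ambiguity -> N
    )
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seqs[rec.id] = str(rec.seq).upper().translate(table)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_lines(path: str | Path) -> Iterator[str]:
    with _open_text(path) as fh:
        yield from fh
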
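"""Assembly of per-bin feature tables and W-bin classifier input windows.

A :class:`BinFeatureTable` holds, per chromosome, a bins x features matrix of
named, typed (gaussian/bernoulli) per-bin features from the accessibility and
motif modules.  The classifier input for a candidate summit bin ``i`` is the
concatenation of all per-bin features over the W adjacent bins centered at
``i`` (W odd); bins referenced beyond the chromosome ends are clamped to the
first/last bin.  Tables can be stored as a sparse, gzip-compressed TSV that
omits zero values.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import dnase, motifs
from .binning import BinIndex
from .io_formats import CoverageTrack, PeakRecord
from .model import BERNOULLI, GAUSSIAN


@dataclass
class BinFeatureTable:
    """Named per-bin features for every chromosome of a bin index."""

    bins: BinIndex
    names: list[str]
    families: list[str]  # per feature: 'gaussian' or 'bernoulli'
    data: dict[str, np.ndarray]  # chrom -> (n_bins, n_features)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.families):
            raise ValueError("names/families length mismatch")
        for chrom, arr in self.data.items():
            if arr.shape != (self.bins.n_bins(chrom), len(self.names)):
                raise ValueError(f"{chrom}: feature matrix shape {arr.shape} invalid")
            if not np.isfinite(arr).all():
                raise ValueError(f"{chrom}: non-finite feature values")

    @property
    def n_features(self) -> int:
        return len(self.names)

    def column(self, name: str) -> dict[str, np.ndarray]:
        j = self.names.index(name)
        return {c: a[:, j] for c, a in self.data.items()}


FEATURE_GROUPS = ("fold_enrichment", "long_range", "peak", "variation", "motif", "sequence")


def build_feature_table(
    bins: BinIndex,
    coverage: CoverageTrack,
    dnase_conservative: list[PeakRecord],
    dnase_relaxed: list[PeakRecord],
    pwms: list[motifs.PWM],
    genome: dict[str, str] | None = None,
    coverage_by_celltype: dict[str, CoverageTrack] | None = None,
    groups: tuple[str, ...] = FEATURE_GROUPS,
) -> BinFeatureTable:
    """Compute all enabled per-bin feature groups for one cell type.

    ``coverage_by_celltype`` (all cell types, including the current one)
    enables the cross-cell-type variation group; with fewer than two tracks
    the group is omitted.  ``genome`` enables motif and sequence features.
    """
    names: list[str] = []
    families: list[str] = []
    columns: dict[str, list[np.ndarray]] = {c: [] for c in bins.chroms}

    def add(name: str, family: str, per_chrom: dict[str, np.ndarray]) -> None:
        names.append(name)
        families.append(family)
        for c in bins.chroms:
            columns[c].append(np.asarray(per_chrom[c], dtype=np.float64))

    if "fold_enrichment" in groups:
        stats = dnase.bin_stats(coverage, bins)
        for stat in ("min", "max", "mean", "median"):
            add(f"dnase_{stat}", GAUSSIAN, {c: stats[c][stat] for c in bins.chroms})
    if "long_range" in groups:
        lr = dnase.long_range_stats(coverage, bins)
        for key in next(iter(lr.values())):
            add(f"dnase_{key}", GAUSSIAN, {c: lr[c][key] for c in bins.chroms})
    if "peak" in groups:
        pf = dnase.peak_features(bins, dnase_conservative, dnase_relaxed)
        for key in next(iter(pf.values())):
            fam = BERNOULLI if key.endswith("indicator") else GAUSSIAN
            add(f"dnase_peak_{key}", fam, {c: pf[c][key] for c in bins.chroms})
    if "variation" in groups and coverage_by_celltype:
        var = dnase.variation_features(coverage_by_celltype, bins)
        if var is not None:
            for key in ("std", "cv"):
                add(f"dnase_var_{key}", GAUSSIAN, {c: var[c][key] for c in bins.chroms})
    if "motif" in groups and genome is not None:
        for pwm in pwms:
            agg = {
                c: motifs.aggregate(motifs.scan(genome[c], pwm).combined(), bins, c)
                for c in bins.chroms
            }
            for key in ("max_log_prob", "log_mean_prob"):
                add(f"motif_{pwm.name}_{key}", GAUSSIAN, {c: agg[c][key] for c in bins.chroms})
    if "sequence" in groups and genome is not None:
        sf = {c: motifs.sequence_features(genome[c], bins, c) for c in bins.chroms}
        for key in ("gc", "cpg", "homopolymer_run"):
            add(f"seq_{key}", GAUSSIAN, {c: sf[c][key] for c in bins.chroms})

    data = {c: np.column_stack(cols) for c, cols in columns.items()}
    return BinFeatureTable(bins=bins, names=names, families=families, data=data)


def extract_windows(
    table: BinFeatureTable, centers: list[tuple[str, int]], width: int
) -> tuple[np.ndarray, list[str], list[str]]:
    """Feature vectors for W adjacent bins centered at each candidate bin.

    Returns ``(X, names, families)`` where ``X`` is (n_centers, W * n_features)
    and names carry a bin-offset suffix.  Out-of-range bins are clamped to the
    chromosome's first/last bin.
    """
    if width % 2 == 0 or width < 1:
        raise ValueError(f"window width in bins must be odd and >= 1, got {width}")
    h = (width - 1) // 2
    offsets = np.arange(-h, h + 1)
    n_feat = table.n_features
    X = np.empty((len(centers), width * n_feat), dtype=np.float64)
    for r, (chrom, i) in enumerate(centers):
        arr = table.data[chrom]
        idx = np.clip(i + offsets, 0, arr.shape[0] - 1)
        X[r] = arr[idx].ravel()
    names = [f"{nm}@{off:+d}" for off in offsets for nm in table.names]
    families = [fam for _ in offsets for fam in table.families]
    return X, names, families


def window_centers_for_chrom(table: BinFeatureTable, chrom: str) -> list[tuple[str, int]]:
    return [(chrom, i) for i in range(table.bins.n_bins(chrom))]


def predict_bin_posteriors(
    model, table: BinFeatureTable, width: int, chroms: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Per-bin posterior P_i that bin i holds a peak summit, for each chromosome."""
    out: dict[str, np.ndarray] = {}
    for chrom in chroms or table.bins.chroms:
        centers = window_centers_for_chrom(table, chrom)
        X, _, _ = extract_windows(table, centers, width)
        out[chrom] = model.posterior(X)
    return out


def write_feature_table(table: BinFeatureTable, path: str | Path) -> None:
    """Sparse gzip TSV: chrom, bin, then feature:value pairs omitting zeros."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("#names\t" + "\t".join(table.names) + "\n")
        fh.write("#families\t" + "\t".join(table.families) + "\n")
        fh.write("#bin_width\t" + str(table.bins.bin_width) + "\n")
        for chrom in table.bins.chroms:
            fh.write(f"#chrom\t{chrom}\t{table.bins.sizes[chrom]}\n")
            arr = table.data[chrom]
            for i in range(arr.shape[0]):
                nz = np.flatnonzero(arr[i])
                pairs = "\t".join(f"{j}:{float(arr[i, j])!r}" for j in nz)
                fh.write(f"{chrom}\t{i}\t{pairs}\n" if len(nz) else f"{chrom}\t{i}\n")


def read_feature_table(path: str | Path) -> BinFeatureTable:
    opener = gzip.open if str(path).endswith(".gz") else open
    names: list[str] = []
    families: list[str] = []
    sizes: dict[str, int] = {}
    rows: dict[str, list[tuple[int, list[str]]]] = {}
    bin_width = 50
    with opener(path, "rt") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#names":
                names = fields[1:]
            elif fields[0] == "#families":
                families = fields[1:]
            elif fields[0] == "#bin_width":
                bin_width = int(fields[1])
            elif fields[0] == "#chrom":
                sizes[fields[1]] = int(fields[2])
                rows[fields[1]] = []
            elif fields[0].startswith("#"):
                continue
            else:
                rows[fields[0]].append((int(fields[1]), fields[2:]))
    bins = BinIndex(sizes=sizes, bin_width=bin_width)
    data: dict[str, np.ndarray] = {}
    for chrom in sizes:
        arr = np.zeros((bins.n_bins(chrom), len(names)))
        for i, pairs in rows[chrom]:
            for pair in pairs:
                if pair:
                    j, v = pair.split(":")
                    arr[i, int(j)] = float(v)
        data[chrom] = arr
    return BinFeatureTable(bins=bins, names=names, families=families, data=data)
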
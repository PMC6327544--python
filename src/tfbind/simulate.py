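"""Synthetic toy datasets with known ground truth.

The generator emulates the input bundle of a cell type-specific TF binding
study: a random genome (FASTA), per-cell-type TF ChIP-seq peak lists in
conservative and relaxed flavors, and per-cell-type chromatin-accessibility
fold-enrichment tracks with matching accessibility peak lists.  True binding
sites carry an embedded motif instance and an accessibility bump; decoy open
regions carry a bump but no motif, so accessibility alone cannot separate
bound from unbound.  Conservative ChIP peaks span +-150 bp around a site
summit and relaxed peaks +-200 bp, so conservative peaks nest inside relaxed
ones as in the real data.  A configurable fraction of sites is shared across
cell types; the remainder are cell type-private.  Accessibility bumps are
smoothed with a 150-bp moving average, echoing the fold-enrichment tracks the
method consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_formats import (
    ChromSizes,
    CoverageTrack,
    PeakRecord,
    write_chrom_sizes,
    write_coverage,
    write_fasta,
    write_narrowpeak,
)
from .motifs import BASES, PWM

CONS_HALF = 150  # conservative ChIP peak half-width (bp)
RELAX_HALF = 200  # relaxed ChIP peak half-width (bp)
ACC_HALF = 200  # accessibility peak half-width (bp)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixture.

    Defaults describe a desk-scale genome (3 x 200 kb, two cell types) with a
    12-bp motif, 60 true sites per cell type of which half are shared, and as
    many motif-free decoy open regions as true sites per cell type.
    """

    n_chroms: int = 3
    chrom_length: int = 200_000
    n_cell_types: int = 2
    motif_consensus: str = "TGACGTCATAGC"
    motif_match_prob: float = 0.85
    mutation_rate: float = 0.05  # per-base rate when writing site instances
    n_sites: int = 60  # per cell type
    shared_fraction: float = 0.5
    n_decoys: int = 60  # per cell type, open but motif-free
    signal_height: float = 8.0  # accessibility bump height (fold enrichment)
    smooth_width: int = 150  # moving-average window (bp)
    background_noise: float = 0.3
    background_gc: float = 0.41
    embed_motif: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if min(self.n_chroms, self.chrom_length, self.n_cell_types) < 1:
            raise ValueError("counts must be positive")
        if self.n_sites < 0 or self.n_decoys < 0:
            raise ValueError("site counts must be >= 0")


@dataclass
class SimData:
    """Generated fixture plus ground truth."""

    config: SimConfig
    genome: dict[str, str]
    sizes: ChromSizes
    pwm: PWM
    chip_conservative: dict[str, list[PeakRecord]]  # cell type -> peaks
    chip_relaxed: dict[str, list[PeakRecord]]
    accessibility: dict[str, CoverageTrack]
    accessibility_peaks: dict[str, list[PeakRecord]]
    true_sites: dict[str, list[tuple[str, int]]]  # cell type -> (chrom, summit)
    decoy_sites: list[tuple[str, int]] = field(default_factory=list)

    @property
    def cell_types(self) -> list[str]:
        return list(self.chip_conservative)

    def write(self, outdir: str | Path) -> None:
        """Write the complete fixture bundle as plain-text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_chrom_sizes(self.sizes, outdir / "chrom.sizes")
        from .motifs import write_pwm_file

        write_pwm_file([self.pwm], outdir / "motif.txt")
        for ct in self.cell_types:
            write_narrowpeak(self.chip_conservative[ct], outdir / f"{ct}.chip.conservative.narrowPeak")
            write_narrowpeak(self.chip_relaxed[ct], outdir / f"{ct}.chip.relaxed.narrowPeak")
            write_narrowpeak(self.accessibility_peaks[ct], outdir / f"{ct}.dnase.narrowPeak")
            write_coverage(self.accessibility[ct], outdir / f"{ct}.dnase.bedGraph")
        with open(outdir / "true_sites.tsv", "w") as fh:
            for ct, sites in self.true_sites.items():
                for chrom, pos in sites:
                    fh.write(f"{ct}\t{chrom}\t{pos}\n")


def _random_genome(rng: np.random.Generator, config: SimConfig) -> dict[str, str]:
    p_gc = config.background_gc / 2.0
    p_at = (1.0 - config.background_gc) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A, C, G, T
    genome = {}
    for k in range(config.n_chroms):
        codes = rng.choice(4, size=config.chrom_length, p=probs)
        genome[f"chr{k + 1}"] = "".join(BASES[c] for c in codes)
    return genome


def _sample_positions(
    rng: np.random.Generator, config: SimConfig, n: int, taken: list[tuple[str, int]]
) -> list[tuple[str, int]]:
    """Site summits spread over chromosomes, kept off the edges and apart."""
    margin = 2 * RELAX_HALF + config.smooth_width
    min_sep = 1200
    capacity = config.n_chroms * max(0, (config.chrom_length - 2 * margin) // min_sep)
    if n > capacity:
        raise ValueError(f"cannot place {n} sites: capacity about {capacity}")
    out: list[tuple[str, int]] = []
    occupied = {c: [p for cc, p in taken if cc == c] for c in
                [f"chr{k + 1}" for k in range(config.n_chroms)]}
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError("site placement failed; chromosome too crowded")
        chrom = f"chr{rng.integers(1, config.n_chroms + 1)}"
        pos = int(rng.integers(margin, config.chrom_length - margin))
        if all(abs(pos - q) >= min_sep for q in occupied[chrom]):
            occupied[chrom].append(pos)
            out.append((chrom, pos))
    return out


def _embed_motif(
    genome: dict[str, str], rng: np.random.Generator, config: SimConfig,
    sites: list[tuple[str, int]],
) -> None:
    m = len(config.motif_consensus)
    for chrom, pos in sites:
        inst = list(config.motif_consensus)
        for i in range(m):
            if rng.random() < config.mutation_rate:
                inst[i] = BASES[rng.integers(4)]
        if rng.random() < 0.5:  # strand
            from .motifs import reverse_complement

            inst = list(reverse_complement("".join(inst)))
        start = pos - m // 2
        seq = genome[chrom]
        genome[chrom] = seq[:start] + "".join(inst) + seq[start + m :]


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def generate(config: SimConfig) -> SimData:
    """Generate the full fixture; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genome = _random_genome(rng, config)
    sizes: ChromSizes = {c: len(s) for c, s in genome.items()}
    pwm = PWM.from_consensus("SIM", config.motif_consensus, config.motif_match_prob)

    n_shared = int(round(config.shared_fraction * config.n_sites))
    shared = _sample_positions(rng, config, n_shared, [])
    taken = list(shared)
    sites_by_ct: dict[str, list[tuple[str, int]]] = {}
    for k in range(config.n_cell_types):
        ct = f"cell{k + 1}"
        private = _sample_positions(rng, config, config.n_sites - n_shared, taken)
        taken.extend(private)
        sites_by_ct[ct] = sorted(shared + private)
    decoys = _sample_positions(rng, config, config.n_decoys, taken)

    if config.embed_motif:
        all_sites = sorted({s for sites in sites_by_ct.values() for s in sites})
        _embed_motif(genome, rng, config, all_sites)

    chip_cons: dict[str, list[PeakRecord]] = {}
    chip_relax: dict[str, list[PeakRecord]] = {}
    acc: dict[str, CoverageTrack] = {}
    acc_peaks: dict[str, list[PeakRecord]] = {}
    for ct, sites in sites_by_ct.items():
        cons, relax = [], []
        for j, (chrom, pos) in enumerate(sites):
            cons.append(
                PeakRecord(chrom, pos - CONS_HALF, pos + CONS_HALF,
                           name=f"{ct}_cons_{j}", score=0, strand=".",
                           signal_value=config.signal_height, summit=CONS_HALF)
            )
            relax.append(
                PeakRecord(chrom, pos - RELAX_HALF, pos + RELAX_HALF,
                           name=f"{ct}_relax_{j}", score=0, strand=".",
                           signal_value=config.signal_height, summit=RELAX_HALF)
            )
        chip_cons[ct] = cons
        chip_relax[ct] = relax

        open_regions = sorted(sites + decoys)
        track: CoverageTrack = {}
        peaks: list[PeakRecord] = []
        for chrom, length in sizes.items():
            raw = np.abs(rng.normal(0.0, config.background_noise, size=length))
            for c2, pos in open_regions:
                if c2 != chrom:
                    continue
                height = config.signal_height * rng.uniform(0.6, 1.4)
                lo, hi = pos - ACC_HALF, pos + ACC_HALF
                x = np.arange(lo, hi)
                raw[lo:hi] += height * np.exp(-0.5 * ((x - pos) / (ACC_HALF / 2.5)) ** 2)
            smooth = _smooth(raw, config.smooth_width)
            track[chrom] = np.maximum(np.round(smooth, 4), 0.0)
        for j, (chrom, pos) in enumerate(open_regions):
            peaks.append(
                PeakRecord(chrom, pos - ACC_HALF, pos + ACC_HALF,
                           name=f"{ct}_open_{j}", score=0, strand=".",
                           signal_value=config.signal_height, summit=ACC_HALF)
            )
        acc[ct] = track
        acc_peaks[ct] = peaks

    return SimData(
        config=config,
        genome=genome,
        sizes=sizes,
        pwm=pwm,
        chip_conservative=chip_cons,
        chip_relaxed=chip_relax,
        accessibility=acc,
        accessibility_peaks=acc_peaks,
        true_sites=sites_by_ct,
        decoy_sites=decoys,
    )


def motif_free_config(base: SimConfig | None = None) -> SimConfig:
    """Variant where true sites carry no motif instance (accessibility only)."""
    return replace(base or SimConfig(), embed_motif=False)
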
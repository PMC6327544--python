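"""PWM scanning and per-bin motif / sequence composition features.

A motif model assigns a natural-log probability to each m-mer.  Only position
weight matrices (independent columns) are implemented here; the interface
(`MotifModel.log_prob_profile`) admits richer models.  Scanning slides the
motif over both strands at base-pair resolution; per position the two strand
scores are combined by taking the maximum.  Profiles are aggregated into two
per-bin features: the maximum log-probability in the bin (affinity of the
strongest site) and the log of the average probability (general affinity of
the region), the latter computed via a stable log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .binning import BinIndex

BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

PSEUDO_FLOOR = 1e-4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0 C=1 G=2 T=3, other -> -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix: per-position probabilities over A,C,G,T.

    Columns are floored at ``floor`` by mixing with the uniform distribution
    (p' = (1 - 4*floor) * p + floor), which keeps every entry >= floor and
    each column summing to 1, so log scores are finite.
    """

    name: str
    matrix: np.ndarray  # shape (m, 4), rows sum to 1
    floor: float = PSEUDO_FLOOR

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (m, 4)")
        if np.any(self.matrix < 0):
            raise ValueError("PWM entries must be non-negative")
        rows = self.matrix.sum(axis=1, keepdims=True)
        if np.any(rows <= 0):
            raise ValueError("PWM has an all-zero column")
        p = self.matrix / rows
        if self.floor > 0:
            p = (1.0 - 4.0 * self.floor) * p + self.floor
        self.matrix = p

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_matrix(self) -> np.ndarray:
        return np.log(self.matrix)

    @classmethod
    def from_consensus(
        cls, name: str, consensus: str, match_prob: float = 0.85, floor: float = PSEUDO_FLOOR
    ) -> "PWM":
        m = len(consensus)
        mat = np.full((m, 4), (1.0 - match_prob) / 3.0)
        codes = encode(consensus)
        if (codes < 0).any():
            raise ValueError("consensus must be ACGT only")
        mat[np.arange(m), codes] = match_prob
        return cls(name, mat, floor=floor)

    def log_prob_profile(self, codes: np.ndarray) -> np.ndarray:
        """Log-probability of the m-mer starting at each position (one strand).

        ``codes`` is an encoded sequence; N positions (code -1) contribute the
        log of the minimum probability of the corresponding PWM column.
        """
        m = len(self)
        n = len(codes) - m + 1
        if n <= 0:
            return np.empty(0, dtype=np.float64)
        logs = self.log_matrix
        # column 4 handles N: minimum column probability
        lut = np.concatenate([logs, logs.min(axis=1, keepdims=True)], axis=1)
        idx = np.where(codes < 0, 4, codes)
        out = np.zeros(n, dtype=np.float64)
        for k in range(m):
            out += lut[k, idx[k : k + n]]
        return out


@dataclass
class ScoreProfile:
    """Strand-resolved log-probability profiles for one chromosome and motif."""

    forward: np.ndarray
    reverse: np.ndarray  # aligned to forward coordinates (start of the m-mer)

    def combined(self) -> np.ndarray:
        return np.maximum(self.forward, self.reverse)

    def __len__(self) -> int:
        return len(self.forward)


def scan(seq: str, pwm: PWM) -> ScoreProfile:
    """Scan both strands of ``seq``; profiles have length len(seq) - m + 1.

    The reverse-strand score at position i is the score of the reverse
    complement of ``seq[i:i+m]``.
    """
    codes = encode(seq)
    fwd = pwm.log_prob_profile(codes)
    rc_codes = encode(reverse_complement(seq))
    rev = pwm.log_prob_profile(rc_codes)[::-1] if len(fwd) else fwd.copy()
    return ScoreProfile(forward=fwd, reverse=rev)


def aggregate(
    profile: np.ndarray, bins: BinIndex, chrom: str
) -> dict[str, np.ndarray]:
    """Per-bin max log-probability and log mean probability of a score profile.

    Positions are assigned to the bin containing the m-mer start.  Bins beyond
    the end of the profile (chromosome tail shorter than the motif) are imputed
    with the chromosome-wide minimum of each feature.
    """
    if len(profile) == 0:
        raise ValueError("empty score profile")
    n = bins.n_bins(chrom)
    w = bins.bin_width
    n_full = min(n, len(profile) // w)
    max_lp = np.full(n, np.nan)
    log_mean = np.full(n, np.nan)
    if n_full > 0:
        block = profile[: n_full * w].reshape(n_full, w)
        m = block.max(axis=1)
        max_lp[:n_full] = m
        log_mean[:n_full] = m + np.log(
            np.exp(block - m[:, None]).mean(axis=1)
        )
    # partial tail bin with at least one position
    if n_full < n and len(profile) > n_full * w:
        tail = profile[n_full * w :]
        m = tail.max()
        max_lp[n_full] = m
        log_mean[n_full] = m + np.log(np.exp(tail - m).mean())
    # impute empty bins with chromosome-wide minima
    for arr in (max_lp, log_mean):
        empty = np.isnan(arr)
        if empty.any():
            arr[empty] = np.nanmin(arr) if not empty.all() else 0.0
    return {"max_log_prob": max_lp, "log_mean_prob": log_mean}


def sequence_features(seq: str, bins: BinIndex, chrom: str) -> dict[str, np.ndarray]:
    """Per-bin G/C fraction, CpG dinucleotide frequency, and longest
    homopolymer run.

    CpG frequency is the CG dinucleotide count divided by the number of
    dinucleotide positions inside the bin (bin_width - 1).  N bases count
    as neither G/C nor part of a run or CpG.
    """
    codes = encode(seq)
    n = bins.n_bins(chrom)
    w = bins.bin_width
    block = codes[: n * w].reshape(n, w)
    gc = ((block == 1) | (block == 2)).mean(axis=1)
    pair_a = block[:, :-1]
    pair_b = block[:, 1:]
    cpg = ((pair_a == 1) & (pair_b == 2)).sum(axis=1) / (w - 1)
    same = (pair_a == pair_b) & (pair_a >= 0)
    run = np.ones(n, dtype=np.int64)
    cur = np.ones(n, dtype=np.int64)
    for k in range(w - 1):
        cur = np.where(same[:, k], cur + 1, 1)
        run = np.maximum(run, cur)
    return {
        "gc": gc.astype(np.float64),
        "cpg": cpg.astype(np.float64),
        "homopolymer_run": run.astype(np.float64),
    }


def read_pwm_file(path: str | Path, floor: float = PSEUDO_FLOOR) -> list[PWM]:
    """Read JASPAR-style plain-text matrices.

    Expected layout per motif: a ``>name`` header followed by four rows
    (A, C, G, T) of whitespace-separated counts or probabilities, optionally
    wrapped in ``A [ ... ]`` brackets.
    """
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, name
        if name is not None:
            if len(rows) != 4:
                raise ValueError(f"motif {name!r}: expected 4 rows, got {len(rows)}")
            mat = np.asarray(rows, dtype=np.float64).T  # (m, 4)
            pwms.append(PWM(name, mat, floor=floor))
        rows = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                continue
            body = line
            if body[0] in "ACGT" and ("[" in body or body[1:2].isspace()):
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            rows.append([float(x) for x in body.split()])
    flush()
    if not pwms:
        raise ValueError(f"{path}: no motifs found")
    return pwms


def write_pwm_file(pwms: list[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for b, base in enumerate(BASES):
                row = " ".join(f"{float(v)!r}" for v in pwm.matrix[:, b])
                fh.write(f"{base} [ {row} ]\n")
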
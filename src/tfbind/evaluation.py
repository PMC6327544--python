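"""Evaluation metrics for imbalanced window classification: AUC-PR, AUC-ROC,
recall at fixed FDR, and peak-overlap Jaccard.

AUC-PR uses continuous (non-linear) interpolation between operating points:
between two adjacent points the true-positive count varies linearly and the
false-positive count linearly in it, so precision follows
``t / ((1+s) t + c)`` and the area has a closed form.  Tied scores form a
single operating point.  Ambiguous (A) windows are excluded from all metrics
upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import PeakRecord


@dataclass
class EvalResult:
    auc_pr: float
    auc_roc: float
    recall_at_fdr10: float
    recall_at_fdr50: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auc_pr": self.auc_pr,
            "auc_roc": self.auc_roc,
            "recall_at_fdr10": self.recall_at_fdr10,
            "recall_at_fdr50": self.recall_at_fdr50,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def _operating_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (TP, FP) at each distinct threshold, descending scores."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep the last index of each tied-score block
    last = np.flatnonzero(np.diff(s) != 0)
    keep = np.concatenate([last, [len(s) - 1]])
    return tp[keep].astype(np.float64), fp[keep].astype(np.float64)


def _check_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("need at least one positive and one negative example")
    return scores, labels


def auc_pr(scores, labels) -> float:
    """Area under the precision-recall curve, continuous interpolation.

    The curve starts at recall 0 with the precision of the top-scoring block
    and integrates precision over recall with the non-linear interpolation of
    the operating points.
    """
    scores, labels = _check_binary(scores, labels)
    tp, fp = _operating_points(scores, labels)
    n_pos = labels.sum()
    tp = np.concatenate([[0.0], tp])
    fp = np.concatenate([[0.0], fp])
    area = 0.0
    for (ta, fa), (tb, fb) in zip(zip(tp[:-1], fp[:-1]), zip(tp[1:], fp[1:])):
        if tb == ta:
            continue
        s = (fb - fa) / (tb - ta)
        c = fa - s * ta
        u = 1.0 + s
        if abs(c) < 1e-12:
            area += (tb - ta) / u
        else:
            def antider(t: float) -> float:
                return t / u - c / (u * u) * np.log(u * t + c)

            area += antider(tb) - antider(ta)
    return float(area / n_pos)


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve (trapezoidal; ties as one operating point)."""
    scores, labels = _check_binary(scores, labels)
    tp, fp = _operating_points(scores, labels)
    n_pos, n_neg = labels.sum(), len(labels) - labels.sum()
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    return float(np.trapezoid(tpr, fpr))


def recall_at_fdr(scores, labels, fdr: float) -> float:
    """Maximum recall over thresholds where precision >= 1 - fdr (0 if none)."""
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    scores, labels = _check_binary(scores, labels)
    tp, fp = _operating_points(scores, labels)
    n_pos = labels.sum()
    precision = tp / (tp + fp)
    ok = precision >= 1.0 - fdr
    if not ok.any():
        return 0.0
    return float(tp[ok].max() / n_pos)


def evaluate_windows(scores, labels: list[str]) -> EvalResult:
    """All metrics on B/A/U-labeled windows; A windows are excluded."""
    scores = np.asarray(scores, dtype=np.float64)
    lab = np.asarray(labels)
    keep = lab != "A"
    y = (lab[keep] == "B").astype(np.float64)
    s = scores[keep]
    return EvalResult(
        auc_pr=auc_pr(s, y),
        auc_roc=auc_roc(s, y),
        recall_at_fdr10=recall_at_fdr(s, y, 0.10),
        recall_at_fdr50=recall_at_fdr(s, y, 0.50),
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def jaccard_peaks(a: list[PeakRecord], b: list[PeakRecord]) -> float:
    """Base-pair Jaccard of two peak sets (intersection / union of merged
    intervals); 0 when both sets are empty."""
    chroms = {p.chrom for p in a} | {p.chrom for p in b}
    inter = 0
    union = 0
    for chrom in chroms:
        ia = _merge([(p.start, p.end) for p in a if p.chrom == chrom])
        ib = _merge([(p.start, p.end) for p in b if p.chrom == chrom])
        union_iv = _merge(ia + ib)
        len_a = sum(e - s for s, e in ia)
        len_b = sum(e - s for s, e in ib)
        len_u = sum(e - s for s, e in union_iv)
        union += len_u
        inter += len_a + len_b - len_u
    if union == 0:
        return 0.0
    return inter / union
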
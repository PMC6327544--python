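"""Iterative hard-negative training: five rounds, five classifiers.

Round 1 trains on the initial sampled training set.  Each subsequent round
first scores all labeled 200-bp windows on the selection chromosomes with the
average of the window probabilities from every classifier trained so far,
determines the 1% percentile of the scores of bound (B) windows, and adds all
unbound (U) windows scoring strictly above that percentile to the negative set
with weight 1 (ambiguous windows are ignored, and a window enters the negative
set at most once).  The positives never change and the negative set grows
monotonically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binning import LabeledWindow, WINDOW_STEP
from .features import BinFeatureTable, extract_windows, predict_bin_posteriors
from .model import TwoClassModel, train_mcl
from .prediction import predict_window_scores
from .sampling import TrainingSet

N_ROUNDS = 5
PERCENTILE = 0.01


@dataclass
class IterationState:
    """Bookkeeping for the refinement loop."""

    training_set: TrainingSet
    models: list[TwoClassModel] = field(default_factory=list)
    added_per_round: list[list[tuple[str, int]]] = field(default_factory=list)
    #: per selection round: the B-score percentile threshold tau
    taus: list[float] = field(default_factory=list)
    #: per selection round: (chrom, window start, score) of each added negative
    added_windows: list[list[tuple[str, int, float]]] = field(default_factory=list)

    @property
    def round(self) -> int:
        return len(self.models)


def positive_score_percentile(scores_b: np.ndarray, q: float = PERCENTILE) -> float:
    """The ceil(q * n)-th smallest of the bound-window scores (order statistic)."""
    scores_b = np.sort(np.asarray(scores_b, dtype=np.float64))
    if len(scores_b) == 0:
        raise ValueError("no bound windows: cannot compute the score percentile")
    k = max(1, math.ceil(q * len(scores_b)))
    return float(scores_b[k - 1])


def select_additional_negatives(
    window_scores: np.ndarray,
    labels: list[str],
    q: float = PERCENTILE,
) -> tuple[np.ndarray, float]:
    """Indices of U-labeled windows scoring strictly above the B-score percentile.

    ``window_scores`` and ``labels`` are aligned; A-labeled windows are never
    selected.  Returns (selected indices, threshold tau).
    """
    window_scores = np.asarray(window_scores, dtype=np.float64)
    labels_arr = np.asarray(labels)
    tau = positive_score_percentile(window_scores[labels_arr == "B"], q)
    selected = np.flatnonzero((labels_arr == "U") & (window_scores > tau))
    return selected, tau


def _window_center_bin(start: int) -> int:
    """Training-example center bin for a 200-bp window: the bin holding the
    window midpoint (start + 100)."""
    return (start + 100) // WINDOW_STEP


def iterative_train(
    initial: TrainingSet,
    table: BinFeatureTable,
    labeled_windows: list[LabeledWindow],
    width_bins: int,
    *,
    selection_chroms: list[str] | None = None,
    n_rounds: int = N_ROUNDS,
    prior_scale: float = 1.0,
) -> IterationState:
    """Run the hard-negative refinement loop and return all trained models.

    ``labeled_windows`` are the B/A/U windows of the training cell type;
    selection is restricted to ``selection_chroms`` (default: every chromosome
    appearing in the labels, appropriate for toy genomes).
    """
    if selection_chroms is None:
        selection_chroms = sorted({lw.chrom for lw in labeled_windows})
    sel = [lw for lw in labeled_windows if lw.chrom in selection_chroms]
    sel_labels = [lw.label for lw in sel]
    state = IterationState(training_set=initial)
    seen_negatives = initial.negative_center_set()

    for _ in range(n_rounds):
        ts = state.training_set
        X, _, families = extract_windows(table, ts.centers, width_bins)
        model = train_mcl(
            X,
            ts.labels,
            ts.weight_array,
            families,
            prior_scale=prior_scale,
        )
        state.models.append(model)
        if state.round >= n_rounds:
            state.added_per_round.append([])
            break
        # average window scores of all classifiers trained so far
        tracks = []
        for m in state.models:
            post = predict_bin_posteriors(m, table, width_bins, chroms=selection_chroms)
            tracks.append(predict_window_scores(post, width_bins))
        mean_scores = {
            c: np.mean([t.scores[c] for t in tracks], axis=0) for c in selection_chroms
        }
        win_scores = np.array(
            [mean_scores[lw.chrom][lw.start // WINDOW_STEP] for lw in sel]
        )
        selected, tau = select_additional_negatives(win_scores, sel_labels)
        state.taus.append(tau)
        added: list[tuple[str, int]] = []
        added_w: list[tuple[str, int, float]] = []
        for j in selected:
            lw = sel[j]
            center = (lw.chrom, _window_center_bin(lw.start))
            if center in seen_negatives or center[1] >= table.bins.n_bins(lw.chrom):
                continue
            seen_negatives.add(center)
            ts.add(center[0], center[1], "U", 1.0, "iterative")
            added.append(center)
            added_w.append((lw.chrom, lw.start, float(win_scores[j])))
        state.added_per_round.append(added)
        state.added_windows.append(added_w)
    return state
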
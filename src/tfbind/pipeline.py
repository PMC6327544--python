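"""End-to-end driver: features -> sampling -> iterative training -> ensemble
prediction -> evaluation.

For each of the K training cell types, an initial training set is sampled from
that cell type's ChIP peaks and accessibility, and five classifiers are
trained by the iterative hard-negative procedure, yielding 5*K classifiers.
For prediction on a target cell type, every classifier is applied to the
target's feature table (accessibility is cell type-specific; motif and
sequence features are shared), the per-bin posteriors are turned into window
probabilities, and the 5*K window tracks are averaged.  Evaluation uses the
target cell type's B/A/U window labels with ambiguous windows excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binning import (
    WINDOW_STEP,
    bin_genome,
    derive_labels,
    enumerate_windows,
    peak_width_bins,
)
from .evaluation import EvalResult, evaluate_windows
from .features import BinFeatureTable, build_feature_table, predict_bin_posteriors
from .iterative import IterationState, iterative_train
from .prediction import ProbabilityTrack, ensemble_average, predict_window_scores
from .sampling import build_initial_training_set
from .simulate import SimConfig, SimData, generate


@dataclass
class PipelineResult:
    eval_result: EvalResult
    ensemble_track: ProbabilityTrack
    round1_eval: EvalResult
    states: dict[str, IterationState]
    width_bins: int
    tables: dict[str, BinFeatureTable] = field(default_factory=dict)
    test_labels: list = field(default_factory=list)


def feature_tables(data: SimData, groups=None) -> dict[str, BinFeatureTable]:
    """Per-cell-type feature tables (accessibility + motif + sequence)."""
    bins = bin_genome(data.sizes)
    kwargs = {} if groups is None else {"groups": groups}
    return {
        ct: build_feature_table(
            bins,
            data.accessibility[ct],
            data.accessibility_peaks[ct],
            data.accessibility_peaks[ct],
            [data.pwm],
            genome=data.genome,
            coverage_by_celltype=data.accessibility,
            **kwargs,
        )
        for ct in data.cell_types
    }


def run_pipeline(
    data: SimData,
    *,
    train_chroms: list[str],
    test_chroms: list[str],
    target_celltype: str | None = None,
    seed: int = 0,
    n_rounds: int = 5,
    catchitt_mode: bool = False,
    groups=None,
    prior_scale: float = 1.0,
) -> PipelineResult:
    """Train on ``train_chroms`` of every cell type; evaluate the 5*K-classifier
    ensemble on ``test_chroms`` of the target cell type.

    ``catchitt_mode`` restricts to single-cell-type operation: the
    cross-cell-type sampling schema is skipped and only the target cell type
    is trained (5 classifiers instead of 5*K).
    """
    rng = np.random.default_rng(seed)
    bins = bin_genome(data.sizes)
    target = target_celltype or data.cell_types[0]
    tables = feature_tables(data, groups=groups)
    width = peak_width_bins([data.chip_conservative[ct] for ct in data.cell_types])

    train_cts = [target] if catchitt_mode else data.cell_types
    states: dict[str, IterationState] = {}
    windows_train = {
        c: w for c, w in enumerate_windows(data.sizes).items() if c in train_chroms
    }
    for ct in train_cts:
        labels_ct = derive_labels(
            windows_train, data.chip_conservative[ct], data.chip_relaxed[ct]
        )
        others = (
            {}
            if catchitt_mode
            else {
                o: data.chip_conservative[o] for o in data.cell_types if o != ct
            }
        )
        initial = build_initial_training_set(
            bins,
            data.chip_conservative[ct],
            data.chip_relaxed[ct],
            data.accessibility[ct],
            rng,
            other_conservative=others,
            chroms=train_chroms,
        )
        states[ct] = iterative_train(
            initial,
            tables[ct],
            labels_ct,
            width,
            selection_chroms=train_chroms,
            n_rounds=n_rounds,
            prior_scale=prior_scale,
        )

    # ensemble prediction on the target cell type's features
    tracks: list[ProbabilityTrack] = []
    round1_tracks: list[ProbabilityTrack] = []
    for ct, state in states.items():
        for r, model in enumerate(state.models):
            post = predict_bin_posteriors(model, tables[target], width, chroms=test_chroms)
            track = predict_window_scores(post, width)
            tracks.append(track)
            if r == 0:
                round1_tracks.append(track)
    ensemble = ensemble_average(tracks)
    round1 = ensemble_average(round1_tracks)

    windows_test = {
        c: w for c, w in enumerate_windows(data.sizes).items() if c in test_chroms
    }
    test_labels = derive_labels(
        windows_test, data.chip_conservative[target], data.chip_relaxed[target]
    )

    def eval_track(track: ProbabilityTrack) -> EvalResult:
        scores = np.array(
            [track.scores[lw.chrom][lw.start // WINDOW_STEP] for lw in test_labels]
        )
        return evaluate_windows(scores, [lw.label for lw in test_labels])

    return PipelineResult(
        eval_result=eval_track(ensemble),
        ensemble_track=ensemble,
        round1_eval=eval_track(round1),
        states=states,
        width_bins=width,
        tables=tables,
        test_labels=test_labels,
    )


def end_to_end_check(
    config: SimConfig | None = None, seed: int = 0, **kwargs
) -> PipelineResult:
    """Generate a fixture, hold out the last chromosome, run the pipeline."""
    config = config or SimConfig(seed=seed)
    data = generate(config)
    chroms = list(data.sizes)
    return run_pipeline(
        data,
        train_chroms=chroms[:-1],
        test_chroms=chroms[-1:],
        seed=seed,
        **kwargs,
    )
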
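import numpy as np
import pytest

from tfbind.binning import bin_genome, derive_labels, enumerate_windows
from tfbind.features import extract_windows
from tfbind.iterative import (
    iterative_train,
    positive_score_percentile,
    select_additional_negatives,
)
from tfbind.model import train_mcl
from tfbind.pipeline import feature_tables
from tfbind.sampling import build_initial_training_set


def test_select_worked_example():
    """B scores {0.5,..,0.8}: tau is the 1st order statistic (ceil(0.04)=1)."""
    scores = np.array([0.5, 0.6, 0.7, 0.8, 0.4, 0.55])
    labels = ["B", "B", "B", "B", "U", "U"]
    selected, tau = select_additional_negatives(scores, labels)
    assert tau == 0.5
    assert selected.tolist() == [5]  # only the 0.55 U window


def test_select_edge_cases():
    scores = np.array([0.9, 0.8, 0.1, 0.2])
    labels = ["B", "B", "U", "U"]
    sel, _ = select_additional_negatives(scores, labels)
    assert sel.size == 0  # all U below tau
    scores2 = np.array([0.3, 0.4, 0.95, 0.99])
    sel2, _ = select_additional_negatives(scores2, labels)
    assert sel2.tolist() == [2, 3]  # every U above tau


def test_ambiguous_windows_never_selected():
    scores = np.array([0.5, 0.99, 0.98])
    labels = ["B", "A", "U"]
    sel, _ = select_additional_negatives(scores, labels)
    assert sel.tolist() == [2]


def test_ties_at_tau_excluded():
    scores = np.array([0.5, 0.5, 0.6])
    labels = ["B", "U", "U"]
    sel, tau = select_additional_negatives(scores, labels)
    assert tau == 0.5 and sel.tolist() == [2]  # strict '>' excludes the tie


def test_percentile_requires_bound_windows():
    with pytest.raises(ValueError):
        positive_score_percentile(np.array([]))


def test_percentile_order_statistic_convention():
    scores = np.arange(1, 201) / 200.0  # n=200 -> ceil(2) = 2nd smallest
    assert positive_score_percentile(scores) == pytest.approx(2 / 200)


@pytest.fixture(scope="module")
def trained_state(small_sim_data):
    data = small_sim_data
    ct = "cell1"
    bins = bin_genome(data.sizes)
    windows = enumerate_windows(data.sizes)
    labels = derive_labels(windows, data.chip_conservative[ct], data.chip_relaxed[ct])
    rng = np.random.default_rng(3)
    initial = build_initial_training_set(
        bins, data.chip_conservative[ct], data.chip_relaxed[ct],
        data.accessibility[ct], rng,
    )
    n_initial = len(initial)
    # restrict to accessibility-only features so decoy open regions are true
    # hard negatives and the selection step has work to do
    dnase_table = feature_tables(data, groups=("fold_enrichment", "long_range", "peak"))[ct]
    state = iterative_train(initial, dnase_table, labels, width_bins=7)
    return state, n_initial, labels, dnase_table


def test_five_rounds_five_models(trained_state):
    state, _, _, _ = trained_state
    assert len(state.models) == 5
    assert len(state.added_per_round) == 5


def test_negative_set_grows_monotonically(trained_state):
    state, n_initial, _, _ = trained_state
    sizes = np.cumsum([0] + [len(a) for a in state.added_per_round]) + n_initial
    assert np.all(np.diff(sizes) >= 0)
    assert len(state.training_set) == sizes[-1]
    # the hard-negative mechanism actually fired on this fixture
    assert len(state.added_per_round[0]) > 0


def test_added_negatives_are_unlabeled_bound_free(trained_state):
    state, n_initial, labels, _ = trained_state
    added = state.training_set.provenance[n_initial:]
    assert all(p == "iterative" for p in added)
    for (chrom, i), lab in zip(
        state.training_set.centers[n_initial:], state.training_set.labels[n_initial:]
    ):
        assert lab == "U"


def test_positives_unchanged_across_rounds(trained_state):
    state, n_initial, _, _ = trained_state
    n_pos = sum(1 for l in state.training_set.labels if l == "B")
    assert all(l == "U" for l in state.training_set.labels[n_initial:])
    assert n_pos == sum(1 for l in state.training_set.labels[:n_initial] if l == "B")


def test_single_round_equals_plain_training(small_sim_data):
    data = small_sim_data
    ct = "cell1"
    bins = bin_genome(data.sizes)
    table = feature_tables(data)[ct]
    windows = enumerate_windows(data.sizes)
    labels = derive_labels(windows, data.chip_conservative[ct], data.chip_relaxed[ct])
    rng = np.random.default_rng(9)
    initial = build_initial_training_set(
        bins, data.chip_conservative[ct], data.chip_relaxed[ct],
        data.accessibility[ct], rng,
    )
    state = iterative_train(initial, table, labels, width_bins=5, n_rounds=1)
    assert len(state.models) == 1
    X, _, fams = extract_windows(table, initial.centers, 5)
    plain = train_mcl(X, initial.labels, initial.weight_array, fams)
    np.testing.assert_allclose(
        state.models[0].posterior(X), plain.posterior(X), atol=1e-9
    )


def test_same_inputs_same_negative_additions(small_sim_data):
    data = small_sim_data
    ct = "cell1"
    bins = bin_genome(data.sizes)
    table = feature_tables(data, groups=("fold_enrichment", "long_range", "peak"))[ct]
    windows = enumerate_windows(data.sizes)
    labels = derive_labels(windows, data.chip_conservative[ct], data.chip_relaxed[ct])

    def run():
        rng = np.random.default_rng(4)
        initial = build_initial_training_set(
            bins, data.chip_conservative[ct], data.chip_relaxed[ct],
            data.accessibility[ct], rng,
        )
        return iterative_train(initial, table, labels, width_bins=7, n_rounds=2)

    a, b = run(), run()
    assert a.added_per_round == b.added_per_round
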
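import numpy as np
import pytest

from tfbind.binning import bin_genome
from tfbind.io_formats import PeakRecord
from tfbind.sampling import (
    build_initial_training_set,
    covered_bins_mask,
    positives_from_peaks,
    sample_cross_celltype,
    sample_dnase_matched,
    sample_uniform,
)


def _random_fixture(rng, n_chroms=2, length=50_000, n_peaks=12):
    sizes = {f"chr{i+1}": length for i in range(n_chroms)}
    bins = bin_genome(sizes)
    cons, relax = [], []
    for k in range(n_peaks):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        s = int(rng.integers(500, length - 900))
        w = int(rng.integers(150, 400))
        cons.append(PeakRecord(chrom, s, s + w, summit=w // 2))
        relax.append(PeakRecord(chrom, s - 50, s + w + 50))
    coverage = {c: rng.random(length) * 3 for c in sizes}
    return sizes, bins, cons, relax, coverage


def test_positives_centered_at_summit_bin():
    bins = bin_genome({"chr1": 10_000})
    peaks = [PeakRecord("chr1", 100, 400, summit=150)]  # summit at bp 250
    ts = positives_from_peaks(bins, peaks)
    assert ts.centers == [("chr1", 5)] and ts.labels == ["B"]


def test_uniform_counts_ten_per_positive_per_chromosome(rng):
    sizes, bins, cons, relax, _ = _random_fixture(rng)
    pos = positives_from_peaks(bins, cons)
    neg = sample_uniform(bins, relax, pos, rng)
    pos_per_chrom = {c: sum(1 for cc, _ in pos.centers if cc == c) for c in sizes}
    neg_per_chrom = {c: sum(1 for cc, _ in neg.centers if cc == c) for c in sizes}
    for c in sizes:
        assert neg_per_chrom[c] == 10 * pos_per_chrom[c]
    assert all(w == 1.0 for w in neg.weights)


def test_uniform_negatives_avoid_relaxed_peaks_and_are_reproducible(rng):
    sizes, bins, cons, relax, _ = _random_fixture(rng)
    pos = positives_from_peaks(bins, cons)
    neg1 = sample_uniform(bins, relax, pos, np.random.default_rng(5))
    neg2 = sample_uniform(bins, relax, pos, np.random.default_rng(5))
    assert neg1.centers == neg2.centers
    for chrom in sizes:
        mask = covered_bins_mask(bins, relax, chrom)
        for c, i in neg1.centers:
            if c == chrom:
                assert not mask[i]


def test_uniform_all_covered_yields_empty_with_warning(caplog):
    bins = bin_genome({"chr1": 1000})
    relax = [PeakRecord("chr1", 0, 1000)]
    pos = positives_from_peaks(bins, [PeakRecord("chr1", 400, 600, summit=100)])
    with caplog.at_level("WARNING"):
        neg = sample_uniform(bins, relax, pos, np.random.default_rng(0))
    assert len(neg) == 0
    assert any("eligible" in r.message for r in caplog.records)


def test_matched_weights_are_importance_weights(rng):
    """Weight of a draw from stratum g is (N_g/N_neg) / (n_g/n_total)."""
    sizes, bins, cons, relax, coverage = _random_fixture(rng, n_peaks=8)
    pos = positives_from_peaks(bins, cons)
    neg = sample_dnase_matched(bins, relax, pos, coverage, rng)
    assert len(neg) > 0
    # when the coverage is uninformative the weights are bounded and positive
    assert all(w > 0 for w in neg.weights)
    for chrom in sizes:
        mask = covered_bins_mask(bins, relax, chrom)
        for c, i in neg.centers:
            if c == chrom:
                assert not mask[i]


def test_matched_weights_reduce_to_one_when_distributions_match():
    """Uniform coverage puts positives and negatives in the same stratum."""
    bins = bin_genome({"chr1": 50_000})
    cons = [PeakRecord("chr1", s, s + 200, summit=100) for s in range(1000, 9000, 2000)]
    relax = cons
    coverage = {"chr1": np.zeros(50_000)}  # all bins identical -> one stratum
    pos = positives_from_peaks(bins, cons)
    neg = sample_dnase_matched(bins, relax, pos, coverage, np.random.default_rng(1))
    np.testing.assert_allclose(neg.weights, 1.0)
    assert sum(neg.weights) == pytest.approx(len(neg))


def test_matched_overweights_accessible_strata(rng):
    """Open-chromatin positives force over-sampling of high-signal negatives,
    which are then down-weighted below 1."""
    length = 100_000
    bins = bin_genome({"chr1": length})
    coverage = {"chr1": np.zeros(length)}
    # positives sit in high-signal regions
    cons = []
    for s in range(2000, 42_000, 4000):
        coverage["chr1"][s - 500 : s + 700] = 5.0
        cons.append(PeakRecord("chr1", s, s + 200, summit=100))
    # some high-signal decoy regions that are not peaks
    for s in range(50_000, 70_000, 4000):
        coverage["chr1"][s : s + 1000] = 5.0
    relax = cons
    pos = positives_from_peaks(bins, cons)
    neg = sample_dnase_matched(bins, relax, pos, coverage, np.random.default_rng(2))
    weights = np.asarray(neg.weights)
    from tfbind.sampling import bin_median_coverage, covered_bins_mask

    medians = bin_median_coverage(bins, coverage, "chr1")
    eligible = medians[~covered_bins_mask(bins, relax, "chr1")]
    drawn = medians[[i for _, i in neg.centers]]
    # every positive sits in the high-signal stratum, so every draw does too
    assert np.all(drawn == 5.0)
    # importance weight = population share of that stratum / draw share (=1)
    expected = (eligible == 5.0).mean()
    np.testing.assert_allclose(weights, expected)
    assert expected < 1.0


def test_cross_celltype_counts_and_weight_normalization(rng):
    sizes, bins, cons, relax, coverage = _random_fixture(rng, n_peaks=10)
    pos = positives_from_peaks(bins, cons)
    other = {
        "ct2": [
            PeakRecord(c, s, s + 300, summit=150)
            for c, s in [("chr1", 20_000), ("chr1", 30_000), ("chr2", 25_000)]
        ]
    }
    neg = sample_cross_celltype(
        bins, other, relax, pos, rng, base_weight_total=1000.0
    )
    for chrom in sizes:
        n_pos = sum(1 for c, _ in pos.centers if c == chrom)
        n_neg = sum(1 for c, _ in neg.centers if c == chrom)
        eligible = (
            covered_bins_mask(bins, other["ct2"], chrom)
            & ~covered_bins_mask(bins, relax, chrom)
        ).sum()
        assert n_neg == min(4 * n_pos, eligible)
        got = sum(w for (c, _), w in zip(neg.centers, neg.weights) if c == chrom)
        n_putative = (~covered_bins_mask(bins, relax, chrom)).sum()
        if n_neg:
            assert got == pytest.approx(eligible / n_putative * 1000.0)


def test_cross_celltype_empty_without_other_celltypes(rng):
    sizes, bins, cons, relax, _ = _random_fixture(rng)
    pos = positives_from_peaks(bins, cons)
    neg = sample_cross_celltype(bins, {}, relax, pos, rng, base_weight_total=100.0)
    assert len(neg) == 0


def test_sampling_contracts_on_many_random_fixtures():
    """Counts, weights and the relaxed-peak exclusion across 20 fixtures."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        sizes, bins, cons, relax, coverage = _random_fixture(
            rng, n_peaks=int(rng.integers(4, 14))
        )
        ts = build_initial_training_set(
            bins, cons, relax, coverage, rng,
            other_conservative={"o": [PeakRecord("chr1", 15_000, 15_400)]},
        )
        labels = np.asarray(ts.labels)
        weights = np.asarray(ts.weights)
        assert (weights > 0).all()
        assert set(labels) <= {"B", "U"}
        n_pos = (labels == "B").sum()
        n_uni = sum(1 for p in ts.provenance if p == "uniform")
        assert n_uni == 10 * n_pos
        for (chrom, i), lab in zip(ts.centers, ts.labels):
            if lab == "U":
                assert not covered_bins_mask(bins, relax, chrom)[i]
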
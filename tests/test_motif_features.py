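import math

import numpy as np
import pytest

from tfbind.binning import bin_genome
from tfbind.motifs import (
    PWM,
    aggregate,
    read_pwm_file,
    reverse_complement,
    scan,
    sequence_features,
    write_pwm_file,
)


def brute_force_profile(seq: str, pwm: PWM) -> np.ndarray:
    """Per-position product of column probabilities, in log space."""
    m = len(pwm)
    out = []
    for i in range(len(seq) - m + 1):
        v = 1.0
        for k, ch in enumerate(seq[i : i + m]):
            if ch in "ACGT":
                v *= pwm.matrix[k, "ACGT".index(ch)]
            else:
                v *= pwm.matrix[k].min()
        out.append(math.log(v))
    return np.asarray(out)


def test_uniform_pwm_closed_form():
    pwm = PWM("u", np.full((4, 4), 0.25))
    prof = scan("ACGTACGT", pwm)
    np.testing.assert_allclose(prof.forward, 4 * math.log(0.25))
    np.testing.assert_allclose(prof.reverse, 4 * math.log(0.25))


def test_consensus_pwm_scores_zero_at_hit():
    pwm = PWM("c", np.eye(4), floor=0.0)  # consensus ACGT
    with np.errstate(divide="ignore"):
        prof = scan("TTACGTTT", pwm)
    assert prof.forward[2] == 0.0
    assert prof.combined()[2] == 0.0


def test_combined_is_max_over_strands(rng):
    seq = "".join(rng.choice(list("ACGT"), 60))
    pwm = PWM("r", rng.dirichlet(np.ones(4), size=5))
    prof = scan(seq, pwm)
    np.testing.assert_array_equal(
        prof.combined(), np.maximum(prof.forward, prof.reverse)
    )


def test_reverse_complement_mirror_property(rng):
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), 200))
        pwm = PWM("r", rng.dirichlet(np.ones(4), size=7))
        a = scan(seq, pwm)
        b = scan(reverse_complement(seq), pwm)
        np.testing.assert_allclose(a.forward, b.reverse[::-1], atol=1e-12)
        np.testing.assert_allclose(a.reverse, b.forward[::-1], atol=1e-12)


def test_scan_matches_brute_force_oracle_random_1kb(rng):
    seq = "".join(rng.choice(list("ACGTN"), 1000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    pwm = PWM("r", rng.dirichlet(np.ones(4) * 2, size=9))
    prof = scan(seq, pwm)
    np.testing.assert_allclose(prof.forward, brute_force_profile(seq, pwm), atol=1e-10)
    np.testing.assert_allclose(
        prof.reverse, brute_force_profile(reverse_complement(seq), pwm)[::-1], atol=1e-10
    )


def test_scan_shorter_than_motif_empty():
    pwm = PWM("u", np.full((6, 4), 0.25))
    assert len(scan("ACG", pwm)) == 0


def test_pwm_floor_keeps_entries_above_floor():
    pwm = PWM("f", np.array([[1.0, 0.0, 0.0, 0.0]]), floor=1e-4)
    assert pwm.matrix.min() >= 1e-4
    np.testing.assert_allclose(pwm.matrix.sum(axis=1), 1.0)


def test_aggregate_constant_profile():
    bins = bin_genome({"x": 200})
    agg = aggregate(np.full(200, -3.0), bins, "x")
    np.testing.assert_allclose(agg["max_log_prob"], -3.0)
    np.testing.assert_allclose(agg["log_mean_prob"], -3.0)


def test_aggregate_log_mean_logsumexp_oracle():
    bins = bin_genome({"x": 100}, bin_width=2)
    profile = np.concatenate([[math.log(0.1), math.log(0.3)], np.full(97, -30.0)])
    agg = aggregate(profile, bins, "x")
    assert agg["log_mean_prob"][0] == pytest.approx(math.log(0.2), abs=1e-12)
    assert agg["max_log_prob"][0] == pytest.approx(math.log(0.3))


def test_aggregate_max_dominates_and_bounds(rng):
    bins = bin_genome({"x": 500})
    profile = rng.normal(-10, 3, size=460)  # tail bins partially/fully empty
    agg = aggregate(profile, bins, "x")
    assert np.all(agg["log_mean_prob"] <= agg["max_log_prob"] + 1e-12)
    # strong single site dominates the max
    profile2 = np.full(500, -20.0)
    profile2[10] = 0.0
    agg2 = aggregate(profile2, bins, "x")
    assert agg2["max_log_prob"][0] == 0.0


def test_aggregate_empty_tail_bins_imputed_with_minimum():
    bins = bin_genome({"x": 150})
    profile = np.array([-1.0, -5.0, -2.0])  # only bin 0 has positions
    agg = aggregate(profile, bins, "x")
    assert agg["max_log_prob"][2] == agg["max_log_prob"].min()


def test_sequence_features_worked_examples():
    bins = bin_genome({"x": 50})
    sf = sequence_features("G" * 50, bins, "x")
    assert (sf["gc"][0], sf["cpg"][0], sf["homopolymer_run"][0]) == (1.0, 0.0, 50.0)
    sf = sequence_features("AT" * 25, bins, "x")
    assert (sf["gc"][0], sf["homopolymer_run"][0]) == (0.0, 1.0)
    sf = sequence_features("ACGCGT" + "A" * 44, bins, "x")
    assert sf["cpg"][0] == pytest.approx(2 / 49)


def test_pwm_file_round_trip(tmp_path, rng):
    pwms = [
        PWM("m1", rng.dirichlet(np.ones(4), size=8)),
        PWM("m2", rng.dirichlet(np.ones(4), size=12)),
    ]
    path = tmp_path / "motifs.txt"
    write_pwm_file(pwms, path)
    back = read_pwm_file(path, floor=0.0)  # matrices already floored on write
    assert [p.name for p in back] == ["m1", "m2"]
    for a, b in zip(pwms, back):
        np.testing.assert_allclose(a.matrix, b.matrix, rtol=1e-12)
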
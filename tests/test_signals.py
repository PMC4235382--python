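"""Unit and property tests for the per-window sequence statistics."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oriscape import (
    BaseCounts,
    GenomicInterval,
    count_bases,
    entropy,
    gc_profile,
    gc_skew,
    lag_pairs,
    redundancy,
    redundancy_spectrum,
    reverse_complement,
    sliding_windows,
)
from oriscape.signals import (
    mononucleotide_shuffle,
    window_redundancy_values,
    window_track_means,
    window_values,
)

from conftest import random_dna

# ---------------------------------------------------------------------------
# Independent brute-force oracles (explicit enumeration, direct log sums)


def brute_counts(seq: str) -> tuple[int, int, int, int]:
    return tuple(seq.count(b) for b in "ACGT")


def brute_entropy(seq: str) -> float:
    a, c, g, t = brute_counts(seq)
    n = a + c + g + t
    h = 0.0
    for x in (a, c, g, t):
        if x:
            h -= (x / n) * math.log2(x / n)
    return h


def brute_redundancy(seq: str, k: int) -> float:
    pairs = [
        (seq[t], seq[t + k + 1])
        for t in range(len(seq) - k - 1)
        if seq[t] in "ACGT" and seq[t + k + 1] in "ACGT"
    ]
    n = len(pairs)
    joint = Counter(pairs)
    marginal = Counter()
    for x, y in pairs:
        marginal[x] += 1
        marginal[y] += 1
    h = -sum((c / (2 * n)) * math.log2(c / (2 * n)) for c in marginal.values())
    return 2 * h + sum((c / n) * math.log2(c / n) for c in joint.values())


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [("GCAT", (1, 1, 1, 1)), ("NNNN", (0, 0, 0, 0)), ("AAGG", (2, 0, 2, 0))],
)
def test_count_bases_ignores_ambiguous(seq, expected):
    c = count_bases(seq)
    assert (c.a, c.c, c.g, c.t) == expected


@pytest.mark.parametrize(
    "seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5)]
)
def test_gc_profile_bounds_and_balance(seq, expected):
    assert gc_profile(count_bases(seq)) == expected


@pytest.mark.parametrize(
    "seq,expected", [("CCCC", -1.0), ("GCGC", 0.0), ("GGGC", 0.5)]
)
def test_gc_skew_values(seq, expected):
    assert gc_skew(count_bases(seq)) == expected


def test_undefined_windows_propagate_nan():
    assert math.isnan(gc_profile(count_bases("NNN")))
    assert math.isnan(gc_skew(count_bases("ATAT")))
    assert math.isnan(entropy(BaseCounts(0, 0, 0, 0)))


@pytest.mark.parametrize(
    "seq,expected", [("ACGT", 2.0), ("AAAA", 0.0), ("AACC", 1.0)]
)
def test_entropy_worked_values(seq, expected):
    assert entropy(count_bases(seq)) == pytest.approx(expected, abs=1e-12)


def test_lag_pairs_enumeration():
    lp = lag_pairs("ATAT", 0)  # adjacent pairs AT, TA, AT
    assert lp.counts[0, 3] == 2 and lp.counts[3, 0] == 1
    assert lp.total == 3

    lp = lag_pairs("ACGT", 1)  # pairs (A,G), (C,T) with one intervening base
    assert lp.counts[0, 2] == 1 and lp.counts[1, 3] == 1
    assert lp.total == 2

    lp = lag_pairs("ANAT", 0)  # (A,N) and (N,A) skipped
    assert lp.counts[0, 3] == 1
    assert lp.total == 1


def test_lag_pairs_too_short_raises():
    with pytest.raises(ValueError):
        lag_pairs("AC", 5)
    with pytest.raises(ValueError):
        lag_pairs("ANNT", 0)  # every adjacent pair touches an N


def test_redundancy_worked_examples():
    assert redundancy("AAAAAA", 0) == pytest.approx(0.0, abs=1e-12)
    assert redundancy("ATAT", 0) == pytest.approx(1.08170, abs=1e-4)


def test_redundancy_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        seq = random_dna(rng, int(rng.integers(10, 501)), with_n=True)
        for k in (0, 1, 5):
            if len(seq) < k + 2:
                continue
            try:
                ours = redundancy(seq, k)
            except ValueError:
                continue
            assert ours == pytest.approx(brute_redundancy(seq, k), abs=1e-12)


def test_redundancy_sequence_marginals_mode():
    # literal whole-sequence-frequency reading: 2H(sequence) + sum p log p
    seq = "ATATGCGCAT"
    a, c, g, t = brute_counts(seq)
    lp = lag_pairs(seq, 0)
    joint_term = sum(
        (x / lp.total) * math.log2(x / lp.total)
        for x in lp.counts.ravel() if x
    )
    expected = 2 * brute_entropy(seq) + joint_term
    assert redundancy(seq, 0, marginals="sequence") == pytest.approx(expected, abs=1e-12)


def test_iid_sequence_has_vanishing_redundancy():
    rng = np.random.default_rng(123)
    seq = random_dna(rng, 100_000)
    spectrum = redundancy_spectrum(seq, k_max=10)
    assert spectrum.values.max() < 0.001


def test_alternating_sequence_is_dependent_at_every_lag():
    # a strict 2-periodic sequence determines the base at EVERY lag, so
    # all D values sit at the 1-bit ceiling of its two-letter alphabet
    seq = "AT" * 100
    spectrum = redundancy_spectrum(seq, k_max=2)
    assert np.allclose(spectrum.values, 1.0, atol=1e-4)


def test_markov_sequence_spectrum_peaks_at_adjacent_lag():
    # copy-previous-with-prob-lambda chains decay geometrically with lag,
    # so the adjacent correlation (gap k+2 = 2) dominates the spectrum
    rng = np.random.default_rng(17)
    lam = 0.5
    codes = [int(rng.integers(4))]
    for _ in range(4999):
        codes.append(codes[-1] if rng.random() < lam else int(rng.integers(4)))
    seq = "".join("ACGT"[c] for c in codes)
    spectrum = redundancy_spectrum(seq, k_max=5)
    assert spectrum.argmax_gap == 2
    assert spectrum.values[0] > 0.1


def test_constant_sequence_spectrum_is_zero():
    spectrum = redundancy_spectrum("A" * 200, k_max=5)
    assert np.allclose(spectrum.values, 0.0, atol=1e-12)


def test_shuffling_destroys_redundancy():
    seq = "AT" * 100
    assert redundancy(seq, 0) > 0.1
    rng = np.random.default_rng(99)
    shuffled = [redundancy(mononucleotide_shuffle(seq, rng), 0) for _ in range(50)]
    assert np.mean(shuffled) < 0.01


def test_statistic_ranges_on_random_windows():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        seq = random_dna(rng, int(rng.integers(10, 200)), with_n=True)
        counts = count_bases(seq)
        gc = gc_profile(counts)
        skew = gc_skew(counts)
        h = entropy(counts)
        if not math.isnan(gc):
            assert 0.0 <= gc <= 1.0
        if not math.isnan(skew):
            assert -1.0 <= skew <= 1.0
        if not math.isnan(h):
            assert 0.0 <= h <= 2.0
        try:
            d = redundancy(seq, 0)
        except ValueError:
            continue
        assert -1e-9 <= d <= 2.0


def test_strand_symmetries():
    rng = np.random.default_rng(11)
    for _ in range(200):
        seq = random_dna(rng, int(rng.integers(20, 200)))
        rc = reverse_complement(seq)
        assert gc_profile(count_bases(rc)) == pytest.approx(
            gc_profile(count_bases(seq)), abs=1e-12
        )
        assert gc_skew(count_bases(rc)) == pytest.approx(
            -gc_skew(count_bases(seq)), abs=1e-12
        )
        assert entropy(count_bases(rc)) == pytest.approx(
            entropy(count_bases(seq)), abs=1e-12
        )


@pytest.mark.parametrize(
    "length,window,step,expected",
    [(300, 300, 300, 1), (600, 50, 1, 551), (40, 50, 1, 0), (1000, 300, 300, 3)],
)
def test_sliding_window_counts(length, window, step, expected):
    region = GenomicInterval("chr1", 0, length)
    windows = sliding_windows(region, window, step)
    assert len(windows) == expected
    for w in windows:
        assert w.length == window
        assert 0 <= w.start and w.end <= length


@settings(max_examples=100, derandomize=True)
@given(
    length=st.integers(1, 500),
    window=st.integers(1, 120),
    step=st.integers(1, 60),
)
def test_sliding_window_tiling_property(length, window, step):
    region = GenomicInterval("c", 10, 10 + length)
    windows = sliding_windows(region, window, step)
    if window > length:
        assert windows == []
    else:
        assert len(windows) == (length - window) // step + 1
        starts = [w.start for w in windows]
        assert starts == sorted(starts)
        assert all(w.end <= region.end for w in windows)


def test_vectorised_windows_agree_with_scalar_path():
    rng = np.random.default_rng(5)
    seq = random_dna(rng, 400, with_n=True)
    for stat, fn in [("gc_profile", gc_profile), ("gc_skew", gc_skew),
                     ("entropy", entropy)]:
        vec = window_values(seq, 50, 3, stat=stat)
        for i, v in enumerate(vec):
            expected = fn(count_bases(seq[i * 3 : i * 3 + 50]))
            assert (math.isnan(v) and math.isnan(expected)) or v == pytest.approx(
                expected, abs=1e-12
            )
    vec = window_redundancy_values(seq, 150, 7, k=0)
    for i, v in enumerate(vec):
        sub = seq[i * 7 : i * 7 + 150]
        assert v == pytest.approx(brute_redundancy(sub, 0), abs=1e-12)


def test_window_track_means_skip_missing():
    values = np.array([1.0, np.nan, 3.0, 5.0, np.nan, np.nan])
    out = window_track_means(values, window=3, step=1)
    assert out[0] == pytest.approx(2.0)  # mean of 1, 3
    assert out[1] == pytest.approx(4.0)  # mean of 3, 5
    assert math.isnan(window_track_means(np.full(4, np.nan), 3, 1)[0])
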
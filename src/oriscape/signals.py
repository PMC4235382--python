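"""Per-window sequence statistics: GC profile, GC skew, entropy, and
lag-k information redundancy.

The GC profile of a window is (G+C)/(A+C+G+T) and the GC skew is
(G-C)/(G+C); both count only unambiguous bases.  The informational entropy
H = -sum_a p_a log2 p_a of the base composition is measured in bits
(maximum 2 for DNA).  The k-order information redundancy

    D_{k+2} = 2H + sum_{ij} p_i(k)j log2 p_i(k)j

measures the dependence between bases separated by k intervening
positions (k = 0 is adjacent pairs), where p_i(k)j is the joint
probability of base j occurring after base i at lag k+1.  Under the
default marginal convention H is the entropy of the pooled first/second
position marginal of the lag-k pair ensemble, which makes D_{k+2} a
mutual-information-like quantity and non-negative up to rounding; passing
``marginals="sequence"`` uses whole-sequence base frequencies instead
(the literal composition reading, which can go slightly negative on
finite sequences).

Windows with an empty denominator (all-N for GC profile, no G or C for
GC skew, no valid pair for D) propagate NaN rather than raising, so that
metagene averaging can simply skip them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .io import GenomicInterval

Marginals = Literal["pairs", "sequence"]

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0, C=1, G=2, T=3, other=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class BaseCounts:
    """Counts of unambiguous bases in a window (N excluded)."""

    a: int
    c: int
    g: int
    t: int

    def __post_init__(self) -> None:
        if min(self.a, self.c, self.g, self.t) < 0:
            raise ValueError("base counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t


@dataclass(frozen=True)
class LagPairDistribution:
    """4x4 counts of base pairs (i, j) at lag k (k intervening bases)."""

    k: int
    counts: np.ndarray  # shape (4, 4), int

    def __post_init__(self) -> None:
        if self.counts.shape != (4, 4):
            raise ValueError("pair counts must be 4x4")
        if self.counts.min() < 0:
            raise ValueError("pair counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        n = self.total
        if n < 1:
            raise ValueError("no valid pairs: cannot form probabilities")
        return self.counts / n


@dataclass(frozen=True)
class RedundancySpectrum:
    """D_{k+2} values (bits) for k = 0..k_max; ``gaps`` is the k+2 axis."""

    values: np.ndarray
    k_max: int

    @property
    def gaps(self) -> np.ndarray:
        return np.arange(2, self.k_max + 3)

    @property
    def argmax_gap(self) -> int:
        """The k+2 value at which the spectrum is maximal."""
        return int(np.nanargmax(self.values)) + 2


def count_bases(seq: str) -> BaseCounts:
    """Count A/C/G/T in *seq*; N and any other symbol are ignored."""
    codes = encode_bases(seq)
    n = np.bincount(codes, minlength=5)
    return BaseCounts(int(n[0]), int(n[1]), int(n[2]), int(n[3]))


def gc_profile(counts: BaseCounts) -> float:
    """(G+C)/(A+C+G+T), in [0, 1]; NaN for an all-N window."""
    if counts.total == 0:
        return float("nan")
    return (counts.g + counts.c) / counts.total


def gc_skew(counts: BaseCounts) -> float:
    """(G-C)/(G+C), in [-1, 1]; NaN when the window has no G or C."""
    gc = counts.g + counts.c
    if gc == 0:
        return float("nan")
    return (counts.g - counts.c) / gc


def entropy(counts: BaseCounts) -> float:
    """Shannon entropy of the base composition, in bits (0..2)."""
    if counts.total == 0:
        return float("nan")
    p = np.array([counts.a, counts.c, counts.g, counts.t], dtype=float) / counts.total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def lag_pairs(seq: str, k: int) -> LagPairDistribution:
    """Count ordered base pairs at lag *k* (k intervening bases).

    k = 0 counts adjacent pairs.  Pairs in which either base is N are
    skipped.  Raises ``ValueError`` if no valid pair exists.
    """
    if k < 0:
        raise ValueError("lag k must be non-negative")
    codes = encode_bases(seq)
    if len(codes) < k + 2:
        raise ValueError(f"sequence too short for lag k={k} (length {len(codes)})")
    first = codes[: -(k + 1)]
    second = codes[k + 1 :]
    valid = (first < 4) & (second < 4)
    if not valid.any():
        raise ValueError(f"no valid base pair at lag k={k} after N exclusion")
    flat = np.bincount(first[valid] * 4 + second[valid], minlength=16)
    return LagPairDistribution(k, flat.reshape(4, 4).astype(np.int64))


def _plogp(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def redundancy_from_pairs(
    pairs: LagPairDistribution,
    marginals: Marginals = "pairs",
    sequence_counts: BaseCounts | None = None,
) -> float:
    """D_{k+2} = 2H + sum p log2 p from a lag-pair distribution."""
    joint = pairs.probabilities
    joint_term = float(_plogp(joint).sum())
    if marginals == "pairs":
        pooled = (joint.sum(axis=1) + joint.sum(axis=0)) / 2.0
        h = float(-_plogp(pooled).sum())
    elif marginals == "sequence":
        if sequence_counts is None:
            raise ValueError("sequence_counts required for marginals='sequence'")
        h = entropy(sequence_counts)
    else:
        raise ValueError(f"unknown marginal convention {marginals!r}")
    return 2.0 * h + joint_term


def redundancy(seq: str, k: int, marginals: Marginals = "pairs") -> float:
    """k-order information redundancy D_{k+2} of *seq*, in bits."""
    pairs = lag_pairs(seq, k)
    seq_counts = count_bases(seq) if marginals == "sequence" else None
    return redundancy_from_pairs(pairs, marginals, seq_counts)


def redundancy_spectrum(
    seq: str, k_max: int = 48, marginals: Marginals = "pairs"
) -> RedundancySpectrum:
    """D_{k+2} for k = 0..k_max on a single sequence."""
    values = np.array([redundancy(seq, k, marginals) for k in range(k_max + 1)])
    return RedundancySpectrum(values, k_max)


def average_redundancy_spectrum(
    seqs: Sequence[str],
    k_max: int = 48,
    method: Literal["pooled", "mean"] = "pooled",
    marginals: Marginals = "pairs",
) -> RedundancySpectrum:
    """Average D_{k+2} spectrum over a set of sequences.

    ``pooled`` (default) sums the lag-pair counts over all sequences
    before forming D, treating the set as draws from one ensemble; this
    avoids the positive small-sample bias that per-sequence estimates
    carry on short windows.  ``mean`` averages per-sequence spectra.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    if method == "mean":
        spectra = [redundancy_spectrum(s, k_max, marginals).values for s in seqs]
        return RedundancySpectrum(np.mean(spectra, axis=0), k_max)
    values = np.empty(k_max + 1)
    for k in range(k_max + 1):
        total = np.zeros((4, 4), dtype=np.int64)
        for s in seqs:
            total += lag_pairs(s, k).counts
        values[k] = redundancy_from_pairs(LagPairDistribution(k, total), marginals="pairs")
    return RedundancySpectrum(values, k_max)


def sliding_windows(
    region: GenomicInterval, window: int, step: int
) -> list[GenomicInterval]:
    """Full windows tiling *region*; trailing partial windows are discarded."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    length = region.length
    if window > length:
        return []
    return [
        GenomicInterval(region.chrom, region.start + m * step,
                        region.start + m * step + window, region.strand)
        for m in range((length - window) // step + 1)
    ]


# ---------------------------------------------------------------------------
# Vectorised window evaluation (used by the metagene and classify stages)


def window_base_counts(seq: str, window: int, step: int = 1) -> np.ndarray:
    """(n_windows, 4) A/C/G/T counts for all full windows of *seq*."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    codes = encode_bases(seq)
    n = len(codes)
    if n < window:
        return np.empty((0, 4), dtype=np.int64)
    onehot = (codes[:, None] == np.arange(4, dtype=np.uint8)).astype(np.int64)
    cum = np.vstack([np.zeros((1, 4), dtype=np.int64), np.cumsum(onehot, axis=0)])
    starts = np.arange(0, n - window + 1, step)
    return cum[starts + window] - cum[starts]


def window_values(seq: str, window: int, step: int = 1,
                  stat: str = "gc_profile") -> np.ndarray:
    """Per-window gc_profile / gc_skew / entropy values; NaN where undefined."""
    counts = window_base_counts(seq, window, step).astype(float)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if stat == "gc_profile":
            out = np.where(total > 0, (counts[:, 1] + counts[:, 2]) / np.maximum(total, 1), np.nan)
        elif stat == "gc_skew":
            gc = counts[:, 1] + counts[:, 2]
            out = np.where(gc > 0, (counts[:, 2] - counts[:, 1]) / np.maximum(gc, 1), np.nan)
        elif stat == "entropy":
            p = counts / np.maximum(total, 1)[:, None]
            out = np.where(total > 0, -_plogp_rows(p), np.nan)
        else:
            raise ValueError(f"unknown window statistic {stat!r}")
    return out


def _plogp_rows(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out.sum(axis=1)


def window_redundancy_values(
    seq: str, window: int, step: int = 1, k: int = 0
) -> np.ndarray:
    """Per-window D_{k+2} (pair-ensemble marginals); NaN for pairless windows."""
    if window < k + 2:
        raise ValueError(f"window {window} too small for lag k={k}")
    codes = encode_bases(seq)
    n = len(codes)
    if n < window:
        return np.empty(0)
    first = codes[: -(k + 1)]
    second = codes[k + 1 :]
    valid = (first < 4) & (second < 4)
    flat = np.where(valid, first.astype(np.int64) * 4 + second, 16)
    onehot = (flat[:, None] == np.arange(16)).astype(np.int64)
    cum = np.vstack([np.zeros((1, 16), dtype=np.int64), np.cumsum(onehot, axis=0)])
    starts = np.arange(0, n - window + 1, step)
    # pairs fully inside window [s, s+window): start positions s .. s+window-k-2
    counts = (cum[starts + window - k - 1] - cum[starts]).astype(float)
    total = counts.sum(axis=1)
    ok = total > 0
    joint = counts / np.maximum(total, 1)[:, None]
    joint_term = _plogp_rows(joint)
    sq = joint.reshape(-1, 4, 4)
    pooled = (sq.sum(axis=2) + sq.sum(axis=1)) / 2.0
    h = -_plogp_rows(pooled)
    out = 2.0 * h + joint_term
    out[~ok] = np.nan
    return out


def window_track_means(values: np.ndarray, window: int, step: int = 1) -> np.ndarray:
    """NaN-aware per-window means of a per-base track slice."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < window:
        return np.empty(0)
    finite = np.isfinite(v)
    cum = np.concatenate([[0.0], np.cumsum(np.where(finite, v, 0.0))])
    cnt = np.concatenate([[0], np.cumsum(finite)])
    starts = np.arange(0, n - window + 1, step)
    s = cum[starts + window] - cum[starts]
    c = cnt[starts + window] - cnt[starts]
    return np.where(c > 0, s / np.maximum(c, 1), np.nan)


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random permutation of the bases of *seq* (composition preserved)."""
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)
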
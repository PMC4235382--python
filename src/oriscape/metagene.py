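"""Anchored (metagene) profiles around replication origins and rank-sum
comparisons of window statistics between region sets.

An anchored profile aligns every anchor interval at its midpoint
(offset 0), evaluates a window statistic in sliding windows across
``[midpoint - flank, midpoint + flank)`` and assigns each window's value
to the offset of its centre; means are taken across anchors per offset.
Anchors truncated by chromosome ends contribute only to the offsets they
cover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import GenomeSequence, GenomicInterval, SignalTrack
from . import signals as sig

SIGNALS = ("gc_profile", "gc_skew", "entropy", "d2", "track")


@dataclass(frozen=True)
class AnchoredProfile:
    """Mean signal per offset relative to a set of anchors."""

    offsets: np.ndarray  # bp relative to anchor midpoint, strictly increasing
    means: np.ndarray  # NaN where no anchor contributed
    counts: np.ndarray  # contributing anchors per offset
    signal: str

    def min_offset(self) -> int:
        """Offset (bp) at which the mean profile is minimal."""
        return int(self.offsets[np.nanargmin(self.means)])

    def max_offset(self) -> int:
        return int(self.offsets[np.nanargmax(self.means)])


@dataclass(frozen=True)
class RegionComparison:
    """Two-group summary plus a two-sided Mann-Whitney U test."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    u_statistic: float
    p_value: float


def _window_values_for(
    seq_or_track: str | np.ndarray, signal: str, window: int, step: int
) -> np.ndarray:
    if signal in ("gc_profile", "gc_skew", "entropy"):
        return sig.window_values(seq_or_track, window, step, stat=signal)
    if signal == "d2":
        return sig.window_redundancy_values(seq_or_track, window, step, k=0)
    if signal == "track":
        return sig.window_track_means(seq_or_track, window, step)
    raise ValueError(f"unknown signal {signal!r}; expected one of {SIGNALS}")


def anchored_profile(
    genome: Sequence[GenomeSequence],
    anchors: Sequence[GenomicInterval],
    signal: str = "gc_profile",
    flank: int = 300,
    window: int = 50,
    step: int = 1,
    track: SignalTrack | None = None,
) -> AnchoredProfile:
    """Mean *signal* in sliding windows around anchor midpoints.

    ``flank`` is the half-width of the profiled region in bp; windows of
    ``window`` bp advance by ``step`` bp and report at their centre offset.
    ``track`` is required iff ``signal == "track"``.
    """
    if not anchors:
        raise ValueError("empty anchor set")
    if flank < window:
        raise ValueError("flank must be >= window")
    if signal == "track" and track is None:
        raise ValueError("signal='track' requires a SignalTrack")
    chroms = {g.name: g for g in genome}
    n_win = (2 * flank - window) // step + 1
    sums = np.zeros(n_win)
    counts = np.zeros(n_win, dtype=np.int64)
    for a in anchors:
        if a.chrom not in chroms:
            raise ValueError(f"anchor chromosome {a.chrom!r} not in genome")
        chrom_len = len(chroms[a.chrom])
        mid = a.midpoint
        starts = mid - flank + np.arange(n_win) * step
        valid = (starts >= 0) & (starts + window <= chrom_len)
        if not valid.any():
            continue
        j = np.flatnonzero(valid)
        lo, hi = int(starts[j[0]]), int(starts[j[-1]]) + window
        if signal == "track":
            data = track.values(a.chrom, lo, hi)
        else:
            data = chroms[a.chrom].seq[lo:hi]
        vals = _window_values_for(data, signal, window, step)
        ok = np.isfinite(vals)
        sums[j[ok]] += vals[ok]
        counts[j[ok]] += 1
    offsets = -flank + np.arange(n_win) * step + window // 2
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AnchoredProfile(offsets, means, counts, signal)


def compare_regions(
    values_a: Sequence[float], values_b: Sequence[float]
) -> RegionComparison:
    """Two-sided Mann-Whitney U comparison of two value sets.

    Exact enumeration when both groups are small (min n <= 8) and tie-free,
    tie-corrected normal approximation otherwise.  Identical constant
    groups return p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must contain at least one finite value")
    summary = dict(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=0)), n_a=len(a),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=0)), n_b=len(b),
    )
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        return RegionComparison(**summary, u_statistic=len(a) * len(b) / 2.0, p_value=1.0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RegionComparison(
        **summary, u_statistic=float(res.statistic), p_value=float(res.pvalue)
    )


def genome_background_windows(
    genome: Sequence[GenomeSequence], window: int = 300, step: int = 300
) -> list[GenomicInterval]:
    """Tile every chromosome with windows; trailing partials discarded."""
    out: list[GenomicInterval] = []
    for g in genome:
        if len(g) < window:
            continue
        region = GenomicInterval(g.name, 0, len(g))
        out.extend(sig.sliding_windows(region, window, step))
    return out


def interval_gc(genome: Sequence[GenomeSequence], iv: GenomicInterval) -> float:
    chroms = {g.name: g for g in genome}
    return sig.gc_profile(sig.count_bases(chroms[iv.chrom].seq[iv.start:iv.end]))


def ori_centered_windows(
    genome: Sequence[GenomeSequence],
    oris: Sequence[GenomicInterval],
    window: int = 300,
    warn_dropped: bool = True,
) -> list[GenomicInterval]:
    """The *window*-bp interval centred on each ORI midpoint (clipped ORIs dropped)."""
    chroms = {g.name: len(g) for g in genome}
    half = window // 2
    kept = []
    dropped = 0
    for o in oris:
        mid = o.midpoint
        start, end = mid - half, mid - half + window
        if start < 0 or end > chroms.get(o.chrom, -1):
            dropped += 1
            continue
        kept.append(GenomicInterval(o.chrom, start, end, ".", o.label))
    if dropped and warn_dropped:
        warnings.warn(f"{dropped} ORI window(s) exceeded chromosome bounds; dropped",
                      stacklevel=2)
    return kept


def ori_vs_genome_gc(
    genome: Sequence[GenomeSequence],
    oris: Sequence[GenomicInterval],
    ori_window: int = 300,
) -> RegionComparison:
    """GC of ORI-centred windows vs genome-wide non-overlapping windows."""
    ori_windows = ori_centered_windows(genome, oris, ori_window)
    if not ori_windows:
        raise ValueError("no usable ORI window")
    background = genome_background_windows(genome, ori_window, ori_window)
    gc_ori = [interval_gc(genome, w) for w in ori_windows]
    gc_bg = [interval_gc(genome, w) for w in background]
    return compare_regions(gc_ori, gc_bg)


def ori_occupancy_contrast(
    track: SignalTrack,
    genome: Sequence[GenomeSequence],
    oris: Sequence[GenomicInterval],
    core_half: int = 75,
    far_from: int = 500,
    flank: int = 1000,
) -> RegionComparison:
    """Mean occupancy in the ORI core [-core_half, +core_half] vs the far
    flanks (beyond +-far_from, within +-flank), one value per ORI per side.
    """
    chroms = {g.name: len(g) for g in genome}
    core_vals, far_vals = [], []
    for o in oris:
        mid = o.midpoint
        n = chroms[o.chrom]
        if mid - flank < 0 or mid + flank > n:
            continue
        vec = track.values(o.chrom, mid - flank, mid + flank)
        rel = np.arange(-flank, flank)
        core = vec[(rel >= -core_half) & (rel <= core_half)]
        far = vec[(rel < -far_from) | (rel > far_from)]
        if np.isfinite(core).any():
            core_vals.append(np.nanmean(core))
        if np.isfinite(far).any():
            far_vals.append(np.nanmean(far))
    return compare_regions(core_vals, far_vals)
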
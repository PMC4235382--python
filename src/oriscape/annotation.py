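"""Positional genomics of replication origins: intergenic-region
orientation classes, per-ORI location categories, and ORI-TSS distances.

Adjacent gene pairs define three kinds of intergenic region: *tandem*
(same strand), *divergent* (<- ->, both promoters inside the gap) and
*convergent* (-> <-, both terminators inside).  Each ORI is assigned
exactly one positional category by its midpoint: one of the three
intergenic classes, or coding head / tail / internal when the midpoint
falls in a gene body (head and tail are the 5'- and 3'-most fractions of
the gene, strand-aware).
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

from .io import GenomicInterval

INTERGENIC_CLASSES = ("tandem", "divergent", "convergent")
ORI_CATEGORIES = (
    "convergent", "tandem", "divergent",
    "coding_head", "coding_tail", "coding_internal",
)


@dataclass(frozen=True)
class IntergenicRegion:
    interval: GenomicInterval
    left_gene: GenomicInterval
    right_gene: GenomicInterval
    cls: str


@dataclass(frozen=True)
class OriLocation:
    ori: GenomicInterval
    category: str
    hit: GenomicInterval | None  # containing gene or intergenic interval


def classify_gene_pair(left_strand: str, right_strand: str) -> str:
    """Orientation class of the gap between two adjacent genes."""
    if left_strand not in ("+", "-") or right_strand not in ("+", "-"):
        raise ValueError("gene strands must be '+' or '-'")
    if (left_strand, right_strand) == ("-", "+"):
        return "divergent"
    if (left_strand, right_strand) == ("+", "-"):
        return "convergent"
    return "tandem"


def _overlap_clusters(genes: list[GenomicInterval]) -> list[list[GenomicInterval]]:
    """Maximal clusters of mutually overlapping genes, sorted by start."""
    ordered = sorted(genes, key=lambda g: (g.start, g.end))
    clusters: list[list[GenomicInterval]] = []
    cur: list[GenomicInterval] = []
    cur_end = -1
    for g in ordered:
        if cur and g.start < cur_end:
            cur.append(g)
            cur_end = max(cur_end, g.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [g]
            cur_end = g.end
    if cur:
        clusters.append(cur)
    return clusters


def build_intergenic_regions(
    genes: Sequence[GenomicInterval],
) -> list[IntergenicRegion]:
    """Intergenic regions between consecutive non-overlapping genes.

    Overlapping genes are merged out of consideration: gaps flanked by a
    multi-gene overlap cluster are excluded, as are zero-length gaps and
    chromosome-terminal gaps (only one flanking gene).
    """
    regions: list[IntergenicRegion] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in by_chrom:
        clusters = _overlap_clusters(by_chrom[chrom])
        for left_c, right_c in zip(clusters, clusters[1:]):
            if len(left_c) != 1 or len(right_c) != 1:
                continue
            left, right = left_c[0], right_c[0]
            if left.end >= right.start:  # abutting: zero-length gap
                continue
            regions.append(
                IntergenicRegion(
                    GenomicInterval(chrom, left.end, right.start),
                    left,
                    right,
                    classify_gene_pair(left.strand, right.strand),
                )
            )
    return regions


def intergenic_class_counts(regions: Sequence[IntergenicRegion]) -> dict[str, int]:
    counts = {cls: 0 for cls in INTERGENIC_CLASSES}
    for r in regions:
        counts[r.cls] += 1
    return counts


def assign_ori_location(
    ori: GenomicInterval,
    genes: Sequence[GenomicInterval],
    intergenic: Sequence[IntergenicRegion],
    head_tail_fraction: float = 0.25,
) -> OriLocation:
    """Positional category of one ORI, decided by its midpoint.

    Midpoints in excluded zones (terminal gaps, merged-overlap zones)
    fall back to ``coding_internal`` with a warning.
    """
    if not 0 < head_tail_fraction < 0.5:
        raise ValueError("head_tail_fraction must be in (0, 0.5)")
    chrom_genes = [g for g in genes if g.chrom == ori.chrom]
    if not chrom_genes:
        raise ValueError(f"no annotation on chromosome {ori.chrom!r}")
    mid = ori.midpoint
    containing = [g for g in chrom_genes if g.start <= mid < g.end]
    if containing:
        if len(containing) > 1:
            warnings.warn(
                f"ORI midpoint {ori.chrom}:{mid} inside overlapping genes; "
                "categorised coding_internal", stacklevel=2,
            )
            return OriLocation(ori, "coding_internal", None)
        gene = containing[0]
        offset_5p = mid - gene.start if gene.strand == "+" else gene.end - 1 - mid
        cut = head_tail_fraction * gene.length
        if offset_5p < cut:
            return OriLocation(ori, "coding_head", gene)
        if offset_5p >= gene.length - cut:
            return OriLocation(ori, "coding_tail", gene)
        return OriLocation(ori, "coding_internal", gene)
    for region in intergenic:
        iv = region.interval
        if iv.chrom == ori.chrom and iv.start <= mid < iv.end:
            return OriLocation(ori, region.cls, iv)
    warnings.warn(
        f"ORI midpoint {ori.chrom}:{mid} in an excluded zone (terminal gap or "
        "merged-overlap zone); categorised coding_internal", stacklevel=2,
    )
    return OriLocation(ori, "coding_internal", None)


def assign_ori_locations(
    oris: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    head_tail_fraction: float = 0.25,
) -> list[OriLocation]:
    intergenic = build_intergenic_regions(genes)
    return [
        assign_ori_location(o, genes, intergenic, head_tail_fraction) for o in oris
    ]


def category_fractions(locations: Sequence[OriLocation]) -> dict[str, float]:
    """Fraction of ORIs per positional category (fractions sum to 1)."""
    if not locations:
        raise ValueError("empty location set")
    counts = {c: 0 for c in ORI_CATEGORIES}
    for loc in locations:
        counts[loc.category] += 1
    n = len(locations)
    return {c: counts[c] / n for c in ORI_CATEGORIES}


def ori_tss_distances(
    oris: Sequence[GenomicInterval],
    tsses: Sequence[GenomicInterval],
    threshold: int = 500,
) -> tuple[list[float | None], float]:
    """Minimal |TSS - ORI midpoint| per ORI and the fraction strictly
    below *threshold* bp (ORIs on TSS-less chromosomes are excluded from
    the fraction with a warning)."""
    if not oris or not tsses:
        raise ValueError("both ORI and TSS sets must be non-empty")
    tss_by_chrom: dict[str, list[int]] = {}
    for t in tsses:
        tss_by_chrom.setdefault(t.chrom, []).append(t.midpoint)
    for positions in tss_by_chrom.values():
        positions.sort()
    distances: list[float | None] = []
    missing = 0
    for o in oris:
        positions = tss_by_chrom.get(o.chrom)
        if not positions:
            distances.append(None)
            missing += 1
            continue
        mid = o.midpoint
        i = bisect_right(positions, mid)
        best = min(
            abs(positions[j] - mid) for j in (i - 1, i) if 0 <= j < len(positions)
        )
        distances.append(float(best))
    if missing:
        warnings.warn(
            f"{missing} ORI(s) on chromosomes without TSSs excluded from summary",
            stacklevel=2,
        )
    defined = [d for d in distances if d is not None]
    if not defined:
        raise ValueError("no ORI has a defined TSS distance")
    fraction = sum(1 for d in defined if d < threshold) / len(defined)
    return distances, fraction
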
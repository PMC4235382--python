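"""Intergenic classification, ORI positional categories, TSS distances.

The toy annotation below is hand-constructed: ten genes on one
chromosome giving two tandem, two divergent and two convergent
intergenic gaps, one abutting pair (no gap) and one overlapping pair
(excluded from intergenic construction).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oriscape import (
    GenomicInterval,
    assign_ori_location,
    assign_ori_locations,
    build_intergenic_regions,
    category_fractions,
    classify_gene_pair,
    intergenic_class_counts,
    ori_tss_distances,
)


def g(start, end, strand, label):
    return GenomicInterval("chrT", start, end, strand, label)


TOY_GENES = [
    g(100, 1100, "+", "g1"),
    g(1300, 2300, "+", "g2"),   # gap [1100,1300) tandem (+,+)
    g(2500, 3500, "-", "g3"),   # gap [2300,2500) convergent (+,-)
    g(3700, 4700, "+", "g4"),   # gap [3500,3700) divergent (-,+)
    g(4900, 5900, "-", "g5"),   # gap [4700,4900) convergent (+,-)
    g(6100, 7100, "-", "g6"),   # gap [5900,6100) tandem (-,-)
    g(7300, 8300, "+", "g7"),   # gap [7100,7300) divergent (-,+)
    g(8300, 9300, "+", "g8"),   # abutting g7: zero-length gap, no region
    g(9500, 10100, "+", "g9"),  # overlaps g10: both merged out
    g(10000, 10800, "+", "g10"),
]

TOY_TSSES = [
    GenomicInterval("chrT", 100, 101, "+", "t1"),
    GenomicInterval("chrT", 1300, 1301, "+", "t2"),
    GenomicInterval("chrT", 3499, 3500, "-", "t3"),
]


@pytest.mark.parametrize(
    "left,right,expected",
    [("-", "+", "divergent"), ("+", "-", "convergent"),
     ("+", "+", "tandem"), ("-", "-", "tandem")],
)
def test_classify_gene_pair(left, right, expected):
    assert classify_gene_pair(left, right) == expected


@settings(max_examples=20, derandomize=True)
@given(left=st.sampled_from("+-"), right=st.sampled_from("+-"))
def test_classify_gene_pair_mirror_symmetry(left, right):
    """Strand-flipping both genes and mirroring coordinates swaps
    divergent and convergent and fixes tandem.  Mirroring alone reverses
    gene order and flips strands, so the composition reduces to an order
    swap with the original strands."""
    direct = classify_gene_pair(left, right)
    composed = classify_gene_pair(right, left)
    swap = {"divergent": "convergent", "convergent": "divergent", "tandem": "tandem"}
    assert composed == swap[direct]


def test_toy_intergenic_regions_exact():
    regions = build_intergenic_regions(TOY_GENES)
    got = [(r.interval.start, r.interval.end, r.cls) for r in regions]
    assert got == [
        (1100, 1300, "tandem"),
        (2300, 2500, "convergent"),
        (3500, 3700, "divergent"),
        (4700, 4900, "convergent"),
        (5900, 6100, "tandem"),
        (7100, 7300, "divergent"),
    ]
    assert intergenic_class_counts(regions) == {
        "tandem": 2, "divergent": 2, "convergent": 2,
    }


def test_toy_simple_pairs():
    two = [g(100, 200, "+", "a"), g(300, 400, "+", "b")]
    (r,) = build_intergenic_regions(two)
    assert (r.interval.start, r.interval.end, r.cls) == (200, 300, "tandem")

    three = [g(100, 200, "+", "a"), g(300, 400, "-", "b"), g(500, 600, "+", "c")]
    regions = build_intergenic_regions(three)
    assert [(r.interval.start, r.interval.end, r.cls) for r in regions] == [
        (200, 300, "convergent"), (400, 500, "divergent"),
    ]

    abutting = [g(100, 200, "+", "a"), g(200, 300, "+", "b")]
    assert build_intergenic_regions(abutting) == []


def test_single_gene_chromosome_yields_nothing():
    assert build_intergenic_regions([g(100, 200, "+", "a")]) == []


def ori(mid, label):
    return GenomicInterval("chrT", mid - 50, mid + 50, ".", label)


def test_toy_ori_categories_exact():
    cases = {
        "tandem": ori(1200, "o1"),          # in gap [1100,1300)
        "convergent": ori(2400, "o2"),
        "divergent": ori(3600, "o3"),
        "coding_head": ori(150, "o4"),      # offset 50 of + gene g1 (< 250)
        "coding_tail": ori(1000, "o5"),     # offset 900 of g1 (>= 750)
        "coding_internal": ori(600, "o6"),  # offset 500: interior
    }
    regions = build_intergenic_regions(TOY_GENES)
    for expected, o in cases.items():
        loc = assign_ori_location(o, TOY_GENES, regions)
        assert loc.category == expected, o.label


def test_minus_strand_head_tail_reversal():
    regions = build_intergenic_regions(TOY_GENES)
    # g3 is - strand [2500, 3500): its 5' end is at 3499
    head = assign_ori_location(ori(3400, "h"), TOY_GENES, regions)
    assert head.category == "coding_head"  # 5' offset 99 < 250
    tail = assign_ori_location(ori(2600, "t"), TOY_GENES, regions)
    assert tail.category == "coding_tail"  # 5' offset 899 >= 750
    # mirror of the spec toy: position 110 of a 100-bp gene
    small = [g(100, 200, "+", "p"), g(100, 200, "-", "m")]
    plus = assign_ori_location(GenomicInterval("chrT", 105, 115, ".", "x"),
                               [small[0], g(400, 500, "+", "q")],
                               build_intergenic_regions([small[0], g(400, 500, "+", "q")]))
    assert plus.category == "coding_head"
    minus = assign_ori_location(GenomicInterval("chrT", 105, 115, ".", "x"),
                                [small[1], g(400, 500, "+", "q")],
                                build_intergenic_regions([small[1], g(400, 500, "+", "q")]))
    assert minus.category == "coding_tail"


def test_excluded_zones_fall_back_with_warning():
    regions = build_intergenic_regions(TOY_GENES)
    with pytest.warns(UserWarning, match="excluded zone"):
        loc = assign_ori_location(ori(50, "telomeric"), TOY_GENES, regions)
    assert loc.category == "coding_internal"
    with pytest.warns(UserWarning, match="overlapping genes"):
        loc = assign_ori_location(ori(10050, "ov"), TOY_GENES, regions)
    assert loc.category == "coding_internal"


def test_every_ori_gets_one_category_and_fractions_sum_to_one(small_bundle):
    locations = assign_ori_locations(small_bundle.oris, small_bundle.genes)
    assert len(locations) == len(small_bundle.oris)
    fractions = category_fractions(locations)
    assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)


def test_ori_tss_distances_strict_threshold():
    oris = [
        GenomicInterval("chrT", 950, 1050, ".", "near"),   # mid 1000
        GenomicInterval("chrT", 450, 550, ".", "boundary"),  # mid 500
    ]
    tsses = [
        GenomicInterval("chrT", 1400, 1401),
        GenomicInterval("chrT", 5000, 5001),
        GenomicInterval("chrT", 1000, 1001),
    ]
    distances, fraction = ori_tss_distances([oris[0]], tsses[:2])
    assert distances == [400.0]
    assert fraction == 1.0
    # distance exactly 500 is NOT counted ("less than 500 bp" is strict)
    distances, fraction = ori_tss_distances([oris[1]], [tsses[2]])
    assert distances == [500.0]
    assert fraction == 0.0


def test_ori_without_tss_chromosome_excluded_with_warning():
    oris = [
        GenomicInterval("chrT", 950, 1050, ".", "a"),
        GenomicInterval("chrU", 100, 200, ".", "b"),
    ]
    tsses = [GenomicInterval("chrT", 1100, 1101)]
    with pytest.warns(UserWarning, match="without TSS"):
        distances, fraction = ori_tss_distances(oris, tsses)
    assert distances == [100.0, None]
    assert fraction == 1.0


def test_tss_proximity_recovered_from_generator(small_bundle):
    _, fraction = ori_tss_distances(small_bundle.oris, small_bundle.tsses)
    assert fraction == pytest.approx(
        small_bundle.spec.tss_proximity_fraction, abs=0.05
    )
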
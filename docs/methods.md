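# Methods

## Scope and model

oriscape analyses replication-origin (ORI) intervals on a genome
sequence through four lenses: windowed composition (GC profile, GC
skew, entropy), base–base correlation (lag-k information redundancy),
positional genomics (intergenic orientation classes, coding head/tail,
ORI–TSS distances), and supervised discrimination (RBF-SVM on window
feature profiles). All analyses operate on plain intervals and
per-base tracks; nothing assumes a particular organism beyond a
single-copy nuclear genome with annotated, stranded genes.

## Coordinates and alphabet

Internally every interval is 0-based half-open (BED convention); GFF3's
1-based inclusive coordinates are converted at the I/O boundary in both
directions, and the conversion is tested to be an identity on round
trips. Sequences are normalised to uppercase `{A,C,G,T,N}`; any other
symbol becomes `N` with a warning. `N` is excluded from every
frequency count: window denominators use only unambiguous bases, and a
base pair containing `N` is skipped in lag-pair counting. Windows with
an empty denominator (all-N composition, no G or C for skew, no valid
pair for redundancy) yield NaN and are excluded from profile means
rather than raising.

## Window statistics

`sliding_windows` emits full windows `[start + m·step, start + m·step +
window)` and discards trailing partial windows, so every window of a
profile has an identical denominator. Defaults mirror the study
design: 50-bp windows at 1-bp step for GC profile and skew, 300/300
non-overlapping tiling for the genome background, 150-bp windows for
the D₂ profile, 300-bp ORI-centred windows for composition contrasts
and classification.

### Information redundancy: marginal convention

The redundancy D_{k+2} = 2H + Σ p_{ij} log₂ p_{ij} needs a definition
of H. We compute H from the pooled first/second-position marginal of
the lag-k pair ensemble (counts of a base appearing as either member of
a counted pair, divided by twice the pair count). By concavity of
entropy, 2·H(pooled) ≥ H(X) + H(Y) ≥ H(X,Y), so D ≥ 0: the statistic
behaves as a mutual information and "zero means independent" holds
exactly. The alternative literal reading — H from whole-sequence base
frequencies — is available via `marginals="sequence"`; on finite
sequences it can go slightly negative because the sequence composition
differs from the pair-ensemble marginals at the boundaries. "Distance
k" means k intervening bases: k = 0 is the adjacent-pair term D₂, and
log base 2 makes all quantities bits.

### Spectrum averaging over ORI sets

The averaged D_{k+2} spectrum over an ORI set pools the 4×4 lag-pair
counts across all sequences before forming D, treating the set as draws
from one ensemble. The alternative (mean of per-sequence spectra,
available as `method="mean"`) carries the plug-in mutual-information
bias ≈ (4−1)²/(2N ln 2) bits for N counted pairs — about 0.02 bits on a
300-bp window — which would swamp the near-zero spectrum of an
independent sequence; pooling across 100 ORIs divides the bias by the
set size and leaves the null spectrum below 10⁻³ bits. Spectra are
computed on fixed-length ORI-centred windows (default 300 bp) so every
sequence contributes the same number of pairs per lag.

## Metagene profiles

Anchors are ORI interval midpoints (`floor((start+end)/2)`) — symmetric
and length-independent, since ORI interval lengths vary. Each sliding
window's value is assigned to the offset of its centre
(`window // 2` from the window start), giving symmetric smoothing with
the dip/peak centred at offset 0. Means are taken per offset across
anchors; anchors truncated by chromosome ends contribute only to
offsets whose windows lie fully on the chromosome, and the
per-offset contributing count is reported alongside the mean. ORI
strand is ignored: GC profile is strand-symmetric, and the GC skew
profile is computed on the plus strand for all anchors because no
per-ORI orientation is defined — a caveat for interpreting skew sign
changes at the anchor.

## Region comparisons

`compare_regions` is a two-sided Mann–Whitney U test: exact enumeration
when both groups are small (min n ≤ 8) and tie-free — cheap and exact —
and the tie-corrected normal approximation otherwise
(scipy.stats.mannwhitneyu supplies both). Two identical constant
groups short-circuit to p = 1 with a warning. The nucleosome contrast
statistic compares per-ORI mean occupancy in the core (offsets −75..+75)
against the far flanks (beyond ±500 bp, within the ±1000-bp profile
span), one value per ORI per side.

## Positional genomics

Gene pairs classify their gap by strands alone: (−,+) divergent (both
promoters inside the gap), (+,−) convergent (both terminators inside),
same-strand tandem. Intergenic regions are built per chromosome from
genes sorted by start; overlapping genes are merged into clusters and
excluded — only gaps flanked by two single (non-overlapping) genes form
regions — and zero-length gaps and chromosome-terminal gaps (one
flanking gene, orientation undefined) are skipped.

Each ORI gets exactly one category from its midpoint: the containing
intergenic region's class, or, inside a gene body, coding head / tail /
internal where head and tail are the 5′- and 3′-most
`head_tail_fraction` (default 0.25) of the gene length, strand-aware.
The midpoint rule (rather than any-overlap) makes the categories a
partition, so fractions sum to 1. Midpoints in excluded zones fall
back to `coding_internal` with a warning. ORI–TSS distance is the
minimum over same-chromosome TSSs of |TSS − ORI midpoint|; the summary
fraction uses a strict `< threshold` comparison (default 500 bp), so a
distance of exactly 500 is not counted.

## Classification

Positives are 300-bp windows centred on ORI midpoints; negatives are
the abutting 300 bp immediately upstream (lower coordinates; ORIs are
unstranded). Negatives that run off the chromosome or overlap another
ORI's positive window are dropped with a warning (label-noise control).
Feature vectors are the per-window signal values across the instance —
251 dims for GC profile/skew (50-bp windows, 1-bp step), 151 dims for
D₂ (150-bp windows), 300 per-base values for nucleosome occupancy —
because scalar means would reduce the compositional families to one
dimension; a `scalar` feature mode is kept for comparison. Evaluation
is stratified k-fold cross-validation (default 10 folds, seeded
shuffle): within each fold, imputation means (for NaN features),
standardisation parameters and zero-variance feature drops are fitted
on the training split only, and an SVC with RBF kernel, C = 1 and
`gamma="scale"` (inverse of feature count × variance) is trained.
Confusion totals are pooled over held-out folds; Sn = TP/(TP+FN),
Sp = TN/(TN+FP), Acc = (TP+TN)/total. With a fixed seed the whole
procedure is bit-reproducible.

## Synthetic-data generator

The generator is the package's test-bed: it plants the signal structure
the analyses look for, with each axis independently switchable.

- **Background**: iid bases at GC 0.38 (A=T, C=G within the
  constraint).
- **Genes/TSSs**: sequential tiling of gene lengths ~N(1500, 375²) (min
  300) and gaps ~N(400, 100²) (min 60) with uniform random strands —
  producing all three intergenic classes at roughly 2:1:1
  tandem:divergent:convergent — and one TSS at each gene's 5′ end with
  N(0, 25²) jitter. Lengths are yeast-like in scale; the tiling is not
  a karyotype model.
- **ORIs**: 100 non-overlapping 300-bp intervals. A fraction (0.31) is
  placed strictly within 500 bp of a random TSS and the remainder is
  rejection-sampled to lie ≥ 500 bp from every TSS, so the planted
  proximity rate equals the target up to rounding and is recoverable as
  a parameter. ORI interiors are resampled at GC 0.317; when the ACS
  motif (T/A)TTTAT(A/G)TTT(T/A) is planted (one instance at the ORI
  centre, degenerate positions uniform, random strand), the interior GC
  is adjusted for the motif's expected 0.5 G+C bases so the whole
  window still hits 0.317 in expectation. Optional first-order
  structure uses the copy-previous-with-probability-λ chain (λ = 0.3,
  transition matrix λI + (1−λ)·1πᵀ with the ORI composition π as
  stationary distribution): its lag-m dependence decays as λ^m, so the
  redundancy spectrum peaks at the adjacent term by construction.
- **Nucleosome track**: a phenomenological positive sinusoid of 165-bp
  period with Gaussian noise, multiplied by Gaussian depletion
  envelopes (depth 0.8, width 300 bp) at ORI midpoints and shallower
  ones (0.5, 200 bp) at promoters, clipped at zero. It reproduces the
  depletion contrast, not nucleosome positioning.
- **Null mode** disables *everything* ORI-specific — composition,
  motif, Markov structure, ORI *and* promoter depletion, and the
  TSS-biased placement — so null ORIs are exchangeable with background
  and every downstream contrast is calibrated at its nominal level.

What the generator does **not** emulate: real yeast karyotype and
isochore structure, replication timing, ACS positional degeneracy and
multiplicity, overlapping genes (rare in yeast and merged out of the
intergenic logic anyway), nucleosome phasing off barriers, and
measurement noise of occupancy assays. Passing tests therefore show
that the pipeline recovers the stated signal structure when present and
stays quiet when absent — not that real OriDB/GenBank data would yield
any particular effect size.

## Problem sizes and numerical choices

Tests and the reproduction script run on the generator defaults (one
1-Mb chromosome, 100 ORIs, ~530 genes), which gives ~3,300 background
windows and ~200 classification instances — large enough for every
contrast to be decisive (rank-sum p well below 10⁻³⁰) while keeping a
full run in seconds. All randomness flows from a single
`numpy.random.default_rng` seed per bundle and a seeded fold shuffle,
making bundles and pipeline outputs byte-reproducible; floats in
reports are written at six significant digits. Degenerate inputs are
handled as: undefined windows → NaN, excluded from means; identical
comparison groups → p = 1 with warning; all-degenerate feature fold →
error; infeasible ORI placement → error after bounded retries.

## Known limitations

- GC-skew metagene interpretation is orientation-blind (plus-strand
  convention), so antisymmetric per-ORI skew patterns can cancel in the
  mean when origins fire in mixed orientations.
- The redundancy spectrum on strictly periodic sequences is flat at its
  ceiling (every lag is informative), so "argmax at D₂" is a property
  of decaying short-range dependence, not of dependence per se.
- Per-sequence redundancy estimates on short windows are biased upward
  by ~(9/2N ln 2) bits; use the pooled spectrum (the default) for
  near-zero comparisons.
- The intergenic construction ignores nested/overlapping gene
  architecture beyond merging it out; genomes with pervasive overlap
  would leave many ORIs in excluded zones.
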
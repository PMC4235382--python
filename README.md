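# oriscape

Sequence-signature analysis of DNA replication origins (ORIs) in the
budding-yeast genome: compositional bias, base–base correlation,
chromatin context and SVM-based discrimination of ORI windows, packaged
as a reusable, tested pipeline with a synthetic-genome generator so that
every stage can be validated without external downloads.

## Who this is for

Researchers studying replication initiation in *Saccharomyces
cerevisiae* (or any compact eukaryotic genome) who want to ask: do my
origin intervals carry a compositional footprint? Are they depleted of
nucleosomes? Where do they sit relative to genes and transcription start
sites (TSSs)? And how well do simple sequence signals discriminate
origins from flanking DNA?

## The statistics at the core

For a sliding window *i* with base frequencies *f_i*(A), *f_i*(C),
*f_i*(G), *f_i*(T):

- **GC profile** = (*f_i*(G) + *f_i*(C)) / (*f_i*(A) + *f_i*(C) +
  *f_i*(G) + *f_i*(T)), in [0, 1]. Yeast ORIs are AT-rich, so the
  anchored profile dips at the origin.
- **GC skew** = (*f_i*(G) − *f_i*(C)) / (*f_i*(G) + *f_i*(C)), in
  [−1, 1]; its sign change marks replication origins in bacterial
  replichores.
- **Informational entropy** *H* = −Σ_a *p_a* log₂ *p_a* (bits, ≤ 2 for
  DNA).
- **k-order information redundancy**
  *D*<sub>k+2</sub> = 2*H* + Σ_{ij} *p_i*(k)*j* log₂ *p_i*(k)*j*,
  where *p_i*(k)*j* is the joint probability of base *j* following base
  *i* with *k* intervening bases (*k* = 0 is adjacent). With *H* taken
  from the marginals of the lag-k pair ensemble (the default), this is a
  mutual information: zero for an independent sequence, large where
  bases are correlated. ORI sequences show a short-range dominance —
  the spectrum over *k* + 2 = 2…50 peaks at *D*₂.

Downstream, the pipeline aggregates these signals into anchored
(metagene) profiles around ORI midpoints, contrasts ORI windows against
the genome with a Mann–Whitney U test, classifies intergenic regions as
tandem / divergent / convergent from flanking-gene orientation, assigns
each ORI a positional category (intergenic class or coding head / tail /
internal), measures ORI–TSS distances, and cross-validates an
RBF-kernel SVM on per-family feature profiles (sensitivity,
specificity, accuracy from pooled 10-fold confusion totals).

## Worked example

Generate a synthetic bundle with the study conditions — a 1-Mb
chromosome at background GC 0.38 with 100 planted 300-bp ORIs at GC
0.317, each carrying one ARS-consensus motif (T/A)TTTAT(A/G)TTT(T/A)
and first-order adjacent-base structure, plus genes, TSSs and a
nucleosome occupancy track depleted over ORIs and promoters — then run
the full pipeline:

```bash
oriscape simulate --outdir bundle --seed 7
cat > config.yaml <<EOF
genome: bundle/genome.fasta
oris: bundle/oris.bed
genes: bundle/genes.gff3
tss: bundle/tss.bed
track: bundle/nucleosome.bedgraph
outdir: results
seed: 7
EOF
oriscape run --config config.yaml
```

`results/summary.txt` then reports (abridged):

```
ORI vs genome GC (300 bp windows): mean(ORI) = 0.310767 (n=100), mean(genome) = 0.377702 (n=3333), U = 22969, p = 4.75716e-49
GC-profile dip offset (bp from ORI midpoint): -17
nucleosome occupancy, ORI core vs far flanks: mean(core) = 0.111092, mean(far) = 0.447191, p = 2.56214e-34
D_(k+2) spectrum (k_max=48): max at k+2 = 2, value 0.158527 bits
intergenic regions: tandem=278, divergent=126, convergent=125
ORIs within 500 bp of a TSS: 0.31
SVM 10-fold CV (Sn / Sp / Acc):
  gc_profile: 0.9000 / 0.9184 / 0.9091
  gc_skew: 0.7700 / 0.8878 / 0.8283
  d2: 1.0000 / 1.0000 / 1.0000
  nucleosome: 1.0000 / 0.9898 / 0.9949
```

Reading: ORI windows are markedly AT-richer than the genome tiling
(0.311 vs 0.378, vanishing rank-sum p); the anchored GC profile dips at
the origin midpoint (−17 bp, within half a window of 0); occupancy in
the ORI core is a quarter of the far-flank level (the planted
nucleosome-depleted region); the redundancy spectrum peaks at the
adjacent-pair term *D*₂; the planted TSS-proximity rate (31 %) is
recovered exactly; and every feature family separates ORI windows from
their upstream neighbours well above chance. Per-offset profile tables,
the *D* spectrum, intergenic counts, per-ORI categories and the CV
table are written alongside as TSV files, and re-running the same
config reproduces every output byte-for-byte.

The stages are also available individually (`oriscape signals`,
`profile`, `annotate`, `classify`) and as a Python API
(`oriscape.generate`, `oriscape.anchored_profile`,
`oriscape.cross_validate_svm`, …).

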
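"""Synthetic genome bundles with the signal structure of budding-yeast
replication origins, for end-to-end pipeline testing without downloads.

The generator plants four independently tunable signal axes on an iid
background genome (GC 0.38 by default):

* **GC depression** — ORI intervals are resampled AT-rich (GC 0.317 by
  default), with the interior composition adjusted so the whole window
  hits the target despite the planted motif;
* **ACS motif** — one 11-mer instance of the ARS consensus
  (T/A)TTTAT(A/G)TTT(T/A) at each ORI centre, on a random strand;
* **adjacent-base correlation** — an optional first-order Markov chain
  inside ORIs (transition matrix ``lam * I + (1 - lam) * 1 pi^T`` with
  the ORI composition as stationary distribution), which elevates D_2
  and decays geometrically with lag;
* **nucleosome depletion** — a phenomenological occupancy track
  (positive sinusoid of ~165-bp period plus noise) multiplied by
  Gaussian depletion envelopes at ORIs and promoters.

Gene/gap tiling with random strands yields tandem, divergent and
convergent intergenic regions; TSSs sit at gene 5' ends with jitter; a
configurable fraction of ORIs is placed within 500 bp of a TSS and the
remainder strictly farther away, so the planted proximity rate is exact
up to rounding.

``generate_null`` disables every planted signal (including TSS-biased
placement and promoter depletion) so null ORIs are exchangeable with
background sequence — the negative control for every downstream
contrast.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    GenomeSequence,
    GenomicInterval,
    SignalTrack,
    reverse_complement,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gff3_genes,
    write_tsv_report,
)

# ARS consensus (T/A)TTTAT(A/G)TTT(T/A): allowed bases per position
ACS_CONSENSUS: tuple[str, ...] = (
    "TA", "T", "T", "T", "A", "T", "AG", "T", "T", "T", "TA"
)
ACS_LENGTH = len(ACS_CONSENSUS)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic bundle; defaults are the study conditions."""

    chrom_lengths: tuple[int, ...] = (1_000_000,)
    background_gc: float = 0.38
    ori_count: int = 100
    ori_length: int = 300
    ori_gc: float = 0.317
    plant_acs: bool = True
    plant_markov: bool = True
    markov_strength: float = 0.3  # P(copy previous base); 0 = iid
    mean_gene_length: int = 1500
    mean_gap: int = 400
    min_gene_length: int = 300
    min_gap: int = 60
    tss_jitter: int = 25
    tss_proximity_fraction: float = 0.31
    tss_proximity_bp: int = 500
    nucleosome_period: int = 165
    nucleosome_amplitude: float = 1.0
    nucleosome_noise: float = 0.05
    ndr_depth: float = 0.8
    ndr_width: int = 300
    promoter_ndr_depth: float = 0.5
    promoter_ndr_width: int = 200
    edge_margin: int = 2000  # keep ORIs clear of chromosome ends
    seed: int = 0
    null: bool = False

    def __post_init__(self) -> None:
        for name in ("background_gc", "ori_gc", "tss_proximity_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if min(self.chrom_lengths) < 1 or self.ori_length < ACS_LENGTH:
            raise ValueError("lengths must be positive (ORI >= motif length)")
        if self.ori_count * self.ori_length >= sum(self.chrom_lengths) / 2:
            raise ValueError("ORIs would cover more than half the genome")
        if not 0 <= self.markov_strength < 1:
            raise ValueError("markov_strength must be in [0, 1)")


@dataclass
class SyntheticBundle:
    genome: list[GenomeSequence]
    oris: list[GenomicInterval]
    genes: list[GenomicInterval]
    tsses: list[GenomicInterval]
    track: SignalTrack
    manifest: dict[str, object]
    spec: GeneratorSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle as FASTA/BED/GFF3/bedGraph/TSV files."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fasta",
            "oris": out / "oris.bed",
            "genes": out / "genes.gff3",
            "tss": out / "tss.bed",
            "track": out / "nucleosome.bedgraph",
            "manifest": out / "manifest.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_bed(self.oris, paths["oris"])
        write_gff3_genes(self.genes, paths["genes"])
        write_bed(self.tsses, paths["tss"])
        write_bedgraph(self.track, paths["track"])
        rows = [
            {"key": k, "value": v if not isinstance(v, float) else float(v)}
            for k, v in self.manifest.items()
        ]
        write_tsv_report(rows, paths["manifest"], columns=["key", "value"])
        return paths


def _composition(gc: float) -> np.ndarray:
    """Base probabilities (A, C, G, T) for a given GC fraction."""
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def _interior_gc(spec: GeneratorSpec) -> float:
    """ORI interior GC adjusted so the whole window hits ori_gc on average."""
    if not spec.plant_acs:
        return spec.ori_gc
    motif_gc = 0.5  # only position 7 (A/G) can contribute G, with prob 1/2
    g = (spec.ori_gc * spec.ori_length - motif_gc) / (spec.ori_length - ACS_LENGTH)
    if not 0 < g < 1:
        raise ValueError("ori_gc infeasible with the planted motif")
    return g


def _sample_iid(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=n, p=probs)


def _sample_markov(rng: np.random.Generator, n: int, probs: np.ndarray,
                   lam: float) -> np.ndarray:
    """First-order chain: copy the previous base with prob lam, else draw iid."""
    iid = rng.choice(4, size=n, p=probs)
    stay = rng.random(n) < lam
    codes = iid.copy()
    for t in range(1, n):
        if stay[t]:
            codes[t] = codes[t - 1]
    return codes


def _sample_acs(rng: np.random.Generator) -> str:
    motif = "".join(choices[rng.integers(len(choices))] for choices in ACS_CONSENSUS)
    if rng.random() < 0.5:
        motif = reverse_complement(motif)
    return motif


def _place_genes(
    rng: np.random.Generator, spec: GeneratorSpec, chrom: str, length: int,
    gene_offset: int,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    genes: list[GenomicInterval] = []
    tsses: list[GenomicInterval] = []
    pos = spec.edge_margin
    i = gene_offset
    while True:
        glen = max(spec.min_gene_length,
                   int(round(rng.normal(spec.mean_gene_length, spec.mean_gene_length / 4))))
        if pos + glen > length - spec.edge_margin:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        i += 1
        gene = GenomicInterval(chrom, pos, pos + glen, strand, f"gene{i}")
        genes.append(gene)
        five_prime = gene.start if strand == "+" else gene.end - 1
        tss = five_prime + int(round(rng.normal(0, spec.tss_jitter)))
        tss = int(np.clip(tss, 0, length - 1))
        tsses.append(GenomicInterval(chrom, tss, tss + 1, strand, f"tss{i}"))
        gap = max(spec.min_gap, int(round(rng.normal(spec.mean_gap, spec.mean_gap / 4))))
        pos += glen + gap
    return genes, tsses


def _min_tss_distance(mid: int, tss_positions: np.ndarray) -> int:
    return int(np.abs(tss_positions - mid).min())


def _place_oris(
    rng: np.random.Generator, spec: GeneratorSpec, chrom: str, length: int,
    n_ori: int, tsses: Sequence[GenomicInterval], ori_offset: int,
    max_tries: int = 2000,
) -> list[GenomicInterval]:
    half = spec.ori_length // 2
    tss_positions = np.array([t.start for t in tsses]) if tsses else np.empty(0, int)
    lo = spec.edge_margin
    hi = length - spec.edge_margin
    placed: list[GenomicInterval] = []

    def free(start: int, end: int) -> bool:
        return all(end <= o.start or o.end <= start for o in placed)

    n_near = 0 if spec.null else int(round(spec.tss_proximity_fraction * n_ori))
    for i in range(n_ori):
        want_near = i < n_near and len(tss_positions) > 0
        for _ in range(max_tries):
            if want_near:
                tss = int(tss_positions[rng.integers(len(tss_positions))])
                offset = int(rng.integers(0, spec.tss_proximity_bp))
                mid = tss + offset if rng.random() < 0.5 else tss - offset
            else:
                mid = int(rng.integers(lo + half, hi - half))
            start, end = mid - half, mid - half + spec.ori_length
            if start < lo or end > hi or not free(start, end):
                continue
            if not spec.null:
                d = _min_tss_distance(mid, tss_positions) if len(tss_positions) else 10**9
                if want_near and d >= spec.tss_proximity_bp:
                    continue
                if not want_near and d < spec.tss_proximity_bp:
                    continue
            placed.append(GenomicInterval(chrom, start, end, ".",
                                          f"ori{ori_offset + len(placed) + 1}"))
            break
        else:
            raise RuntimeError(
                f"could not place ORI {i + 1} on {chrom} after {max_tries} tries"
            )
    return placed


def _nucleosome_track(
    rng: np.random.Generator, spec: GeneratorSpec, length: int,
    oris: Sequence[GenomicInterval], tsses: Sequence[GenomicInterval],
) -> np.ndarray:
    x = np.arange(length)
    phase = rng.uniform(0, 2 * np.pi)
    occ = spec.nucleosome_amplitude * 0.5 * (1 + np.sin(2 * np.pi * x / spec.nucleosome_period + phase))
    occ = occ + rng.normal(0, spec.nucleosome_noise, size=length)
    occ = np.clip(occ, 0.0, None)
    envelope = np.ones(length)

    def deplete(center: int, depth: float, width: int) -> None:
        sigma = width / 2.0
        span = int(4 * sigma)
        a, b = max(0, center - span), min(length, center + span)
        local = np.arange(a, b)
        envelope[a:b] *= 1.0 - depth * np.exp(-((local - center) ** 2) / (2 * sigma**2))

    if not spec.null:
        for o in oris:
            deplete(o.midpoint, spec.ndr_depth, spec.ndr_width)
        for t in tsses:
            deplete(t.start, spec.promoter_ndr_depth, spec.promoter_ndr_width)
    return occ * envelope


def generate(spec: GeneratorSpec) -> SyntheticBundle:
    """Generate a deterministic bundle (genome, ORIs, genes, TSSs, track)."""
    rng = np.random.default_rng(spec.seed)
    bg_probs = _composition(spec.background_gc)
    interior = _composition(_interior_gc(spec))
    total_len = sum(spec.chrom_lengths)

    genome: list[GenomeSequence] = []
    all_oris: list[GenomicInterval] = []
    all_genes: list[GenomicInterval] = []
    all_tsses: list[GenomicInterval] = []
    track_data: dict[str, np.ndarray] = {}

    remaining_oris = spec.ori_count
    for ci, length in enumerate(spec.chrom_lengths):
        chrom = f"chr{ci + 1}"
        if ci == len(spec.chrom_lengths) - 1:
            n_ori = remaining_oris
        else:
            n_ori = int(round(spec.ori_count * length / total_len))
            remaining_oris -= n_ori

        genes, tsses = _place_genes(rng, spec, chrom, length, len(all_genes))
        oris = _place_oris(rng, spec, chrom, length, n_ori, tsses, len(all_oris))

        codes = _sample_iid(rng, length, bg_probs)
        if not spec.null:
            for o in oris:
                n = o.length
                if spec.plant_markov:
                    ori_codes = _sample_markov(rng, n, interior, spec.markov_strength)
                else:
                    ori_codes = _sample_iid(rng, n, interior)
                codes[o.start:o.end] = ori_codes
                if spec.plant_acs:
                    motif = _sample_acs(rng)
                    m0 = o.midpoint - ACS_LENGTH // 2
                    codes[m0:m0 + ACS_LENGTH] = [
                        "ACGT".index(b) for b in motif
                    ]
        seq = "".join(_BASES[codes])
        genome.append(GenomeSequence(chrom, seq))
        track_data[chrom] = _nucleosome_track(rng, spec, length, oris, tsses)

        all_genes.extend(genes)
        all_tsses.extend(tsses)
        all_oris.extend(oris)

    track = SignalTrack(track_data)

    # realized planted properties
    ori_gc_values = []
    for o in all_oris:
        g = next(gs for gs in genome if gs.name == o.chrom)
        window = g.seq[o.start:o.end]
        ori_gc_values.append((window.count("G") + window.count("C")) / len(window))
    tss_pos_by_chrom = {
        g.name: np.array([t.start for t in all_tsses if t.chrom == g.name])
        for g in genome
    }
    near = sum(
        1 for o in all_oris
        if len(tss_pos_by_chrom[o.chrom])
        and _min_tss_distance(o.midpoint, tss_pos_by_chrom[o.chrom]) < spec.tss_proximity_bp
    )
    manifest: dict[str, object] = {
        "null": spec.null,
        "seed": spec.seed,
        "genome_length": total_len,
        "n_chromosomes": len(spec.chrom_lengths),
        "n_oris": len(all_oris),
        "n_genes": len(all_genes),
        "n_tsses": len(all_tsses),
        "background_gc_target": spec.background_gc,
        "ori_gc_target": spec.ori_gc,
        "ori_gc_realized": float(np.mean(ori_gc_values)),
        "tss_proximity_target": (
            spec.tss_proximity_fraction if not spec.null else float("nan")
        ),
        "tss_proximity_realized": near / len(all_oris) if all_oris else float("nan"),
        "acs_planted": spec.plant_acs and not spec.null,
        "markov_planted": spec.plant_markov and not spec.null,
        "markov_strength": spec.markov_strength,
        "ndr_depth": spec.ndr_depth if not spec.null else 0.0,
    }
    return SyntheticBundle(genome, all_oris, all_genes, all_tsses, track, manifest, spec)


def generate_null(spec: GeneratorSpec) -> SyntheticBundle:
    """Same bundle geometry, but every ORI-specific signal disabled."""
    return generate(dataclasses.replace(spec, null=True))
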
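"""End-to-end orchestration: signals -> metagene -> annotation -> classify.

``run_all`` reads a genome, ORI set, gene annotation, TSS set and
(optionally) a nucleosome occupancy track, runs every analysis stage
with the configured window parameters, and writes per-stage TSVs plus a
single plain-text summary.  Every number in the summary is re-derivable
from the stage TSVs, and re-running with the same config and inputs is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import annotation, classify, metagene, signals
from .io import (
    read_bed,
    read_bedgraph,
    read_fasta,
    read_gff3_genes,
    write_tsv_report,
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""


@dataclass(frozen=True)
class RunConfig:
    """Input paths and analysis parameters (defaults match the published
    study design: 50/1 GC windows, 300/300 background, 150-bp D_2 windows,
    k_max 48, +-1000 bp nucleosome flank, 500-bp TSS threshold, 300-bp
    instances, 10-fold CV)."""

    genome: str
    oris: str
    genes: str | None = None
    tss: str | None = None
    track: str | None = None
    outdir: str = "oriscape_out"
    gc_window: int = 50
    gc_step: int = 1
    background_window: int = 300
    background_step: int = 300
    d2_window: int = 150
    d2_step: int = 1
    k_max: int = 48
    profile_flank: int = 300
    nucleosome_flank: int = 1000
    tss_threshold: int = 500
    instance_window: int = 300
    head_tail_fraction: float = 0.25
    folds: int = 10
    seed: int = 0
    redundancy_marginals: str = "pairs"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def _write_profile(profile: metagene.AnchoredProfile, path: Path) -> None:
    rows = [
        {"offset": int(o), "mean": float(m), "count": int(c)}
        for o, m, c in zip(profile.offsets, profile.means, profile.counts)
    ]
    write_tsv_report(rows, path, columns=["offset", "mean", "count"])


def _write_comparison(cmp: metagene.RegionComparison, path: Path, label: str) -> None:
    write_tsv_report(
        [{
            "comparison": label,
            "mean_a": cmp.mean_a, "sd_a": cmp.sd_a, "n_a": cmp.n_a,
            "mean_b": cmp.mean_b, "sd_b": cmp.sd_b, "n_b": cmp.n_b,
            "U": cmp.u_statistic, "p_value": cmp.p_value,
        }],
        path,
        columns=["comparison", "mean_a", "sd_a", "n_a", "mean_b", "sd_b", "n_b",
                 "U", "p_value"],
    )


def run_all(config: RunConfig) -> dict[str, object]:
    """Execute every stage; returns the computed result objects."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    summary: list[str] = ["oriscape pipeline summary", "=" * 26, ""]
    summary.append("parameters:")
    for f in dataclasses.fields(RunConfig):
        summary.append(f"  {f.name} = {getattr(config, f.name)}")
    summary.append("")

    def stage(name: str):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - single abort point
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("load_inputs")
    def _inputs():
        genome = read_fasta(config.genome)
        oris = read_bed(config.oris)
        genes = read_gff3_genes(config.genes) if config.genes else None
        tsses = read_bed(config.tss) if config.tss else None
        track = read_bedgraph(config.track, genome) if config.track else None
        return genome, oris, genes, tsses, track

    genome, oris, genes, tsses, track = _inputs

    @stage("gc_comparison")
    def _gc_cmp():
        cmp = metagene.ori_vs_genome_gc(genome, oris, config.background_window)
        _write_comparison(cmp, out / "gc_comparison.tsv", "ori_vs_genome_gc")
        summary.append(
            f"ORI vs genome GC ({config.background_window} bp windows): "
            f"mean(ORI) = {_fmt(cmp.mean_a)} (n={cmp.n_a}), "
            f"mean(genome) = {_fmt(cmp.mean_b)} (n={cmp.n_b}), "
            f"U = {_fmt(cmp.u_statistic)}, p = {_fmt(cmp.p_value)}"
        )
        return cmp

    results["gc_comparison"] = _gc_cmp

    @stage("metagene_profiles")
    def _profiles():
        profiles = {}
        for name, window, step in (
            ("gc_profile", config.gc_window, config.gc_step),
            ("gc_skew", config.gc_window, config.gc_step),
            ("d2", config.d2_window, config.d2_step),
        ):
            p = metagene.anchored_profile(
                genome, oris, signal=name, flank=config.profile_flank,
                window=window, step=step,
            )
            _write_profile(p, out / f"profile_{name}.tsv")
            profiles[name] = p
        summary.append(
            "GC-profile dip offset (bp from ORI midpoint): "
            f"{profiles['gc_profile'].min_offset()}"
        )
        summary.append(
            f"D2 profile peak offset (bp): {profiles['d2'].max_offset()}"
        )
        if track is not None:
            p = metagene.anchored_profile(
                genome, oris, signal="track", flank=config.nucleosome_flank,
                window=1, step=1, track=track,
            )
            _write_profile(p, out / "profile_nucleosome.tsv")
            profiles["nucleosome"] = p
            contrast = metagene.ori_occupancy_contrast(
                track, genome, oris, flank=config.nucleosome_flank,
            )
            _write_comparison(contrast, out / "nucleosome_contrast.tsv",
                              "ori_core_vs_far_occupancy")
            results["nucleosome_contrast"] = contrast
            summary.append(
                "nucleosome occupancy, ORI core vs far flanks: "
                f"mean(core) = {_fmt(contrast.mean_a)}, "
                f"mean(far) = {_fmt(contrast.mean_b)}, p = {_fmt(contrast.p_value)}"
            )
        return profiles

    results["profiles"] = _profiles

    @stage("redundancy_spectrum")
    def _spectrum():
        windows = metagene.ori_centered_windows(genome, oris, config.instance_window)
        chroms = {g.name: g for g in genome}
        seqs = [chroms[w.chrom].seq[w.start:w.end] for w in windows]
        spec = signals.average_redundancy_spectrum(seqs, config.k_max)
        rows = [
            {"gap": int(g), "D": float(v)} for g, v in zip(spec.gaps, spec.values)
        ]
        write_tsv_report(rows, out / "d2_spectrum.tsv", columns=["gap", "D"])
        summary.append(
            f"D_(k+2) spectrum (k_max={config.k_max}): max at k+2 = "
            f"{spec.argmax_gap}, value {_fmt(float(np.max(spec.values)))} bits"
        )
        return spec

    results["spectrum"] = _spectrum

    if genes is not None:
        @stage("annotation")
        def _annot():
            regions = annotation.build_intergenic_regions(genes)
            counts = annotation.intergenic_class_counts(regions)
            write_tsv_report(
                [{"class": k, "count": v} for k, v in counts.items()],
                out / "intergenic_counts.tsv", columns=["class", "count"],
            )
            locations = annotation.assign_ori_locations(
                oris, genes, config.head_tail_fraction
            )
            fractions = annotation.category_fractions(locations)
            write_tsv_report(
                [{"category": k, "fraction": v} for k, v in fractions.items()],
                out / "ori_categories.tsv", columns=["category", "fraction"],
            )
            summary.append(
                "intergenic regions: "
                + ", ".join(f"{k}={v}" for k, v in counts.items())
            )
            summary.append(
                "ORI categories: "
                + ", ".join(f"{k}={_fmt(v)}" for k, v in fractions.items())
            )
            result: dict[str, object] = {
                "regions": regions, "counts": counts,
                "locations": locations, "fractions": fractions,
            }
            if tsses is not None:
                distances, fraction = annotation.ori_tss_distances(
                    oris, tsses, config.tss_threshold
                )
                rows = [
                    {
                        "ori": o.label if o.label else f"{o.chrom}:{o.start}-{o.end}",
                        "category": loc.category,
                        "tss_distance": float("nan") if d is None else d,
                    }
                    for o, loc, d in zip(oris, locations, distances)
                ]
                write_tsv_report(rows, out / "ori_locations.tsv",
                                 columns=["ori", "category", "tss_distance"])
                summary.append(
                    f"ORIs within {config.tss_threshold} bp of a TSS: "
                    f"{_fmt(fraction)}"
                )
                result["tss_distances"] = distances
                result["tss_fraction"] = fraction
            return result

        results["annotation"] = _annot

    @stage("classify")
    def _classify():
        families = ["gc_profile", "gc_skew", "d2"]
        if track is not None:
            families.append("nucleosome")
        reports = []
        for family in families:
            instances = classify.build_instance_sets(
                genome, oris, family=family, track=track,
                instance_window=config.instance_window,
                signal_window=config.gc_window, d2_window=config.d2_window,
            )
            reports.append(
                classify.cross_validate_svm(
                    instances, folds=config.folds, seed=config.seed
                )
            )
        table = classify.report_table(reports)
        rows = table.to_dict(orient="records")
        write_tsv_report(rows, out / "cv_table.tsv", columns=list(table.columns))
        summary.append("SVM 10-fold CV (Sn / Sp / Acc):")
        for r in reports:
            summary.append(
                f"  {r.family}: {r.sn:.4f} / {r.sp:.4f} / {r.acc:.4f}"
            )
        return reports

    results["cv_reports"] = _classify

    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return results
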
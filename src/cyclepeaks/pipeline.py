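"""End-to-end orchestration: validate a config, run the enabled stages in
dependency order, and write per-stage outputs plus a consolidated report.

The report (JSON + plain text) is byte-identical across reruns with the
same config and seeds: stage order, dict key order and float formatting are
all fixed, and every stochastic stage derives its generator from the
configured seed.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from .annotate import (
    category_distribution,
    compare_class_fractions,
    gc_content,
    read_bed12,
    read_fasta,
    read_gff3,
)
from .classify import ClassifiedSites, SiteClass, class_proportions, classify_sites
from .conservation import (
    build_conservation_table,
    liftover_peaks,
    observed_expected_conservation,
    read_chains,
)
from .intervals import PeakSet, ValidationError, read_bed, read_chrom_sizes
from .motifs import default_two_part_motif, read_jaspar, two_part_fraction, TwoPartMotif
from .simulate import SyntheticConfig, generate_all, sequences_as_str, write_bundle
from .spatial import (
    boundary_enrichment_profile,
    boundary_spacing_permutation_test,
    label_boundaries,
    nearest_neighbor_permutation_test,
    read_domain_bed,
    write_labeled_boundaries,
)
from .tracks import aggregate_profile, read_bedgraph

log = logging.getLogger("cyclepeaks")

ALL_STAGES = ["classify", "annotate", "conserve", "motif", "profile", "spatial"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see `from_yaml`)."""

    outdir: Path
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    synthetic: Optional[SyntheticConfig] = None
    inputs: Dict[str, Any] = field(default_factory=dict)
    params: Dict[str, Any] = field(default_factory=dict)

    # parameter defaults; tss_window/flank/min_match/n_perm follow the
    # source study's stated settings
    _DEFAULTS = {
        "min_overlap": 1,
        "tss_window": 200,
        "flank": 2000,
        "min_match": 0.5,
        "n_perm": 1000,
        "motif_window": 100,
        "gc_window": 100,
        "profile_flank": 2000,
        "profile_bin": 100,
        "boundary_flank": 100_000,
        "boundary_bin": 10_000,
        "boundary_window": 500,
        "conservation_n": 2,
    }

    def param(self, name: str) -> Any:
        if name in self.params:
            log.info("parameter %s = %r (user override)", name, self.params[name])
            return self.params[name]
        return self._DEFAULTS[name]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Dict[str, Any], base: Path = Path(".")) -> "PipelineConfig":
        outdir = Path(raw.get("outdir", "cyclepeaks_out"))
        if not outdir.is_absolute():
            outdir = base / outdir
        synthetic = None
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            synthetic = SyntheticConfig(**syn)
        inputs = dict(raw.get("inputs", {}) or {})
        for key, val in list(inputs.items()):
            if isinstance(val, str):
                p = Path(val)
                inputs[key] = str(p if p.is_absolute() else base / p)
            elif isinstance(val, dict):
                inputs[key] = {
                    k: str(Path(v) if Path(v).is_absolute() else base / v)
                    for k, v in val.items()
                }
        return cls(
            outdir=outdir,
            seed=int(raw.get("seed", 0)),
            stages=list(raw.get("stages", ALL_STAGES)),
            synthetic=synthetic,
            inputs=inputs,
            params=dict(raw.get("params", {}) or {}),
        )

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if self.synthetic is not None:
            return  # synthetic mode provides everything
        required = {"interphase", "mitosis", "chrom_sizes"}
        if "annotate" in self.stages:
            required.add("genes")
        if "conserve" in self.stages:
            required.update({"chains", "species_peaks"})
        if "motif" in self.stages:
            required.add("fasta")
        if "profile" in self.stages:
            required.add("tracks")
        if "spatial" in self.stages:
            required.add("domains")
        missing = sorted(required - set(self.inputs))
        if missing:
            raise ValidationError(f"missing inputs for enabled stages: {missing}")
        for key, val in self.inputs.items():
            paths = val.values() if isinstance(val, dict) else [val]
            for p in paths:
                if not Path(p).exists():
                    raise ValidationError(f"input {key!r}: no such file {p}")


def _round_floats(obj: Any, ndigits: int = 10) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> Dict[str, Any]:
    """Execute enabled stages in dependency order and write the report.

    Returns the report dict. Raises before any stage runs when an enabled
    stage's inputs are missing.
    """
    config.validate()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    report: Dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            k: config.param(k) for k in sorted(PipelineConfig._DEFAULTS)
        },
    }

    # ------------------------------------------------------------------ inputs
    sequences = None
    genes = None
    domains = None
    chains_by_species = None
    species_peaks = None
    tracks = {}
    if config.synthetic is not None:
        log.info("generating synthetic inputs (seed=%d)", config.synthetic.seed)
        need_seq = "motif" in config.stages or "annotate" in config.stages
        bundle = generate_all(config.synthetic, with_sequence=need_seq)
        write_bundle(bundle, outdir / "synthetic")
        genome = bundle.genome
        interphase, mitosis = bundle.interphase, bundle.mitosis
        if bundle.sequences is not None:
            sequences = sequences_as_str(bundle.sequences)
        genes = bundle.genes
        domains = bundle.domains
        chains_by_species = bundle.chains
        species_peaks = bundle.species_peaks()
        tracks = bundle.tracks
    else:
        genome = read_chrom_sizes(config.inputs["chrom_sizes"])
        interphase = read_bed(config.inputs["interphase"], genome)
        mitosis = read_bed(config.inputs["mitosis"], genome)
        if "genes" in config.inputs:
            gpath = config.inputs["genes"]
            genes = read_bed12(gpath) if gpath.endswith(".bed") else read_gff3(gpath)
        if "fasta" in config.inputs:
            sequences = read_fasta(config.inputs["fasta"])
        if "domains" in config.inputs:
            domains = read_domain_bed(config.inputs["domains"], genome)
        if "chains" in config.inputs:
            chains_by_species = {
                sp: read_chains(p) for sp, p in sorted(config.inputs["chains"].items())
            }
        if "species_peaks" in config.inputs:
            # species-coordinate peak BEDs; lifted below
            species_peaks = {}
            for sp, p in sorted(config.inputs["species_peaks"].items()):
                species_peaks[sp] = read_bed(p, genome)
        if "tracks" in config.inputs:
            tracks = {
                name: read_bedgraph(p)
                for name, p in sorted(config.inputs["tracks"].items())
            }

    # ----------------------------------------------------------------- classify
    classified: Optional[ClassifiedSites] = None
    if "classify" in config.stages:
        log.info("stage classify")
        classified = classify_sites(
            interphase, mitosis, min_overlap=config.param("min_overlap")
        )
        classified.write(outdir, prefix="sites")
        report["classification"] = {
            "counts": classified.counts(),
            "proportions": class_proportions(classified),
            "source_interphase": classified.source_interphase_count,
            "source_mitosis": classified.source_mitosis_count,
            "min_overlap": classified.min_overlap,
        }
    else:
        return _finalize(report, outdir)

    # ----------------------------------------------------------------- annotate
    if "annotate" in config.stages:
        log.info("stage annotate")
        if genes is None:
            raise ValidationError("annotate stage requires gene models")
        tssw, flank = config.param("tss_window"), config.param("flank")
        dist = category_distribution(classified, genes, tssw, flank)
        dist.to_csv(outdir / "categories.tsv", sep="\t", index=False, float_format="%.6g")
        cat_section: Dict[str, Any] = {"table": dist.to_dict(orient="records")}
        # headline comparison: TSS-region fraction, IM vs IO
        im_tss = dist[(dist["class"] == "IM") & (dist["category"] == "TSS_region")]
        io_tss = dist[(dist["class"] == "IO") & (dist["category"] == "TSS_region")]
        if len(im_tss) and len(io_tss) and len(classified.im) and len(classified.io):
            a = int(im_tss["count"].iloc[0])
            b = int(io_tss["count"].iloc[0])
            p = compare_class_fractions(
                (a, len(classified.im) - a), (b, len(classified.io) - b)
            )
            cat_section["tss_im_vs_io_fisher_p"] = p
        if sequences is not None:
            gcw = config.param("gc_window")
            gc_means = {}
            for cls in SiteClass:
                vals = [
                    v
                    for v in (
                        gc_content(s, sequences, gcw) for s in classified.peak_set(cls)
                    )
                    if v is not None
                ]
                gc_means[cls.value] = float(np.mean(vals)) if vals else None
            cat_section["gc_mean"] = gc_means
        report["categories"] = cat_section

    # ----------------------------------------------------------------- conserve
    if "conserve" in config.stages:
        log.info("stage conserve")
        if chains_by_species is None or species_peaks is None:
            raise ValidationError("conserve stage requires chains and species peaks")
        lifted = {}
        for sp in sorted(chains_by_species):
            lifted[sp] = liftover_peaks(
                species_peaks[sp],
                chains_by_species[sp],
                genome,
                min_match=config.param("min_match"),
            )
            from .intervals import write_bed

            write_bed(lifted[sp], outdir / f"lifted.{sp}.bed")
        all_sites = list(classified.im) + list(classified.io) + list(classified.mo)
        table = build_conservation_table(all_sites, lifted)
        frames = []
        max_n = 1 + len(table.species)
        for n in range(2, min(4, max_n) + 1):
            frames.append(observed_expected_conservation(classified, table, n))
        import pandas as pd

        oe = pd.concat(frames, ignore_index=True)
        oe.to_csv(outdir / "conservation.tsv", sep="\t", index=False, float_format="%.6g")
        report["conservation"] = oe.to_dict(orient="records")

    # -------------------------------------------------------------------- motif
    if "motif" in config.stages:
        log.info("stage motif")
        if sequences is None:
            raise ValidationError("motif stage requires genome sequence")
        motif = _resolve_motif(config)
        frac = two_part_fraction(
            classified, sequences, motif, window=config.param("motif_window")
        )
        frac.to_csv(outdir / "motif_fractions.tsv", sep="\t", index=False,
                    float_format="%.6g")
        report["motifs"] = frac.to_dict(orient="records")

    # ------------------------------------------------------------------ profile
    if "profile" in config.stages and tracks:
        log.info("stage profile")
        pf, pb = config.param("profile_flank"), config.param("profile_bin")
        section = {}
        for name in sorted(tracks):
            per_class = {}
            for cls in SiteClass:
                peaks = classified.peak_set(cls)
                if len(peaks) == 0:
                    continue
                prof = aggregate_profile(peaks, tracks[name], pf, pb)
                prof.write_tsv(outdir / f"profile.{name}.{cls.value}.tsv")
                per_class[cls.value] = {
                    "mean_at_center": float(prof.mean[len(prof.mean) // 2]),
                    "mean_overall": float(prof.mean.mean()),
                    "n_sites": prof.n_sites,
                }
            section[name] = per_class
        report["signal"] = section

    # ------------------------------------------------------------------ spatial
    if "spatial" in config.stages:
        log.info("stage spatial")
        if domains is None:
            raise ValidationError("spatial stage requires domains")
        n_perm = config.param("n_perm")
        rng_seed = config.seed
        section: Dict[str, Any] = {"nearest_neighbor": {}, "boundary_spacing": {}}
        for i, cls in enumerate(SiteClass):
            peaks = classified.peak_set(cls)
            if len(peaks) < 2:
                continue
            try:
                res = nearest_neighbor_permutation_test(
                    peaks, peaks, n_perm=n_perm, seed=rng_seed + i,
                    statistic_name=f"nearest_{cls.value}_to_{cls.value}",
                )
            except ValidationError as exc:
                section["nearest_neighbor"][cls.value] = {"error": str(exc)}
                continue
            res.write_json(outdir / f"nearest.{cls.value}.json")
            section["nearest_neighbor"][cls.value] = res.summary()
        bf, bb = config.param("boundary_flank"), config.param("boundary_bin")
        for cls in SiteClass:
            peaks = classified.peak_set(cls)
            if len(peaks) == 0:
                continue
            prof = boundary_enrichment_profile(peaks, domains, bf, bb)
            prof.write_tsv(outdir / f"boundary_profile.{cls.value}.tsv")
        boundaries = label_boundaries(
            domains, classified, boundary_window=config.param("boundary_window")
        )
        write_labeled_boundaries(boundaries, outdir / "boundaries.labeled.bed")
        for i, cls in enumerate(SiteClass):
            try:
                res = boundary_spacing_permutation_test(
                    domains, boundaries, cls, n_perm=n_perm, seed=rng_seed + 10 + i
                )
            except ValidationError as exc:
                section["boundary_spacing"][cls.value] = {"error": str(exc)}
                continue
            res.write_json(outdir / f"boundary_spacing.{cls.value}.json")
            section["boundary_spacing"][cls.value] = res.summary()
        report["spatial"] = section

    return _finalize(report, outdir)


def _resolve_motif(config: PipelineConfig) -> TwoPartMotif:
    inputs = config.inputs
    if "motif_a" in inputs and "motif_b" in inputs:
        return TwoPartMotif(
            module_a=read_jaspar(inputs["motif_a"]),
            module_b=read_jaspar(inputs["motif_b"]),
            min_gap=config.params.get("min_gap", 0),
            max_gap=config.params.get("max_gap", 15),
        )
    return default_two_part_motif()


def _finalize(report: Dict[str, Any], outdir: Path) -> Dict[str, Any]:
    report = _round_floats(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(_render_text(report))
    return report


def _render_text(report: Dict[str, Any]) -> str:
    lines = [f"cyclepeaks report (seed={report.get('seed')})", ""]
    cl = report.get("classification")
    if cl:
        lines.append("Classification:")
        for k in ("IM", "IO", "MO"):
            lines.append(
                f"  {k}: {cl['counts'][k]} sites ({cl['proportions'][k]:.1%})"
            )
        lines.append("")
    if "categories" in report:
        lines.append("Genomic categories: see categories.tsv")
        p = report["categories"].get("tss_im_vs_io_fisher_p")
        if p is not None:
            lines.append(f"  TSS-region fraction IM vs IO Fisher p = {p:.3g}")
        gc = report["categories"].get("gc_mean")
        if gc:
            lines.append(
                "  mean GC: " + ", ".join(f"{k}={v:.3f}" for k, v in sorted(gc.items()) if v is not None)
            )
        lines.append("")
    for rec in report.get("conservation", []):
        lines.append(
            f"Conservation {rec['class']} (>= {rec['n_species']} species): "
            f"O/E = {rec['ratio']:.3f} (p = {rec['fisher_p']:.3g})"
        )
    for rec in report.get("motifs", []):
        if rec["n"]:
            lines.append(
                f"Two-part motif {rec['class']}: {rec['fraction']:.1%} "
                f"({rec['positives']}/{rec['n']})"
            )
    sp = report.get("spatial", {})
    for cls, s in sorted(sp.get("nearest_neighbor", {}).items()):
        if "p_value" in s:
            lines.append(
                f"Nearest-{cls} distance: median {s['observed_median']:.0f} vs "
                f"null {s['null_median']:.0f}, p = {s['p_value']:.3g}"
            )
    for cls, s in sorted(sp.get("boundary_spacing", {}).items()):
        if "p_value" in s:
            lines.append(
                f"{cls}-boundary spacing: median {s['observed_median']:.1f} vs "
                f"null {s['null_median']:.1f}, p = {s['p_value']:.3g}"
            )
    return "\n".join(lines) + "\n"
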
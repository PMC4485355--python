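"""Synthetic data generator: genomes, gene models, domains, chains, peak
sets with planted IM/IO/MO structure, signal tracks and truth tables.

Every pipeline input can be generated with controllable statistical
structure so all stages are testable offline. IM sites are duplicated into
both phase peak sets with jitter bounded below the peak width, so the
classifier recovers the planted composition exactly; the truth table is a
first-class output recording each site's intended class and properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotate import GeneModel, write_fasta
from .conservation import Chain
from .intervals import (
    GenomeTable,
    GenomicInterval,
    PeakSet,
    ValidationError,
)
from .motifs import MODULE_A_CONSENSUS, MODULE_B_CONSENSUS
from .spatial import DomainSet
from .tracks import SignalTrack

__all__ = [
    "SyntheticConfig",
    "generate_genome",
    "generate_annotations_and_domains",
    "generate_peak_data",
    "generate_all",
]

_CLASSES = ("IM", "IO", "MO")


@dataclass
class SyntheticConfig:
    """All knobs of the generator; identical config + seed => identical data."""

    seed: int = 0
    chromosomes: Dict[str, int] = field(
        default_factory=lambda: {"chr2L": 3_000_000, "chr2R": 2_500_000, "chrX": 2_000_000}
    )
    gc_background: float = 0.40

    # genes
    n_genes: int = 150
    gene_length: Tuple[int, int] = (2_000, 8_000)
    exons_per_gene: Tuple[int, int] = (2, 5)

    # peaks
    n_sites: Dict[str, int] = field(
        default_factory=lambda: {"IM": 100, "IO": 200, "MO": 120}
    )
    peak_width: int = 200
    im_jitter: int = 50  # must stay < peak_width for exact recovery
    tss_fraction: Dict[str, float] = field(
        default_factory=lambda: {"IM": 0.0, "IO": 0.0, "MO": 0.0}
    )
    boundary_fraction: Dict[str, float] = field(
        default_factory=lambda: {"IM": 0.0, "IO": 0.0, "MO": 0.0}
    )
    # (number of clusters, radius bp) per class; None = no clustering
    clusters: Dict[str, Optional[Tuple[int, int]]] = field(
        default_factory=lambda: {"IM": None, "IO": None, "MO": None}
    )
    min_site_separation: int = 500  # between planted sites of any class

    # sequence planting (skipped when sequences are not provided)
    motif_fraction: Dict[str, float] = field(
        default_factory=lambda: {"IM": 0.0, "IO": 0.0, "MO": 0.0}
    )
    motif_gap: Tuple[int, int] = (4, 8)
    gc_target: Dict[str, Optional[float]] = field(
        default_factory=lambda: {"IM": None, "IO": None, "MO": None}
    )
    gc_window: int = 100

    # domains
    n_domains: int = 30
    domain_width: Tuple[int, int] = (50_000, 150_000)

    # chains: species name -> mappable fraction of each chromosome
    species: Dict[str, float] = field(
        default_factory=lambda: {"speciesA": 0.9, "speciesB": 0.8, "speciesC": 0.7}
    )
    chain_period: int = 1_000
    # probability a site of each class is planted as present in each species
    conservation_prob: Dict[str, float] = field(
        default_factory=lambda: {"IM": 0.0, "IO": 0.0, "MO": 0.0}
    )

    # signal
    signal_amplitude: Dict[str, float] = field(
        default_factory=lambda: {"IM": 10.0, "IO": 5.0, "MO": 5.0}
    )
    signal_width: int = 500
    signal_bin: int = 50

    def validate(self) -> None:
        if not self.chromosomes:
            raise ValidationError("config needs at least one chromosome")
        for c, n in self.chromosomes.items():
            if n < 10_000:
                raise ValidationError(f"chromosome {c} shorter than 10 kb")
        for d in (self.tss_fraction, self.boundary_fraction, self.motif_fraction,
                  self.conservation_prob):
            for k, v in d.items():
                if not 0 <= v <= 1:
                    raise ValidationError(f"fraction {k}={v} outside [0,1]")
        if any(v < 0 for v in self.n_sites.values()):
            raise ValidationError("negative site count")
        if self.im_jitter >= self.peak_width:
            raise ValidationError("im_jitter must be smaller than peak_width")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(
    config: SyntheticConfig, with_sequence: bool = True
) -> Tuple[GenomeTable, Optional[Dict[str, np.ndarray]]]:
    """Genome table plus (optionally) i.i.d. sequences at the background GC.

    Sequences are returned as uint8 arrays of ASCII codes so that motif and
    GC planting can mutate them in place; use `sequences_as_str` /
    `annotate.write_fasta` to materialize strings.
    """
    config.validate()
    rng = np.random.default_rng(_stage_seed(config.seed, "genome"))
    genome = GenomeTable(config.chromosomes)
    if not with_sequence:
        return genome, None
    gc = config.gc_background
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for chrom in genome.chromosomes():
        n = genome[chrom]
        seqs[chrom] = alphabet[rng.choice(4, size=n, p=probs)]
    return genome, seqs


def sequences_as_str(seqs: Mapping[str, np.ndarray]) -> Dict[str, str]:
    return {c: a.tobytes().decode() for c, a in seqs.items()}


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    # crc32, not hash(): str hashing is randomized per process
    import zlib

    return np.random.SeedSequence([seed, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Annotations, domains, chains
# ---------------------------------------------------------------------------

def generate_annotations_and_domains(
    config: SyntheticConfig, genome: GenomeTable
) -> Tuple[List[GeneModel], DomainSet, Dict[str, List[Chain]]]:
    """Non-overlapping genes, tiled domains and per-species chain files."""
    rng = np.random.default_rng(_stage_seed(config.seed, "annotations"))
    chroms = genome.chromosomes()

    # --- genes: greedy non-overlapping placement ---
    genes: List[GeneModel] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    total_len = sum(genome[c] for c in chroms)
    need = config.n_genes * config.gene_length[1]
    if need > 0.6 * total_len:
        raise ValidationError(
            f"cannot pack {config.n_genes} genes of up to {config.gene_length[1]} bp "
            f"into {total_len} bp of genome"
        )
    attempts = 0
    while len(genes) < config.n_genes:
        attempts += 1
        if attempts > 50 * config.n_genes:
            raise ValidationError("gene placement failed; genome too crowded")
        chrom = chroms[rng.integers(len(chroms))]
        glen = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
        if glen >= genome[chrom]:
            continue
        start = int(rng.integers(0, genome[chrom] - glen))
        end = start + glen
        if any(s < end and e > start for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        # split the span into alternating exon/intron pieces
        cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2, replace=False))
        edges = np.concatenate(([0], cuts, [glen]))
        exons = [
            (start + int(edges[2 * i]), start + int(edges[2 * i + 1]))
            for i in range(n_ex)
        ]
        # CDS: trim the outermost exons to leave UTRs
        cds = [(max(s, exons[0][0] + (exons[0][1] - exons[0][0]) // 2), e)
               if i == 0 else (s, e) for i, (s, e) in enumerate(exons)]
        if strand == "-":
            cds = [(s, min(e, exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2))
                   if i == len(exons) - 1 else (s, e) for i, (s, e) in enumerate(exons)]
        cds = [(s, e) for s, e in cds if e > s]
        genes.append(
            GeneModel(chrom, start, end, strand, exons, cds, f"gene{len(genes):05d}")
        )
    genes.sort(key=lambda g: (g.chrom, g.start))

    # --- domains: contiguous tiling from a random offset on each chromosome ---
    domains: List[GenomicInterval] = []
    per_chrom = max(1, config.n_domains // len(chroms))
    for chrom in chroms:
        pos = int(rng.integers(0, max(1, genome[chrom] // 20)))
        for d in range(per_chrom):
            width = int(rng.integers(config.domain_width[0], config.domain_width[1] + 1))
            if pos + width > genome[chrom]:
                break
            domains.append(
                GenomicInterval(chrom, pos, pos + width, f"{chrom}_dom{d:03d}")
            )
            pos += width
    domain_set = DomainSet(domains, genome, kind="TAD")

    # --- chains: periodic mapped blocks, symmetric gaps, species coords == ref ---
    chains: Dict[str, List[Chain]] = {}
    chain_id = 1
    for sp in sorted(config.species):
        frac = config.species[sp]
        if not 0 < frac <= 1:
            raise ValidationError(f"mappable fraction for {sp} must be in (0, 1]")
        sp_chains = []
        for chrom in chroms:
            n = genome[chrom]
            period = config.chain_period
            mapped = max(1, int(round(frac * period)))
            gap = period - mapped
            blocks_mut: List[List[int]] = []
            pos = 0
            while pos < n:
                size = min(mapped, n - pos)
                g = min(gap, n - pos - size)
                blocks_mut.append([size, g, g])
                pos += size + g
            blocks_mut[-1][1] = blocks_mut[-1][2] = 0
            blocks = [tuple(b) for b in blocks_mut]
            t_span = sum(s + dt for s, dt, _ in blocks)
            sp_chains.append(
                Chain(
                    score=1000.0,
                    t_name=chrom,
                    t_size=n,
                    t_strand="+",
                    t_start=0,
                    t_end=t_span,
                    q_name=chrom,
                    q_size=n,
                    q_strand="+",
                    q_start=0,
                    q_end=t_span,
                    chain_id=chain_id,
                    blocks=blocks,
                )
            )
            chain_id += 1
        chains[sp] = sp_chains
    return genes, domain_set, chains


# ---------------------------------------------------------------------------
# Peaks, sequence planting, tracks, truth table
# ---------------------------------------------------------------------------

class _Placer:
    """Collision-avoiding placement of site anchors along the genome."""

    def __init__(self, genome: GenomeTable, margin: int):
        self.genome = genome
        self.margin = margin
        self._placed: Dict[str, List[int]] = {c: [] for c in genome.chromosomes()}

    def try_place(self, chrom: str, anchor: int, half_width: int) -> bool:
        n = self.genome[chrom]
        if anchor - half_width < 0 or anchor + half_width > n:
            return False
        import bisect

        arr = self._placed[chrom]
        i = bisect.bisect_left(arr, anchor)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(arr[j] - anchor) < self.margin:
                return False
        arr.insert(i, anchor)
        return True


def generate_peak_data(
    config: SyntheticConfig,
    genome: GenomeTable,
    genes: Optional[Sequence[GeneModel]] = None,
    domains: Optional[DomainSet] = None,
    sequences: Optional[Dict[str, np.ndarray]] = None,
) -> Tuple[PeakSet, PeakSet, Dict[str, SignalTrack], pd.DataFrame]:
    """Plant sites by class and emit phase peak sets, tracks and the truth table.

    Placement rules per class (honored as exact counts where possible): a
    TSS-proximal fraction (requires ``genes``), a boundary fraction
    (requires ``domains``), optional clustering, remainder uniform. Motif
    and GC planting mutate ``sequences`` in place and are skipped when
    sequences are absent.
    """
    config.validate()
    rng = np.random.default_rng(_stage_seed(config.seed, "peaks"))
    chroms = genome.chromosomes()
    chrom_lens = np.array([genome[c] for c in chroms], dtype=np.int64)
    chrom_probs = chrom_lens / chrom_lens.sum()
    width = config.peak_width
    half = width // 2
    placer = _Placer(genome, max(config.min_site_separation, width + config.im_jitter + 1))

    tss_list = [(g.chrom, g.tss) for g in genes] if genes else []
    boundary_list: List[Tuple[str, int]] = []
    if domains is not None:
        for chrom in domains.chromosomes():
            for pos in domains.boundary_positions(chrom):
                boundary_list.append((chrom, int(pos)))

    records: List[dict] = []
    for cls in _CLASSES:
        n = config.n_sites.get(cls, 0)
        if n == 0:
            continue
        n_tss = int(round(n * config.tss_fraction.get(cls, 0.0)))
        n_bound = int(round(n * config.boundary_fraction.get(cls, 0.0)))
        if n_tss and not tss_list:
            raise ValidationError(f"{cls}: TSS placement requested but no genes given")
        if n_bound and not boundary_list:
            raise ValidationError(f"{cls}: boundary placement requested but no domains")
        if n_tss + n_bound > n:
            raise ValidationError(f"{cls}: tss_fraction + boundary_fraction exceed 1")
        cluster_cfg = config.clusters.get(cls)
        placements = (
            ["tss"] * n_tss
            + ["boundary"] * n_bound
            + ["cluster" if cluster_cfg else "uniform"] * (n - n_tss - n_bound)
        )
        cluster_centers: List[Tuple[str, int]] = []
        if cluster_cfg:
            n_clusters, radius = cluster_cfg
            for _ in range(n_clusters):
                ci = int(rng.choice(len(chroms), p=chrom_probs))
                chrom = chroms[ci]
                margin = radius + half + 1
                cluster_centers.append(
                    (chrom, int(rng.integers(margin, genome[chrom] - margin)))
                )
        for k, mode in enumerate(placements):
            placed = False
            for _ in range(2000):
                if mode == "tss":
                    chrom, tss = tss_list[int(rng.integers(len(tss_list)))]
                    anchor = int(tss + rng.integers(-150, 151))
                elif mode == "boundary":
                    chrom, pos = boundary_list[int(rng.integers(len(boundary_list)))]
                    anchor = int(pos + rng.integers(-200, 201))
                elif mode == "cluster":
                    chrom, center = cluster_centers[int(rng.integers(len(cluster_centers)))]
                    radius = cluster_cfg[1]
                    anchor = int(center + rng.integers(-radius, radius + 1))
                else:
                    ci = int(rng.choice(len(chroms), p=chrom_probs))
                    chrom = chroms[ci]
                    anchor = int(rng.integers(half, genome[chrom] - half))
                if placer.try_place(chrom, anchor, half):
                    placed = True
                    break
            if not placed:
                raise ValidationError(
                    f"could not place {cls} site {k} with mode {mode}: "
                    "genome too small or min_site_separation too large"
                )
            records.append(
                {
                    "name": f"{cls}_{k:05d}",
                    "class": cls,
                    "chrom": chrom,
                    "start": anchor - half,
                    "end": anchor - half + width,
                    "summit": half,
                    "placement": mode,
                }
            )

    # --- sequence planting ---
    gap_lo, gap_hi = config.motif_gap
    motif_span = len(MODULE_A_CONSENSUS) + gap_hi + len(MODULE_B_CONSENSUS)
    for rec in records:
        cls = rec["class"]
        rec["motif_planted"] = False
        rec["gc_planted"] = False
        if sequences is None:
            continue
        seq = sequences[rec["chrom"]]
        anchor = rec["start"] + rec["summit"]
        gc_t = config.gc_target.get(cls)
        if gc_t is not None:
            w = config.gc_window
            lo, hi = max(0, anchor - w), min(len(seq), anchor + w)
            probs = [(1 - gc_t) / 2, gc_t / 2, gc_t / 2, (1 - gc_t) / 2]
            alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
            seq[lo:hi] = alphabet[rng.choice(4, size=hi - lo, p=probs)]
            rec["gc_planted"] = True
        if rng.random() < config.motif_fraction.get(cls, 0.0):
            gap = int(rng.integers(gap_lo, gap_hi + 1))
            motif_seq = (
                MODULE_A_CONSENSUS
                + "".join("ACGT"[rng.integers(4)] for _ in range(gap))
                + MODULE_B_CONSENSUS
            )
            pos = anchor - len(motif_seq) // 2
            if pos >= 0 and pos + len(motif_seq) <= len(seq):
                seq[pos : pos + len(motif_seq)] = np.frombuffer(
                    motif_seq.encode(), dtype=np.uint8
                )
                rec["motif_planted"] = True

    # --- conservation planting ---
    species = sorted(config.species)
    for rec in records:
        p = config.conservation_prob.get(rec["class"], 0.0)
        for sp in species:
            rec[f"conserved_{sp}"] = bool(rng.random() < p)

    # --- phase peak sets ---
    interphase: List[GenomicInterval] = []
    mitosis: List[GenomicInterval] = []
    for rec in records:
        iv = GenomicInterval(
            rec["chrom"], rec["start"], rec["end"], rec["name"],
            score=1.0, strand=".", summit=rec["summit"],
        )
        if rec["class"] == "IM":
            interphase.append(iv)
            jit = int(rng.integers(-config.im_jitter, config.im_jitter + 1))
            s = min(max(0, rec["start"] + jit), genome[rec["chrom"]] - width)
            mitosis.append(
                GenomicInterval(rec["chrom"], s, s + width, rec["name"] + "_m",
                                score=1.0, strand=".", summit=half)
            )
        elif rec["class"] == "IO":
            interphase.append(iv)
        else:
            mitosis.append(iv)

    # --- signal tracks: triangular bumps at summits ---
    tracks = {
        "interphase": _bump_track(records, ("IM", "IO"), config, genome),
        "mitosis": _bump_track(records, ("IM", "MO"), config, genome),
    }

    truth = pd.DataFrame(records)
    return (
        PeakSet(interphase, genome),
        PeakSet(mitosis, genome),
        tracks,
        truth,
    )


def _bump_track(
    records: Sequence[dict],
    classes: Tuple[str, ...],
    config: SyntheticConfig,
    genome: GenomeTable,
) -> SignalTrack:
    """Sum of per-site triangular bumps, discretized to signal_bin steps."""
    bin_ = config.signal_bin
    half_w = config.signal_width // 2
    acc: Dict[str, Dict[int, float]] = {}
    for rec in records:
        if rec["class"] not in classes:
            continue
        amp = config.signal_amplitude.get(rec["class"], 0.0)
        if amp <= 0:
            continue
        chrom = rec["chrom"]
        anchor = rec["start"] + rec["summit"]
        n = genome[chrom]
        d = acc.setdefault(chrom, {})
        for b in range(
            max(0, (anchor - half_w) // bin_), min(n // bin_ + 1, (anchor + half_w) // bin_ + 1)
        ):
            center = b * bin_ + bin_ // 2
            if b * bin_ + bin_ > n:
                continue
            v = amp * max(0.0, 1.0 - abs(center - anchor) / half_w)
            if v > 0:
                d[b] = d.get(b, 0.0) + v
    rows: List[Tuple[str, int, int, float]] = []
    for chrom in sorted(acc):
        for b in sorted(acc[chrom]):
            rows.append((chrom, b * bin_, b * bin_ + bin_, acc[chrom][b]))
    return SignalTrack.from_intervals(rows)


# ---------------------------------------------------------------------------
# One-call bundle + file emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    genome: GenomeTable
    sequences: Optional[Dict[str, np.ndarray]]
    genes: List[GeneModel]
    domains: DomainSet
    chains: Dict[str, List[Chain]]
    interphase: PeakSet
    mitosis: PeakSet
    tracks: Dict[str, SignalTrack]
    truth: pd.DataFrame

    def species_peaks(self, min_shift: int = 0) -> Dict[str, PeakSet]:
        """Per-species peak sets (in species coordinates, which the periodic
        chains keep aligned with the reference) for conserved sites."""
        out: Dict[str, PeakSet] = {}
        for sp in sorted(self.chains):
            col = f"conserved_{sp}"
            ivs = []
            for _, rec in self.truth.iterrows():
                if col in rec and rec[col]:
                    ivs.append(
                        GenomicInterval(
                            rec["chrom"], int(rec["start"]), int(rec["end"]),
                            f"{rec['name']}_{sp}",
                        )
                    )
            out[sp] = PeakSet(ivs, self.genome)
        return out


def generate_all(config: SyntheticConfig, with_sequence: bool = True) -> SyntheticBundle:
    genome, seqs = generate_genome(config, with_sequence=with_sequence)
    genes, domains, chains = generate_annotations_and_domains(config, genome)
    interphase, mitosis, tracks, truth = generate_peak_data(
        config, genome, genes=genes, domains=domains, sequences=seqs
    )
    return SyntheticBundle(
        genome, seqs, genes, domains, chains, interphase, mitosis, tracks, truth
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> Dict[str, str]:
    """Emit every artifact as plain-text files; returns a path manifest."""
    from .conservation import write_chains
    from .intervals import write_bed, write_chrom_sizes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, str] = {}

    p = outdir / "genome.chrom.sizes"
    write_chrom_sizes(bundle.genome, p)
    manifest["chrom_sizes"] = str(p)
    if bundle.sequences is not None:
        p = outdir / "genome.fa"
        write_fasta(sequences_as_str(bundle.sequences), p)
        manifest["fasta"] = str(p)
    p = outdir / "genes.gff3"
    _write_gff3(bundle.genes, p)
    manifest["genes"] = str(p)
    p = outdir / "domains.bed"
    domain_ivs = [d for c in bundle.domains.chromosomes() for d in bundle.domains.domains(c)]
    write_bed(domain_ivs, p)
    manifest["domains"] = str(p)
    for phase, peaks in (("interphase", bundle.interphase), ("mitosis", bundle.mitosis)):
        p = outdir / f"peaks.{phase}.bed"
        write_bed(peaks, p)
        manifest[f"peaks_{phase}"] = str(p)
    for sp, chains in bundle.chains.items():
        p = outdir / f"chain.{sp}.chain"
        write_chains(chains, p)
        manifest[f"chain_{sp}"] = str(p)
    for sp, peaks in bundle.species_peaks().items():
        p = outdir / f"peaks.{sp}.bed"
        write_bed(peaks, p)
        manifest[f"peaks_{sp}"] = str(p)
    for name, track in bundle.tracks.items():
        p = outdir / f"signal.{name}.bedgraph"
        track.write_bedgraph(p)
        manifest[f"track_{name}"] = str(p)
    p = outdir / "truth.tsv"
    bundle.truth.to_csv(p, sep="\t", index=False)
    manifest["truth"] = str(p)
    return manifest


def _write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tcyclepeaks\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.id}\n"
            )
            for i, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tcyclepeaks\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.id}.exon{i};Parent={g.id}\n"
                )
            for i, (s, e) in enumerate(g.cds or []):
                fh.write(
                    f"{g.chrom}\tcyclepeaks\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.id}.cds{i};Parent={g.id}\n"
                )
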
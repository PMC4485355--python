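"""Genomic-category assignment relative to gene models, class-fraction
comparison (Fisher's exact test) and GC content.

Each site is assigned exactly one category based on its anchor point, using
the precedence TSS_region > Promoter > Downstream > UTR5 > CodingExon >
Intron > Intergenic evaluated over all genes. ``TSS_region`` is within
``tss_window`` bp of a transcription start site; ``Promoter`` is within
``flank`` bp upstream of the TSS region (strand-aware); ``Downstream`` is
within ``flank`` bp past the transcription termination site.

Exonic anchors 5' of the first coding base are ``UTR5``; all other exonic
anchors of a coding gene count as ``CodingExon`` (the enumeration carries no
3'UTR category). Genes without CDS contribute exonic anchors as CodingExon
and non-exonic gene body as Intron.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

from .classify import ClassifiedSites, SiteClass
from .intervals import GenomicInterval, ValidationError

__all__ = [
    "GeneModel",
    "GenomicCategory",
    "assign_category",
    "category_distribution",
    "compare_class_fractions",
    "gc_content",
    "read_gff3",
    "read_bed12",
    "read_fasta",
    "write_fasta",
]


class GenomicCategory(str, enum.Enum):
    TSS_region = "TSS_region"
    Promoter = "Promoter"
    Downstream = "Downstream"
    UTR5 = "UTR5"
    CodingExon = "CodingExon"
    Intron = "Intron"
    Intergenic = "Intergenic"


# precedence: lower rank wins
_RANK = {cat: i for i, cat in enumerate(GenomicCategory)}


@dataclass
class GeneModel:
    """A gene with strand, exon structure and optional CDS.

    ``start``/``end`` are the 0-based half-open gene span. The TSS is
    ``start`` on the + strand and ``end`` on the - strand (the first
    transcribed base reads right-to-left); the TTS is the opposite end.
    """

    chrom: str
    start: int
    end: int
    strand: str
    exons: List[Tuple[int, int]]
    cds: Optional[List[Tuple[int, int]]] = None
    id: str = "."

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.id}: invalid span")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValidationError(f"gene {self.id}: overlapping exons")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValidationError(f"gene {self.id}: exon outside gene span")
        if self.cds is not None:
            self.cds = sorted(self.cds)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    def first_cds_base(self) -> Optional[int]:
        if not self.cds:
            return None
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1] - 1


def _categorize_for_gene(
    anchor: int, gene: GeneModel, tss_window: int, flank: int
) -> GenomicCategory:
    tss, tts = gene.tss, gene.tts
    if abs(anchor - tss) <= tss_window:
        return GenomicCategory.TSS_region
    if gene.strand == "+":
        in_promoter = tss - tss_window - flank <= anchor < tss - tss_window
        in_downstream = tts < anchor <= tts + flank
    else:
        in_promoter = tss + tss_window < anchor <= tss + tss_window + flank
        in_downstream = tts - flank <= anchor < tts
    if in_promoter:
        return GenomicCategory.Promoter
    if in_downstream and not (gene.start <= anchor < gene.end):
        return GenomicCategory.Downstream
    if gene.start <= anchor < gene.end:
        in_exon = any(s <= anchor < e for s, e in gene.exons)
        if not in_exon:
            return GenomicCategory.Intron
        first = gene.first_cds_base()
        if first is None:
            return GenomicCategory.CodingExon
        if (gene.strand == "+" and anchor < first) or (
            gene.strand == "-" and anchor > first
        ):
            return GenomicCategory.UTR5
        return GenomicCategory.CodingExon
    return GenomicCategory.Intergenic


def assign_category(
    site: GenomicInterval,
    genes: Sequence[GeneModel],
    tss_window: int = 200,
    flank: int = 2000,
) -> GenomicCategory:
    """Category of the site's anchor point under the module precedence."""
    if not genes:
        raise ValidationError("no genes loaded")
    anchor = site.anchor
    best = GenomicCategory.Intergenic
    for gene in genes:
        if gene.chrom != site.chrom:
            continue
        # genes further than flank + tss_window from the anchor cannot matter
        if anchor < gene.start - flank - tss_window or anchor > gene.end + flank + tss_window:
            continue
        cat = _categorize_for_gene(anchor, gene, tss_window, flank)
        if _RANK[cat] < _RANK[best]:
            best = cat
    return best


def category_distribution(
    c: ClassifiedSites,
    genes: Sequence[GeneModel],
    tss_window: int = 200,
    flank: int = 2000,
) -> pd.DataFrame:
    """Per-class counts and fractions over genomic categories.

    Returns a tidy frame with columns (class, category, count, fraction);
    empty classes are omitted (their fractions are undefined).
    """
    if c.total == 0:
        raise ValidationError("empty classification")
    rows = []
    for cls in SiteClass:
        peaks = c.peak_set(cls)
        if len(peaks) == 0:
            continue
        counts = {cat: 0 for cat in GenomicCategory}
        for site in peaks:
            counts[assign_category(site, genes, tss_window, flank)] += 1
        for cat in GenomicCategory:
            rows.append(
                {
                    "class": cls.value,
                    "category": cat.value,
                    "count": counts[cat],
                    "fraction": counts[cat] / len(peaks),
                }
            )
    return pd.DataFrame(rows)


def compare_class_fractions(
    k1: Tuple[int, int], k2: Tuple[int, int]
) -> float:
    """Two-sided Fisher exact p for 2x2 table [[in_A, out_A], [in_B, out_B]].

    ``k1``/``k2`` are (count-in, count-out) pairs for the two classes.
    """
    for v in (*k1, *k2):
        if v < 0:
            raise ValidationError("negative count in contingency table")
    if sum(k1) == 0 or sum(k2) == 0:
        raise ValidationError("empty class in contingency table")
    _, p = stats.fisher_exact([[k1[0], k1[1]], [k2[0], k2[1]]], alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_content(
    site: GenomicInterval,
    sequences: Mapping[str, str],
    window: int = 100,
) -> Optional[float]:
    """GC fraction of the ``[anchor - window, anchor + window)`` sequence.

    Case-insensitive; N (or any non-ACGT) bases are excluded from the
    denominator. Returns None when no ACGT base falls in the window.
    """
    seq = sequences[site.chrom]
    a = site.anchor
    lo, hi = max(0, a - window), min(len(seq), a + window)
    sub = str(seq[lo:hi]).upper()
    gc = sub.count("G") + sub.count("C")
    at = sub.count("A") + sub.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _parse_gff_attrs(attr: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> List[GeneModel]:
    """Read gene models from GFF3 (gene / exon / CDS features).

    Exons and CDS are attached to genes through the Parent attribute chain
    (mRNA level optional). Coordinates converted 1-based closed -> 0-based
    half-open.
    """
    genes: Dict[str, dict] = {}
    parent_of: Dict[str, str] = {}
    pending: List[Tuple[str, str, int, int]] = []  # (kind, parent, start, end)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValidationError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = f[:9]
            start, end = int(start1) - 1, int(end1)
            a = _parse_gff_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID", f"gene{lineno}")
                genes[gid] = {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "id": gid,
                }
            elif ftype in ("mRNA", "transcript"):
                tid = a.get("ID")
                parent = a.get("Parent")
                if tid and parent:
                    parent_of[tid] = parent
            elif ftype in ("exon", "CDS"):
                parent = a.get("Parent", "")
                pending.append((ftype, parent, start, end))
    for ftype, parent, start, end in pending:
        gid = parent_of.get(parent, parent)
        if gid in genes:
            key = "exons" if ftype == "exon" else "cds"
            genes[gid][key].append((start, end))
    out = []
    for g in genes.values():
        cds = sorted(g["cds"]) or None
        exons = sorted(g["exons"]) or [(g["start"], g["end"])]
        out.append(
            GeneModel(g["chrom"], g["start"], g["end"], g["strand"], exons, cds, g["id"])
        )
    out.sort(key=lambda g: (g.chrom, g.start))
    return out


def read_bed12(path: str | Path) -> List[GeneModel]:
    """Read gene models from BED12 (blocks = exons, thick region = CDS)."""
    out: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValidationError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            cds = None
            if thick_e > thick_s:
                cds = [
                    (max(s, thick_s), min(e, thick_e))
                    for s, e in exons
                    if min(e, thick_e) > max(s, thick_s)
                ]
            out.append(GeneModel(chrom, start, end, strand, exons, cds, name))
    out.sort(key=lambda g: (g.chrom, g.start))
    return out


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read a (small) FASTA into a dict of upper-case sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
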
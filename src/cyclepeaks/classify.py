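"""Partition interphase and mitosis peak sets into IM / IO / MO classes.

IM ("interphase-mitosis-common") sites are interphase peaks that overlap at
least one mitosis peak by ``min_overlap`` bp; IO ("interphase-only") are the
remaining interphase peaks; MO ("mitosis-only") are mitosis peaks with no
qualifying overlap. IM coordinates are taken from the interphase record, so
IM and IO together tile the interphase set exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .intervals import GenomicInterval, PeakSet, ValidationError, write_bed

__all__ = ["SiteClass", "ClassifiedSites", "classify_sites", "class_proportions"]


class SiteClass(str, enum.Enum):
    IM = "IM"
    IO = "IO"
    MO = "MO"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class ClassifiedSites:
    """Three disjoint peak sets labeled IM/IO/MO, with provenance counts."""

    im: PeakSet
    io: PeakSet
    mo: PeakSet
    source_interphase_count: int
    source_mitosis_count: int
    min_overlap: int

    def __post_init__(self) -> None:
        if len(self.im) + len(self.io) != self.source_interphase_count:
            raise ValidationError("IM + IO must tile the interphase set")

    @property
    def total(self) -> int:
        return len(self.im) + len(self.io) + len(self.mo)

    def counts(self) -> Dict[str, int]:
        return {"IM": len(self.im), "IO": len(self.io), "MO": len(self.mo)}

    def peak_set(self, cls: SiteClass | str) -> PeakSet:
        cls = SiteClass(cls)
        return {SiteClass.IM: self.im, SiteClass.IO: self.io, SiteClass.MO: self.mo}[cls]

    def write(self, outdir: str | Path, prefix: str = "sites") -> None:
        """Emit one BED per class plus a TSV summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cls in SiteClass:
            write_bed(self.peak_set(cls), outdir / f"{prefix}.{cls.value}.bed")
        props = class_proportions(self)
        with open(outdir / f"{prefix}.summary.tsv", "w") as fh:
            fh.write("class\tcount\tfraction\n")
            for cls in SiteClass:
                fh.write(f"{cls.value}\t{len(self.peak_set(cls))}\t{props[cls.value]:.6f}\n")


def _has_overlap(
    iv: GenomicInterval,
    starts: np.ndarray,
    ends: np.ndarray,
    min_overlap: int,
) -> bool:
    """Any interval in (starts, ends) overlapping iv by >= min_overlap bp?

    starts/ends sorted by start; uses max-end prefix to bound the scan.
    """
    if len(starts) == 0:
        return False
    # candidates: starts < iv.end - min_overlap + 1 and ends > iv.start
    hi = int(np.searchsorted(starts, iv.end - min_overlap, side="right"))
    if hi == 0:
        return False
    ov = np.minimum(ends[:hi], iv.end) - np.maximum(starts[:hi], iv.start)
    return bool((ov >= min_overlap).any())


def classify_sites(
    interphase: PeakSet, mitosis: PeakSet, min_overlap: int = 1
) -> ClassifiedSites:
    """Partition two phase-specific peak sets into IM, IO and MO classes."""
    if min_overlap < 1:
        raise ValidationError(f"min_overlap must be >= 1, got {min_overlap}")
    if interphase.genome != mitosis.genome:
        raise ValidationError("interphase and mitosis peak sets use different genomes")

    mito_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in mitosis.by_chrom().items():
        mito_by_chrom[chrom] = (
            np.array([i.start for i in ivs], dtype=np.int64),
            np.array([i.end for i in ivs], dtype=np.int64),
        )
    inter_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in interphase.by_chrom().items():
        inter_by_chrom[chrom] = (
            np.array([i.start for i in ivs], dtype=np.int64),
            np.array([i.end for i in ivs], dtype=np.int64),
        )

    im: List[GenomicInterval] = []
    io: List[GenomicInterval] = []
    for iv in interphase:
        s, e = mito_by_chrom.get(iv.chrom, (np.zeros(0, np.int64), np.zeros(0, np.int64)))
        (im if _has_overlap(iv, s, e, min_overlap) else io).append(iv)

    mo: List[GenomicInterval] = []
    for iv in mitosis:
        s, e = inter_by_chrom.get(iv.chrom, (np.zeros(0, np.int64), np.zeros(0, np.int64)))
        if not _has_overlap(iv, s, e, min_overlap):
            mo.append(iv)

    genome = interphase.genome
    return ClassifiedSites(
        im=PeakSet(im, genome),
        io=PeakSet(io, genome),
        mo=PeakSet(mo, genome),
        source_interphase_count=len(interphase),
        source_mitosis_count=len(mitosis),
        min_overlap=min_overlap,
    )


def class_proportions(c: ClassifiedSites, precision: int | None = None) -> Dict[str, float]:
    """Fractions of IM/IO/MO among all classified sites (they sum to 1)."""
    if c.total == 0:
        raise ValidationError("empty classification has no proportions")
    fracs = {k: v / c.total for k, v in c.counts().items()}
    if precision is not None:
        fracs = {k: round(v, precision) for k, v in fracs.items()}
    return fracs
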
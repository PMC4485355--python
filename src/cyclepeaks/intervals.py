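"""Genomic interval data model, BED/chrom.sizes I/O and primitive operations.

Coordinates are 0-based, half-open (BED convention) throughout the package.
The *anchor* of an interval is its summit when one is recorded, otherwise the
midpoint ``floor((start + end) / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "GenomicInterval",
    "GenomeTable",
    "PeakSet",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "nearest_same_chrom_distance",
    "shuffle_peaks",
]


class ValidationError(ValueError):
    """Raised when an interval, genome table or input file fails validation."""


@dataclass(slots=True)
class GenomicInterval:
    """A genomic interval with optional name, score, strand and summit.

    ``summit`` is an offset from ``start`` (so ``0 <= summit < end - start``),
    marking the single-base position of maximal signal within the interval.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    summit: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.score < 0:
            raise ValidationError(f"negative score {self.score}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValidationError(
                f"summit {self.summit} outside interval of length {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def anchor(self) -> int:
        """Summit position when present, midpoint otherwise (absolute coords)."""
        if self.summit is not None:
            return self.start + self.summit
        return (self.start + self.end) // 2

    def same_identity(self, other: "GenomicInterval") -> bool:
        """Identity for self-exclusion: chrom, start, end and name all equal."""
        return (
            self.chrom == other.chrom
            and self.start == other.start
            and self.end == other.end
            and self.name == other.name
        )

    def shifted(self, new_start: int) -> "GenomicInterval":
        return replace(self, start=new_start, end=new_start + self.length)


class GenomeTable:
    """Mapping of chromosome name to length, with an optional whitelist."""

    def __init__(
        self,
        sizes: Mapping[str, int],
        whitelist: Optional[Sequence[str]] = None,
    ) -> None:
        if whitelist is not None:
            sizes = {c: n for c, n in sizes.items() if c in set(whitelist)}
        for chrom, size in sizes.items():
            if size <= 0:
                raise ValidationError(f"non-positive length {size} for {chrom}")
        self._sizes: Dict[str, int] = dict(sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeTable) and self._sizes == other._sizes

    def chromosomes(self) -> List[str]:
        return sorted(self._sizes)

    def items(self) -> Iterable:
        return sorted(self._sizes.items())

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._sizes:
            raise ValidationError(f"chromosome {iv.chrom!r} not in genome table")
        if iv.end > self._sizes[iv.chrom]:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self._sizes[iv.chrom]}"
            )


class PeakSet:
    """A validated, sorted collection of intervals on one genome.

    Intervals are normalized on construction: sorted by (chrom, start, end,
    name) and each checked against the genome table.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], genome: GenomeTable):
        ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end, i.name))
        for iv in ivs:
            genome.validate_interval(iv)
        self.intervals: List[GenomicInterval] = ivs
        self.genome = genome

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def same_intervals(self, other: "PeakSet") -> bool:
        if len(self) != len(other):
            return False
        return all(a.same_identity(b) for a, b in zip(self.intervals, other.intervals))

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def anchors_by_chrom(self) -> Dict[str, np.ndarray]:
        """Sorted anchor positions per chromosome."""
        out: Dict[str, np.ndarray] = {}
        for chrom, ivs in self.by_chrom().items():
            out[chrom] = np.sort(np.array([iv.anchor for iv in ivs], dtype=np.int64))
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path, whitelist: Optional[Sequence[str]] = None) -> GenomeTable:
    """Read a two-column TSV of chromosome name and length."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns")
            try:
                size = int(fields[1])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
            sizes[fields[0]] = size
    return GenomeTable(sizes, whitelist=whitelist)


def write_chrom_sizes(genome: GenomeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in genome.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path: str | Path, genome: GenomeTable) -> PeakSet:
    """Read BED3/BED6 with an optional 7th summit-offset column.

    A summit column value of ``-1`` means "no summit".
    """
    ivs: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: bad coordinates") from exc
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            summit: Optional[int] = None
            if len(f) > 6 and f[6] not in (".", ""):
                summit = int(f[6])
                if summit < 0:
                    summit = None
            try:
                ivs.append(
                    GenomicInterval(f[0], start, end, name, score, strand, summit)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(ivs, genome)


def _fmt_score(x: float) -> str:
    return f"{x:g}"


def write_bed(peaks: PeakSet | Sequence[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (+summit column when any interval carries one)."""
    ivs = list(peaks)
    with_summit = any(iv.summit is not None for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name, _fmt_score(iv.score), iv.strand]
            if with_summit:
                cols.append(str(iv.summit) if iv.summit is not None else "-1")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def nearest_same_chrom_distance(
    bait: GenomicInterval, targets: PeakSet
) -> Optional[int]:
    """Distance from the bait's anchor to the nearest target anchor on the
    same chromosome, excluding targets identical to the bait.

    Returns ``None`` when no eligible same-chromosome target exists.
    """
    best: Optional[int] = None
    a = bait.anchor
    for t in targets:
        if t.chrom != bait.chrom or t.same_identity(bait):
            continue
        d = abs(a - t.anchor)
        if best is None or d < best:
            best = d
    return best


def nearest_distances(
    bait_anchors: np.ndarray, target_anchors: np.ndarray, same_set: bool = False
) -> np.ndarray:
    """Vectorized nearest-anchor distances on one chromosome.

    ``target_anchors`` must be sorted. With ``same_set=True`` the arrays are
    the same positions and each element is excluded from its own search
    (duplicated positions still yield distance 0, as two distinct sites may
    share an anchor).
    """
    b = np.asarray(bait_anchors, dtype=np.int64)
    t = np.asarray(target_anchors, dtype=np.int64)
    if same_set:
        if len(t) < 2:
            return np.zeros(0, dtype=np.int64)
        s = np.sort(t)
        gaps = np.diff(s)
        left = np.concatenate(([np.iinfo(np.int64).max], gaps))
        right = np.concatenate((gaps, [np.iinfo(np.int64).max]))
        return np.minimum(left, right)
    if len(t) == 0:
        return np.zeros(0, dtype=np.int64)
    idx = np.searchsorted(t, b)
    lo = np.clip(idx - 1, 0, len(t) - 1)
    hi = np.clip(idx, 0, len(t) - 1)
    return np.minimum(np.abs(b - t[lo]), np.abs(b - t[hi]))


def shuffle_peaks(
    peaks: PeakSet,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PeakSet:
    """Uniformly re-place each interval on its own chromosome.

    Lengths, chromosome assignment and per-interval metadata (name, score,
    strand, summit offset) are preserved; overlaps among shuffled intervals
    are allowed. Deterministic for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    genome = peaks.genome
    out: List[GenomicInterval] = []
    for chrom, ivs in sorted(peaks.by_chrom().items()):
        chrom_len = genome[chrom]
        lengths = np.array([iv.length for iv in ivs], dtype=np.int64)
        too_long = lengths > chrom_len
        if too_long.any():
            bad = ivs[int(np.argmax(too_long))]
            raise ValidationError(
                f"interval {bad.chrom}:{bad.start}-{bad.end} ({bad.name}) longer "
                f"than chromosome ({chrom_len} bp)"
            )
        starts = rng.integers(0, chrom_len - lengths + 1)
        out.extend(iv.shifted(int(s)) for iv, s in zip(ivs, starts))
    return PeakSet(out, genome)
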
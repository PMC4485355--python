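"""Step-function signal tracks (bedGraph) and meta-profiles around anchors.

A profile averages the length-weighted mean track value in fixed bins of a
symmetric window around each site anchor; regions without data count as 0.
Windows clipped at chromosome ends contribute only the bins that lie fully
inside the chromosome, and each bin's denominator counts only the sites
covering it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomeTable, PeakSet, ValidationError

__all__ = ["SignalTrack", "MetaProfile", "read_bedgraph", "aggregate_profile"]


class SignalTrack:
    """Per-chromosome sorted, non-overlapping (start, end, value) segments."""

    def __init__(self, segments: Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: Dict[str, np.ndarray] = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if (ends <= starts).any():
                raise ValidationError(f"{chrom}: empty or inverted segment")
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError(f"{chrom}: overlapping segments")
            self._data[chrom] = (starts, ends, values)
            # cumulative integral up to each segment start, for O(log n) queries
            self._cum[chrom] = np.concatenate(
                ([0.0], np.cumsum(values * (ends - starts)))
            )

    @classmethod
    def from_intervals(cls, rows: List[Tuple[str, int, int, float]]) -> "SignalTrack":
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, s, e, v in rows:
            by_chrom.setdefault(chrom, []).append((s, e, v))
        return cls(
            {
                chrom: (
                    np.array([r[0] for r in segs]),
                    np.array([r[1] for r in segs]),
                    np.array([r[2] for r in segs]),
                )
                for chrom, segs in by_chrom.items()
            }
        )

    def chromosomes(self) -> List[str]:
        return sorted(self._data)

    def integral(self, chrom: str, a: int, b: int) -> float:
        """Integral of the step function over [a, b); absent data counts 0."""
        if b <= a:
            return 0.0
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        cum = self._cum[chrom]
        # segments fully before b / a
        i = int(np.searchsorted(ends, a, side="right"))
        j = int(np.searchsorted(starts, b, side="left"))
        total = 0.0
        for k in range(i, j):
            lo = max(a, int(starts[k]))
            hi = min(b, int(ends[k]))
            if hi > lo:
                total += float(values[k]) * (hi - lo)
        return total

    def mean_over(self, chrom: str, a: int, b: int) -> float:
        """Length-weighted mean over [a, b) with absent regions as 0."""
        if b <= a:
            return 0.0
        return self.integral(chrom, a, b) / (b - a)

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chromosomes():
                starts, ends, values = self._data[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    rows: List[Tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 columns")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return SignalTrack.from_intervals(rows)


@dataclass
class MetaProfile:
    """Mean signal per offset bin around site anchors.

    ``offsets`` are bin-start offsets from the anchor; the bin with offset 0
    starts at the anchor. ``n_per_bin`` is the per-bin site denominator.
    """

    offsets: np.ndarray
    mean: np.ndarray
    n_sites: int
    n_per_bin: np.ndarray
    bin_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "n": self.n_per_bin}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def aggregate_profile(
    sites: PeakSet, track: SignalTrack, flank: int, bin: int
) -> MetaProfile:
    """Average track signal in bins of the window [anchor-flank, anchor+flank)."""
    if len(sites) == 0:
        raise ValidationError("empty site set")
    if flank % bin != 0:
        raise ValidationError("flank must be divisible by bin")
    nbins = 2 * flank // bin
    offsets = np.arange(-flank, flank, bin, dtype=np.int64)
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    genome = sites.genome
    for iv in sites:
        anchor = iv.anchor
        chrom_len = genome[iv.chrom]
        for k in range(nbins):
            a = anchor + int(offsets[k])
            b = a + bin
            if a < 0 or b > chrom_len:
                continue  # clipped bins excluded
            sums[k] += track.mean_over(iv.chrom, a, b)
            counts[k] += 1
    mean = np.divide(sums, counts, out=np.zeros(nbins), where=counts > 0)
    return MetaProfile(
        offsets=offsets, mean=mean, n_sites=len(sites), n_per_bin=counts, bin_size=bin
    )
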
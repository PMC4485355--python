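"""Spatial statistics: nearest-neighbor distance permutation tests, domain
boundary enrichment profiles, boundary labeling, and minimum-domain-number
spacing tests against label-permutation nulls.

Permutation nulls pool the per-permutation statistic distributions with
equal weight into a single null sample and compare observed vs null with a
two-sided Wilcoxon rank-sum test; per-permutation medians are retained so
alternative summaries can be inspected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .classify import ClassifiedSites, SiteClass
from .intervals import (
    GenomeTable,
    GenomicInterval,
    PeakSet,
    ValidationError,
    nearest_distances,
)
from .tracks import MetaProfile

__all__ = [
    "DomainSet",
    "LabeledBoundary",
    "PermutationTestResult",
    "read_domain_bed",
    "nearest_neighbor_permutation_test",
    "boundary_enrichment_profile",
    "label_boundaries",
    "boundary_spacing_permutation_test",
    "write_labeled_boundaries",
]


class DomainSet:
    """Ordered, non-overlapping domain intervals per chromosome."""

    def __init__(
        self,
        domains: Sequence[GenomicInterval],
        genome: GenomeTable,
        kind: str = "TAD",
    ) -> None:
        if kind not in ("TAD", "synteny12D", "syntenyHD"):
            raise ValidationError(f"unknown domain kind {kind!r}")
        self.kind = kind
        self.genome = genome
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for d in sorted(domains, key=lambda i: (i.chrom, i.start)):
            genome.validate_interval(d)
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, ds in by_chrom.items():
            for a, b in zip(ds, ds[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"overlapping domains on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )
        self._by_chrom = by_chrom

    def chromosomes(self) -> List[str]:
        return sorted(self._by_chrom)

    def domains(self, chrom: str) -> List[GenomicInterval]:
        return self._by_chrom.get(chrom, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def boundary_positions(self, chrom: str) -> np.ndarray:
        """Unique sorted edge positions of the chromosome's domains."""
        pos: Set[int] = set()
        for d in self._by_chrom.get(chrom, []):
            pos.add(d.start)
            pos.add(d.end)
        return np.array(sorted(pos), dtype=np.int64)


def read_domain_bed(path: str | Path, genome: GenomeTable, kind: str = "TAD") -> DomainSet:
    from .intervals import read_bed

    return DomainSet(list(read_bed(path, genome)), genome, kind=kind)


@dataclass
class LabeledBoundary:
    """A domain boundary with its ordinal index and the site classes it holds."""

    chrom: str
    start: int
    end: int  # end == start for point boundaries
    index: int
    labels: Set[str] = field(default_factory=set)

    @property
    def position(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PermutationTestResult:
    """Observed and pooled-null statistic samples with a Wilcoxon p-value."""

    observed: np.ndarray
    null: np.ndarray
    n_perm: int
    seed: Optional[int]
    p_value: float
    statistic_name: str
    perm_medians: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def observed_median(self) -> float:
        return float(np.median(self.observed))

    @property
    def null_median(self) -> float:
        return float(np.median(self.null))

    def summary(self) -> Dict[str, object]:
        return {
            "statistic": self.statistic_name,
            "n_observed": int(len(self.observed)),
            "n_null": int(len(self.null)),
            "n_perm": self.n_perm,
            "seed": self.seed,
            "p_value": self.p_value,
            "observed_median": self.observed_median,
            "null_median": self.null_median,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Nearest-neighbor permutation test
# ---------------------------------------------------------------------------

def _peaks_arrays(peaks: PeakSet) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (lengths, anchor offsets from start), in sorted order."""
    out = {}
    for chrom, ivs in sorted(peaks.by_chrom().items()):
        lengths = np.array([iv.length for iv in ivs], dtype=np.int64)
        offs = np.array([iv.anchor - iv.start for iv in ivs], dtype=np.int64)
        out[chrom] = (lengths, offs)
    return out


def _observed_nn(baits: PeakSet, targets: PeakSet, same_set: bool) -> np.ndarray:
    dists: List[np.ndarray] = []
    t_anchors = targets.anchors_by_chrom()
    if same_set:
        for chrom in sorted(t_anchors):
            dists.append(nearest_distances(t_anchors[chrom], t_anchors[chrom], True))
    else:
        b_anchors = baits.anchors_by_chrom()
        for chrom in sorted(b_anchors):
            if chrom not in t_anchors:
                continue
            dists.append(nearest_distances(b_anchors[chrom], t_anchors[chrom], False))
    if not dists:
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(dists)


def _shuffled_anchors(
    arrays: Dict[str, Tuple[np.ndarray, np.ndarray]],
    genome: GenomeTable,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Anchors after a chromosome-preserving uniform shuffle of the intervals.

    Draw-for-draw equivalent to `intervals.shuffle_peaks` on the same rng.
    """
    out = {}
    for chrom, (lengths, offs) in arrays.items():
        starts = rng.integers(0, genome[chrom] - lengths + 1)
        out[chrom] = np.sort(starts + offs)
    return out


def nearest_neighbor_permutation_test(
    baits: PeakSet,
    targets: PeakSet,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    statistic_name: str = "nearest_distance",
) -> PermutationTestResult:
    """Observed nearest-same-chromosome distances vs a shuffled-location null.

    When baits and targets are the same set, self-matches are excluded and
    each permutation shuffles the single set (bait and target positions move
    together). Otherwise targets alone are shuffled. The null pools all
    permutations with equal weight; p is a two-sided Wilcoxon rank-sum.
    """
    genome = baits.genome
    if genome != targets.genome:
        raise ValidationError("baits and targets use different genomes")
    same_set = baits is targets or baits.same_intervals(targets)

    observed = _observed_nn(baits, targets, same_set)
    if len(observed) < 2:
        raise ValidationError("insufficient sites: fewer than 2 finite distances")

    rng = np.random.default_rng(seed)
    t_arrays = _peaks_arrays(targets)
    b_anchors = None if same_set else baits.anchors_by_chrom()
    null_parts: List[np.ndarray] = []
    perm_medians = np.zeros(n_perm)
    for p in range(n_perm):
        shuf = _shuffled_anchors(t_arrays, genome, rng)
        dists: List[np.ndarray] = []
        for chrom in sorted(shuf):
            if same_set:
                dists.append(nearest_distances(shuf[chrom], shuf[chrom], True))
            else:
                if chrom in b_anchors:
                    dists.append(nearest_distances(b_anchors[chrom], shuf[chrom], False))
        d = np.concatenate(dists) if dists else np.zeros(0, dtype=np.int64)
        null_parts.append(d)
        perm_medians[p] = np.median(d) if len(d) else np.nan
    null = np.concatenate(null_parts)
    stat, p_value = stats.ranksums(observed, null)
    return PermutationTestResult(
        observed=observed,
        null=null,
        n_perm=n_perm,
        seed=seed,
        p_value=float(p_value),
        statistic_name=statistic_name,
        perm_medians=perm_medians,
    )


# ---------------------------------------------------------------------------
# Boundary enrichment profile
# ---------------------------------------------------------------------------

def boundary_enrichment_profile(
    sites: PeakSet, domains: DomainSet, flank: int, bin: int
) -> MetaProfile:
    """Site density around domain edges, oriented inside-negative.

    Every domain contributes both edges; anchors on the domain-interior side
    get negative signed distances and anchors outside positive ones. The
    profile is the per-bin site count divided by the number of boundary
    edges (2 x number of domains).
    """
    if len(domains) == 0:
        raise ValidationError("empty domain set")
    if flank % bin != 0:
        raise ValidationError("flank must be divisible by bin")
    nbins = 2 * flank // bin
    offsets = np.arange(-flank, flank, bin, dtype=np.int64)
    counts = np.zeros(nbins, dtype=np.int64)
    anchors = sites.anchors_by_chrom()
    n_boundaries = 0
    for chrom in domains.chromosomes():
        ds = domains.domains(chrom)
        n_boundaries += 2 * len(ds)
        a = anchors.get(chrom)
        if a is None or len(a) == 0:
            continue
        for d in ds:
            # left edge: interior to the right -> signed = start - anchor
            # right edge: interior to the left -> signed = anchor - end
            for signed in np.concatenate((d.start - a, a - d.end)):
                if -flank <= signed < flank:
                    counts[(signed + flank) // bin] += 1
    mean = counts / n_boundaries
    return MetaProfile(
        offsets=offsets,
        mean=mean,
        n_sites=len(sites),
        n_per_bin=np.full(nbins, n_boundaries, dtype=np.int64),
        bin_size=bin,
    )


# ---------------------------------------------------------------------------
# Boundary labeling and spacing test
# ---------------------------------------------------------------------------

def label_boundaries(
    domains: DomainSet,
    c: ClassifiedSites,
    boundary_window: int = 500,
) -> List[LabeledBoundary]:
    """Label each boundary with the site classes overlapping it.

    Boundaries are the unique domain edge positions per chromosome, indexed
    in coordinate order. Point boundaries use a +/- ``boundary_window`` bp
    containment interval; a label requires >= 1 bp overlap with a site of
    that class. Unlabeled boundaries are retained.
    """
    out: List[LabeledBoundary] = []
    class_ivs: Dict[str, Dict[str, List[GenomicInterval]]] = {
        cls.value: c.peak_set(cls).by_chrom() for cls in SiteClass
    }
    for chrom in domains.chromosomes():
        positions = domains.boundary_positions(chrom)
        for idx, pos in enumerate(positions):
            lb = LabeledBoundary(chrom, int(pos), int(pos), idx)
            lo, hi = pos - boundary_window, pos + boundary_window
            for cls_name, by_chrom in class_ivs.items():
                for iv in by_chrom.get(chrom, []):
                    if iv.start < hi and iv.end > lo:
                        lb.labels.add(cls_name)
                        break
            out.append(lb)
    return out


def write_labeled_boundaries(boundaries: Sequence[LabeledBoundary], path: str | Path) -> None:
    """BED output with comma-separated labels in the name field."""
    with open(path, "w") as fh:
        for b in boundaries:
            name = ",".join(sorted(b.labels)) if b.labels else "."
            fh.write(f"{b.chrom}\t{b.start}\t{max(b.end, b.start + 1)}\t{name}\n")


def _domains_between(
    starts: np.ndarray, ends: np.ndarray, lo: int, hi: int
) -> int:
    """Number of domains fully contained in [lo, hi]."""
    i = int(np.searchsorted(starts, lo, side="left"))
    j = int(np.searchsorted(ends, hi, side="right"))
    return max(0, j - i)


def _spacing_statistics(
    positions: np.ndarray,
    labeled_idx: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
) -> np.ndarray:
    """Min domains separating each labeled boundary from its nearest same-label
    partner on the chromosome (one value per labeled boundary)."""
    k = len(labeled_idx)
    out = np.zeros(k, dtype=np.int64)
    pos = positions[labeled_idx]
    for i in range(k):
        best = None
        for j in range(k):
            if i == j:
                continue
            lo, hi = int(min(pos[i], pos[j])), int(max(pos[i], pos[j]))
            n = _domains_between(starts, ends, lo, hi)
            if best is None or n < best:
                best = n
        out[i] = best
    return out


def boundary_spacing_permutation_test(
    domains: DomainSet,
    boundaries: Sequence[LabeledBoundary],
    site_class: SiteClass | str,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> PermutationTestResult:
    """Minimum-domain-number spacing of same-label boundaries vs permuted labels.

    For each boundary carrying the class label, the statistic is the number
    of domains separating it from the nearest other boundary with the same
    label on the same chromosome (adjacent boundaries of one domain are 1
    apart). The null permutes the label assignment uniformly over each
    chromosome's boundaries, preserving the per-chromosome label count, and
    pools ``n_perm`` permutations. Chromosomes with fewer than 2 labeled
    boundaries contribute nothing; if no chromosome has 2, an error is raised.
    """
    cls = SiteClass(site_class).value
    by_chrom: Dict[str, List[LabeledBoundary]] = {}
    for b in boundaries:
        by_chrom.setdefault(b.chrom, []).append(b)

    rng = np.random.default_rng(seed)
    observed_parts: List[np.ndarray] = []
    chrom_setups = []  # (positions, n_labeled, starts, ends)
    for chrom in sorted(by_chrom):
        bs = sorted(by_chrom[chrom], key=lambda b: b.index)
        positions = np.array([b.position for b in bs], dtype=np.int64)
        labeled_idx = np.array(
            [i for i, b in enumerate(bs) if cls in b.labels], dtype=np.int64
        )
        if len(labeled_idx) < 2:
            continue
        ds = domains.domains(chrom)
        starts = np.array([d.start for d in ds], dtype=np.int64)
        ends = np.array([d.end for d in ds], dtype=np.int64)
        observed_parts.append(_spacing_statistics(positions, labeled_idx, starts, ends))
        chrom_setups.append((positions, len(labeled_idx), starts, ends))
    if not observed_parts:
        raise ValidationError(
            f"fewer than 2 {cls}-labeled boundaries on every chromosome"
        )
    observed = np.concatenate(observed_parts)

    null_parts: List[np.ndarray] = []
    perm_medians = np.zeros(n_perm)
    for p in range(n_perm):
        parts = []
        for positions, k, starts, ends in chrom_setups:
            perm_idx = np.sort(rng.choice(len(positions), size=k, replace=False))
            parts.append(_spacing_statistics(positions, perm_idx, starts, ends))
        d = np.concatenate(parts)
        null_parts.append(d)
        perm_medians[p] = np.median(d)
    null = np.concatenate(null_parts)
    _, p_value = stats.ranksums(observed, null)
    return PermutationTestResult(
        observed=observed,
        null=null,
        n_perm=n_perm,
        seed=seed,
        p_value=float(p_value),
        statistic_name=f"min_domains_between_{cls}_boundaries",
        perm_medians=perm_medians,
    )
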
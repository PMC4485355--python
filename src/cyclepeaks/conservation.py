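"""Cross-species coordinate lift-over through chain alignments and
observed/expected conservation ratios per site class.

A chain maps intervals from its *target* genome to its *query* genome through
ungapped aligned blocks. An interval maps when at least ``min_match`` of its
bases fall in aligned blocks of the best covering chain; the result is the
minimal query interval spanning all mapped bases, flipped to the forward
strand for minus-strand chains (mirroring liftOver -minMatch semantics).

The *expected* number of conserved sites in a class is the class-size
proportional share of all conserved sites; shuffle-based expectations can be
built by the caller from `intervals.shuffle_peaks` if preferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifiedSites, SiteClass
from .intervals import GenomicInterval, PeakSet, ValidationError

__all__ = [
    "Chain",
    "read_chains",
    "write_chains",
    "map_through_chain",
    "liftover_peaks",
    "ConservationTable",
    "build_conservation_table",
    "observed_expected_conservation",
]


@dataclass
class Chain:
    """One UCSC chain: header fields plus (size, dt, dq) block triples.

    ``blocks`` has one triple per aligned block; the final block's gaps are
    zero. Query coordinates of minus-strand chains are on the reversed
    strand, as in the UCSC format.
    """

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: List[Tuple[int, int, int]]

    def __post_init__(self) -> None:
        if self.t_strand != "+":
            raise ValidationError(f"chain {self.chain_id}: target strand must be +")
        if self.q_strand not in ("+", "-"):
            raise ValidationError(f"chain {self.chain_id}: bad query strand")
        t_span = sum(s + dt for s, dt, _ in self.blocks)
        q_span = sum(s + dq for s, _, dq in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ValidationError(
                f"chain {self.chain_id}: block sizes + target gaps ({t_span}) "
                f"do not equal target span ({self.t_end - self.t_start})"
            )
        if q_span != self.q_end - self.q_start:
            raise ValidationError(
                f"chain {self.chain_id}: block sizes + query gaps ({q_span}) "
                f"do not equal query span ({self.q_end - self.q_start})"
            )

    def block_coords(self) -> List[Tuple[int, int, int]]:
        """(t_block_start, q_block_start, size) for each aligned block.

        Query starts are in chain-strand coordinates (reversed for '-').
        """
        out = []
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            out.append((t, q, size))
            t += size + dt
            q += size + dq
        return out

    def q_forward(self, qpos: int) -> int:
        """Convert a chain-strand query position to forward-strand coords."""
        if self.q_strand == "+":
            return qpos
        return self.q_size - qpos - 1


def read_chains(path: str | Path) -> List[Chain]:
    """Parse a UCSC chain file (possibly containing several chains)."""
    chains: List[Chain] = []
    header: Optional[List[str]] = None
    blocks: List[Tuple[int, int, int]] = []

    def flush() -> None:
        nonlocal header, blocks
        if header is None:
            return
        chains.append(
            Chain(
                score=float(header[1]),
                t_name=header[2],
                t_size=int(header[3]),
                t_strand=header[4],
                t_start=int(header[5]),
                t_end=int(header[6]),
                q_name=header[7],
                q_size=int(header[8]),
                q_strand=header[9],
                q_start=int(header[10]),
                q_end=int(header[11]),
                chain_id=int(header[12]) if len(header) > 12 else len(chains),
                blocks=blocks,
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                flush()
                header = line.split()
                if len(header) < 12:
                    raise ValidationError(f"{path}:{lineno}: short chain header")
                blocks = []
            else:
                f = line.split()
                if header is None:
                    raise ValidationError(f"{path}:{lineno}: block outside chain")
                if len(f) == 3:
                    blocks.append((int(f[0]), int(f[1]), int(f[2])))
                elif len(f) == 1:
                    blocks.append((int(f[0]), 0, 0))
                else:
                    raise ValidationError(f"{path}:{lineno}: bad block line")
    flush()
    return chains


def write_chains(chains: Sequence[Chain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for i, (size, dt, dq) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")
            fh.write("\n")


def map_through_chain(
    interval: GenomicInterval,
    chains: Sequence[Chain],
    min_match: float = 0.5,
) -> Optional[GenomicInterval]:
    """Map an interval from chain target coordinates to query coordinates.

    Selects the highest-scoring chain whose target span overlaps the
    interval (ties broken by lowest chain id), maps each base through its
    aligned blocks and, when the mapped-base fraction reaches ``min_match``,
    returns the minimal query interval spanning all mapped bases on the
    forward strand. Returns None otherwise.
    """
    candidates = [
        c
        for c in chains
        if c.t_name == interval.chrom
        and c.t_start < interval.end
        and c.t_end > interval.start
    ]
    if not candidates:
        return None
    chain = min(candidates, key=lambda c: (-c.score, c.chain_id))

    mapped = 0
    q_lo: Optional[int] = None
    q_hi: Optional[int] = None
    for t0, q0, size in chain.block_coords():
        lo = max(t0, interval.start)
        hi = min(t0 + size, interval.end)
        if hi <= lo:
            continue
        mapped += hi - lo
        qa = q0 + (lo - t0)
        qb = q0 + (hi - t0) - 1  # inclusive chain-strand endpoints
        fa, fb = chain.q_forward(qa), chain.q_forward(qb)
        a, b = min(fa, fb), max(fa, fb)
        q_lo = a if q_lo is None else min(q_lo, a)
        q_hi = b if q_hi is None else max(q_hi, b)
    if mapped == 0 or mapped / interval.length < min_match:
        return None
    assert q_lo is not None and q_hi is not None
    return GenomicInterval(
        chain.q_name, q_lo, q_hi + 1, interval.name, interval.score, interval.strand
    )


def liftover_peaks(
    peaks: PeakSet | Sequence[GenomicInterval],
    chains: Sequence[Chain],
    query_genome,
    min_match: float = 0.5,
) -> PeakSet:
    """Map every interval of a set; unmapped intervals are dropped."""
    mapped = []
    for iv in peaks:
        m = map_through_chain(iv, chains, min_match)
        if m is not None:
            mapped.append(m)
    return PeakSet(mapped, query_genome)


# ---------------------------------------------------------------------------
# Conservation table and observed/expected ratios
# ---------------------------------------------------------------------------

class ConservationTable:
    """Per-site, per-species conservation flags for a reference site list.

    A reference site is conserved in a species when it overlaps (>= 1 bp) at
    least one of that species' lifted-over sites. ``conserved_in_at_least(N)``
    counts the reference species itself, so N=2 means "this species plus at
    least one other".
    """

    def __init__(self, sites: Sequence[GenomicInterval], species: Sequence[str]):
        self.sites = list(sites)
        self.species = list(species)
        self.flags = pd.DataFrame(
            False,
            index=range(len(self.sites)),
            columns=self.species,
            dtype=bool,
        )

    def n_species_conserved(self) -> np.ndarray:
        """Number of species supporting each site, reference included."""
        return 1 + self.flags.to_numpy().sum(axis=1)

    def conserved_in_at_least(self, n: int) -> np.ndarray:
        return self.n_species_conserved() >= n

    def site_key(self, iv: GenomicInterval) -> Tuple[str, int, int, str]:
        return (iv.chrom, iv.start, iv.end, iv.name)


def _overlaps_any(iv: GenomicInterval, starts: np.ndarray, ends: np.ndarray) -> bool:
    if len(starts) == 0:
        return False
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    if hi == 0:
        return False
    return bool((ends[:hi] > iv.start).any())


def build_conservation_table(
    sites: PeakSet | Sequence[GenomicInterval],
    lifted: Mapping[str, PeakSet],
) -> ConservationTable:
    """Overlap reference sites against per-species lifted-over peak sets."""
    table = ConservationTable(list(sites), sorted(lifted))
    per_species: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]] = {}
    for sp, ps in lifted.items():
        per_species[sp] = {
            chrom: (
                np.array([i.start for i in ivs], dtype=np.int64),
                np.array([i.end for i in ivs], dtype=np.int64),
            )
            for chrom, ivs in ps.by_chrom().items()
        }
    for idx, iv in enumerate(table.sites):
        for sp in table.species:
            s, e = per_species[sp].get(
                iv.chrom, (np.zeros(0, np.int64), np.zeros(0, np.int64))
            )
            if _overlaps_any(iv, s, e):
                table.flags.loc[idx, sp] = True
    return table


def observed_expected_conservation(
    c: ClassifiedSites,
    table: ConservationTable,
    n: int,
) -> pd.DataFrame:
    """Per-class O/E conservation ratio at support level >= n species.

    Observed is the number of class sites conserved in at least ``n``
    species; expected allocates the total conserved count proportionally to
    class size. The Fisher p compares each class against all other classes
    on conserved / not-conserved counts. MO rows carry a caveat flag: when
    no mitosis-phase data exist for the non-reference species the MO ratio
    is not interpretable as evolutionary conservation.
    """
    if not (2 <= n <= 1 + len(table.species)):
        raise ValidationError(f"n={n} outside supported range")
    key_to_idx = {table.site_key(iv): i for i, iv in enumerate(table.sites)}
    conserved = table.conserved_in_at_least(n)

    class_idx: Dict[str, np.ndarray] = {}
    for cls in SiteClass:
        idx = []
        for iv in c.peak_set(cls):
            k = (iv.chrom, iv.start, iv.end, iv.name)
            if k not in key_to_idx:
                raise ValidationError(f"site {k} of class {cls.value} absent from table")
            idx.append(key_to_idx[k])
        class_idx[cls.value] = np.array(idx, dtype=np.int64)

    total_sites = sum(len(v) for v in class_idx.values())
    total_conserved = int(
        sum(conserved[v].sum() for v in class_idx.values())
    )
    rows = []
    for cls in SiteClass:
        idx = class_idx[cls.value]
        size = len(idx)
        obs = int(conserved[idx].sum()) if size else 0
        exp = total_conserved * size / total_sites if total_sites else float("nan")
        ratio = obs / exp if exp > 0 else float("nan")
        other_size = total_sites - size
        other_obs = total_conserved - obs
        if size and other_size:
            _, p = stats.fisher_exact(
                [[obs, size - obs], [other_obs, other_size - other_obs]],
                alternative="two-sided",
            )
        else:
            p = float("nan")
        rows.append(
            {
                "class": cls.value,
                "n_species": n,
                "observed": obs,
                "expected": exp,
                "ratio": ratio,
                "fisher_p": float(p),
                "caveat": "no cross-species mitosis data" if cls is SiteClass.MO else "",
            }
        )
    return pd.DataFrame(rows)
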
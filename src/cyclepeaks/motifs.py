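"""Position weight matrix scanning and two-part motif occurrence fractions.

Scores are log2 odds of the pseudocount-smoothed PWM against the background
distribution, scanned on both strands. A site is two-part-positive when a
module A hit and a module B hit lie on the same strand with A 5' of B and a
gap (in bp between the end of A and the start of B, reading 5'->3') within
the configured range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import ClassifiedSites, SiteClass
from .intervals import GenomicInterval, ValidationError

__all__ = [
    "PWM",
    "Hit",
    "TwoPartMotif",
    "scan_pwm",
    "two_part_hit",
    "two_part_fraction",
    "read_jaspar",
    "read_meme_minimal",
    "default_two_part_motif",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PWM:
    """Per-position base probabilities with pseudocount smoothing.

    The stored matrix is re-normalized after adding ``pseudocount`` to every
    cell, so rows sum to 1 exactly.
    """

    def __init__(
        self,
        matrix: np.ndarray,
        pseudocount: float = 0.001,
        background: Optional[Sequence[float]] = None,
        name: str = "pwm",
    ) -> None:
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValidationError("PWM matrix must be L x 4")
        if (m < 0).any():
            raise ValidationError("PWM matrix entries must be nonnegative")
        m = m + pseudocount
        rowsum = m.sum(axis=1, keepdims=True)
        if (rowsum == 0).any():
            raise ValidationError("PWM has an all-zero row and zero pseudocount")
        self.matrix = m / rowsum
        self.pseudocount = pseudocount
        bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
        if not np.isclose(bg.sum(), 1.0):
            raise ValidationError("background frequencies must sum to 1")
        self.background = bg
        self.name = name

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 matrix of log2(p / q); -inf where p == 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        p: float = 0.97,
        pseudocount: float = 0.001,
        background: Optional[Sequence[float]] = None,
        name: str = "pwm",
    ) -> "PWM":
        """High-information PWM giving probability ``p`` to the consensus base."""
        off = (1 - p) / 3
        m = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus.upper()):
            if b not in _BASE_INDEX:
                raise ValidationError(f"non-ACGT consensus base {b!r}")
            m[i, _BASE_INDEX[b]] = p
        return cls(m, pseudocount=pseudocount, background=background, name=name)


@dataclass(frozen=True)
class Hit:
    offset: int  # forward-strand offset of the match start
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i
    return code[arr]


def _scan_one_strand(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Score at every offset; windows containing non-ACGT bases get -inf."""
    L = lod.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i in range(L):
        c = codes[i : i + n]
        bad = c < 0
        valid &= ~bad
        scores += np.where(bad, 0.0, lod[i, np.clip(c, 0, 3)])
    scores[~valid] = -np.inf
    return scores


def scan_pwm(sequence: str, pwm: PWM, threshold_bits: float) -> List[Hit]:
    """All hits with log-odds score >= threshold on either strand.

    Minus-strand hits are reported at the forward-strand offset where the
    (reverse-complemented) match begins, so offsets of + and - hits index
    the same coordinate system.
    """
    if not np.isfinite(threshold_bits):
        raise ValidationError("threshold must be finite")
    L = len(pwm)
    if len(sequence) < L:
        return []
    codes = _encode(sequence)
    lod = pwm.log_odds
    hits: List[Hit] = []
    fwd = _scan_one_strand(codes, lod)
    for off in np.flatnonzero(fwd >= threshold_bits):
        hits.append(Hit(int(off), "+", float(fwd[off])))
    rc_codes = _encode(reverse_complement(sequence))
    rev = _scan_one_strand(rc_codes, lod)
    n = len(sequence)
    for off in np.flatnonzero(rev >= threshold_bits):
        hits.append(Hit(n - L - int(off), "-", float(rev[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


@dataclass
class TwoPartMotif:
    """Bipartite motif: module A 5' of module B, separated by a bounded gap."""

    module_a: PWM
    module_b: PWM
    min_gap: int = 0
    max_gap: int = 15
    threshold_a: Optional[float] = None  # bits; default 60% of max
    threshold_b: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.min_gap <= self.max_gap):
            raise ValidationError("need 0 <= min_gap <= max_gap")
        if self.threshold_a is None:
            self.threshold_a = 0.6 * self.module_a.max_score
        if self.threshold_b is None:
            self.threshold_b = 0.6 * self.module_b.max_score

    @property
    def span(self) -> int:
        return len(self.module_a) + self.max_gap + len(self.module_b)


def two_part_hit(sequence: str, motif: TwoPartMotif) -> bool:
    """True when the sequence contains a valid A+gap+B arrangement."""
    a_hits = scan_pwm(sequence, motif.module_a, motif.threshold_a)
    if not a_hits:
        return False
    b_hits = scan_pwm(sequence, motif.module_b, motif.threshold_b)
    if not b_hits:
        return False
    la, lb = len(motif.module_a), len(motif.module_b)
    for a in a_hits:
        for b in b_hits:
            if a.strand != b.strand:
                continue
            if a.strand == "+":
                gap = b.offset - (a.offset + la)
            else:
                # 5'->3' on the minus strand runs right to left in forward coords
                gap = a.offset - (b.offset + lb)
            if motif.min_gap <= gap <= motif.max_gap:
                return True
    return False


def two_part_fraction(
    c: ClassifiedSites,
    sequences: Mapping[str, str],
    motif: TwoPartMotif,
    window: int = 100,
) -> pd.DataFrame:
    """Per-class fraction of sites containing the two-part motif.

    Each site contributes the sequence ``[anchor - window, anchor + window)``
    (clipped at chromosome ends). Empty classes yield a NaN fraction.
    """
    rows = []
    for cls in SiteClass:
        peaks = c.peak_set(cls)
        if len(peaks) == 0:
            rows.append(
                {"class": cls.value, "n": 0, "positives": 0, "fraction": float("nan")}
            )
            continue
        pos = 0
        for site in peaks:
            seq = sequences[site.chrom]
            a = site.anchor
            lo, hi = max(0, a - window), min(len(seq), a + window)
            if two_part_hit(str(seq[lo:hi]), motif):
                pos += 1
        rows.append(
            {
                "class": cls.value,
                "n": len(peaks),
                "positives": pos,
                "fraction": pos / len(peaks),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_jaspar(path: str | Path, pseudocount: float = 0.001) -> PWM:
    """Read a JASPAR-format matrix (4 bracketed count rows for A/C/G/T)."""
    name = "jaspar"
    rows: Dict[str, List[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            base = line[0].upper()
            if base not in _BASE_INDEX:
                raise ValidationError(f"unexpected JASPAR row {line[:20]!r}")
            nums = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in nums]
    if sorted(rows) != list("ACGT"):
        raise ValidationError("JASPAR matrix must have A, C, G and T rows")
    lens = {len(v) for v in rows.values()}
    if len(lens) != 1:
        raise ValidationError("JASPAR rows have unequal lengths")
    m = np.array([rows[b] for b in _BASES]).T
    return PWM(m, pseudocount=pseudocount, name=name)


def read_meme_minimal(path: str | Path, pseudocount: float = 0.001) -> List[PWM]:
    """Read PWMs from MEME minimal motif format."""
    pwms: List[PWM] = []
    name = None
    rows: List[List[float]] = []
    background = None
    in_matrix = False
    with open(path) as fh:
        lines = list(fh)
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            freqs = lines[i + 1].split()
            background = [float(freqs[j]) for j in (1, 3, 5, 7)]
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            continue
        if line.startswith("letter-probability matrix"):
            in_matrix = True
            rows = []
            i += 1
            continue
        if in_matrix:
            parts = line.split()
            if len(parts) == 4:
                rows.append([float(x) for x in parts])
                i += 1
                continue
            in_matrix = False
            pwms.append(
                PWM(np.array(rows), pseudocount=pseudocount, background=background,
                    name=name or f"motif{len(pwms) + 1}")
            )
            continue
        i += 1
    if in_matrix and rows:
        pwms.append(
            PWM(np.array(rows), pseudocount=pseudocount, background=background,
                name=name or f"motif{len(pwms) + 1}")
        )
    return pwms


# Consensus strings used by the synthetic generator and as scanning defaults:
# a ~20 bp core module and a shorter downstream module.
MODULE_A_CONSENSUS = "TGCAGTGTCCCTCTACTGGT"
MODULE_B_CONSENSUS = "CTAGATGGCA"


def default_two_part_motif(
    min_gap: int = 0, max_gap: int = 15, p: float = 0.97
) -> TwoPartMotif:
    """The built-in bipartite motif used by the synthetic generator."""
    return TwoPartMotif(
        module_a=PWM.from_consensus(MODULE_A_CONSENSUS, p=p, name="moduleA"),
        module_b=PWM.from_consensus(MODULE_B_CONSENSUS, p=p, name="moduleB"),
        min_gap=min_gap,
        max_gap=max_gap,
    )
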
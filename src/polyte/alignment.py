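"""Pairwise alignment, Kimura 2-parameter distance and insertion-age dating.

An LTR retrotransposon inserts with two identical long terminal repeats;
the two copies then diverge neutrally. The insertion age follows from the
substitution-corrected divergence d between the 5' and 3' LTRs as

    age = d / (2 * mu)

with mu the per-site substitution rate per year (default 1.3e-8). The K2P
correction distinguishes the transition fraction P from the transversion
fraction Q over ungapped alignment columns:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from Bio import Align

from .core import DEFAULT_MUTATION_RATE, PolyteError

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(PolyteError):
    """Divergence too high for the K2P correction (log argument <= 0)."""


def make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    """Global (end-to-end) nucleotide aligner with the toolkit's defaults."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_ltr_pair(
    seq5: str, seq3: str, aligner: Align.PairwiseAligner | None = None
) -> Tuple[str, str]:
    """Globally align two LTR sequences; returns the two gapped rows."""
    if not seq5 or not seq3:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(seq5.upper(), seq3.upper())[0]
    return str(aln[0]), str(aln[1])


@dataclass(frozen=True)
class AlignmentStats:
    """Column tallies of a pairwise alignment (gap columns counted apart)."""

    matches: int
    transitions: int
    transversions: int
    gap_columns: int
    length: int  # total alignment columns

    @property
    def ungapped(self) -> int:
        return self.length - self.gap_columns

    @property
    def identity(self) -> float:
        """Matches over all alignment columns, gap columns included."""
        return self.matches / self.length if self.length else 0.0

    @property
    def mismatch_fraction(self) -> float:
        n = self.ungapped
        return (self.transitions + self.transversions) / n if n else 0.0


def alignment_stats(row_a: str, row_b: str) -> AlignmentStats:
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    matches = transitions = transversions = gaps = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a == "-" or b == "-":
            gaps += 1
        elif a == b:
            matches += 1
        elif (a in _PURINES and b in _PURINES) or (
            a in _PYRIMIDINES and b in _PYRIMIDINES
        ):
            transitions += 1
        else:
            transversions += 1
    return AlignmentStats(matches, transitions, transversions, gaps, len(row_a))


def kimura2p_from_fractions(p: float, q: float) -> float:
    """K2P distance from transition fraction p and transversion fraction q."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined for P={p:.4f}, Q={q:.4f} (saturated divergence)"
        )
    return max(-0.5 * math.log(w1) - 0.25 * math.log(w2), 0.0)


def kimura2p_distance(row_a: str, row_b: str) -> float:
    """K2P distance of an alignment, gap columns excluded (pairwise deletion)."""
    stats = alignment_stats(row_a, row_b)
    if stats.ungapped == 0:
        raise ValueError("alignment has no ungapped column")
    p = stats.transitions / stats.ungapped
    q = stats.transversions / stats.ungapped
    return kimura2p_from_fractions(p, q)


def estimate_age(distance: float, mu: float = DEFAULT_MUTATION_RATE) -> float:
    """Insertion age in years: distance / (2 * mu)."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return distance / (2.0 * mu)
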
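"""Core coordinate and annotation types shared across the toolkit.

Internal coordinates are 0-based half-open throughout; conversion to and
from the 1-based inclusive GFF3 convention happens only at the I/O layer.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

#: Three-letter repeat superfamily codes (Wicker-style classification).
SUPERFAMILY_CODES = frozenset(
    {
        "RLC",  # Copia LTR retrotransposon
        "RLG",  # Gypsy LTR retrotransposon
        "RLX",  # unclassified LTR retrotransposon
        "RIX",  # LINE
        "RSX",  # SINE
        "DTC",  # CACTA
        "DTM",  # Mutator
        "DTX",  # unclassified TIR transposon
        "DTH",  # Harbinger
        "DTT",  # Mariner
        "DTA",  # hAT
        "DHH",  # Helitron
        "XXX",  # unclassified repeat
    }
)

#: Protein domains diagnostic of LTR retrotransposons.
RETRO_DOMAINS = ("GAG", "PROT", "INT", "RT", "RH")

#: Core enzymatic domains whose order distinguishes Copia from Gypsy.
CORE_DOMAINS = ("INT", "RT", "RH")

#: Per-site substitution rate (substitutions/site/year) used to convert
#: LTR-LTR divergence into insertion age for grass LTR retrotransposons.
DEFAULT_MUTATION_RATE = 1.3e-8

SUBGENOMES = ("A", "B", "D")


class PolyteError(Exception):
    """Base class for toolkit errors."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    Ordering is lexicographic on (chrom, start, end, strand), which gives
    the stable sort order used across the toolkit.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def subgenome_of(chrom: str, override: Optional[Mapping[str, str]] = None) -> str:
    """Infer the subgenome (A/B/D) of a chromosome from its name.

    The final character of the chromosome name is used (wheat-style naming
    ``1A`` ... ``7D``); an explicit override map takes precedence.
    """
    if override and chrom in override:
        return override[chrom]
    tag = chrom[-1].upper()
    if tag not in SUBGENOMES:
        raise ValueError(f"cannot infer subgenome from chromosome name {chrom!r}")
    return tag


@dataclass(frozen=True)
class TECopy:
    """An annotated transposable-element interval."""

    interval: GenomicInterval
    copy_id: str
    family: str
    superfamily_code: str
    subfamily: Optional[str] = None

    def __post_init__(self) -> None:
        if self.superfamily_code not in SUPERFAMILY_CODES:
            raise ValueError(f"unknown superfamily code {self.superfamily_code!r}")
        if not self.family.startswith(self.superfamily_code):
            raise ValueError(
                f"family {self.family!r} inconsistent with superfamily "
                f"{self.superfamily_code!r}"
            )
        if self.subfamily is not None and not self.subfamily.startswith(self.family):
            raise ValueError(
                f"subfamily {self.subfamily!r} inconsistent with family "
                f"{self.family!r}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene model including untranslated regions.

    ``tss``/``tts`` are strand-aware: for a plus-strand gene the TSS is the
    interval start and the TTS the interval end boundary; reversed on minus.
    """

    interval: GenomicInterval
    gene_id: str
    subgenome: str

    def __post_init__(self) -> None:
        if self.subgenome not in SUBGENOMES:
            raise ValueError(f"unknown subgenome {self.subgenome!r}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand != "-" else self.interval.end

    @property
    def tts(self) -> int:
        return self.interval.end if self.interval.strand != "-" else self.interval.start


@dataclass
class GenomeAssembly:
    """Chromosome sequences plus the chromosome-to-subgenome map."""

    sequences: dict
    subgenomes: dict

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GenomeAssembly":
        return cls(
            sequences=dict(sequences),
            subgenomes={c: subgenome_of(c) for c in sequences},
        )

    def lengths(self) -> dict:
        return {c: len(s) for c, s in self.sequences.items()}

    def validate_annotations(self, intervals) -> None:
        """Check every interval fits inside its chromosome."""
        lens = self.lengths()
        for iv in intervals:
            if iv.chrom not in lens:
                raise ValueError(f"annotated chromosome {iv.chrom!r} absent from assembly")
            if iv.end > lens[iv.chrom]:
                raise ValueError(
                    f"interval {iv} exceeds chromosome length {lens[iv.chrom]}"
                )
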
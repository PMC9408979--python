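"""Domain types shared across the toolkit.

All coordinates are 0-based half-open (``[start, end)``) regardless of the
dialect of the source file; readers convert on ingest.
"""
from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = frozenset({"+", "-", "."})

#: TE superfamily -> mechanistic class. Class II (DNA transposons) move via a
#: cut-and-paste DNA intermediate, Class I (retrotransposons) via reverse
#: transcription of an RNA intermediate.
SUPERFAMILY_CLASS = {
    "hAT": "DNA",
    "Mutator": "DNA",
    "Helitron": "DNA",
    "PIF_Harbinger": "DNA",
    "Tc1_Mariner": "DNA",
    "CACTA": "DNA",
    "Gypsy": "retrotransposon",
    "Copia": "retrotransposon",
    "LINE": "retrotransposon",
    "SINE": "retrotransposon",
}


class ValidationError(ValueError):
    """Raised when a record violates a domain-type invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A span on a chromosome, 0-based, half-open, length > 0."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of +,-,. got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + self.length // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int | float:
        """Edge-to-edge gap in bp; 0 if the intervals share >= 1 bp.

        Returns ``inf`` for intervals on different chromosomes.
        """
        if self.chrom != other.chrom:
            return float("inf")
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class Acr:
    """An accessible chromatin region (ATAC-seq peak).

    ``summit_offset`` is the bp offset of the point of maximal signal from
    ``interval.start`` (narrowPeak column 10); peaks without a recorded summit
    default to the interval midpoint.
    """

    interval: GenomicInterval
    name: str
    summit_offset: int = -1
    per_tissue_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.summit_offset < 0:
            self.summit_offset = self.interval.length // 2
        if not 0 <= self.summit_offset < self.interval.length:
            raise ValidationError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )
        for tissue, count in self.per_tissue_counts.items():
            if count < 0:
                raise ValidationError(f"negative count for tissue {tissue}")

    @property
    def summit(self) -> int:
        """Absolute genomic position of the summit (0-based)."""
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class TeFeature:
    """A transposable element annotation with superfamily and class."""

    interval: GenomicInterval
    superfamily: str
    te_class: str = ""

    def __post_init__(self) -> None:
        if not self.te_class:
            try:
                object.__setattr__(
                    self, "te_class", SUPERFAMILY_CLASS[self.superfamily]
                )
            except KeyError:
                raise ValidationError(
                    f"unknown superfamily {self.superfamily!r}; pass te_class "
                    "explicitly or extend the controlled vocabulary"
                ) from None
        if self.te_class not in ("DNA", "retrotransposon"):
            raise ValidationError(f"te_class must be DNA or retrotransposon")


@dataclass(frozen=True)
class GeneModel:
    """A gene body (TSS to TTS). Strand is mandatory."""

    interval: GenomicInterval
    gene_id: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or - for TSS logic"
            )

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.interval.strand == "+" else self.interval.start


CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class MethylSite:
    """One cytosine from a CGmap file; position is 0-based."""

    chrom: str
    pos: int
    context: str
    methylated: int
    total: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if not 0 <= self.methylated <= self.total:
            raise ValidationError(
                f"methylated reads ({self.methylated}) exceed total ({self.total})"
            )

    @property
    def covered(self) -> bool:
        return self.total > 0
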
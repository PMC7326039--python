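"""Genomic interval primitives.

Every coordinate inside the package is 0-based, half-open ([start, end)),
the BED convention. Readers for 1-based dialects (chimeric tables, GTF-lite)
shift on input; nothing downstream ever re-adjusts an offset. Chromosome
names are compared as exact strings — no "chr" prefix normalization unless a
reader is explicitly asked for it — so cohort mismatches surface instead of
being papered over.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand.

    Parameters
    ----------
    chrom : str
        Chromosome name, matched verbatim.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must be > start.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if self.start < 0:
            raise ValidationError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end {self.end} <= start {self.start} "
                f"({self.chrom})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset, self.strand
        )
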
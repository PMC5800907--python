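"""Strand-aware gene models and interval helpers.

Coordinates are 0-based, half-open everywhere inside the package; GTF I/O
converts to/from 1-based inclusive at the boundary, BED stays 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class AnnotationError(ValueError):
    """Raised for malformed gene models or coordinate conventions."""


@dataclass(frozen=True)
class GeneModel:
    """A gene body with ordered exons on a named contig.

    Exons must be sorted, non-overlapping and contained in the gene body.
    5'/3' always refer to transcriptional orientation: for a minus-strand
    gene the 5' end is the highest genomic coordinate.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"{self.gene_id}: empty or negative gene body")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise AnnotationError(
                    f"{self.gene_id}: exons must be sorted, disjoint and "
                    f"inside the gene body"
                )
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def tx_position(self, genomic_pos: int) -> float:
        """Fractional position along the gene in transcriptional orientation.

        0.0 is the 5' end of the transcript, 1.0 the 3' end.
        """
        frac = (genomic_pos - self.start) / self.length
        return frac if self.strand == "+" else 1.0 - frac

    def tx_interval(self, lo_frac: float, hi_frac: float) -> tuple[int, int]:
        """Genomic interval for a transcriptional-coordinate slice.

        ``(0.0, 0.3)`` is the 5'-most 30% of the gene body regardless of
        strand; the returned interval is genomic (start < end).
        """
        if not (0.0 <= lo_frac < hi_frac <= 1.0):
            raise AnnotationError("tx fractions must satisfy 0 <= lo < hi <= 1")
        if self.strand == "+":
            a = self.start + int(round(lo_frac * self.length))
            b = self.start + int(round(hi_frac * self.length))
        else:
            a = self.end - int(round(hi_frac * self.length))
            b = self.end - int(round(lo_frac * self.length))
        return a, b


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the intersection of two half-open intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def find_gene_at(genes: list[GeneModel], chrom: str, start: int, end: int) -> GeneModel | None:
    """First gene whose body overlaps [start, end) on chrom."""
    for g in genes:
        if g.chrom == chrom and overlap_length(g.start, g.end, start, end) > 0:
            return g
    return None
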
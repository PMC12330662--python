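"""Shared domain objects for the long-read splicing pipeline.

All genomic coordinates are 0-based, half-open. SAM emission converts to
1-based at the file boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

# CIGAR operations that consume reference bases.
REF_CONSUMING = frozenset("M=XDN")
# CIGAR operations that consume read (query) bases.
READ_CONSUMING = frozenset("M=XIS")


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic span and exon structure.

    Introns are derived as the gaps between consecutive exons; every intron
    must be at least 20 bases so that segmentation boundaries remain
    detectable under the 10-base CIGAR merge rule.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside span")
            if prev_end is not None:
                if s <= prev_end:
                    raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
                if s - prev_end < 20:
                    raise ValueError(f"{self.gene_id}: intron shorter than 20 bases")
            prev_end = e
        if self.exons and (self.exons[0][0] != self.start or self.exons[-1][1] != self.end):
            raise ValueError(f"{self.gene_id}: exons must tile the span ends")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IsoformSpec:
    """An isoform of a gene, identified by the set of introns it retains.

    An empty ``retained_introns`` is the fully spliced isoform.
    """

    isoform_id: str
    gene_id: str
    retained_introns: frozenset[int] = frozenset()


@dataclass
class AlignedRead:
    """One read's spliced alignment against the reference.

    ``cigar`` is an ordered list of (op, length) with SAM semantics
    (M/=/X aligned, I insertion, D deletion, N intron skip, S soft clip).
    ``aligned_fraction`` is the proportion of read bases consumed by
    M/=/X/I operations.
    """

    read_id: str
    chrom: str
    start: int
    cigar: list[tuple[str, int]]
    sample_id: str | None = None
    aligned_fraction: float = 1.0

    def __post_init__(self) -> None:
        for op, length in self.cigar:
            if length <= 0:
                raise ValueError(f"{self.read_id}: non-positive CIGAR run {op}{length}")
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ValueError(f"{self.read_id}: aligned_fraction outside [0,1]")

    @property
    def reference_length(self) -> int:
        """Reference footprint length (sum of M/=/X/D/N runs)."""
        return sum(l for op, l in self.cigar if op in REF_CONSUMING)

    @property
    def end(self) -> int:
        return self.start + self.reference_length


def compute_aligned_fraction(cigar: Iterable[tuple[str, int]]) -> float:
    """Fraction of read bases that are aligned (M/=/X/I over all read-consuming ops)."""
    aligned = 0
    total = 0
    for op, length in cigar:
        if op in READ_CONSUMING:
            total += length
            if op != "S":
                aligned += length
    return aligned / total if total else 0.0


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
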
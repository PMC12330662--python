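"""Per-base percent-spliced-in (%SI) pileups from spliced CIGAR alignments.

Each genomic position in a gene accumulates two counters: spliced-in reads
that include a base at the position (mismatched bases count) and the total
reads spanning the position. CIGAR runs shorter than 10 bases are absorbed
into the preceding run and insertions are ignored, so alignment noise does
not masquerade as splicing; the first and last run of every read are
discarded to suppress 5'/3' end-alignment variability; reads must be more
than 80% aligned to survive.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .models import AlignedRead, GeneModel

DEFAULT_MIN_RUN = 10
DEFAULT_MIN_ALIGNED_FRACTION = 0.8

PRESENT_OPS = frozenset("M=X")
ABSENT_OPS = frozenset("DN")


@dataclass
class SplicePileup:
    """Per-position spliced-in / spanning counts over one gene's span."""

    gene_id: str
    chrom: str
    start: int  # genomic coordinate of position 0
    spliced_in: np.ndarray
    spanning: np.ndarray

    def __post_init__(self) -> None:
        if self.spliced_in.shape != self.spanning.shape:
            raise ValueError("counter arrays must share a shape")

    @property
    def end(self) -> int:
        return self.start + len(self.spanning)

    def psi(self) -> np.ndarray:
        """Percent spliced-in per position; NaN where nothing spans."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.spanning > 0, self.spliced_in / np.maximum(self.spanning, 1), np.nan)


def preprocess_cigar(
    cigar: Sequence[tuple[str, int]], min_run: int = DEFAULT_MIN_RUN
) -> list[tuple[str, int]]:
    """Clean a CIGAR into (class, length) runs with class in {present, absent}.

    M/=/X map to present, N/D to absent; insertions and clips are dropped
    (no reference footprint). Runs shorter than ``min_run`` are combined with
    the preceding run, adopting its class; a leading short run, having no
    predecessor, is folded into the following run. Adjacent same-class runs
    coalesce.
    """
    out: list[list] = []
    pending = 0  # leading short run(s) awaiting a successor
    for op, length in cigar:
        if op in PRESENT_OPS:
            cls = "present"
        elif op in ABSENT_OPS:
            cls = "absent"
        else:
            continue  # I, S, H, P: no reference footprint
        if length < min_run:
            if out:
                out[-1][1] += length
            else:
                pending += length
        else:
            if out and out[-1][0] == cls:
                out[-1][1] += length + pending
            else:
                out.append([cls, length + pending])
            pending = 0
    if pending and out:
        # only short runs followed by nothing long before them cannot occur
        # here: pending is always flushed on the first long run
        out[0][1] += pending
    return [(c, l) for c, l in out]


def read_filters(
    read: AlignedRead, min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION
) -> tuple[bool, str]:
    """Keep reads that are more than 80% aligned to the reference; short,
    spurious alignments are dropped (strict inequality at the boundary)."""
    if read.aligned_fraction > min_aligned_fraction:
        return True, ""
    return False, f"aligned_fraction {read.aligned_fraction:.3f} <= {min_aligned_fraction}"


def accumulate_pileup(
    reads: Iterable[AlignedRead],
    gene: GeneModel,
    min_run: int = DEFAULT_MIN_RUN,
    min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION,
    apply_filters: bool = True,
) -> SplicePileup:
    """Accumulate %SI counters over a gene's span.

    For each read the first and last cleaned runs contribute to neither
    counter; interior present runs increment spliced_in and spanning,
    interior absent runs increment spanning only. A read with fewer than
    three cleaned runs contributes nothing.
    """
    length = gene.length
    spliced = np.zeros(length, dtype=np.int32)
    spanning = np.zeros(length, dtype=np.int32)
    for read in reads:
        if read.chrom != gene.chrom:
            continue
        if apply_filters and not read_filters(read, min_aligned_fraction)[0]:
            continue
        runs = preprocess_cigar(read.cigar, min_run)
        if len(runs) < 3:
            continue
        pos = read.start
        for i, (cls, l) in enumerate(runs):
            if 0 < i < len(runs) - 1:
                lo = max(pos, gene.start) - gene.start
                hi = min(pos + l, gene.end) - gene.start
                if hi > lo:
                    spanning[lo:hi] += 1
                    if cls == "present":
                        spliced[lo:hi] += 1
            pos += l
    return SplicePileup(gene.gene_id, gene.chrom, gene.start, spliced, spanning)


def pileups_by_sample(
    reads: Iterable[AlignedRead],
    genes: Sequence[GeneModel],
    gene_of_read: dict[str, str],
    min_run: int = DEFAULT_MIN_RUN,
    min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION,
) -> dict[str, dict[str, SplicePileup]]:
    """Group reads by (gene, sample) and pile up: {gene_id: {sample_id: pileup}}."""
    by_key: dict[tuple[str, str], list[AlignedRead]] = {}
    samples = set()
    for r in reads:
        g = gene_of_read.get(r.read_id)
        if g is None or r.sample_id is None:
            continue
        samples.add(r.sample_id)
        by_key.setdefault((g, r.sample_id), []).append(r)
    out: dict[str, dict[str, SplicePileup]] = {}
    for gene in genes:
        per_sample = {}
        for s in sorted(samples):
            per_sample[s] = accumulate_pileup(
                by_key.get((gene.gene_id, s), []),
                gene,
                min_run=min_run,
                min_aligned_fraction=min_aligned_fraction,
            )
        out[gene.gene_id] = per_sample
    return out


def write_pileup_tsv(pileups: dict[str, dict[str, SplicePileup]], path: str | Path) -> None:
    """Long-format TSV: gene, sample, position, spliced_in, spanning (nonzero rows)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tsample_id\tposition\tspliced_in\tspanning\n")
        for gene_id in sorted(pileups):
            for s in sorted(pileups[gene_id]):
                p = pileups[gene_id][s]
                nz = np.flatnonzero(p.spanning)
                for i in nz:
                    fh.write(
                        f"{gene_id}\t{s}\t{p.start + int(i)}\t{int(p.spliced_in[i])}\t{int(p.spanning[i])}\n"
                    )


def write_psi_bedgraph(pileups: dict[str, dict[str, SplicePileup]], path: str | Path) -> None:
    """Combined (all samples summed) %SI as a BEDGraph track."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="percent_spliced_in"\n')
        for gene_id in sorted(pileups):
            per_sample = pileups[gene_id]
            if not per_sample:
                continue
            first = next(iter(per_sample.values()))
            spliced = sum(p.spliced_in for p in per_sample.values())
            spanning = sum(p.spanning for p in per_sample.values())
            nz = np.flatnonzero(spanning)
            for i in nz:
                psi = spliced[i] / spanning[i]
                fh.write(f"{first.chrom}\t{first.start + int(i)}\t{first.start + int(i) + 1}\t{psi:.4f}\n")
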
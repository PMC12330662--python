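"""Gene assignment of spliced alignments and gene-count tables.

Each alignment is assigned to the annotation maximising
``overlap / max(annotation length, alignment footprint length)``, where the
footprint is the full genomic span the alignment covers (N runs included).
Counts per (sample, gene) feed an external differential-expression engine;
only the count table and the reported significance thresholds live here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .models import AlignedRead, GeneModel, compute_aligned_fraction

logger = logging.getLogger(__name__)

_OP_CODE_TO_CHAR = "MIDNSHP=X"


class GeneIndex:
    """Per-chromosome interval index over gene spans."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        self.by_id = {g.gene_id: g for g in self.genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree())[g.start : g.end] = g

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._trees


def overlap_score(read_start: int, read_end: int, gene: GeneModel) -> float:
    """Overlap ratio: shared bases over the longer of annotation and footprint."""
    ov = min(read_end, gene.end) - max(read_start, gene.start)
    if ov <= 0:
        return 0.0
    return ov / max(gene.length, read_end - read_start)


def assign_gene(read: AlignedRead, index: GeneIndex) -> str | None:
    """Gene with the greatest overlap ratio, or None when nothing overlaps.

    Ties on score break by larger absolute overlap, then lexicographic
    gene_id (logged).
    """
    if not index.has_chrom(read.chrom):
        logger.warning("read %s: chromosome %s absent from annotation", read.read_id, read.chrom)
        return None
    start, end = read.start, read.end
    best: tuple[float, int, str] | None = None
    tie = False
    for gene in index.overlapping(read.chrom, start, end):
        ov = min(end, gene.end) - max(start, gene.start)
        score = ov / max(gene.length, end - start)
        key = (score, ov, gene.gene_id)
        if best is None or (score, ov) > (best[0], best[1]):
            best, tie = key, False
        elif (score, ov) == (best[0], best[1]):
            tie = True
            if gene.gene_id < best[2]:
                best = key
    if best is None or best[0] <= 0:
        return None
    if tie:
        logger.info("read %s: overlap-score tie broken lexicographically", read.read_id)
    return best[2]


def build_counts(
    reads: Sequence[AlignedRead], index: GeneIndex | Sequence[GeneModel]
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene-count table (samples x genes) plus per-sample unassigned counts.

    Every read lands in exactly one gene column or the unassigned tally, so
    table row sums plus unassigned equal the per-sample input counts.
    """
    if not isinstance(index, GeneIndex):
        index = GeneIndex(index)
    samples = sorted({r.sample_id or "sample" for r in reads})
    gene_ids = sorted(g.gene_id for g in index.genes)
    counts = pd.DataFrame(0, index=samples, columns=gene_ids, dtype=int)
    unassigned = pd.Series(0, index=samples, dtype=int)
    for read in reads:
        s = read.sample_id or "sample"
        g = assign_gene(read, index)
        if g is None:
            unassigned[s] += 1
        else:
            counts.loc[s, g] += 1
    return counts, unassigned


def de_threshold_filter(
    table: pd.DataFrame,
    max_fdr: float = 0.05,
    min_abs_log2fc: float = 0.5,
    lfc_col: str = "log2FoldChange",
    padj_col: str = "padj",
) -> list[str]:
    """Genes passing both reported significance filters:
    BH-adjusted value <= ``max_fdr`` and |log2 fold-change| >= ``min_abs_log2fc``."""
    missing = {lfc_col, padj_col} - set(table.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if table.empty:
        return []
    keep = (table[padj_col] <= max_fdr) & (table[lfc_col].abs() >= min_abs_log2fc)
    return list(table.index[keep])


# ---------------------------------------------------------------------------
# file I/O


def read_sam(path: str | Path, primary_only: bool = True) -> list[AlignedRead]:
    """Load a SAM/BAM into AlignedRead records (primary alignments only by
    default); aligned fraction is recomputed from the CIGAR."""
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            if primary_only and (seg.is_secondary or seg.is_supplementary):
                continue
            cigar = [(_OP_CODE_TO_CHAR[op], l) for op, l in seg.cigartuples]
            out.append(
                AlignedRead(
                    read_id=seg.query_name,
                    chrom=seg.reference_name,
                    start=seg.reference_start,
                    cigar=cigar,
                    aligned_fraction=compute_aligned_fraction(cigar),
                )
            )
    return out


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Gene models from a GTF: gene spans plus the exon structure of each
    gene's first (reference) transcript."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = list(db.children(g, featuretype="transcript", order_by="start"))
        exons: list[tuple[int, int]] = []
        if transcripts:
            # prefer the transcript with the most exons (the fully spliced form)
            best = max(
                transcripts,
                key=lambda t: len(list(db.children(t, featuretype="exon"))),
            )
            exons = [
                (e.start - 1, e.end) for e in db.children(best, featuretype="exon", order_by="start")
            ]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=tuple(exons),
            )
        )
    return genes


def write_counts(
    counts: pd.DataFrame, path: str | Path, unassigned: pd.Series | None = None
) -> None:
    """Count table as TSV, genes as rows and samples as columns."""
    table = counts.T
    table.index.name = "gene_id"
    table.to_csv(path, sep="\t")
    if unassigned is not None:
        p = Path(path)
        unassigned.rename("unassigned").to_csv(
            p.with_name(p.stem + ".unassigned.tsv"), sep="\t", header=True
        )


def write_counts_mtx(counts: pd.DataFrame, path: str | Path) -> None:
    """Matrix-market export of the count table (genes x samples)."""
    from scipy import io as sio
    from scipy.sparse import csr_matrix

    p = Path(path)
    sio.mmwrite(str(p), csr_matrix(counts.T.values))
    p.with_suffix(".genes.txt").write_text("\n".join(counts.columns) + "\n")
    p.with_suffix(".samples.txt").write_text("\n".join(counts.index) + "\n")
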
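"""Synthetic long-read transcriptome generator.

Emulates a barcoded oligo-dT nanopore cDNA experiment: genes with spliced
vs intron-retained isoforms mixed at condition-specific proportions, three
biological replicates per condition, 5'-truncated reads (oligo-dT priming
anchors the 3' end), substitution sequencing errors, and the
[barcode][poly-T][revcomp cDNA][revcomp common-primer] read architecture.
Everything is deterministic for a fixed seed, and a truth table records the
origin of every read so each downstream stage can be verified exactly.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
import pysam

from .models import AlignedRead, GeneModel, IsoformSpec, revcomp

# Default sample barcodes: 16 nt, pairwise infix edit distance >= 7, so two
# barcodes can never both fall within the 3-edit matching tolerance.
DEFAULT_BARCODES: tuple[str, ...] = (
    "CACGAACAAGACCACC",
    "TGATAATCAGAGTTTG",
    "CTATCTACTACACTGC",
    "AACCTCGATGGACTAG",
    "GGGGCCCATCACATTG",
    "ACATAACTTCAGTTAC",
    "GCAAGTTATAGGGGCG",
    "GAGTCCTCTAAGTAAT",
    "AGAGGAAAGTCGTCCA",
    "GGTATCGGTGGATTCT",
    "TTGTCTATAGAAACCC",
    "TCCGCCTTAACCCATG",
    "GGGCAGAGTAGGTATG",
    "AATAGAACATACGCAG",
    "CGGCCCCGGTTCATCC",
    "AACACGGGTTGCTGCT",
    "TGTACAAGCGGTCGAC",
    "AATGGCTGGGACGGAA",
    "ATTATTCCGACCGAGC",
    "CTCTAGCTTGAACAGA",
    "GAGATCGCACCTTGTT",
    "TCAAGGTCCCAGGAGA",
    "CTACCCGGCCAACGCA",
    "GCTTTCGTGGGGCACC",
)

DEFAULT_COMMON_PRIMER = "AAGCAGTGGTATCAACGCAGAG"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ReadArchitecture:
    """Physical layout and noise model of the raw reads.

    ``truncation_min``/``truncation_max`` bound the uniformly drawn fraction
    of each transcript retained from its 3' end. ``error_rate`` is the
    per-base substitution probability; ``indel_rate`` the per-base
    insertion-or-deletion probability (default 0 so demultiplexing mismatch
    counts are predictable; the matcher still uses edit distance).
    ``spurious_rate`` is the fraction of reads emitted with a short,
    heavily soft-clipped alignment, emulating the spurious alignments the
    aligned-fraction filter is designed to remove.
    """

    barcodes: tuple[str, ...] = DEFAULT_BARCODES
    common_primer: str = DEFAULT_COMMON_PRIMER
    polyt_min: int = 12
    polyt_max: int = 25
    error_rate: float = 0.02
    indel_rate: float = 0.0
    truncation_min: float = 0.5
    truncation_max: float = 1.0
    forward_prob: float = 0.5
    spurious_rate: float = 0.02

    def validate(self) -> None:
        if len(self.common_primer) < 10:
            raise ValueError("common primer must be at least 10 nt")
        for bc in self.barcodes:
            if len(bc) < 12:
                raise ValueError(f"barcode {bc} shorter than 12 nt")
        for i, a in enumerate(self.barcodes):
            for b in self.barcodes[i + 1 :]:
                d = edlib.align(a, b)["editDistance"]
                if d < 7:
                    raise ValueError(
                        f"barcodes {a}/{b} at edit distance {d} < 7; "
                        "ambiguous under the 3-edit tolerance"
                    )
        for rate in (self.error_rate, self.indel_rate, self.forward_prob, self.spurious_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be probabilities")
        if not 0.0 < self.truncation_min <= self.truncation_max <= 1.0:
            raise ValueError("truncation bounds must satisfy 0 < min <= max <= 1")


@dataclass(frozen=True)
class ConditionDesign:
    """Experimental design: conditions, replicates, and isoform mixtures.

    ``retention[c][g]`` is the mixing proportion of gene g's intron-retaining
    isoform under condition c (the fully spliced isoform takes the
    complement). If ``retention`` is None the generator draws a baseline
    retention per gene and shifts a subset of genes in later conditions.
    ``barcode_map`` assigns one barcode index per (condition, replicate).
    """

    conditions: tuple[str, ...] = ("baseline", "stress")
    n_replicates: int = 3
    mean_reads: float = 300.0
    retention: Mapping[str, Sequence[float]] | None = None
    shift_prob: float = 0.3
    barcode_map: Mapping[tuple[str, int], int] | None = None

    def validate(self, n_barcodes: int) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.retention is not None:
            for cond, probs in self.retention.items():
                if cond not in self.conditions:
                    raise ValueError(f"retention given for unknown condition {cond!r}")
                for p in probs:
                    mixture = (1.0 - p, p)
                    if not all(0.0 <= q <= 1.0 for q in mixture) or abs(sum(mixture) - 1.0) > 1e-9:
                        raise ValueError(
                            f"invalid isoform proportions for condition {cond!r}: "
                            f"{mixture} does not form a probability vector summing to 1"
                        )
        n_samples = len(self.conditions) * self.n_replicates
        if n_samples > n_barcodes:
            raise ValueError(f"need {n_samples} barcodes, architecture provides {n_barcodes}")

    def samples(self) -> list[tuple[str, int]]:
        return [(c, r) for c in self.conditions for r in range(1, self.n_replicates + 1)]

    def barcode_index(self, condition: str, replicate: int) -> int:
        if self.barcode_map is not None:
            return self.barcode_map[(condition, replicate)]
        return self.samples().index((condition, replicate))


def sample_id(condition: str, replicate: int) -> str:
    return f"{condition}_rep{replicate}"


@dataclass
class ReadTruth:
    read_id: str
    barcode_id: str
    condition: str
    replicate: int
    gene_id: str
    isoform_id: str
    orientation: str  # forward | reverse
    tx_start: int  # transcript-coordinate start after 5' truncation
    polyt_len: int
    spurious: bool


@dataclass
class SimTruth:
    """Ground truth of a simulation: every read's origin plus the retention
    probability of every (gene, intron, condition)."""

    seed: int
    reads: list[ReadTruth]
    retention: dict[tuple[str, int, str], float]
    genes: dict[str, GeneModel]
    isoforms: dict[str, IsoformSpec]
    references: dict[str, str]
    design: ConditionDesign
    arch: ReadArchitecture


@dataclass
class Simulation:
    references: dict[str, str]
    genes: list[GeneModel]
    isoforms: list[IsoformSpec]
    truth: SimTruth


# ---------------------------------------------------------------------------
# transcript geometry


def _isoform_blocks(gene: GeneModel, iso: IsoformSpec) -> list[tuple[int, int]]:
    """Genomic blocks (merged exons + retained introns) of an isoform."""
    introns = gene.introns
    blocks: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(gene.exons):
        if blocks and blocks[-1][1] == s:
            blocks[-1] = (blocks[-1][0], e)
        else:
            blocks.append((s, e))
        if i in iso.retained_introns and i < len(introns):
            blocks[-1] = (blocks[-1][0], introns[i][1])
    return blocks


def transcript_sequence(gene: GeneModel, iso: IsoformSpec, refs: Mapping[str, str]) -> str:
    chrom = refs[gene.chrom]
    seq = "".join(chrom[s:e] for s, e in _isoform_blocks(gene, iso))
    return revcomp(seq) if gene.strand == "-" else seq


def transcript_length(gene: GeneModel, iso: IsoformSpec) -> int:
    return sum(e - s for s, e in _isoform_blocks(gene, iso))


def truncated_blocks(
    gene: GeneModel, iso: IsoformSpec, tx_start: int
) -> list[tuple[int, int]]:
    """Genomic blocks covered by a transcript truncated at 5' offset tx_start.

    The 5' end is the genomic left end for + genes and the right end for -
    genes; truncation therefore trims blocks from the corresponding side.
    """
    blocks = _isoform_blocks(gene, iso)
    remaining = tx_start
    if gene.strand == "+":
        out = []
        for s, e in blocks:
            if remaining >= e - s:
                remaining -= e - s
                continue
            out.append((s + remaining, e))
            remaining = 0
        return out
    out = []
    for s, e in reversed(blocks):
        if remaining >= e - s:
            remaining -= e - s
            continue
        out.append((s, e - remaining))
        remaining = 0
    return list(reversed(out))


# ---------------------------------------------------------------------------
# simulation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _make_genes(
    rng: np.random.Generator, n_genes: int, genes_per_chrom: int = 5
) -> tuple[dict[str, str], list[GeneModel], list[IsoformSpec], dict[str, int]]:
    """Random gene models, 4-6 exons each, on synthetic chromosomes.

    Each gene gets two isoforms: fully spliced, and one retaining a single
    middle intron (so the retained intron is flanked by constitutive splice
    junctions and sits inside interior CIGAR runs of every read).
    """
    refs: dict[str, str] = {}
    genes: list[GeneModel] = []
    isoforms: list[IsoformSpec] = []
    retained_idx: dict[str, int] = {}
    gap = 600
    for gi in range(n_genes):
        chrom = f"chr{gi // genes_per_chrom + 1}"
        n_exons = int(rng.integers(4, 7))
        exon_lens = rng.integers(120, 351, size=n_exons)
        intron_lens = rng.integers(60, 201, size=n_exons - 1)
        start = 0 if chrom not in refs else len(refs[chrom]) + gap
        pos = start
        exons = []
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(
            gene_id=f"GENE{gi:04d}",
            chrom=chrom,
            strand=strand,
            start=start,
            end=pos,
            exons=tuple(exons),
        )
        genes.append(gene)
        j_ret = int(rng.integers(1, n_exons - 2))  # middle intron
        retained_idx[gene.gene_id] = j_ret
        isoforms.append(IsoformSpec(f"{gene.gene_id}.spliced", gene.gene_id, frozenset()))
        isoforms.append(
            IsoformSpec(f"{gene.gene_id}.retained", gene.gene_id, frozenset({j_ret}))
        )
        prev = refs.get(chrom, "")
        pad = _random_seq(rng, start - len(prev)) if start > len(prev) else ""
        refs[chrom] = prev + pad + _random_seq(rng, pos - start)
    for chrom in refs:
        refs[chrom] += _random_seq(rng, 300)  # trailing flank
    return refs, genes, isoforms, retained_idx


def simulate_transcriptome(
    n_genes: int,
    seed: int,
    design: ConditionDesign | None = None,
    arch: ReadArchitecture | None = None,
) -> Simulation:
    """Build a synthetic experiment: reference, genes, isoforms and read truth.

    Deterministic for a fixed seed. Read counts per (gene, sample) are
    Poisson around ``design.mean_reads``; each read draws an isoform from the
    condition's mixing proportions, a 5' truncation point, an orientation and
    a poly-T tract length.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    design = design or ConditionDesign()
    arch = arch or ReadArchitecture()
    arch.validate()
    design.validate(len(arch.barcodes))
    rng = np.random.default_rng(seed)

    refs, genes, isoforms, retained_idx = _make_genes(rng, n_genes)
    iso_by_gene = {g.gene_id: [iso for iso in isoforms if iso.gene_id == g.gene_id] for g in genes}

    # retention probability of the intron-retaining isoform per gene/condition
    if design.retention is not None:
        for cond, probs in design.retention.items():
            if len(probs) != n_genes:
                raise ValueError(
                    f"retention for condition {cond!r} has {len(probs)} entries, expected {n_genes}"
                )
        retention = {c: np.asarray(design.retention[c], dtype=float) for c in design.conditions}
    else:
        base = rng.uniform(0.1, 0.9, size=n_genes)
        retention = {design.conditions[0]: base}
        for cond in design.conditions[1:]:
            shifted = base.copy()
            which = rng.random(n_genes) < design.shift_prob
            delta = rng.uniform(0.2, 0.4, size=n_genes) * np.where(rng.random(n_genes) < 0.5, -1, 1)
            shifted[which] = np.clip(base[which] + delta[which], 0.02, 0.98)
            retention[cond] = shifted

    truth_retention: dict[tuple[str, int, str], float] = {}
    for gi, gene in enumerate(genes):
        for cond in design.conditions:
            truth_retention[(gene.gene_id, retained_idx[gene.gene_id], cond)] = float(
                retention[cond][gi]
            )

    reads: list[ReadTruth] = []
    counter = 0
    for cond in design.conditions:
        for rep in range(1, design.n_replicates + 1):
            bc_idx = design.barcode_index(cond, rep)
            bc_id = f"BC{bc_idx + 1:02d}"
            for gi, gene in enumerate(genes):
                n_reads = int(rng.poisson(design.mean_reads))
                p_ret = float(retention[cond][gi])
                spliced, retained = iso_by_gene[gene.gene_id]
                for _ in range(n_reads):
                    iso = retained if rng.random() < p_ret else spliced
                    tx_len = transcript_length(gene, iso)
                    frac = rng.uniform(arch.truncation_min, arch.truncation_max)
                    kept = max(min(tx_len, 100), int(round(tx_len * frac)))
                    tx_start = tx_len - kept
                    orientation = "forward" if rng.random() < arch.forward_prob else "reverse"
                    polyt = int(rng.integers(arch.polyt_min, arch.polyt_max + 1))
                    spurious = bool(rng.random() < arch.spurious_rate)
                    reads.append(
                        ReadTruth(
                            read_id=f"read{counter:07d}",
                            barcode_id=bc_id,
                            condition=cond,
                            replicate=rep,
                            gene_id=gene.gene_id,
                            isoform_id=iso.isoform_id,
                            orientation=orientation,
                            tx_start=tx_start,
                            polyt_len=polyt,
                            spurious=spurious,
                        )
                    )
                    counter += 1

    truth = SimTruth(
        seed=seed,
        reads=reads,
        retention=truth_retention,
        genes={g.gene_id: g for g in genes},
        isoforms={iso.isoform_id: iso for iso in isoforms},
        references=refs,
        design=design,
        arch=arch,
    )
    return Simulation(references=refs, genes=genes, isoforms=isoforms, truth=truth)


# ---------------------------------------------------------------------------
# raw reads


def _inject_errors(rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float) -> str:
    if sub_rate <= 0 and indel_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n = len(arr)
    subs = np.flatnonzero(rng.random(n) < sub_rate)
    if subs.size:
        # substitute with one of the three other bases
        orig = arr[subs]
        repl = _BASES[rng.integers(0, 4, size=subs.size)]
        clash = repl == orig
        while clash.any():
            repl[clash] = _BASES[rng.integers(0, 4, size=int(clash.sum()))]
            clash = repl == orig
        arr[subs] = repl
    if indel_rate > 0:
        out = []
        events = rng.random(n) < indel_rate
        kinds = rng.random(n) < 0.5  # True: deletion, False: insertion
        ins = _BASES[rng.integers(0, 4, size=n)]
        for i in range(n):
            if events[i]:
                if kinds[i]:
                    continue  # deletion
                out.append(ins[i])
            out.append(arr[i])
        arr = np.array(out, dtype="S1")
    return arr.tobytes().decode()


def emit_raw_reads(truth: SimTruth, arch: ReadArchitecture | None = None) -> list[tuple[str, str]]:
    """Materialise raw reads as (read_id, sequence) in truth order.

    Forward-orientation layout:
    ``[barcode][poly-T][revcomp(truncated transcript)][revcomp(common primer)]``;
    reverse-orientation reads are the reverse complement of that. Substitution
    (and optional indel) errors are injected at the configured rates.
    Deterministic for a fixed truth (its seed feeds the error stream).
    """
    arch = arch or truth.arch
    rng = np.random.default_rng(truth.seed + 1_000_003)
    bc_by_id = {f"BC{i + 1:02d}": bc for i, bc in enumerate(arch.barcodes)}
    cp_rc = revcomp(arch.common_primer)
    out = []
    for rt in truth.reads:
        gene = truth.genes[rt.gene_id]
        iso = truth.isoforms[rt.isoform_id]
        cdna = transcript_sequence(gene, iso, truth.references)[rt.tx_start :]
        read = bc_by_id[rt.barcode_id] + "T" * rt.polyt_len + revcomp(cdna) + cp_rc
        read = _inject_errors(rng, read, arch.error_rate, arch.indel_rate)
        if rt.orientation == "reverse":
            read = revcomp(read)
        out.append((rt.read_id, read))
    return out


# ---------------------------------------------------------------------------
# alignments


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            if gap > 0:
                cigar.append(("N", gap))
        cigar.append(("M", e - s))
    return cigar


def emit_alignments(truth: SimTruth, genes: Sequence[GeneModel] | None = None) -> list[AlignedRead]:
    """Spliced alignments constructed directly from the truth table.

    Fully spliced isoforms yield M runs over exons and N runs over introns;
    a retained intron yields M across it. 5'-truncation shortens the
    alignment from the transcript 5' end. Alignments are always recorded in
    reference (forward-strand) orientation. Reads flagged spurious get a
    short alignment with most of the read soft-clipped, driving their
    aligned fraction below the 0.8 keep threshold.
    """
    gene_by_id = {g.gene_id: g for g in (genes if genes is not None else truth.genes.values())}
    rng = np.random.default_rng(truth.seed + 2_000_003)
    out: list[AlignedRead] = []
    for rt in truth.reads:
        gene = gene_by_id.get(rt.gene_id)
        if gene is None:
            raise KeyError(f"read {rt.read_id} maps to unknown gene {rt.gene_id}")
        iso = truth.isoforms[rt.isoform_id]
        tx_len = transcript_length(gene, iso)
        tx_start = rt.tx_start
        read_len = tx_len - tx_start
        if rt.spurious:
            # keep only a short 3' fragment aligned; soft-clip the rest
            frac = float(rng.uniform(0.2, 0.6))
            aligned_len = max(40, int(read_len * frac))
            clip = read_len - aligned_len
            tx_start = tx_len - aligned_len
        else:
            clip = 0
        blocks = truncated_blocks(gene, iso, tx_start)
        cigar = _blocks_to_cigar(blocks)
        # soft clip goes at the transcript-5' side of the alignment
        if clip > 0:
            if gene.strand == "+":
                cigar.insert(0, ("S", clip))
            else:
                cigar.append(("S", clip))
        aligned = sum(l for op, l in cigar if op == "M")
        frac_aligned = aligned / (aligned + clip) if aligned + clip else 0.0
        out.append(
            AlignedRead(
                read_id=rt.read_id,
                chrom=gene.chrom,
                start=blocks[0][0],
                cigar=cigar,
                aligned_fraction=frac_aligned,
            )
        )
    return out


# ---------------------------------------------------------------------------
# file output


def write_fasta(refs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(refs):
            fh.write(f">{name}\n")
            seq = refs[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_gtf(genes: Sequence[GeneModel], isoforms: Sequence[IsoformSpec], path: str | Path) -> None:
    """GTF (1-based, inclusive) with gene, transcript and exon features."""
    iso_by_gene: dict[str, list[IsoformSpec]] = {}
    for iso in isoforms:
        iso_by_gene.setdefault(iso.gene_id, []).append(iso)
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tnanosplice\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for iso in iso_by_gene.get(g.gene_id, []):
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{iso.isoform_id}";'
                fh.write(
                    f"{g.chrom}\tnanosplice\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in _isoform_blocks(g, iso):
                    fh.write(
                        f"{g.chrom}\tnanosplice\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


def sam_header(refs: Mapping[str, str]) -> pysam.AlignmentHeader:
    names = sorted(refs)
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": len(refs[n])} for n in names],
        }
    )


def write_sam(
    alignments: Sequence[AlignedRead], refs: Mapping[str, str], path: str | Path
) -> None:
    header = sam_header(refs)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.reference_name = aln.chrom
            seg.reference_start = aln.start
            seg.mapping_quality = 60
            seg.cigarstring = "".join(f"{l}{op}" for op, l in aln.cigar)
            seg.flag = 0
            out.write(seg)


def write_truth_tables(truth: SimTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    reads = pd.DataFrame([dataclasses.asdict(rt) for rt in truth.reads])
    reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    rows = [
        {"gene_id": g, "intron_index": i, "condition": c, "retention": p}
        for (g, i, c), p in sorted(truth.retention.items())
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth_retention.tsv", sep="\t", index=False)


def write_sample_sheet(design: ConditionDesign, arch: ReadArchitecture, path: str | Path) -> None:
    rows = []
    for cond, rep in design.samples():
        idx = design.barcode_index(cond, rep)
        rows.append(
            {
                "sample_id": sample_id(cond, rep),
                "barcode_id": f"BC{idx + 1:02d}",
                "barcode_seq": arch.barcodes[idx],
                "condition": cond,
                "replicate": rep,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_simulation(sim: Simulation, outdir: str | Path) -> dict[str, Path]:
    """Write reference FASTA, raw FASTQ, alignments SAM, annotation GTF,
    sample sheet and truth tables; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = sim.truth
    paths = {
        "reference": outdir / "reference.fasta",
        "reads": outdir / "reads.fastq",
        "alignments": outdir / "alignments.sam",
        "annotation": outdir / "annotation.gtf",
        "sample_sheet": outdir / "sample_sheet.tsv",
    }
    write_fasta(sim.references, paths["reference"])
    write_fastq(emit_raw_reads(truth), paths["reads"])
    write_sam(emit_alignments(truth), sim.references, paths["alignments"])
    write_gtf(sim.genes, sim.isoforms, paths["annotation"])
    write_sample_sheet(truth.design, truth.arch, paths["sample_sheet"])
    write_truth_tables(truth, outdir)
    return paths
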
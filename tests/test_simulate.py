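"""Generator contracts: determinism, mixture sampling, read architecture,
and direct CIGAR construction from the gene model."""
from __future__ import annotations

import numpy as np
import pytest

import nanosplice as ns
from nanosplice.simulate import ReadTruth, SimTruth, transcript_sequence


def _one_gene_design(p_retained: float, mean_reads: float = 100.0) -> ns.ConditionDesign:
    return ns.ConditionDesign(
        conditions=("only",),
        n_replicates=1,
        mean_reads=mean_reads,
        retention={"only": [p_retained]},
    )


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    a = ns.simulate_transcriptome(2, seed=5, design=ns.ConditionDesign(mean_reads=30))
    b = ns.simulate_transcriptome(2, seed=5, design=ns.ConditionDesign(mean_reads=30))
    ns.write_simulation(a, tmp_path / "a")
    ns.write_simulation(b, tmp_path / "b")
    for name in ("reference.fasta", "reads.fastq", "alignments.sam", "annotation.gtf",
                 "sample_sheet.tsv", "truth_reads.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_truth_fastq_and_alignment_counts_agree(clean_sim):
    raw = ns.emit_raw_reads(clean_sim.truth)
    alns = ns.emit_alignments(clean_sim.truth)
    assert len(raw) == len(alns) == len(clean_sim.truth.reads)
    assert len({rt.read_id for rt in clean_sim.truth.reads}) == len(clean_sim.truth.reads)


def test_degenerate_mixture_yields_only_spliced_isoform():
    sim = ns.simulate_transcriptome(1, seed=2, design=_one_gene_design(0.0))
    assert all(rt.isoform_id.endswith(".spliced") for rt in sim.truth.reads)


def test_every_gene_has_two_isoforms_differing_by_one_intron(clean_sim):
    by_gene = {}
    for iso in clean_sim.isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    for gene in clean_sim.genes:
        isos = by_gene[gene.gene_id]
        assert len(isos) == 2
        retained = [iso for iso in isos if iso.retained_introns]
        assert len(retained) == 1 and len(retained[0].retained_introns) == 1
        assert len(gene.exons) >= 2
        assert all(e - s >= 20 for s, e in gene.introns)


def test_invalid_mixture_proportions_rejected():
    design = ns.ConditionDesign(conditions=("only",), retention={"only": [1.3]})
    with pytest.raises(ValueError, match="probability vector"):
        ns.simulate_transcriptome(1, seed=0, design=design)


def test_empirical_retained_fraction_matches_binomial_sampling():
    p = 0.3
    design = _one_gene_design(p, mean_reads=10_000)
    sim = ns.simulate_transcriptome(1, seed=17, design=design)
    n = len(sim.truth.reads)
    frac = sum(rt.isoform_id.endswith(".retained") for rt in sim.truth.reads) / n
    sd = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * sd


def test_error_free_reads_carry_exact_barcode_and_primer():
    arch = ns.ReadArchitecture(error_rate=0.0, spurious_rate=0.0, forward_prob=1.0)
    sim = ns.simulate_transcriptome(1, seed=3, design=_one_gene_design(0.5, 50), arch=arch)
    cp_rc = ns.revcomp(ns.DEFAULT_COMMON_PRIMER)
    for (rid, seq), rt in zip(ns.emit_raw_reads(sim.truth), sim.truth.reads):
        assert seq.startswith(ns.DEFAULT_BARCODES[0])
        assert seq.endswith(cp_rc)
        assert rt.orientation == "forward"


def test_expected_barcode_mismatches_scale_with_error_rate():
    # 16 nt at 2% substitution error: expect ~0.32 mismatches per barcode
    arch = ns.ReadArchitecture(error_rate=0.02, spurious_rate=0.0, forward_prob=1.0)
    sim = ns.simulate_transcriptome(1, seed=19, design=_one_gene_design(0.5, 3000), arch=arch)
    bc = ns.DEFAULT_BARCODES[0]
    mismatches = [
        sum(a != b for a, b in zip(seq[: len(bc)], bc)) for _, seq in ns.emit_raw_reads(sim.truth)
    ]
    n = len(mismatches)
    expected = len(bc) * 0.02
    se = np.sqrt(len(bc) * 0.02 * 0.98 / n)
    assert abs(np.mean(mismatches) - expected) < 4 * se


def _manual_truth(gene, isoforms, refs, iso_id, tx_start):
    rt = ReadTruth(
        read_id="r0", barcode_id="BC01", condition="only", replicate=1,
        gene_id=gene.gene_id, isoform_id=iso_id, orientation="forward",
        tx_start=tx_start, polyt_len=12, spurious=False,
    )
    return SimTruth(
        seed=0, reads=[rt], retention={}, genes={gene.gene_id: gene},
        isoforms={iso.isoform_id: iso for iso in isoforms}, references=refs,
        design=ns.ConditionDesign(conditions=("only",), n_replicates=1),
        arch=ns.ReadArchitecture(),
    )


@pytest.mark.parametrize(
    "retained, tx_start, expected_start, expected_cigar",
    [
        (frozenset(), 0, 0, [("M", 100), ("N", 50), ("M", 100)]),
        (frozenset({0}), 0, 0, [("M", 250)]),
        (frozenset(), 100, 150, [("M", 100)]),  # truncation removes first exon
    ],
)
def test_alignment_cigar_constructed_from_gene_model(retained, tx_start, expected_start, expected_cigar):
    gene = ns.GeneModel("G", "chrN", "+", 0, 250, ((0, 100), (150, 250)))
    isoforms = [
        ns.IsoformSpec("G.spliced", "G", frozenset()),
        ns.IsoformSpec("G.retained", "G", frozenset({0})),
    ]
    refs = {"chrN": "A" * 250}
    iso_id = "G.retained" if retained else "G.spliced"
    truth = _manual_truth(gene, isoforms, refs, iso_id, tx_start)
    (aln,) = ns.emit_alignments(truth)
    assert aln.start == expected_start
    assert aln.cigar == expected_cigar
    assert aln.aligned_fraction == 1.0


def test_truncation_is_three_prime_anchored(clean_sim):
    # the 3' exon end is covered by every read of a + strand gene
    refs = clean_sim.references
    for rt in clean_sim.truth.reads[:50]:
        gene = clean_sim.truth.genes[rt.gene_id]
        iso = clean_sim.truth.isoforms[rt.isoform_id]
        cdna = transcript_sequence(gene, iso, refs)[rt.tx_start :]
        full = transcript_sequence(gene, iso, refs)
        assert full.endswith(cdna)
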
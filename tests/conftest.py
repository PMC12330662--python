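from __future__ import annotations

import numpy as np
import pytest

import nanosplice as ns


@pytest.fixture(scope="session")
def clean_sim():
    """Small error-free simulation: 3 genes, 2 conditions x 3 replicates."""
    arch = ns.ReadArchitecture(error_rate=0.0, spurious_rate=0.0)
    design = ns.ConditionDesign(
        mean_reads=60,
        retention={"baseline": [0.5, 0.9, 0.2], "stress": [0.5, 0.3, 0.2]},
    )
    return ns.simulate_transcriptome(3, seed=11, design=design, arch=arch)


@pytest.fixture(scope="session")
def noisy_sim():
    """Simulation at the default 2% substitution error."""
    design = ns.ConditionDesign(mean_reads=60)
    return ns.simulate_transcriptome(3, seed=13, design=design)


@pytest.fixture(scope="session")
def default_barcode_map():
    return {f"BC{i + 1:02d}": bc for i, bc in enumerate(ns.DEFAULT_BARCODES)}


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


def two_exon_gene(exon_len=100, intron_len=50, gene_id="G", chrom="chrN"):
    return ns.GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        start=0,
        end=2 * exon_len + intron_len,
        exons=((0, exon_len), (exon_len + intron_len, 2 * exon_len + intron_len)),
    )


def random_spliced_read(rng, read_id, chrom="chrN", max_start=400):
    """Random alignment with a mix of run classes and lengths for oracle tests."""
    start = int(rng.integers(0, max_start))
    n_runs = int(rng.integers(1, 9))
    cigar = []
    prev_op = None
    for _ in range(n_runs):
        op = str(rng.choice(["M", "N", "D", "I", "=", "X"]))
        length = int(rng.choice([int(rng.integers(1, 10)), int(rng.integers(10, 120))]))
        if op == prev_op:
            op = "M" if op != "M" else "N"
        cigar.append((op, length))
        prev_op = op
    if rng.random() < 0.3:
        cigar.insert(0, ("S", int(rng.integers(1, 50))))
    if rng.random() < 0.3:
        cigar.append(("S", int(rng.integers(1, 50))))
    if not any(op in "M=X" for op, _ in cigar):
        cigar.append(("M", 60))
    frac = float(rng.uniform(0.5, 1.0))
    return ns.AlignedRead(
        read_id=read_id, chrom=chrom, start=start, cigar=cigar, aligned_fraction=frac
    )
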
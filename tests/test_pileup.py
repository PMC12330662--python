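"""%SI pileup: CIGAR cleaning, read filters, terminal-trim accumulation, and
exact agreement with a naive per-base oracle."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanosplice as ns
from conftest import random_spliced_read, two_exon_gene
from oracles import brute_force_pileup


class TestPreprocessCigar:
    @pytest.mark.parametrize(
        "cigar, expected",
        [
            ([("M", 100), ("N", 50), ("M", 100)],
             [("present", 100), ("absent", 50), ("present", 100)]),
            ([("M", 100), ("D", 5), ("M", 100)], [("present", 205)]),
            ([("M", 100), ("I", 8), ("M", 100)], [("present", 200)]),
            ([("S", 30), ("M", 100), ("N", 50), ("M", 100), ("S", 20)],
             [("present", 100), ("absent", 50), ("present", 100)]),
            # leading short run folds into the following run
            ([("M", 4), ("N", 50), ("M", 100)], [("absent", 54), ("present", 100)]),
            # chain of short runs absorbs into the preceding long run
            ([("M", 100), ("D", 3), ("N", 4), ("M", 80)], [("present", 187)]),
        ],
    )
    def test_merge_and_classification_rules(self, cigar, expected):
        assert ns.preprocess_cigar(cigar) == expected

    def test_merge_threshold_is_parameterised(self):
        cigar = [("M", 100), ("D", 5), ("M", 100)]
        assert ns.preprocess_cigar(cigar, min_run=1) == [
            ("present", 100), ("absent", 5), ("present", 100),
        ]

    @given(
        st.lists(
            st.tuples(st.sampled_from("MNDIS=X"), st.integers(1, 150)),
            min_size=1, max_size=10,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_cleaned_length_preserves_reference_footprint(self, cigar):
        footprint = sum(l for op, l in cigar if op in "M=XDN")
        cleaned = ns.preprocess_cigar(cigar)
        if cleaned:
            assert sum(l for _, l in cleaned) == footprint
            assert all(
                a[0] != b[0] for a, b in zip(cleaned, cleaned[1:])
            ), "adjacent runs must alternate class"


class TestReadFilters:
    @pytest.mark.parametrize(
        "fraction, keep",
        [(0.95, True), (0.70, False), (0.80, False), (0.801, True)],
    )
    def test_aligned_fraction_threshold_strict_at_boundary(self, fraction, keep):
        read = ns.AlignedRead("r", "c", 0, [("M", 100)], aligned_fraction=fraction)
        got, reason = ns.read_filters(read)
        assert got is keep
        if not keep:
            assert "aligned_fraction" in reason


class TestAccumulatePileup:
    def test_interior_absent_run_counts_spanning_only(self):
        gene = two_exon_gene()
        read = ns.AlignedRead("r", "chrN", 0, [("M", 100), ("N", 50), ("M", 100)])
        p = ns.accumulate_pileup([read], gene)
        assert (p.spanning[100:150] == 1).all()
        assert (p.spliced_in[100:150] == 0).all()
        # terminal runs contribute nothing
        assert p.spanning[:100].sum() == 0 and p.spanning[150:].sum() == 0

    def test_single_run_read_contributes_nothing(self):
        gene = two_exon_gene()
        read = ns.AlignedRead("r", "chrN", 0, [("M", 250)])
        p = ns.accumulate_pileup([read], gene)
        assert p.spanning.sum() == 0

    def test_soft_clips_do_not_change_contribution(self):
        gene = two_exon_gene()
        base = [("M", 100), ("N", 50), ("M", 100)]
        plain = ns.accumulate_pileup(
            [ns.AlignedRead("r", "chrN", 0, base)], gene
        )
        clipped = ns.accumulate_pileup(
            [ns.AlignedRead("r", "chrN", 0, [("S", 40)] + base + [("S", 25)],
                            aligned_fraction=0.81)],
            gene,
        )
        assert (plain.spanning == clipped.spanning).all()
        assert (plain.spliced_in == clipped.spliced_in).all()

    def test_dropped_read_never_increases_counters(self):
        gene = two_exon_gene()
        keep = ns.AlignedRead("a", "chrN", 0, [("M", 100), ("N", 50), ("M", 100)])
        drop = ns.AlignedRead(
            "b", "chrN", 0, [("M", 100), ("N", 50), ("M", 100)], aligned_fraction=0.5
        )
        with_drop = ns.accumulate_pileup([keep, drop], gene)
        without = ns.accumulate_pileup([keep], gene)
        assert (with_drop.spanning == without.spanning).all()

    def test_exact_agreement_with_per_base_oracle_on_random_reads(self, rng):
        gene = ns.GeneModel("G", "chrN", "+", 0, 900,
                            ((0, 300), (400, 600), (700, 900)))
        reads = [random_spliced_read(rng, f"r{i}") for i in range(500)]
        mine = ns.accumulate_pileup(reads, gene)
        spliced, spanning = brute_force_pileup(reads, gene)
        assert (mine.spliced_in == spliced).all()
        assert (mine.spanning == spanning).all()
        assert (mine.spliced_in <= mine.spanning).all()

    def test_intronic_psi_recovers_retention_probability(self):
        # one gene, retention 0.3, 10,000 full-length reads: intron %SI within
        # 3 binomial SD. Full length matters: a 5'-truncated retained read can
        # lose its upstream junction, making its intron run terminal (trimmed).
        p_true = 0.3
        arch = ns.ReadArchitecture(
            error_rate=0.0, spurious_rate=0.0, truncation_min=1.0, truncation_max=1.0
        )
        design = ns.ConditionDesign(
            conditions=("only",), n_replicates=1, mean_reads=10_000,
            retention={"only": [p_true]},
        )
        sim = ns.simulate_transcriptome(1, seed=23, design=design, arch=arch)
        gene = sim.genes[0]
        alns = ns.emit_alignments(sim.truth)
        pile = ns.accumulate_pileup(alns, gene)
        (j,) = next(
            iso.retained_introns for iso in sim.isoforms if iso.retained_introns
        )
        s, e = gene.introns[j]
        mid = (s + e) // 2 - gene.start
        n = int(pile.spanning[mid])
        psi = pile.spliced_in[mid] / n
        assert abs(psi - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)
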
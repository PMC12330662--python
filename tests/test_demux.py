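"""Demultiplexing: anchored poly-T / common-primer search, mismatch-tolerant
barcode assignment, exclusion rules, and trimming."""
from __future__ import annotations

from collections import Counter

import edlib
import numpy as np
import pytest

import nanosplice as ns
from nanosplice.demux import find_polyt, find_common_primer
from nanosplice.simulate import transcript_sequence

CP = ns.DEFAULT_COMMON_PRIMER
BC = {f"BC{i + 1:02d}": b for i, b in enumerate(ns.DEFAULT_BARCODES[:6])}


class TestFindPolyT:
    def test_single_perfect_run(self):
        hit = find_polyt("AAAA" + "T" * 12 + "CCGG")
        assert (hit.start, hit.end, hit.orientation) == (4, 16, "forward")

    def test_absent_when_no_long_run(self):
        assert find_polyt("ACGT" * 20) is None
        assert find_polyt("AC" + "T" * 9 + "GACGATCGAGCA") is None

    def test_ninety_percent_rule_tolerates_one_interruption(self):
        seq = "GGGG" + "T" * 5 + "C" + "T" * 6 + "GGGG"
        hit = find_polyt(seq)
        assert hit is not None
        assert hit.start == 4 and hit.end == 16  # 11/12 T >= 90%

    def test_window_scan_agrees_with_exhaustive_window_oracle(self, rng):
        # oracle: check every window of every length explicitly
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            found = find_polyt(seq, min_run=10)
            windows = [
                (s, e)
                for L in range(10, 61)
                for s in range(0, 61 - L)
                for e in [s + L]
                if seq[s:e].count("T") >= np.ceil(0.9 * L)
            ]
            if found is None:
                assert not windows
            elif found.orientation == "forward":
                assert windows

    def test_reverse_orientation_detected(self):
        read = ns.revcomp("AAAA" + "T" * 14 + "CCGG")
        hit = find_polyt(read)
        assert hit.orientation == "reverse"
        assert (hit.start, hit.end) == (4, 18)  # on the oriented read


class TestFindCommonPrimer:
    def test_exact_embedding_found_at_distance_zero(self):
        read = "ACGTACGTAC" + ns.revcomp(CP) + "GGCCAAGGCC"
        hit = find_common_primer(read, CP)
        assert hit.distance == 0 and hit.orientation == "forward"
        assert (hit.start, hit.end) == (10, 10 + len(CP))

    def test_two_substitutions_found_at_distance_two(self):
        mutated = list(ns.revcomp(CP))
        mutated[3] = "A" if mutated[3] != "A" else "C"
        mutated[10] = "A" if mutated[10] != "A" else "C"
        read = "ACGTACGTAC" + "".join(mutated) + "GGCCAAGGCC"
        hit = find_common_primer(read, CP)
        # dynamic-programming oracle
        oracle = edlib.align(ns.revcomp(CP), read, mode="HW")["editDistance"]
        assert hit.distance == oracle == 2

    def test_four_edits_exceed_tolerance(self):
        mutated = list(ns.revcomp(CP))
        for i in (2, 7, 12, 17):
            mutated[i] = "A" if mutated[i] != "A" else "C"
        read = "ACGTACGTAC" + "".join(mutated) + "GGCCAAGGCC"
        assert find_common_primer(read, CP, max_dist=3) is None


def _forward_read(bc_seq, insert="ACGGTTCCAAGGTTCCGGAATTCCGGTTAA" * 3, polyt=14):
    return bc_seq + "T" * polyt + insert + ns.revcomp(CP)


class TestAssignBarcode:
    def test_perfect_barcode_adjacent_to_polyt(self):
        a = ns.assign_barcode("r", _forward_read(BC["BC01"]), BC, cp=CP)
        assert (a.status, a.barcode_id, a.distance, a.orientation) == (
            "assigned", "BC01", 0, "forward",
        )

    def test_reverse_complement_read_assigned(self):
        a = ns.assign_barcode("r", ns.revcomp(_forward_read(BC["BC02"])), BC, cp=CP)
        assert (a.status, a.barcode_id, a.orientation) == ("assigned", "BC02", "reverse")

    def test_barcode_in_wrong_orientation_is_none_found(self):
        # barcode reverse-complemented relative to the poly-T: wrong direction
        read = ns.revcomp(BC["BC01"]) + "T" * 14 + "ACGGTTCCAAGG" * 4 + ns.revcomp(CP)
        a = ns.assign_barcode("r", read, BC, cp=CP)
        assert a.status == "none_found"

    def test_adversarial_barcode_pair_is_multiple_found(self):
        bcs = {"X1": "ACGTACGTACGTACGT", "X2": "ACGTACGTACGTAGGT"}  # distance 1
        a = ns.assign_barcode("r", _forward_read(bcs["X1"]), bcs, cp=CP)
        assert a.status == "multiple_found"

    def test_conflicting_anchor_orientations_excluded(self):
        # poly-T implies forward while the CP sits in forward (not revcomp) sense
        read = BC["BC01"] + "T" * 14 + "ACGGTTCCAAGG" * 4 + CP
        a = ns.assign_barcode("r", read, BC, cp=CP)
        assert a.status == "none_found"
        assert "conflict" in a.reason

    def test_empty_barcode_set_rejected(self):
        with pytest.raises(ValueError):
            ns.assign_barcode("r", "ACGT" * 30, {}, cp=CP)


class TestTrim:
    def test_full_layout_trims_to_insert(self):
        insert = "ACGGTTCCAAGGTTCCGGAATTCCGGTTAA" * 3
        read = _forward_read(BC["BC01"], insert=insert)
        a = ns.assign_barcode("r", read, BC, cp=CP)
        trimmed = ns.trim_read(read, a)
        # canonical orientation is transcript sense: the reverse complement
        # of the segment between poly-T and CP
        assert trimmed == ns.revcomp(insert)

    def test_unassigned_read_returned_unchanged_and_flagged(self):
        read = "ACGG" * 40
        a = ns.assign_barcode("r", read, BC, cp=CP)
        assert a.status == "none_found"
        assert ns.trim_read(read, a) == read
        assert not a.trimmed_ok

    def test_trimmed_insert_recovers_truth_at_two_percent_error(self, noisy_sim):
        raw = ns.emit_raw_reads(noisy_sim.truth)
        assignments = ns.demux_reads(raw, BC, cp=CP)
        refs = noisy_sim.references
        identities = []
        for a, rt in list(zip(assignments, noisy_sim.truth.reads))[:150]:
            if a.status != "assigned":
                continue
            gene = noisy_sim.truth.genes[rt.gene_id]
            iso = noisy_sim.truth.isoforms[rt.isoform_id]
            cdna = transcript_sequence(gene, iso, refs)[rt.tx_start :]
            d = edlib.align(a.trimmed, cdna)["editDistance"]
            identities.append(1 - d / len(cdna))
        assert np.mean(identities) >= 0.95


class TestDemuxDriver:
    def test_error_free_assignment_has_perfect_precision_and_recall(self, clean_sim):
        raw = ns.emit_raw_reads(clean_sim.truth)
        assignments = ns.demux_reads(raw, BC, cp=CP)
        truth_bc = {rt.read_id: rt.barcode_id for rt in clean_sim.truth.reads}
        assert all(a.status == "assigned" for a in assignments)
        assert all(a.barcode_id == truth_bc[a.read_id] for a in assignments)
        # distances stay within tolerance even when a T-rich barcode suffix
        # borders the poly-T tract
        assert max(a.distance for a in assignments) <= 3

    def test_every_read_receives_exactly_one_status(self, noisy_sim):
        raw = ns.emit_raw_reads(noisy_sim.truth)
        assignments = ns.demux_reads(raw, BC, cp=CP)
        counts = Counter(a.status for a in assignments)
        assert set(counts) <= {"assigned", "none_found", "multiple_found"}
        assert sum(counts.values()) == len(raw)
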
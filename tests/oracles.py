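"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's vectorised/run-based code paths:
pileups are computed by expanding every cleaned CIGAR to one label per
reference base, and gene scores / segmentations by direct loops over the
definitions.
"""
from __future__ import annotations

import numpy as np


def clean_runs(cigar, min_run=10):
    """Reference-footprint runs after the short-run merge rule.

    Single left-to-right pass: insertions and clips are dropped; a run
    shorter than ``min_run`` joins the run before it (keeping that run's
    class); leading short runs, having no predecessor, fold into the first
    long run; same-class neighbours coalesce. Written as an explicit index
    walk, independent of the package's implementation style.
    """
    runs = []
    for op, length in cigar:
        if op in "M=X":
            runs.append(("present", length))
        elif op in "DN":
            runs.append(("absent", length))
    out = []
    i = 0
    leading = 0
    # swallow leading short runs
    while i < len(runs) and runs[i][1] < min_run:
        leading += runs[i][1]
        i += 1
    while i < len(runs):
        cls, length = runs[i]
        if length < min_run:
            out[-1] = (out[-1][0], out[-1][1] + length)
        elif out and out[-1][0] == cls:
            out[-1] = (cls, out[-1][1] + length)
        else:
            out.append((cls, length + leading))
            leading = 0
        i += 1
    return out


def brute_force_pileup(reads, gene, min_run=10, min_aligned_fraction=0.8):
    """Per-base expansion of every read's cleaned CIGAR with the same
    filtering and terminal-trim rules; returns (spliced_in, spanning)."""
    length = gene.end - gene.start
    spliced = np.zeros(length, dtype=int)
    spanning = np.zeros(length, dtype=int)
    for read in reads:
        if read.chrom != gene.chrom:
            continue
        if not read.aligned_fraction > min_aligned_fraction:
            continue
        runs = clean_runs(read.cigar, min_run)
        if len(runs) < 3:
            continue
        base_labels = []
        for run_idx, (cls, l) in enumerate(runs):
            terminal = run_idx == 0 or run_idx == len(runs) - 1
            base_labels.extend([(cls, terminal)] * l)
        for offset, (cls, terminal) in enumerate(base_labels):
            pos = read.start + offset
            if terminal or not (gene.start <= pos < gene.end):
                continue
            spanning[pos - gene.start] += 1
            if cls == "present":
                spliced[pos - gene.start] += 1
    return spliced, spanning


def brute_force_assign_gene(read_start, read_end, genes):
    """Exhaustive overlap-ratio scorer with the documented tie-breaks."""
    best_id = None
    best = (-1.0, -1)
    for g in sorted(genes, key=lambda g: g.gene_id):
        ov = min(read_end, g.end) - max(read_start, g.start)
        if ov <= 0:
            continue
        score = ov / max(g.end - g.start, read_end - read_start)
        if (score, ov) > best:
            best = (score, ov)
            best_id = g.gene_id
    return best_id


def scan_trace_segment(values, max_deviation=0.1):
    """Direct trace of the cumulative-average scan over a dense signal."""
    regions = []
    start = 0
    acc = [values[0]]
    for i, v in enumerate(values[1:], start=1):
        if abs(v - sum(acc) / len(acc)) > max_deviation:
            regions.append((start, i))
            start = i
            acc = [v]
        else:
            acc.append(v)
    regions.append((start, len(values)))
    return regions
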
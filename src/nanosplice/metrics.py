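"""Targeted splicing fractions.

``intron_spanning_fraction`` reproduces the XBP1-style readout: the number
of reads lacking an intron divided by the total reads spanning it, with a
standard error computed in logit space. ``gel_splicing_fraction`` is the
gel-band formula (XBP1s + hybrid/2) / (XBP1u + XBP1s + hybrid) used for the
PCR assay; band intensities are numeric inputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from scipy.special import expit, logit

from .models import AlignedRead
from .pileup import DEFAULT_MIN_RUN, preprocess_cigar

DEFAULT_FLANK = 10
DEFAULT_LACK_COVERAGE = 0.9


@dataclass
class SplicingFraction:
    """Spliced fraction with logit-space uncertainty.

    ``interval`` is fraction +/- 2 SE back-transformed from logit space and
    therefore always within [0, 1]. When the count sits on a boundary
    (k = 0 or k = n) a +0.5 continuity correction is applied to the SE and
    interval, and ``continuity_corrected`` is set.
    """

    spliced_count: int
    spanning_count: int
    fraction: float
    logit_se: float
    interval: tuple[float, float]
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.spliced_count <= self.spanning_count:
            raise ValueError("need 0 <= spliced <= spanning")


def _logit_summary(k: int, n: int) -> SplicingFraction:
    fraction = k / n
    corrected = k == 0 or k == n
    kk = k + 0.5 if corrected else k
    nn = n + 1.0 if corrected else n
    se = math.sqrt(1.0 / kk + 1.0 / (nn - kk))
    center = logit(kk / nn)
    lo, hi = float(expit(center - 2 * se)), float(expit(center + 2 * se))
    return SplicingFraction(k, n, fraction, se, (lo, hi), corrected)


def intron_spanning_fraction(
    reads: Iterable[AlignedRead],
    intron: tuple[int, int],
    chrom: str | None = None,
    flank: int = DEFAULT_FLANK,
    lack_coverage: float = DEFAULT_LACK_COVERAGE,
    min_run: int = DEFAULT_MIN_RUN,
) -> SplicingFraction | None:
    """Fraction of intron-spanning reads that lack (splice out) the intron.

    A read spans the intron when its reference footprint covers the interval
    plus ``flank`` bases on each side; it lacks the intron when an absent
    (N/D) run of its cleaned CIGAR covers at least ``lack_coverage`` of the
    interval (exact splice-site matching is brittle to nanopore wobble).
    Returns None when nothing spans.
    """
    i_start, i_end = intron
    if i_end <= i_start:
        raise ValueError("intron interval must be non-empty")
    need = lack_coverage * (i_end - i_start)
    spanning = 0
    lacking = 0
    for read in reads:
        if chrom is not None and read.chrom != chrom:
            continue
        if not (read.start <= i_start - flank and read.end >= i_end + flank):
            continue
        spanning += 1
        pos = read.start
        for cls, length in preprocess_cigar(read.cigar, min_run):
            if cls == "absent":
                ov = min(pos + length, i_end) - max(pos, i_start)
                if ov >= need:
                    lacking += 1
                    break
            pos += length
    if spanning == 0:
        return None
    return _logit_summary(lacking, spanning)


def gel_splicing_fraction(u: float, s: float, h: float) -> float:
    """Gel-band splicing fraction (s + h/2) / (u + s + h).

    ``u``, ``s`` and ``h`` are the background-corrected band intensities of
    the unspliced, spliced and hybrid-dimer products. Scale-invariant in the
    intensities; all-zero input is undefined.
    """
    if u < 0 or s < 0 or h < 0:
        raise ValueError("band intensities must be non-negative")
    total = u + s + h
    if total == 0:
        raise ValueError("band intensities must not all be zero")
    return (s + h / 2.0) / total
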
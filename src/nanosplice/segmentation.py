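"""Partitioning genes into regions of homogeneous percent-spliced-in.

Replicate pileups are combined by summing counts across all samples under
analysis (summing, not averaging fractions, weights positions by evidence).
Positions are masked out when any sample spans them fewer than 5 times or
any condition's replicate-mean coverage falls below 20. The scan walks the
remaining positions left to right keeping a cumulative mean of the %SI since
the current region start and opens a new region whenever a position's %SI
deviates from that mean by more than 0.1. Regions never retained anywhere
(all-condition mean %SI < 0.05) are dropped, and each surviving region is
summarised per sample by the rounded mean spliced-in and spanning counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pileup import SplicePileup

DEFAULT_MAX_DEVIATION = 0.1
DEFAULT_MIN_SAMPLE_COVERAGE = 5
DEFAULT_MIN_CONDITION_MEAN_COVERAGE = 20
DEFAULT_MIN_RETENTION = 0.05


@dataclass
class SpliceRegion:
    """A segmented interval with per-sample averaged integer counts.

    ``counts[sample_id] = (k, n)``: the region-mean spliced-in and spanning
    counts, rounded half-to-even. ``psi[condition]`` is the pooled
    per-condition point estimate (summed k over summed n).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    psi: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, (k, n) in self.counts.items():
            if k > n:
                raise ValueError(f"{self.gene_id} [{self.start},{self.end}) {s}: k > n")


def coverage_mask(
    pileups: Mapping[str, SplicePileup],
    condition_of: Mapping[str, str],
    min_sample: int = DEFAULT_MIN_SAMPLE_COVERAGE,
    min_condition_mean: int = DEFAULT_MIN_CONDITION_MEAN_COVERAGE,
) -> np.ndarray:
    """Positions kept when every sample spans >= ``min_sample`` and every
    condition's replicate-mean spanning coverage is >= ``min_condition_mean``."""
    samples = sorted(pileups)
    spans = np.stack([pileups[s].spanning for s in samples])
    mask = (spans >= min_sample).all(axis=0)
    conditions = sorted({condition_of[s] for s in samples})
    for cond in conditions:
        rows = [i for i, s in enumerate(samples) if condition_of[s] == cond]
        mask &= spans[rows].mean(axis=0) >= min_condition_mean
    return mask


def segment(
    psi: np.ndarray,
    mask: np.ndarray | None = None,
    max_deviation: float = DEFAULT_MAX_DEVIATION,
) -> list[tuple[int, int]]:
    """Cumulative-average scan over the masked %SI signal.

    Walks positions left to right; whenever |%SI - cumulative mean since the
    region start| exceeds ``max_deviation`` the region closes before the
    position and the cumulative mean restarts there. Masked positions are
    skipped without closing the region. Returns half-open index intervals
    spanning from each region's first to last unmasked position.
    """
    n = len(psi)
    if mask is None:
        mask = ~np.isnan(psi)
    kept = np.flatnonzero(mask)
    regions: list[tuple[int, int]] = []
    if kept.size == 0:
        return regions
    start = last = int(kept[0])
    total = float(psi[kept[0]])
    count = 1
    for idx in kept[1:]:
        value = float(psi[idx])
        if abs(value - total / count) > max_deviation:
            regions.append((start, last + 1))
            start = int(idx)
            total = value
            count = 1
        else:
            total += value
            count += 1
        last = int(idx)
    regions.append((start, last + 1))
    return regions


def summarize_region(
    interval: tuple[int, int],
    pileups: Mapping[str, SplicePileup],
    mask: np.ndarray,
    condition_of: Mapping[str, str],
    gene_id: str,
) -> SpliceRegion:
    """Per-sample rounded mean counts over the region's unmasked positions.

    Rounding is half-to-even so results are bit-reproducible.
    """
    lo, hi = interval
    first = next(iter(pileups.values()))
    idx = np.flatnonzero(mask[lo:hi]) + lo
    counts: dict[str, tuple[int, int]] = {}
    cond_k: dict[str, float] = {}
    cond_n: dict[str, float] = {}
    for s, p in pileups.items():
        k = int(np.round(p.spliced_in[idx].mean()))
        n = int(np.round(p.spanning[idx].mean()))
        counts[s] = (k, n)
        c = condition_of[s]
        cond_k[c] = cond_k.get(c, 0.0) + k
        cond_n[c] = cond_n.get(c, 0.0) + n
    psi = {c: (cond_k[c] / cond_n[c] if cond_n[c] > 0 else float("nan")) for c in cond_k}
    return SpliceRegion(
        gene_id=gene_id,
        chrom=first.chrom,
        start=first.start + lo,
        end=first.start + hi,
        counts=counts,
        psi=psi,
    )


def filter_regions(
    regions: Sequence[SpliceRegion], min_retention: float = DEFAULT_MIN_RETENTION
) -> list[SpliceRegion]:
    """Drop regions not retained in any condition (all-condition mean %SI
    below ``min_retention``)."""
    out = []
    for r in regions:
        values = [v for v in r.psi.values() if not np.isnan(v)]
        if values and max(values) >= min_retention:
            out.append(r)
    return out


def segment_gene(
    pileups: Mapping[str, SplicePileup],
    condition_of: Mapping[str, str],
    max_deviation: float = DEFAULT_MAX_DEVIATION,
    min_sample: int = DEFAULT_MIN_SAMPLE_COVERAGE,
    min_condition_mean: int = DEFAULT_MIN_CONDITION_MEAN_COVERAGE,
    min_retention: float = DEFAULT_MIN_RETENTION,
) -> list[SpliceRegion]:
    """Mask, segment, summarise and filter one gene's replicate pileups."""
    if not pileups:
        return []
    first = next(iter(pileups.values()))
    mask = coverage_mask(pileups, condition_of, min_sample, min_condition_mean)
    if not mask.any():
        return []
    spliced = sum(p.spliced_in for p in pileups.values())
    spanning = sum(p.spanning for p in pileups.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(spanning > 0, spliced / np.maximum(spanning, 1), np.nan)
    intervals = segment(psi, mask, max_deviation)
    regions = [
        summarize_region(iv, pileups, mask, condition_of, first.gene_id) for iv in intervals
    ]
    return filter_regions(regions, min_retention)


def regions_to_frame(regions: Sequence[SpliceRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        row = {"gene_id": r.gene_id, "chrom": r.chrom, "start": r.start, "end": r.end}
        for c, v in sorted(r.psi.items()):
            row[f"psi_{c}"] = v
        for s, (k, n) in sorted(r.counts.items()):
            row[f"k_{s}"] = k
            row[f"n_{s}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def write_regions_bed(regions: Sequence[SpliceRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            values = [v for v in r.psi.values() if not np.isnan(v)]
            mean_psi = float(np.mean(values)) if values else float("nan")
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t{mean_psi:.4f}\n")
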
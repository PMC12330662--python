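"""End-to-end pipeline: demux -> annotate -> pileup -> segment -> diffsplice.

A single configuration object carries every threshold of the analysis with
the reported defaults (barcode mismatch tolerance 3, CIGAR merge length 10,
aligned fraction 0.8, segmentation deviation 0.1, per-sample coverage 5,
per-condition mean coverage 20, retention floor 0.05, FDR 0.05,
|log2FC| 0.5), so the zero-configuration behaviour is the published
analysis. Every run writes a JSON manifest with the configuration and a
SHA-256 hash of each output, making reruns verifiably identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, demux, diffsplice, pileup, segmentation

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    reads: str = ""
    alignments: str = ""
    annotation: str = ""
    sample_sheet: str = ""
    outdir: str = "nanosplice_out"
    common_primer: str = ""
    seed: int = 0
    max_barcode_dist: int = 3
    min_polyt: int = 10
    min_cigar_run: int = 10
    min_aligned_fraction: float = 0.8
    max_psi_deviation: float = 0.1
    min_sample_coverage: int = 5
    min_condition_mean_coverage: int = 20
    min_retention: float = 0.05
    max_fdr: float = 0.05
    min_abs_log2fc: float = 0.5
    condition_a: str = ""
    condition_b: str = ""

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage
        self.reason = reason


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order and return the manifest (also written to
    ``manifest.json``). Any stage failure raises StageError naming the stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": {}}
    outputs: list[Path] = []

    # --- demux ------------------------------------------------------------
    try:
        sheet = pd.read_csv(config.sample_sheet, sep="\t")
        raw_reads = demux.read_fastq(config.reads)
        barcodes = dict(zip(sheet["barcode_id"], sheet["barcode_seq"]))
        assignments = demux.demux_reads(
            raw_reads,
            barcodes,
            cp=config.common_primer or None,
            max_dist=config.max_barcode_dist,
            min_polyt=config.min_polyt,
        )
    except (OSError, KeyError, ValueError) as exc:
        raise StageError("demux", str(exc)) from exc
    report = demux.demux_report(assignments)
    report_path = outdir / "demux_report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    outputs.append(report_path)
    barcode_to_sample = dict(zip(sheet["barcode_id"], sheet["sample_id"]))
    fastq_paths = demux.write_demuxed_fastq(assignments, barcode_to_sample, outdir / "demuxed")
    outputs.extend(fastq_paths.values())
    sample_of_read = {
        a.read_id: barcode_to_sample[a.barcode_id]
        for a in assignments
        if a.status == "assigned" and a.barcode_id in barcode_to_sample
    }
    manifest["stages"]["demux"] = {
        "reads_in": len(raw_reads),
        "status_counts": report["status"].value_counts().to_dict(),
    }
    logger.info("demux: %s", manifest["stages"]["demux"])

    # --- annotate ---------------------------------------------------------
    try:
        genes = annotate.read_gtf(config.annotation)
        reads = annotate.read_sam(config.alignments)
    except (OSError, ValueError) as exc:
        raise StageError("annotate", str(exc)) from exc
    index = annotate.GeneIndex(genes)
    kept_reads = []
    gene_of_read: dict[str, str] = {}
    for r in reads:
        s = sample_of_read.get(r.read_id)
        if s is None:
            continue  # read excluded at demux
        r.sample_id = s
        kept_reads.append(r)
    counts, unassigned = annotate.build_counts(kept_reads, index)
    for r in kept_reads:
        g = annotate.assign_gene(r, index)
        if g is not None:
            gene_of_read[r.read_id] = g
    counts_path = outdir / "gene_counts.tsv"
    annotate.write_counts(counts, counts_path, unassigned)
    outputs.append(counts_path)
    manifest["stages"]["annotate"] = {
        "alignments_in": len(reads),
        "demuxed": len(kept_reads),
        "assigned": int(counts.values.sum()),
        "unassigned": int(unassigned.sum()),
    }
    logger.info("annotate: %s", manifest["stages"]["annotate"])

    # --- pileup -----------------------------------------------------------
    try:
        pileups = pileup.pileups_by_sample(
            kept_reads,
            genes,
            gene_of_read,
            min_run=config.min_cigar_run,
            min_aligned_fraction=config.min_aligned_fraction,
        )
    except ValueError as exc:
        raise StageError("pileup", str(exc)) from exc
    bedgraph_path = outdir / "psi.bedgraph"
    pileup.write_psi_bedgraph(pileups, bedgraph_path)
    outputs.append(bedgraph_path)
    manifest["stages"]["pileup"] = {"genes": len(pileups)}

    # --- segmentation -----------------------------------------------------
    condition_of = dict(zip(sheet["sample_id"], sheet["condition"]))
    regions = []
    for gene_id in sorted(pileups):
        regions.extend(
            segmentation.segment_gene(
                pileups[gene_id],
                condition_of,
                max_deviation=config.max_psi_deviation,
                min_sample=config.min_sample_coverage,
                min_condition_mean=config.min_condition_mean_coverage,
                min_retention=config.min_retention,
            )
        )
    regions_path = outdir / "regions.tsv"
    segmentation.regions_to_frame(regions).to_csv(regions_path, sep="\t", index=False)
    bed_path = outdir / "regions.bed"
    segmentation.write_regions_bed(regions, bed_path)
    outputs.extend([regions_path, bed_path])
    manifest["stages"]["segmentation"] = {"regions": len(regions)}
    logger.info("segmentation: %d regions", len(regions))

    # --- diffsplice -------------------------------------------------------
    conditions = list(dict.fromkeys(sheet["condition"]))
    cond_a = config.condition_a or conditions[0]
    cond_b = config.condition_b or (conditions[1] if len(conditions) > 1 else conditions[0])
    samples_by_condition = {
        c: list(sheet.loc[sheet["condition"] == c, "sample_id"]) for c in conditions
    }
    results = diffsplice.test_regions(regions, cond_a, cond_b, samples_by_condition)
    results_path = outdir / "diffsplice.tsv"
    diffsplice.results_to_frame(results, cond_a, cond_b).to_csv(
        results_path, sep="\t", index=False
    )
    outputs.append(results_path)
    n_sig = sum(
        1 for r in results if r.status == "ok" and r.adjusted <= config.max_fdr
    )
    manifest["stages"]["diffsplice"] = {
        "tested": len(results),
        "significant": n_sig,
        "conditions": [cond_a, cond_b],
    }
    logger.info("diffsplice: %s", manifest["stages"]["diffsplice"])

    manifest["outputs"] = {str(p.relative_to(outdir)): _sha256(p) for p in outputs}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
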
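# nanosplice

Differential splice-isoform analysis for barcoded long-read (nanopore-style)
cDNA sequencing.

Long-read cDNA captures full transcript structure, so intron retention and
other splicing changes — for example the unconventional *XBP1* intron excised
by IRE1 during the unfolded protein response, or stress-induced retention of
introns in genes like *HSP90B1* and *EIF4A2* — can be read directly from the
spliced alignments. `nanosplice` implements the complete path from raw
multiplexed reads to region-level differential-splicing calls:

1. **demux** — reads are assigned to samples by locating the oligo-dT
   primer's poly-T tract and the common primer, then matching a barcode at
   infix edit distance ≤ 3 next to those anchors; reads with no, multiple,
   or wrongly-oriented barcodes are excluded, and primer structure is
   trimmed.
2. **annotate** — each spliced alignment is assigned to the gene maximising
   overlap / max(annotation length, alignment length); per-sample gene
   counts feed standard differential-expression tooling (significance
   filter: BH-FDR ≤ 0.05 and |log₂FC| ≥ 0.5).
3. **pileup** — per genomic position, the percent-spliced-in value
   %SI = (reads including the base) / (reads spanning the position),
   after merging CIGAR runs < 10 bp into their predecessor, ignoring
   insertions, dropping reads ≤ 80% aligned, and discarding each read's
   first and last runs.
4. **segmentation** — positions with coverage < 5 in any sample or
   replicate-mean < 20 are masked; a left-to-right scan opens a new region
   whenever %SI deviates from the running region mean by more than 0.1;
   regions unretained everywhere (%SI < 0.05 in all conditions) are
   dropped; per-sample counts are averaged per region and rounded.
5. **diffsplice** — per region and condition, replicate spliced-in counts
   follow k_i ~ NB(μ = p·n_i, φ); p is the maximum-likelihood retention
   probability, and conditions are compared by the nested likelihood ratio

       λ = L_joint(single p) / (L_A · L_B),   λ ≤ 1,

   BH-adjusted across all tested regions. Small λ ⇒ differential retention;
   Δ%SI = p̂_B − p̂_A gives the volcano-plot x-axis.
6. **metrics** — targeted readouts: the intron-spanning splicing fraction
   (reads lacking an intron / reads spanning it) with logit-space standard
   errors, and the gel-band formula (s + h/2)/(u + s + h).

A synthetic-data generator (`nanosplice.simulate`) produces references,
gene models, isoform mixtures, barcoded error-injected FASTQ, spliced SAM
alignments, GTF annotation and full truth tables, so the entire pipeline is
testable without external data.

## Worked example

Simulate three genes in two conditions × three replicates, where gene 1's
retained intron shifts from 95% to 35% retention under "stress", then run
the full pipeline:

```python
import nanosplice as ns
from nanosplice.pipeline import PipelineConfig, run_pipeline
import pandas as pd

design = ns.ConditionDesign(
    mean_reads=150,
    retention={"baseline": [0.5, 0.95, 0.4], "stress": [0.5, 0.35, 0.4]},
)
sim = ns.simulate_transcriptome(3, seed=7, design=design)
paths = ns.write_simulation(sim, "example_sim")
config = PipelineConfig(
    reads=str(paths["reads"]),
    alignments=str(paths["alignments"]),
    annotation=str(paths["annotation"]),
    sample_sheet=str(paths["sample_sheet"]),
    outdir="example_out",
    common_primer=ns.DEFAULT_COMMON_PRIMER,
)
manifest = run_pipeline(config)
print(manifest["stages"]["demux"]["status_counts"])
df = pd.read_csv("example_out/diffsplice.tsv", sep="\t")
cols = ["gene_id", "start", "end", "delta_psi", "lambda", "adjusted"]
print(df.sort_values("lambda")[cols].head(3).to_string(index=False))
```

Output:

```
{'assigned': 2677, 'none_found': 1}
 gene_id  start  end  delta_psi   lambda  adjusted
GENE0001   3481 3567  -0.657758 0.000010   0.00014
GENE0002   5963 6130   0.022944 0.864281   1.00000
GENE0000   1027 1129  -0.014834 0.951011   1.00000
```

2,677 of 2,678 reads demultiplex (2% substitution error); the top region is
exactly gene 1's retained intron (positions 3481–3567), with Δ%SI ≈ −0.66 —
the measured retention drop — and a likelihood ratio of 10⁻⁵
(BH-adjusted 1.4 × 10⁻⁴). The two runner-up regions are null (λ ≈ 1).
The measured |Δ%SI| is slightly larger than the designed 0.60 because
5'-truncated retained reads lose their upstream junction and deflate
absolute %SI more at low retention (see `docs/methods.md`).

The same stages are available as subcommands of the `nanosplice` CLI
(`simulate`, `demux`, `annotate`, `intron-frac`, `run-all`).

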
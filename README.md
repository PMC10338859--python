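# prclip

CLIP crosslink-site analysis and RNA binding kinetics for arginine-rich
dipeptide repeat (DPR) proteins.

Expanded G4C2 repeats in *C9orf72* — the most common genetic cause of
ALS/FTD — are translated into dipeptide repeat proteins such as poly(PR),
which binds cellular RNA directly. `prclip` implements the computational
side of characterising that binding from individual-nucleotide-resolution
CLIP (iCLIP-style) experiments and from biolayer-interferometry (BLI)
binding assays, for analysts who have aligned CLIP reads (or want a fully
synthetic benchmark) and BLI association traces:

- **Crosslink-event extraction** — demultiplexing by experimental barcode,
  3' adaptor trimming, PCR-duplicate collapse on UMIs, and truncation-model
  site assignment: the crosslinked nucleotide is the base immediately 5' of
  each unique cDNA's aligned 5' end.
- **Significant-site calling** — per-gene permutation FDR: the ±w-nt window
  score of each crosslink position is compared against events redistributed
  uniformly over the gene, and sites are kept at FDR < 0.05.
- **Gene-level binding** — counts-per-million tracks, a ≥300,000-event
  sample QC threshold, and a bound-gene filter (≥200 events in the
  crosslinked sample, <10% of that signal in non-crosslinked and tag-only
  controls), plus genomic region annotation (CDS / UTRs / ncRNA / intron /
  intergenic).
- **Pentamer motif enrichment** — all 1,024 pentamers tested by one-sided
  Fisher exact test on window presence counts, foreground = 36-nt windows
  (−5..+30 nt) around significant sites, background matched per gene from
  site-free spans; p-values computed in log space so values like 1e-930
  remain exact; Bonferroni correction; positional profiles and
  GANGA-style motif tracks.
- **BLI 1:1 binding fits** — steady-state analysis
  `Req(C) = Rmax·C/(C + Kd)` by non-linear least squares on per-replicate
  equilibrium responses, with plateau checking / exponential extrapolation,
  replicate comparison by two-tailed unpaired t test, and an optional global
  kinetic fit.
- **Synthetic data** (`prclip.synthio`) — a toy transcriptome with planted
  GAAGA motifs, CLIP libraries with full ground truth (truncation reads,
  UMIs, PCR duplicates, low-yield controls), and simulated BLI traces, so
  every stage is testable with no downloads.

## Worked example

Run the full pipeline on a small bundled synthetic experiment (5 genes of
~2 kb, 8,000 crosslink events in the PR sample, controls at 5%):

```python
from prclip import pipeline

cfg = pipeline.validate_config({
    "transcriptome": {"n_genes": 5, "gene_length_range": [1500, 2500]},
    "clip": {"n_events": 8000},
    "seed": 3,
})
result = pipeline.run_pipeline(cfg, outdir="demo")
print(open("demo/report.txt").read())
```

```
prclip run report
=================

Sample QC (unique crosslink events):
           sample  unique_crosslink_events  min_events  pass
 FLAG-crosslinked                      400      300000 False
   GA-crosslinked                      400      300000 False
   PR-crosslinked                     8000      300000 False
PR-noncrosslinked                      400      300000 False

Significant crosslink sites: 139
Bound genes: 5

Genomic region distribution of crosslink events:
region
CDS                0.382750
five_prime_UTR     0.036500
three_prime_UTR    0.072500
ncRNA_exon         0.128125
intron             0.380125
intergenic         0.000000

Top enriched pentamer: GAAGA (p = 8.4e-68, Bonferroni p = 8.6e-65)
```

Reading this output: all four libraries fall below the 300,000-event depth
threshold (expected for a deliberately small fixture; QC is in `warn` mode),
139 crosslink positions pass the permutation FDR, all 5 genes pass the
bound-gene filter (each has ≥200 PR events with controls far below 10%),
crosslinks fall mostly in CDS and introns, and the planted GAAGA pentamer
is recovered as the top-ranked motif with a Bonferroni-corrected p of
8.6e-65 — the signature the analysis is designed to detect.

The same stages are available from the shell:

```bash
prclip simulate --out sim --seed 3 --n-genes 5 --n-events 8000
prclip extract --fastq sim/PR-crosslinked.fastq \
    --alignments sim/PR-crosslinked.alignments.bed \
    --layout sim/layout.json --out pr
prclip callsites --events pr.events.bed --genes sim/genes.gff3 --out pr
prclip motif --sites pr.sites.tsv --genome sim/genome.fa \
    --genes sim/genes.gff3 --out pentamers.tsv
prclip bli --traces traces.csv --mode equilibrium --out fits.tsv
```

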
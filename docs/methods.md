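# Methods

`prclip` re-implements, as a tested library, the computational analysis used
to characterise RNA binding of arginine-rich dipeptide repeat (DPR) proteins
such as poly(PR): crosslink-event extraction from iCLIP-style sequencing
reads, permutation-FDR crosslink-site calling, control-aware gene-level
binding quantification, pentamer motif enrichment around crosslink sites,
and steady-state 1:1 fitting of biolayer-interferometry (BLI) binding data.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Crosslink model and read processing

iCLIP-type libraries identify protein–RNA contacts through cDNA
*truncation*: reverse transcription stops one nucleotide short of the
crosslinked base, so a uniquely mapped read's crosslink site is the
nucleotide immediately 5' of its aligned 5' end. In 0-based half-open
coordinates this is `start - 1` for plus-strand reads and `end` for
minus-strand reads; reads whose site would fall outside the reference are
dropped and counted. Readthrough (crosslink-spanning) cDNAs are not
modelled.

Reads carry an experimental barcode, then a unique molecular identifier
(UMI), then the cDNA insert, optionally followed by the 3' sequencing
adaptor. Demultiplexing is exact-match by default (a mismatch budget is
configurable; the barcode table is validated to be unambiguous at twice the
budget). PCR duplicates are collapsed to one representative per
`(reference, start, strand, UMI)` group — exact UMIs only, with no
error-tolerant UMI merging, since nothing in the analysis requires it and
exact collapse is idempotent and auditable. In SAM/BAM mode, secondary and
supplementary records and records below a mapping-quality floor (default
20) are excluded; this implements a "uniquely mapping" filter without
relying on aligner-specific tags. A minimum post-trim insert length
(default 18 nt) guards against adaptor-only reads.

## Site calling: permutation FDR

Crosslink sites are scored per gene. The score of position `p` is the
number of unique events in `[p - w, p + w]` (default `w = 3`). The null
redistributes the gene's `n` events uniformly at random (with replacement)
over the gene's positions, `n_perm = 100` times. For each observed event
position,

    FDR(p) = min(1, E_perm[# permuted event-positions with score >= s(p)]
                    / # observed event-positions with score >= s(p))

evaluated only at positions bearing at least one observed event (sites are
by definition crosslink positions); tied scores share one FDR. Raw
estimates are made monotone non-increasing in score by a running minimum
over ascending scores, so a higher-scoring site never reports a worse FDR
than a lower-scoring one. Sites are retained at FDR < 0.05. Events outside
any annotated gene are tested within fixed-width intergenic tiles (10 kb)
serving as pseudo-genes. Site calling defaults to pooled replicates;
nothing prevents calling per sample. `w` and `n_perm` are exposed because
the permutation-FDR family of CLIP peak callers does not fix them
canonically; all outputs embed the parameters used.

Calibration: on uniform tracks the called fraction at threshold 0.05 stays
at or below the nominal level within Monte-Carlo error (it is strongly
conservative in practice, since uniform nulls rarely produce extreme window
scores); a 100-event pileup on a 1-kb gene is always called.

## Sample QC and gene-level binding

A sample passes depth QC at >= 300,000 unique crosslink events, the depth
below which a crosslinked-sample replicate is excluded from gene-level
analysis; enforcement is `warn` by default because synthetic fixtures are
deliberately smaller, and `strict` aborts the run.

Per-gene event counts use the gene span (half-open, strand-matched);
CPM = count * 1e6 / sample total. A gene is *bound* when it has at least
200 crosslinked-sample events and its control fraction — the max over
control conditions (non-crosslinked and tag-only) of the gene's
control/PR signal ratio — is strictly below 10%.

The control fraction is computed on raw unique-event counts by default.
This was a genuinely open choice: a depth-normalized (CPM) ratio asks
whether the gene's *share* of the control library is small, which erases
exactly the evidence the experimental design produces — control libraries
are low-yield *because* the protein is not crosslinked, and that yield gap
is the specificity signal (in data where controls simply carry ~5% of the
events everywhere, the CPM ratio is ~1 for every gene and the filter can
never pass). `summarize_binding(..., normalization="cpm")` provides the
depth-normalized reading; the choice is recorded in the output metadata.

Region annotation assigns each event exactly one class with precedence
CDS > 5'UTR > 3'UTR > non-coding-RNA exon > intron > intergenic
(config-overridable); proportions partition the event set.

## Pentamer enrichment

Foreground windows cover 5 nt upstream to 30 nt downstream of each
significant site (36 nt, transcript orientation, RNA sense; windows
truncated by gene ends are dropped and counted). Background windows are
drawn uniformly from the same genes, matched 1:1 per gene, restricted to
spans overlapping no significant site; genes with no eligible span are
skipped with a warning and their multiplicity reassigned over the pooled
eligible positions of the remaining genes.

Each of the 1,024 pentamers is tested on window *presence* counts (a
window either contains the pentamer or not — robust to repeat-heavy
windows), with a one-sided Fisher exact test for foreground enrichment.
The hypergeometric upper tail is computed in log space (log-pmf plus
log-sum-exp), so p-values far below double underflow (10^-900 and beyond)
remain exact; agreement with exact integer enumeration is ~1e-14 relative
across all tables with margins <= 30. Correction is Bonferroni over
exactly 1,024 tests — with the full pentamer set enumerable there is no
need for a heuristic motif search or E-value approximation. Results sort
by p ascending with ties broken by foreground count then lexicographically.

Positional profiles report, per offset in −50..+50 nt from the site, the
fraction of sites with a motif occurrence starting there (IUPAC-degenerate
motifs such as GANGA supported; a site is excluded only at offsets whose
span leaves its gene). Motif tracks emit a per-position motif-start
indicator aligned with the CPM crosslink track for browser-style figures.

## BLI: steady-state 1:1 analysis

Association of a 1:1 (Langmuir) interaction follows
`R(t) = Req(C)(1 − e^(−(ka·C + kd_off)t))` with
`Req(C) = Rmax·C/(C + Kd)` and `Kd = kd_off/ka`. The primary analysis is
steady-state, matching how slow-dissociating DPR–RNA interactions are
usually quantified: `Req` is the mean response over the final 10% of each
trace, accepted as plateau when the response drift across the tail is
below 1% of `Req` per 10% of trace duration (no canonical plateau
criterion exists; this one is scale-free). Traces stopped short of plateau
are extrapolated with a single exponential and flagged. The isotherm is
then fitted by non-linear least squares (initialised at
`Rmax0 = max Req`, `Kd0 =` interpolated half-max concentration; steps
scaled by the initial guess since Kd is O(1e-9) in molar units). Data not
reaching half the fitted `Rmax` are flagged low-confidence. Kd is fitted
per replicate and replicates summarised as mean ± SD, compared between
groups with a two-tailed unpaired (Student) t test; zero-variance
degenerate groups return p = 1 when identical, or a p below the smallest
positive double with a flag when separated. A global kinetic fit
(ka, kd_off, Rmax) is available as a secondary analysis.

Default concentration ladders are 2-fold dilution series spanning
2.1–133.3 nM (high-affinity peptides) and 3.1–25 µM (negative-control
peptide).

## Synthetic data: what it emulates, and what it does not

The generator produces a single-chromosome toy genome (default 20 genes of
~5 kb, GC 0.45, 1–4 exons, 80% protein-coding with UTR/CDS structure) with
a 5-mer motif (GAAGA) planted non-overlapping at 2 per kb, every placement
recorded in ground truth. Crosslink events are placed over the full
pre-mRNA span of each gene — mirroring the predominance of intronic
crosslinks in cellular CLIP — with the per-position rate multiplied by
`motif_boost` (default 50) at positions 0–5 nt 5' of a planted motif
start, so the motif lands inside the −5/+30 analysis window of a
motif-driven site. With `motif_boost = 1` placement is uniform. Note the
boost is a *rate* factor: at density 2/kb and boost 50 the expected
motif-proximal event fraction is the boosted weight mass over the total,
about 0.38, which is ample for motif recovery (the planted motif ranks
first with Bonferroni p below 1e-600 at 50,000 events). Control conditions
(non-crosslinked, tag-only, comparison DPR) share the transcriptome and
differ only in event count (5% of the crosslinked sample) and absent motif
bias, isolating the filter logic under test.

Each unique cDNA receives a UMI drawn collision-free within its
(position, strand) group, so unique (position, UMI) pairs equal the event
count exactly and read-level recovery can be tested for exact equality;
real libraries would contain rare UMI collisions (and UMI sequencing
errors), which this generator deliberately omits. PCR duplicate counts are
1 + Poisson(mean − 1) (default mean 3). Reads are single-end and
error-free by default (a substitution rate is configurable); alignment is
consumed, not performed, so truth alignments are emitted directly.
Splicing of reads across junctions, UV dose, and aggregation biology of
the comparison DPR are not modelled. Consequently, passing tests
demonstrate the correctness of the *analysis logic* under the stated
statistical structure — not robustness to mapping artefacts, sequence
error, or the full complexity of cellular transcriptomes.

BLI simulation draws noiseless traces from the 1:1 model (default
ka = 1e5 /M/s, kd_off = 2.6e-4 /s, hence Kd = 2.6 nM with a ~44-min
dissociation half-life, consistent with very slow dissociation) on a
per-concentration time grid reaching 8/kobs, plus additive Gaussian noise
with sd = 1% of Rmax and 3 replicates by default.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open in memory; BED6 on disk as-is; GFF3
  converted to 1-based inclusive on write and back on read.
- Window scores use a length-(2w+1) box convolution; gene edges truncate
  the window naturally.
- All randomness flows through `numpy.random.Generator` seeded from
  explicit config seeds; identical config implies byte-identical outputs
  (pipeline reruns are digest-identical).
- Zero-event genes yield empty site lists (not an error); empty tracks
  cannot be CPM-normalized; a gene with events but zero CPM is an internal
  inconsistency and raises.
- Extremely small p-values are kept in log10 space end-to-end and
  formatted as strings (e.g. `3.1e-930`) only for display.
- Problem sizes in the test and acceptance runs (20 genes x ~5 kb, 50,000
  events, 100 permutations, 5–20 seeds, 200-run Monte-Carlo bands) were
  chosen as the smallest sizes at which the calibration properties are
  statistically meaningful.

## Known limitations

- The permutation null is uniform within the gene; it does not model
  transcript-abundance gradients or RNase sequence bias, so on real data
  the FDR is calibrated against positional clustering only.
- Background windows are sampled with replacement; for genes with few
  eligible positions background windows can repeat.
- The bound-gene filter defaults to pooled replicates; per-replicate
  thresholds need the caller to split samples.
- The steady-state BLI analysis assumes the association phase approaches
  equilibrium or is well-described by a single exponential; mass-transport
  limitation and avidity are not corrected for.
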
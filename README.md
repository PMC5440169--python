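# ncddetect

Driver detection for coding and non-coding genomic elements. The package
compares the observed, functionally weighted mutation burden of a candidate
element against an **exact background score distribution** derived from a
position- and sample-specific model of the somatic mutation rate.

The pipeline:

1. **elements** — derive candidate elements (protein-coding genes, promoters,
   splice sites, 3'/5' UTRs) from transcript annotations, collapsed per gene
   and resolved through a fixed category hierarchy.
2. **annotate** — compute six explanatory variables per position: sample id,
   replication-timing bin, strand-collapsed central base (weak/strong),
   flank pair (16 levels), genomic segment, expression bin and a
   burden-normalized local mutation rate (20 kb windows flanking a skipped
   ±10 kb core), with quantile binning of the numeric tracks.
3. **nullmodel** — aggregate a count table over covariate combinations, fit
   a multinomial logistic background model (4 outcomes: no mutation,
   transition, two transversion classes) as three one-vs-reference binomial
   logits on a sparse design, with 3-fold multiple imputation of missing
   replication timing. An exact multinomial fit is included as a validation
   path.
4. **overdispersion** — estimate extra-binomial variation of windowed
   observed vs expected counts with a beta-binomial model and shrink
   per-window observed/expected ratios into probability correction factors.
5. **scoring** — three schemes on a shared integer deci-grid: mutation
   counts (`nmut`), −log predicted probability (`loglik`) and shifted
   phyloP conservation (`phylop`).
6. **detect** — per-sample background score distributions by dynamic
   programming (capping scored events at the two highest-scoring mutations
   per sample), cross-sample convolution, inclusive upper-tail p-values and
   Benjamini–Hochberg q-values per element category.
7. **simulate** — synthetic cohorts (genome, tracks, transcripts, mutations
   with log-normal per-sample burdens, covariate effects, window-level rate
   heterogeneity, spiked driver elements) so everything is testable offline.

## CLI

All stages are re-runnable from persisted intermediates:

```bash
ncddetect simulate  --config config.yaml --outdir sim/
ncddetect elements  --transcripts sim/transcripts.tsv --out elements.bed
ncddetect annotate  --genome sim/genome.fa --replication sim/replication.bedgraph \
                    --expression sim/expression.bedgraph --elements elements.bed \
                    --mutations sim/mutations.tsv --out annotation.tsv \
                    --boundaries-out bounds.json
ncddetect fit       --annotation annotation.tsv --mutations sim/mutations.tsv \
                    --model final --boundaries bounds.json --seed 1 --out model.json
ncddetect adjust    --annotation annotation.tsv --model model.json \
                    --mutations sim/mutations.tsv --out adjust.json
ncddetect test      --elements elements.bed --annotation annotation.tsv \
                    --model model.json --adjustment adjust.json \
                    --mutations sim/mutations.tsv --scheme phylop \
                    --phylop sim/phylop.bedgraph --fdr 0.10 --out results.tsv
ncddetect signature --mutations sim/mutations.tsv --genome sim/genome.fa \
                    --melanoma-types CT1 --out signature.tsv
```

`--scheme` selects `nmut`, `loglik` or `phylop`; `--model` selects the
covariate ladder (`basic`, `1a`, `1b`, `1c`, `final`).

Mutation input is a MAF-like TSV with header
`sample  chrom  pos  ref  alt [cancer_type]` (1-based positions); a thin
single-sample VCF adapter is available in the library. Tracks are bedGraph
or wiggle fixedStep; element definitions are extended BED
(`chrom start end element_id element_type gene`); transcripts are a
GTF-like TSV (`gene transcript chrom strand feature start end` with
features `exon`/`CDS`/`UTR5`/`UTR3`, 0-based half-open).

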
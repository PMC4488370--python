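# svmicroevo

Microevolutionary analysis of large (≥ 2 kb) deletions and duplications from
differential read coverage, with downstream expression-impact statistics —
plus a planted-truth simulator so every stage is testable offline.

The toolkit covers:

- **SV calling** (`sv_caller`) — a per-window exact conditional test: the two
  Poisson read counts are conditioned on their sum, giving a Binomial null
  for the test count; two-sided p-values use the minimum-likelihood rule.
  Significant windows merge into calls (≥ 2 kb), thresholds are calibrated
  against a labeled truth set (ROC utilities plus a truth-recovery grid
  scan), and per-window genome fractions summarise the landscape.
- **Synteny polarization** (`synteny`) — exact maximal-run detection of
  perfectly collinear gene-order blocks against an outgroup (optionally
  allowing whole-run inversions), and flagging of SV calls that overlap
  block spans as polarized (derived) events.
- **Expression effects** (`gene_effects`) — SV-to-gene assignment (complete
  first-to-last-exon containment, or ≥ 50 % for partial deletions),
  order-of-magnitude FPKM classes, Fisher's exact loss-of-expression test,
  rank-sum dosage fold-change test, Spearman transcriptome correlation.
- **Allele bias** (`allele_bias`) — detection of copy-biased expression from
  DNA vs RNA allele counts at copy-segregating (apparently heterozygous)
  sites, with exact rank-sum enumeration at small site counts and
  Benjamini–Hochberg FDR control across genes.
- **Homology classes** (`homology`) — inparalog-aware best-reciprocal-hit
  1:1 orthologs and connected-component paralogy from tabular hit data,
  giving five exhaustive gene classes.
- **Enrichment** (`enrichment`) — per-class Fisher depletion/enrichment,
  hypergeometric PFAM-family enrichment (with a seeded permutation
  alternative), and diversity stratified by SV overlap.
- **Synthetic data** (`synthetic_data`) — seeded, fully deterministic
  generators for every input above with planted ground truth: Poisson
  coverage over planted copy-number 0/2 segments, log-normal expression with
  deletion/duplication effects, Binomial allele counts, hit tables realizing
  known homology classes, rearranged gene orders with known blocks, and
  two-stratum diversity.

All genomic intervals are 0-based half-open internally; GFF3 and VCF are
converted on read, BED is written natively.

## CLI

A single `svmicroevo` entry point with one subcommand per stage:

```bash
# write a synthetic dataset with truth sidecar
svmicroevo simulate --seed 3 --out-dir data/

# call SVs from per-window counts
svmicroevo call --counts data/window_counts.tsv --out calls.bed --p-cutoff 1e-5

# calibrate thresholds against a truth/label set
svmicroevo calibrate --counts data/window_counts.tsv --truth data/truth.json \
    --out policies.yaml

# collinear blocks + polarization, expression effects, allele bias,
# homology classes, family enrichment
svmicroevo synteny --genes data/genes.gff3 --order-b orderB.txt \
    --orthologs orthologs.tsv --out blocks.tsv
svmicroevo effects --calls calls.bed --genes data/genes.gff3 \
    --expression data/expression.tsv --out effects.json
svmicroevo allele-bias --sites sites.tsv --fdr 0.05 --out bias.tsv
svmicroevo homology --hits hits.tsv --out classes.tsv
svmicroevo enrich --domains domains.tsv --sv-genes sv.txt \
    --background bg.txt --out families.tsv

# full seeded end-to-end synthetic run (simulate -> call -> polarize ->
# effects -> allele bias -> homology -> enrich); writes report.json
svmicroevo run --config config.yaml --seed 1 --out-dir out/
```

`config.yaml` for `run` takes a `seed`, an optional `simulate:` block of
simulator overrides (genome_length, n_genes, n_deletions, depth_ref, ...)
and an optional `call:` block (`max_fpr`, `min_size`). Re-running with the
same seed produces byte-identical reports.

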
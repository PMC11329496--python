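# deamap

Analysis of **antibody-directed C-to-U RNA editing** experiments: a
tethered cytidine deaminase (APOBEC1 fused to an antibody-recognising
nanobody) deposits C→U conversions on transcripts near the RNA-binding
protein (RBP) it is steered to, and the RBP's binding sites are read out
from sequencing as clusters of edited cytosines. `deamap` implements the
computational half of such an experiment, for bulk short reads and for
isoform-resolved long reads, together with a fully seeded synthetic-data
generator that provides ground truth for every stage.

## Who this is for

Computational biologists analysing directed-editing RBP-profiling data
(or evaluating such pipelines) who need a transparent, tested,
desk-scale implementation of the complete chain:

1. **Edit-site calling** — per-site ref/alt counts (from a pileup or a
   count table), a coverage-aware confidence score, and the standard
   filters: score > 0.5, edit fraction < 0.8 (near-fixed fractions are
   SNPs, not enzymatic edits), known-SNP exclusion.
2. **Edit-cluster detection** — sliding windows over annotated features;
   in a window with `n_C` covered cytosines and `k` edit sites,
   significance is the Poisson tail `P(X ≥ k)` with
   `λ = p_bg(class) · n_C`, where `p_bg(class)` is the edit-site density
   per region class (5′UTR/exon/intron/3′UTR); Benjamini–Hochberg FDR at
   0.1; significant windows within 15 nt merged and trimmed to their
   outermost edit sites.
3. **Confident clusters** — strand-aware intersection across replicates
   (anchor semantics of `bedtools intersect -wa -u -s`) followed by
   whole-cluster subtraction of buffer-only control clusters.
4. **Binding-specificity statistics** — motif scanning on gene sense
   strands, the motif-containing fraction against 20 length- and
   feature-preserving shuffles (`Z = (obs − mean)/sd`, enrichment
   `obs/mean`), signed nearest-motif distances, reference-peak overlap,
   and an edit-radius estimator (the distance beyond which case and
   control distance distributions coincide).
5. **Isoform-level editsC** — long-read filtering (mapped, primary,
   non-supplementary, quality ≥ 20, correct strand), removal of
   recurrent and annotated SNPs, `editsC = Σ edited C / Σ C` per isoform
   and sample, coverage ≥ 20 and editsC ≥ 0.02 filters, and selection of
   case-elevated isoforms at > 1.5 residual standard deviations from an
   OLS fit of case on control editsC.

## Worked example

Simulate a small experiment and run the full pipeline:

```bash
deamap simulate --outdir demo --seed 9 --n-genes 40 --n-bound-motifs 10
deamap run-all --config demo/pipeline.yaml
```

The second command prints the stage census, e.g.

```
sites_case_rep0        10637
clusters_case_rep0     14
...
confident_case         10
confident_enzyme_only  0
```

meaning: replicate 0 of the case condition retained 10,637 filtered edit
sites forming 14 clusters; after three-way intersection and buffer
subtraction 10 confident clusters remain (the 10 planted binding sites)
while the enzyme-only control retains none. `demo/pipeline_out/` then
holds per-stage BED/TSV files, including `enrichment.tsv` with the
observed motif fraction, permutation mean/sd, Z and fold enrichment.

The same analyses at study scale live in `analysis/01_simulate.py` …
`analysis/07_isoform_edits.py`; each is a thin driver that prints what it
finds and writes a table under `results/`. With the default seed the
cluster study recovers 30/30 planted binding sites (motif fraction 1.0
vs 0.19 ± 0.09 in shuffles, Z = 9.3, enrichment 5.3), estimates the
edit radius at 215 nt (simulated: 200), and the isoform study selects
22 isoforms at sensitivity 0.96 with replicate Pearson r = 0.99.

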
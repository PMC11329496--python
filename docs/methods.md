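# Methods

`deamap` analyses directed-deaminase RBP-profiling data: a cytidine
deaminase tethered (via antibody recognition) to an RNA-binding protein
converts C to U on nearby transcript positions, and sequencing reads
report those conversions as C→T mismatches (G→A on minus-strand genes).
This note records the models, parameters and numerical choices, what the
synthetic generator does and does not emulate, and the known limitations.

## Coordinates and strand conventions

All internal coordinates are 0-based half-open on the genomic forward
strand; GTF (1-based inclusive) is converted at the I/O boundary, BED
passes through unchanged. Strand is mandatory on every interval record;
unstranded input is rejected rather than guessed. A "sense-strand C" is a
genomic C inside a + gene or a genomic G inside a − gene; the edited base
is T and A respectively. Reads aligned opposite their gene's strand are
excluded everywhere.

## Edit-site confidence score

Public descriptions of deaminase-profiling pipelines state that edit
sites carry a confidence score in [0, 1] with a discard rule of
score < 0.5, but not the scoring formula. We therefore define our own:
with `a` edited and `r` reference reads at a site and background
conversion rate `p_bg`, the score is the posterior probability that the
site's true conversion rate exceeds `p_bg` under a Jeffreys Beta(½, ½)
prior with binomial likelihood,

    score = P(θ > p_bg | a, r) = 1 − I(p_bg; a + ½, r + ½),

computed with the regularised incomplete beta function. The score is
coverage-aware, monotone non-decreasing in `a` and non-increasing in `r`,
and respects the "< 0.5 discard" semantics (at zero edited reads the
posterior median sits near 1/(2·coverage), so well-covered unedited sites
fall below 0.5 for any plausible `p_bg`). It is *not* claimed to be
numerically identical to any published caller's score. Positions with no
converted read carry no edit evidence and are never emitted as candidate
sites; positions with zero coverage are never emitted at all.

`p_bg` defaults to the pooled edit fraction of the buffer-only control
tables when controls are provided (the no-enzyme artifact rate from RNA
damage and RT/PCR error), else to a configuration constant of 0.005.

Filters: retain sites with score > 0.5 **and** edit fraction < 0.8
(both exclusive — a near-fixed apparent fraction marks a cell-line SNP,
not enzymatic editing) **and** position absent from the known-SNP list.

## Edit-cluster model

Windows of 50 nt, stepped by 10 nt, are laid along every annotated
feature (5′UTR, exon, intron, 3′UTR of each gene's primary isoform) that
contains at least one passing edit site. Fixed windows are our design;
the published cluster callers do not document their window construction.
Window statistics use edit-*site* counts rather than read counts, which
decouples significance from the coverage inflation seen at poorly
covered positions.

Per region class, the background `p_bg(class)` is the density of passing
edit sites among covered Cs in that class (classes without coverage
inherit the global density). A window with `n_C` covered Cs and `k` edit
sites gets `p = P(X ≥ k)`, `X ~ Poisson(λ)`, `λ = max(p_bg(class)·n_C,
1e−6)`; the floor avoids zero-expectation degeneracy in uncovered
windows and the tail is evaluated with the survival function, never
`1 − CDF`. p-values are Benjamini–Hochberg adjusted across all windows
of the run; windows with q < 0.1 on the same strand are merged when
their gap is ≤ 15 nt (merging after thresholding; the alternative order
is undocumented in public descriptions), a merged cluster inherits the
minimum member p and q, and its interval is trimmed to the outermost
edit sites it contains, so clusters are tight around the evidence and
non-overlapping on a strand.

## Confident clusters

Replicate cluster sets are intersected with anchor semantics: the
clusters of the first (anchor) replicate that overlap, by at least 1 nt
on the same strand, at least one cluster in every other replicate — the
behaviour of successive `bedtools intersect -wa -u -s` calls, verified
against bedtools itself in the test suite. Which replicate anchors the
intersection changes the result slightly; the anchor is configurable and
logged. Buffer-only control clusters are then subtracted by removing
*whole* overlapping clusters (like `bedtools subtract -A`): downstream
statistics count clusters, and trimming would fabricate cluster
fragments. The output is therefore always a subset of the anchor set.

## Enrichment statistics

Motif occurrences are scanned on the sense strand of every gene (direct
match on + genes, reverse-complement match on − genes); occurrences
outside annotated genes are ignored. A cluster "contains" a motif when
the spans overlap by ≥ 1 nt on the same strand — interval-overlap
semantics consistent with the rest of the package (full containment is a
config switch).

The null model shuffles each cluster 20 times within its host feature:
the exon or intron containing the cluster midpoint (UTRs count as
exonic; adjacent exonic features are fused into one host span), drawing
a new start uniformly over the offsets at which the length-preserved
cluster still fits; clusters longer than their host are clamped to the
host span. Per permutation we record the motif-containing fraction,
giving 20 permuted values; then `Z = (observed − mean)/sd` with the
sample (n−1) standard deviation and fold enrichment
`observed / mean(permuted)`. Zero permutation spread yields a NaN Z
(logged); a zero permutation mean with a positive observation yields
infinite enrichment (logged). The same machinery serves reference-peak
overlap fractions.

Nearest-target distances are midpoint-to-midpoint in genomic nt, sign
flipped on − strands so positive means downstream in transcript
orientation; ties in |d| break upstream. Midpoint convention is our
choice; kernel-density rendering of the distance distributions is a
plotting concern and not part of the statistical artifact.

### Edit-radius estimator

The edit radius is the distance from a true binding site beyond which
directed editing is no longer elevated over control. We model the case
distance sample (|nearest-binding-site distance| of clustered case edit
sites) as the control distribution plus an excess of short distances;
beyond the radius the two samples, *conditioned on exceeding a threshold
d*, follow the same distribution. The estimator returns the smallest d
on [0, grid_max = 1000] from which onward the Kolmogorov–Smirnov
distance between the renormalised tail CDFs stays within
ε = 0.1 plus the two-sample KS sampling allowance
(1.63·√(1/n₁ + 1/n₂), the 99% quantile), with thresholds where either
tail holds fewer than 20 observations treated as converged (no case
signal left to compare). A naive "CDF difference ≤ ε beyond d" rule is
not usable here: when the case sample has excess short-distance mass the
raw CDF difference stays positive until the control CDF itself
approaches 1, so it estimates a high control quantile rather than the
radius. On default simulations with a planted 200 nt radius the
estimator returns ≈ 205–215 nt.

## Isoform-level editsC

Long reads are filtered to mapped, primary, non-supplementary alignments
with mean quality ≥ 20 on the isoform's annotated strand. Putative SNPs
are then removed: any edit position with at least one edited read in
*every* replicate of *every* sample — buffer-only replicates included —
is struck from all per-read edit lists, followed by positions in the
annotated SNP list. Including the buffer-only libraries in the
recurrence set matters: at realistic depth (≈ 20–25 reads/isoform) and
background (≈ 3% per C), genuine background edits appear in *some* read
of an enzyme-containing library at roughly coin-flip probability per
sample, so recurrence across enzyme-containing samples alone
over-removes genuine edits and, worse, removes control-side edits
preferentially at bound positions (where the case libraries are almost
always "present"), biasing the case-vs-control comparison. Buffer-only
libraries edit at the artifact rate (~5×10⁻⁴), so only variant-like
positions recur through them.

editsC for one isoform in one sample is Σ edited-C calls / Σ C calls
over its filtered reads, restricted by construction to C positions in
the isoform's exons and UTRs (read-call-weighted rather than
position-weighted; a 0/0 aggregate is reported as NaN rather than
dropped). Isoforms are kept when read count ≥ 20 in every replicate
("minimum over replicates"; a config switch allows the mean) and mean
case editsC ≥ 0.02 — the filter trims isoforms whose signal cannot be
distinguished from background. Confident isoforms are selected by
ordinary least squares of case mean editsC on control mean editsC (with
intercept) across isoforms, keeping isoforms with residual
> 1.5 sample standard deviations (one-sided: the goal is case-elevated
signal). A perfect case=control fit leaves residuals at machine epsilon;
an absolute floor of 1e−9 prevents rounding noise from being selected.
Under a pure null the selection rate is ≈ P(Z > 1.5) ≈ 6.7%.

## The synthetic generator

The generator emulates the *statistical* structure of a
directed-editing experiment, not its read-level mechanics:

* **Genome and genes.** Non-overlapping stranded toy genes (both
  strands, two chromosomes) with 5′UTR/exons/introns/3′UTR; uniform
  random sequence, so decoy motif occurrences arise at base-composition
  frequency. Optionally a second isoform per gene skipping one internal
  exon.
* **Binding sites.** Exactly `n_bound_motifs` motif instances (default
  UGCAUG, written as DNA on the gene's sense strand), at most one per
  gene, placed in introns for the cluster study (splicing-regulator-like
  binding) or exonic regions for the isoform study (mature-mRNA
  binding); both are config switches. Within `edit_radius` (200 nt,
  measured from a C to the nearest base of the motif) the per-read edit
  probability steps up to `p_bound`; the true distance decay of directed
  editing is unknown, and a step function is an explicit modelling
  choice, not a claim.
* **Short-read counts.** Per transcribed sense-C site: coverage ~
  Poisson(50), edited reads ~ Binomial(coverage, p_site) with p_site =
  `p_bound` (0.05) near bound motifs in the case condition, the
  enzyme-present background `p_bg_enzyme` (0.002) elsewhere and in
  enzyme-only controls, and the artifact rate `p_bg_buffer` (0.0005) in
  buffer-only controls. Three replicates per condition; per-table RNG
  streams derive deterministically from (seed, condition, replicate).
* **SNPs.** Planted sense-C positions edited at
  `ceil(coverage × 0.9)` reads in every condition and replicate — a
  deterministic, homozygous-variant-like fraction ≥ 0.9 that the > 80%
  filter must remove completely, making the filter's purpose testable.
* **Long reads.** Every read spans its whole isoform; per-C calls are
  Bernoulli with a per-isoform baseline rate, log-normal across isoforms
  (median 0.03, σ = 0.25) and shared across conditions and replicates —
  transcript-to-transcript variation in background deamination is what
  makes the case-on-control regression meaningful and replicate
  correlation high. Bound Cs edit at 0.25 in the case condition. The
  baseline level is chosen to sit above the 0.02 editsC filter so the
  filter trims a low-signal tail (as in real data) instead of truncating
  the null distribution, which would otherwise induce a selection-bias
  artifact in the regression. 24 reads per isoform (≈ 21–22 after the
  planted 2%-per-property filter violations: low quality, unmapped,
  secondary, supplementary, wrong strand), deterministic per isoform —
  depth-normalised libraries.

Not emulated: sequencing error beyond the buffer rate, PCR duplicates,
fragment-level short-read structure, alignment artifacts, repeat
regions, the deaminase's local sequence-context preference, and
expression-level variation in coverage. Passing tests therefore
demonstrate the *statistical machinery* (calibration, recovery,
specificity, determinism) under the stated generative model — not
robustness to the full messiness of real libraries.

## Study conditions and problem sizes

The default studies are desk-scale: the cluster study uses 100 genes
(~0.9 Mb of transcribed sequence, ~220k C sites per table, nine tables),
30 intronic binding sites, 50 SNPs; the null-FDR study uses ten
30-gene buffer-only universes; the isoform study uses 200 genes with
~250 isoforms, 20 exonic binding sites and four-plus-two long-read
libraries. These sizes were chosen so the statistics of interest (rates,
fractions, Z-scores) are well resolved while the whole acceptance run
finishes in well under a minute; all statistics are size-free.

## Numerical choices and degenerate inputs

Poisson tails via the survival function; beta tails via `betainc`;
BH adjustment via statsmodels with the textbook step-up oracle kept in
the tests. λ floor 1e−6. Empty edit-site sets produce empty cluster sets
(not errors); empty cluster sets make fractional statistics undefined
and raise. Ties at filter thresholds are resolved by the exclusive
comparisons stated above; the quality filter at exactly 20.0 retains the
read, the coverage filter at exactly 20 retains the isoform, and an
editsC of exactly 0.02 passes. All output tables are sorted and floats
formatted (`%.6g`) so repeated runs are byte-identical.

## Known limitations

* The confidence score is a principled stand-in, not a reimplementation
  of any published caller's score; absolute score values are not
  comparable across tools, only the ≥/< 0.5 decision is.
* Window construction (50/10) and merge-after-threshold order are
  design choices where public descriptions are silent; both are exposed
  in `ClusterModel`.
* The anchor dependence of replicate intersection is surfaced, not
  resolved.
* The edit-radius estimator assumes the case sample is
  control-plus-short-distance-excess; it is not meaningful if the
  control itself carries directed signal.
* With only enzyme-containing long-read libraries (no buffer-only), the
  recurrent-edit SNP heuristic over-removes genuine edits at realistic
  depths; see above.
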
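# Methods

## Regulatory domains and peak-to-gene assignment

Every gene is reduced to a single TSS point (0-based; all coordinates are
BED-style half-open). The *BasalPlusExtension* rule builds, per gene,

* a **basal window**: `[tss − 5000, tss + 1000)` on the + strand,
  `[tss − 1000, tss + 5000)` on the − strand, clipped to the chromosome;
* an **extended domain**: from `max(tss − 1 Mb, basal end of the nearest
  upstream gene)` to `min(tss + 1 Mb, basal start of the nearest downstream
  gene)`, clipped to the chromosome, then unioned with the gene's own basal
  window (so a neighbour whose basal overlaps it can never shrink the
  domain below the basal).

"Nearest" is by TSS coordinate; genes at identical TSS positions are
ordered by gene id, a deterministic tie-break chosen here because nothing
in the data decides it. The 5 kb / 1 kb / 1 Mb defaults are the tool's
conventional defaults and are exposed as parameters. Domains of adjacent
genes may overlap, so one peak can be assigned to several genes.

Two association rules coexist deliberately:

* **openness** (H3K4me3): a gene is open if ≥ 1 peak in ≥ 1 file overlaps
  `[tss − 1000, tss + 1001)` by ≥ 1 bp — evidence from a single file
  suffices;
* **load** (H3K27ac / TF): a peak counts only if `domain_start ≤ peak_start`
  and `peak_end ≤ domain_end` (containment, not overlap).

Peak files from sources that ship unfiltered peaks are filtered to
`fold_change ≥ 3` and `−log₁₀ q ≥ 3` (both inclusive). When one mark has
several files ("replicates"), a peak is kept iff peaks overlapping it by
≥ 1 bp occur in at least ⌈2n/3⌉ of the n replicates (its own counting), and
retained overlapping peaks are merged by interval union; the merged
consensus intervals carry no statistics. Identical-coordinate peaks in one
file remain distinct records and increment the enhancer load separately
(the analysis counts peaks, not positions).

## Loads, tie-extended bins, enrichment

TF load = number of *distinct* TFs with ≥ 1 assigned peak; enhancer load =
raw count of assigned H3K27ac peaks. Binning is performed **after**
restricting to open genes (so the decile population equals the
hypergeometric population); zero-load open genes form a separate bin, the
remaining genes are sorted by descending load and cut at ranks ⌈k·m/10⌉,
and each bin absorbs all genes tying with its last member. Bins emptied by
absorption are dropped. The zero bin is never the "top bin".

Enrichment of disease genes in a bin uses the inclusive upper tail
P(X ≥ k), X ~ Hypergeometric(N, K, n) — note the plain CDF is the lower
tail; the implementation takes `sf(k−1)`. Disease sets keep genes with
association score ≥ 0.08 (0.2 for the curated tier) and require ≥ 15 genes
per disease; the count threshold is applied *before* intersecting with the
background, a deliberate reading (the alternative is a flag) of how a
database-wide disease list meets a study-specific background. BH adjustment
is applied within each sample across its full disease × bin family by
default (`global` and `per-disease` families are options; nothing in the
method fixes the family, so it is explicit). Adjusted significances are
binarized at −log₁₀ p ≥ 1.301, i.e. the printed 3-decimal −log₁₀(0.05), so
a value of exactly 1.301 is significant. The evidence-type split is forced
disjoint with genetic-variation priority: a disease gene with *any*
genetic-variation association goes to that group, remaining disease genes
to "other evidence", the rest of the background to "non-disease" — the
three groups partition the background.

## Network, pathway and 3′UTR statistics

The disease network is the induced subgraph of the PPI over seed disease
genes present in the PPI plus their direct interactors; undirected,
unweighted, no self-loops. Betweenness is reported in the **ordered-pair**
convention, B(v) = Σ_{s≠v≠t} d(s,v,t)/d(s,t) over ordered (s, t) — twice
the textbook unordered value, with no normalization — because that is the
formula the analysis defines; a `normalized` flag gives the conventional
2/((N−1)(N−2)) scaling. Unreachable pairs contribute 0.

The resampling test draws, 10 000 times, |target| genes *without
replacement* from the sampling pool (the sample's open genes for the
pathway test; network ∩ open genes for betweenness) and reports the add-one
estimator p = (1 + #{null mean ≥ observed}) / (R + 1), which cannot be 0.
Pathway counts average only over genes present in ≥ 1 pathway.

3′UTR (and CDS/spliced/unspliced) lengths of high-load genes are compared
against the background with a one-sided two-sample KS test of "background
stochastically smaller": D⁺ = sup_x [F_bg(x) − F_test(x)], p =
exp(−2 D⁺² m n/(m+n)). Sign convention matters — under the alternative the
*test* sample is larger, so F_bg ≥ F_test pointwise. By default the test
genes remain part of the background sample (subset-inclusive; a flag
excludes them). Bonferroni across 139 sample comparisons gives the level
0.05/139 = 0.0003597122. miRNA sites listed at identical 3′UTR coordinates
under several family labels count once; overlapping but non-identical
sites are *not* merged.

## Synthetic data: what it emulates, and what not

The generator's defaults are the package's study conditions: 2 chromosomes
× 50 Mb, 2000 genes (≥ 10 kb TSS spacing), 4 samples in 2 cell types, 25
TFs, negative-binomial enhancer counts (mean 8, dispersion 2), TF events
Poisson with 0.5 expected TFs per enhancer peak (giving the observed
strong positive rank correlation between TF and enhancer load), 90 % open
genes, 50 diseases of 20–40 genes with a 4× sampling odds for
top-decile-load genes (odds 1 = exact null), score bands putting 90 % of
associations above 0.08 and 50 % above 0.2, 100 pathways and a 4000-edge
preferential-attachment PPI both skewed 3× toward high-load genes, and
lognormal 3′UTRs (log-mean 6.6, log-sd 1.0 ≈ 1200 nt mean) whose log-mean
shifts by log 1.39 for top-decile genes (≈ 39 % longer), with Poisson
miRNA sites at 2/kb and a 10 % chance of a second family label at the same
position. Enhancer rates are shared between samples of one cell type
(gamma-Poisson, so marginals stay negative-binomial) — loads correlate
within a cell type and not across, which is what makes the cross-sample
Jaccard and cell-type-specific analyses informative.

Two generator choices trade realism for a sharp ground truth:

* peaks are placed **inside the basal window** of their gene. With ≥ 10 kb
  TSS spacing adjacent basal windows are disjoint, and a basal-placed peak
  is contained in exactly one extended domain, so the pipeline recovers the
  intended per-gene counts exactly and `truth.json` is exact. Real
  enhancers spread across the whole domain and routinely sit in several
  overlapping domains; the assignment code handles that (and is tested
  against a brute-force oracle on random peaks), but the generated data do
  not exercise load leakage between neighbours.
* the planted disease excess targets the tie-extended top decile of open
  genes by the *first sample's* enhancer load, matching how a single
  reference sample would be analysed.

The generator does not emulate nucleotide sequence, reads, peak-caller
noise, genomic clustering of genes, or correlated disease sets. Passing
tests therefore demonstrate correctness of the statistical machinery and
end-to-end plumbing, not robustness to real-data artefacts such as
mappability gaps or batch effects.

## Numerical and degenerate-input choices

* Jaccard of two empty sets is defined as 1 (identical sets).
* The resampling p uses the add-one estimator; with constant values or
  target = pool it returns exactly 1.
* `−log₁₀ p_adj` floors p at 10⁻³⁰⁰ to avoid infinities.
* An empty open-gene set is an error for binning; a disease set disjoint
  from a bin is *not* an error (k = 0, p = 1).
* KS with an empty sample is an error; D⁺ is clipped at 0 when the
  empirical difference is everywhere negative.
* BH adjusted p-values are monotone in raw-p rank and ≥ raw, and the
  rejection set at any α equals the classic step-up decision; re-applying
  the adjustment to already-adjusted values is *not* an identity (no
  step-up adjustment has that property), which the test suite documents.

## Calibration results the suite computes

On the default conditions the suite measures (seeded, 20-replicate
sweeps): exact recovery of the planted top decile by the peak-level
pipeline (Jaccard 1.0); a realised type-I rate of the top-bin test of
≈ 0.02–0.03 at nominal 0.05 — below nominal because the hypergeometric
tail is discrete at top-bin sizes of ~180; BH-significant recovery of
planted diseases of ≈ 0.4 at odds 4 with 30-gene diseases (the top bin is
nevertheless the most significant bin for ≈ 93 % of planted diseases); and
for the KS arm, power ≈ 1.0 at the 0.05/139 level for the planted 39 %
3′UTR shift at 1500 genes per group, with a null rejection rate ≈ 0.03 at
α = 0.05. These numbers are recomputed, not quoted, by
`scripts/acceptance.py`.

## Problem sizes

Default analyses run at 2000 genes, 4 samples, ~16 000 enhancer peaks per
sample, 50 diseases, 100 pathways, 4000 PPI edges, 10 000 resampling
draws; calibration sweeps use 20 replicate seeds (enrichment) and 30/300
replicates (KS power/size). These sizes keep a full run of everything in
well under a minute each while leaving Monte-Carlo error small relative to
the effects studied.
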
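# enhload — regulatory load of genes and disease-gene enrichment

`enhload` scores every protein-coding gene by its *regulatory load* — the
number of distinct transcription factors (TF load) or active-enhancer
H3K27ac peaks (enhancer load) assigned to the gene's regulatory domain —
and asks whether the most heavily regulated genes are enriched for known
disease genes. It is written for regulatory genomicists who have per-sample
ChIP-Seq peak calls (H3K4me3, H3K27ac, per-TF) and a gene annotation, and
who want a tested, scriptable implementation of the whole analysis chain:

1. **Regulatory domains** (GREAT-style *BasalPlusExtension*): each gene gets
   a strand-aware basal window around its TSS (5 kb upstream / 1 kb
   downstream), extended up to 1 Mb but stopping at the neighbouring genes'
   basal windows. A peak belongs to a gene only if it falls *completely
   inside* the domain; a gene is *open* if any H3K4me3 peak overlaps
   TSS ± 1 kb by ≥ 1 bp.
2. **Loads and bins**: per-gene loads are binned into deciles of descending
   load, with a separate zero-load bin and *tie extension* — each decile
   absorbs every gene sharing the load of its last member, so no load value
   spans two bins (samples may end up with fewer than 10 bins).
3. **Enrichment**: for each sample, disease and bin, the inclusive
   hypergeometric upper tail P(X ≥ k) with population N = open genes,
   successes K = open disease genes, draws n = bin size and observed k =
   disease genes in the bin; Benjamini–Hochberg adjusted within each
   sample, binarized at −log₁₀ p = 1.301.
4. **Downstream**: cross-sample Jaccard similarity of top bins,
   cell-type-specific high-load genes, a 10 000-fold resampling test for
   mean pathway membership, ordered-pair betweenness centrality
   B(v) = Σ_{s≠v≠t} d(s,v,t)/d(s,t) in a one-step disease–PPI network, and
   one-sided Kolmogorov–Smirnov comparisons of 3′UTR/CDS/transcript lengths
   with deduplicated miRNA target-site counts.

A first-class synthetic-data module (`enhload.simulate`) generates every
input — genome, peak files, disease-association table, pathways, PPI,
transcript lengths, miRNA sites — with the statistical structure the
analysis assumes (correlated TF/enhancer loads, a planted disease-gene
excess in the top load decile, load-biased pathway/network membership,
longer 3′UTRs for high-load genes), plus a `truth.json` ground-truth
ledger, so the whole pipeline runs and is testable without any downloads.

## Worked example

```bash
python examples/02_disease_enrichment.py
```

prints (seed 4, 2000 genes, 50 diseases drawn with 4× odds from the
top-decile-load genes):

```
50 diseases with >=15 genes at score >= 0.08
strongest top-bin enrichments (N, K, n, k, adjusted -log10 p):
  D010: N=1802 K=31 n=193 k=14 -log10(p_adj)=3.33
  D001: N=1802 K=35 n=193 k=14 -log10(p_adj)=3.07
  D004: N=1802 K=18 n=193 k=10 -log10(p_adj)=3.07
  D050: N=1802 K=19 n=193 k=10 -log10(p_adj)=3.07
  D011: N=1802 K=22 n=193 k=10 -log10(p_adj)=2.54
15/50 diseases significant in the top bin (adjusted -log10 p >= 1.301, i.e. adjusted p <= 0.05);
mean adjusted -log10 p by bin rank (1 = highest load):
  1:1.16  2:0.03  3:0.00  4:0.00  5:0.00  6:0.00  7:0.00  8:0.00  9:0.02  10:0.00
```

Reading: of 1802 open genes, the tie-extended top decile holds n = 193;
disease D010 has K = 31 open genes of which k = 14 land in the top bin —
about nine times the expected count — giving an adjusted p of 10⁻³·³³. The
per-bin means show the enrichment is confined to the highest-load bin. The
other examples cover domains/loads (`01`), pathway occurrence and network
betweenness (`03` — high-load genes show ~4× the mean betweenness of random
gene sets) and 3′UTR/miRNA analysis (`04`).

The same stages are exposed as a thin CLI for shell pipelines:

```bash
enhload --seed 1 --out-dir sim simulate
enhload --out-dir out domains --genes sim/genes.tsv --chrom-sizes sim/chrom.sizes
enhload --out-dir out load --manifest sim/manifest.yaml \
        --genes sim/genes.tsv --chrom-sizes sim/chrom.sizes
enhload --out-dir out enrich --bins out/S01_enhancer_bins.tsv \
        --open-genes out/S01_open.txt --associations sim/associations.tsv
```

plus `jaccard`, `specific`, `pathways`, `network` and `utr` subcommands.

## Scope notes

The package takes peak calls, annotations, association tables, pathway and
PPI files as given — it does not download consortium data, call peaks or
super-enhancers, or lift over genome builds. Latent-block biclustering of
the enrichment matrix is out of scope (the binarized matrix it would
consume is produced). See `docs/methods.md` for the model, parameter
defaults and known limitations.
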
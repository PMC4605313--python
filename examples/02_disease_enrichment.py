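"""Hypergeometric disease-gene enrichment of the load bins.

Simulates a study in which disease genes are drawn with 4x odds from the
top-decile-load genes, then tests every (disease, bin) pair and shows that
the top bin carries the signal.
"""

from enhload import (
    SimConfig,
    bin_by_load,
    build_disease_sets,
    enrich_matrix,
    simulate_all,
)
from enhload.core import LoadTable

sim = simulate_all(SimConfig(seed=4, n_samples=1))
sample = sim.samples["S01"]

table = LoadTable(loads=dict(sample.enhancer_counts), load_kind="enhancer",
                  open_genes=sample.open_genes)
partition = bin_by_load(table)
open_set = set(sample.open_genes)

disease_sets = build_disease_sets(sim.associations, open_set,
                                  min_score=0.08, min_genes=15)
print(f"{len(disease_sets)} diseases with >=15 genes at score >= 0.08")

matrix = enrich_matrix({"S01": partition}, disease_sets, {"S01": open_set})
frame = matrix.to_frame()
top = frame[frame["bin_rank"] == 1].sort_values("neg_log10_p_adj", ascending=False)
print("strongest top-bin enrichments (N, K, n, k, adjusted -log10 p):")
for row in top.head(5).itertuples():
    print(f"  {row.disease_id}: N={row.N} K={row.K} n={row.n} k={row.k} "
          f"-log10(p_adj)={row.neg_log10_p_adj:.2f}")

n_sig = (top["neg_log10_p_adj"] >= 1.301).sum()
print(f"{n_sig}/{len(top)} diseases significant in the top bin "
      "(adjusted -log10 p >= 1.301, i.e. adjusted p <= 0.05);")
mean_by_bin = frame[frame.bin_rank > 0].groupby("bin_rank")["neg_log10_p_adj"].mean()
print("mean adjusted -log10 p by bin rank (1 = highest load):")
print("  " + "  ".join(f"{r}:{v:.2f}" for r, v in mean_by_bin.items()))
print("the enrichment is concentrated in bin 1, as expected when disease "
      "association tracks regulatory load")
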
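"""3'UTR lengths and miRNA target sites of high-load vs background genes.

Compares the 3'UTR length distribution of high-enhancer-load genes against
the full background with the one-sided KS test (background stochastically
smaller under the alternative) and counts deduplicated miRNA sites.
"""

import numpy as np

from enhload import (
    SimConfig,
    bonferroni_threshold,
    compare_lengths,
    count_mirna_sites,
    simulate_all,
    site_family_correlation,
)
from enhload.simulate import top_decile_by_load

sim = simulate_all(SimConfig(seed=4, n_samples=1))
sample = sim.samples["S01"]
hrl = set(top_decile_by_load(sample.enhancer_counts, set(sample.open_genes)))

d_plus, p, bg_mean, hrl_mean = compare_lengths(sim.transcripts, hrl)
level = bonferroni_threshold(0.05, 139)
verdict = "significant" if p <= level else "not significant"
print(f"3'UTR length: background mean {bg_mean:.0f} nt, high-load mean "
      f"{hrl_mean:.0f} nt ({100 * (hrl_mean / bg_mean - 1):.0f}% longer)")
print(f"one-sided KS: D+ = {d_plus:.3f}, p = {p:.3g} -> {verdict} "
      f"at the Bonferroni level 0.05/139 = {level:.10f}")

site_counts = count_mirna_sites(sim.mirna_sites)
hrl_sites = np.mean([site_counts.get(g, 0) for g in hrl])
bg_sites = np.mean([site_counts.get(g, 0) for g in sim.transcripts])
print(f"deduplicated miRNA sites per 3'UTR: high-load {hrl_sites:.2f} vs "
      f"background {bg_sites:.2f}")
rho = site_family_correlation(sim.mirna_sites)
print(f"site count vs distinct miRNA families: Spearman rho = {rho:.2f}")
print("longer 3'UTRs of high-load genes carry proportionally more miRNA "
      "sites, i.e. heavier post-transcriptional regulation")
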
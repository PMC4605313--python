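"""High-level orchestration: manifest -> loads -> bins for each sample.

Glue used by both the CLI and the examples; each step simply delegates to
the dedicated module.  Processing of one sample:

1. read the peak files; for 'filtered' sources apply the fold-change /
   q-value >= 3 filter to every file;
2. if a mark or TF has several files ("replicates"), keep the two-thirds
   replicate consensus;
3. call open genes from the H3K4me3 files (TSS +/- 1 kb overlap);
4. assign H3K27ac and per-TF peaks to regulatory domains by containment and
   derive enhancer / TF loads;
5. bin open genes by load with tie extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

from . import io as eio
from .core import (
    BinPartition,
    ChromSizes,
    GeneRecord,
    LoadTable,
    PeakSet,
    RegulatoryDomain,
    SampleManifest,
)
from .domains import assign_peaks, consensus_replicates, filter_peaks, open_genes
from .load import bin_by_load, enhancer_load, tf_load


def _read_mark(paths: Sequence[str], source: str) -> List[PeakSet]:
    dialect = "peak_with_stats" if source == "filtered" else "bed3"
    peaksets = [eio.read_bed(p, dialect=dialect) for p in paths]
    if source == "filtered":
        peaksets = [filter_peaks(ps) for ps in peaksets]
    return peaksets


def _consolidate(peaksets: List[PeakSet]) -> PeakSet:
    if len(peaksets) == 1:
        return peaksets[0]
    return consensus_replicates(peaksets)


@dataclass
class SampleResult:
    sample_id: str
    open_genes: Set[str]
    enhancer: Optional[LoadTable]
    tf: Optional[LoadTable]
    enhancer_bins: Optional[BinPartition]
    tf_bins: Optional[BinPartition]


def process_sample(
    manifest: SampleManifest,
    genes: Sequence[GeneRecord],
    domains: Sequence[RegulatoryDomain],
    n_quantile_bins: int = 10,
) -> SampleResult:
    """Run one sample from peak files to tie-extended load bins."""
    k4_sets = _read_mark(manifest.h3k4me3, manifest.source)
    # evidence from a single H3K4me3 file is sufficient: no consensus here
    open_set = open_genes(genes, k4_sets)

    enh_table = enh_bins = None
    if manifest.h3k27ac:
        peaks = _consolidate(_read_mark(manifest.h3k27ac, manifest.source))
        assignment = assign_peaks(domains, peaks)
        enh_table = enhancer_load(assignment, open_set, sample_id=manifest.sample_id)
        if open_set:
            enh_bins = bin_by_load(enh_table, n_quantile_bins=n_quantile_bins)

    tf_table = tf_bins = None
    if manifest.tf_peaks:
        tables = {}
        for tf_name in sorted(manifest.tf_peaks):
            peaks = _consolidate(_read_mark(manifest.tf_peaks[tf_name], manifest.source))
            tables[tf_name] = assign_peaks(domains, peaks)
        tf_table = tf_load(tables, open_set, sample_id=manifest.sample_id)
        if open_set:
            tf_bins = bin_by_load(tf_table, n_quantile_bins=n_quantile_bins)

    return SampleResult(
        sample_id=manifest.sample_id,
        open_genes=open_set,
        enhancer=enh_table,
        tf=tf_table,
        enhancer_bins=enh_bins,
        tf_bins=tf_bins,
    )
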
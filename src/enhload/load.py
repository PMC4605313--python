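"""Per-gene regulatory load, tie-extended decile binning, cross-sample sets.

The *regulatory load* of a gene is either the number of distinct TFs with at
least one peak assigned to the gene's regulatory domain (TF load) or the raw
count of H3K27ac peaks assigned to it (enhancer load).  Open genes are binned
into deciles of descending load with a separate zero-load bin; each decile is
extended downward to absorb every gene tying with its last member, so no load
value spans two bins ("tie extension") and samples can end up with fewer than
ten nonzero bins.
"""

from __future__ import annotations

import math
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .core import AssignmentTable, BinPartition, LoadBin, LoadTable


def tf_load(
    assignment_tables: Union[Mapping[str, AssignmentTable], Iterable[Tuple[str, AssignmentTable]]],
    open_gene_set: Set[str],
    sample_id: str = "",
) -> LoadTable:
    """TF load: number of distinct TFs with >= 1 assigned peak per gene.

    Multiple peaks of one TF count once.  Closed genes keep their load value
    but are flagged via the table's open-gene set.
    """
    if isinstance(assignment_tables, Mapping):
        pairs = list(assignment_tables.items())
    else:
        pairs = list(assignment_tables)
    names = [name for name, _ in pairs]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate TF names across assignment tables: {dup}")

    loads: Dict[str, int] = {}
    for _, table in pairs:
        for gene, hits in table.assignments.items():
            loads.setdefault(gene, 0)
            if hits:
                loads[gene] += 1
    return LoadTable(loads=loads, load_kind="tf",
                     open_genes=frozenset(open_gene_set), sample_id=sample_id)


def enhancer_load(
    h3k27ac_assignment: AssignmentTable,
    open_gene_set: Set[str],
    sample_id: str = "",
) -> LoadTable:
    """Enhancer load: raw count of assigned H3K27ac peaks (records, not positions)."""
    loads = {gene: len(hits) for gene, hits in h3k27ac_assignment.assignments.items()}
    return LoadTable(loads=loads, load_kind="enhancer",
                     open_genes=frozenset(open_gene_set), sample_id=sample_id)


def bin_by_load(
    load_table: LoadTable,
    open_gene_set: Union[Set[str], None] = None,
    n_quantile_bins: int = 10,
) -> BinPartition:
    """Bin open genes by descending load into tie-extended quantile bins.

    Zero-load open genes form the separate zero bin.  Decile boundaries are
    placed at ranks ceil(k*m/10) over the m nonzero-load genes; each bin is
    extended downward to absorb all genes tying with its last member, and the
    next bin starts after the absorbed ties.  Bins emptied by absorption are
    dropped, so the partition can have fewer than ``n_quantile_bins`` bins.
    """
    population = set(open_gene_set if open_gene_set is not None else load_table.open_genes)
    population &= set(load_table.loads)
    if not population:
        raise ValueError("empty open-gene population; nothing to bin")

    zero = frozenset(g for g in population if load_table.loads[g] == 0)
    nonzero = sorted(
        (g for g in population if load_table.loads[g] > 0),
        key=lambda g: (-load_table.loads[g], g),
    )
    m = len(nonzero)
    values = [load_table.loads[g] for g in nonzero]

    bins: List[LoadBin] = []
    s = 0
    for k in range(1, n_quantile_bins + 1):
        e = math.ceil(k * m / n_quantile_bins)
        if e <= s:
            continue  # bin emptied by tie absorption
        while e < m and values[e] == values[e - 1]:
            e += 1
        bins.append(
            LoadBin(
                bin_rank=len(bins) + 1,
                load_min=values[e - 1],
                load_max=values[s],
                genes=frozenset(nonzero[s:e]),
            )
        )
        s = e
        if s >= m:
            break
    return BinPartition(bins=bins, zero_bin=zero, population=frozenset(population))


def top_bin(partition: BinPartition) -> FrozenSet[str]:
    """The highest-load bin (never the zero bin)."""
    if not partition.bins:
        raise ValueError("partition has no nonzero-load bins")
    return partition.bins[0].genes


def jaccard(a: Set[str], b: Set[str]) -> float:
    """Jaccard index |A&B|/|A|B|; J(empty, empty) is defined as 1."""
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


def jaccard_matrix(top_bins: Mapping[str, Set[str]]) -> pd.DataFrame:
    """Symmetric sample-by-sample Jaccard similarity of top-bin gene sets."""
    ids = list(top_bins)
    mat = np.ones((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            mat[i, j] = mat[j, i] = jaccard(set(top_bins[a]), set(top_bins[ids[j]]))
    return pd.DataFrame(mat, index=ids, columns=ids)


def cell_type_specific(
    top_bins: Mapping[str, Set[str]],
    target_sample_ids: Iterable[str],
) -> Set[str]:
    """Genes in the union of target-sample top bins but in no other sample's top bin."""
    targets = set(target_sample_ids)
    missing = targets - set(top_bins)
    if missing:
        raise ValueError(f"unknown target samples: {sorted(missing)}")
    target_union: Set[str] = set()
    other_union: Set[str] = set()
    for sample, genes in top_bins.items():
        if sample in targets:
            target_union |= set(genes)
        else:
            other_union |= set(genes)
    return target_union - other_union


def expression_overlap(
    expression: Mapping[str, float],
    hrl_set: Set[str],
    total_gene_count: int,
) -> Dict[str, float]:
    """Cumulative fraction of high-load genes among the top-expressed genes.

    Genes are ranked by descending expression; the four top-expression sets
    contain |HRL|, 3*|HRL|, 0.5*total and 0.9*total genes (the first two
    relative to the high-regulatory-load set, the last two to the total gene
    count).  Each fraction is |HRL & top set| / |HRL|.
    """
    if not hrl_set:
        raise ValueError("empty high-regulatory-load set")
    if len(hrl_set) > len(expression):
        raise ValueError(
            f"|HRL| = {len(hrl_set)} exceeds number of expressed genes {len(expression)}"
        )
    ranked = sorted(expression, key=lambda g: (-expression[g], g))
    sizes = {
        "top_hrl_matched": len(hrl_set),
        "top_3x_hrl": min(3 * len(hrl_set), len(ranked)),
        "top_50pct": min(math.ceil(0.5 * total_gene_count), len(ranked)),
        "top_90pct": min(math.ceil(0.9 * total_gene_count), len(ranked)),
    }
    out = {}
    for label, size in sizes.items():
        top = set(ranked[:size])
        out[label] = len(hrl_set & top) / len(hrl_set)
    return out
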
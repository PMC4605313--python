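"""Disease gene sets and hypergeometric enrichment of load bins.

For each sample, each disease and each load bin, the enrichment of disease
genes in the bin is tested with the inclusive upper tail of the
hypergeometric distribution:

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

with N the number of open (H3K4me3-marked) genes, K the number of open
disease genes, n the bin size and k the number of disease genes in the bin.
Note that the plain hypergeometric CDF is the *lower* tail; enrichment needs
P(X >= k) = 1 - CDF(k - 1), which is what this module computes.  Raw p-values
are Benjamini-Hochberg adjusted, by default within each sample across its
full disease x bin family.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AssociationRecord, BinPartition, DiseaseGeneSet, EnrichmentCell

#: -log10(0.05) at the conventional printed precision (3 decimals); adjusted
#: significances at or above this are called significant, so an adjusted
#: -log10 p of exactly 1.301 binarizes to 1
BINARIZATION_THRESHOLD = round(-math.log10(0.05), 3)

GENETIC_VARIATION = "genetic variation"


def build_disease_sets(
    associations: Sequence[AssociationRecord],
    background_gene_set: Set[str],
    min_score: float = 0.08,
    min_genes: int = 15,
    evidence_filter: Optional[Set[str]] = None,
    min_genes_after_background: bool = False,
) -> List[DiseaseGeneSet]:
    """Build per-disease gene sets from scored associations.

    Per disease, genes with score >= ``min_score`` (and, if given, at least
    one evidence type in ``evidence_filter``) are collected.  By default the
    ``min_genes`` threshold is applied to this count *before* intersecting
    with the background set, and the intersected set is returned; pass
    ``min_genes_after_background=True`` for the post-intersection variant.
    """
    if not background_gene_set:
        raise ValueError("empty background gene set")
    per_disease: Dict[str, Set[str]] = defaultdict(set)
    for rec in associations:
        if rec.score < min_score:
            continue
        if evidence_filter is not None and not (rec.evidence_types & set(evidence_filter)):
            continue
        per_disease[rec.disease_id].add(rec.gene_id)

    out: List[DiseaseGeneSet] = []
    for disease_id in sorted(per_disease):
        genes = per_disease[disease_id]
        in_bg = genes & background_gene_set
        counted = in_bg if min_genes_after_background else genes
        if len(counted) < min_genes:
            continue
        out.append(
            DiseaseGeneSet(
                disease_id=disease_id,
                genes=frozenset(in_bg),
                min_score=min_score,
                evidence_filter=frozenset(evidence_filter) if evidence_filter else None,
            )
        )
    return out


def partition_by_evidence(
    associations: Sequence[AssociationRecord],
    background: Set[str],
    min_score: float = 0.08,
) -> Dict[str, FrozenSet[str]]:
    """Disjoint split of the background into three evidence groups.

    A disease gene (any qualifying association) goes to ``genetic_variation``
    if *any* of its qualifying associations carries that evidence type,
    otherwise to ``other_evidence``; all remaining background genes form
    ``non_disease``.  The three sets partition the background.
    """
    has_gv: Set[str] = set()
    has_any: Set[str] = set()
    for rec in associations:
        if rec.score < min_score or rec.gene_id not in background:
            continue
        has_any.add(rec.gene_id)
        if GENETIC_VARIATION in rec.evidence_types:
            has_gv.add(rec.gene_id)
    return {
        "genetic_variation": frozenset(has_gv),
        "other_evidence": frozenset(has_any - has_gv),
        "non_disease": frozenset(background - has_any),
    }


def hypergeom_upper_tail(N: int, K: int, n: int, k) -> Union[float, np.ndarray]:
    """Inclusive upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` may be a scalar or an array.  Returns 1.0 for k = 0 and raises for
    k > min(K, n).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent parameters N={N}, K={K}, n={n}")
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr > min(K, n)):
        raise ValueError(f"k outside [0, min(K, n)] for N={N}, K={K}, n={n}")
    p = stats.hypergeom.sf(k_arr - 1, N, K, n)
    p = np.minimum(p, 1.0)
    if np.isscalar(k) or k_arr.ndim == 0:
        return float(p)
    return p


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentMatrix:
    """All enrichment cells plus convenience accessors."""

    cells: List[EnrichmentCell] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [c.sample_id for c in self.cells],
                "disease_id": [c.disease_id for c in self.cells],
                "bin_rank": [c.bin_rank for c in self.cells],
                "N": [c.N for c in self.cells],
                "K": [c.K for c in self.cells],
                "n": [c.n for c in self.cells],
                "k": [c.k for c in self.cells],
                "p_raw": [c.p_raw for c in self.cells],
                "p_adj": [c.p_adj for c in self.cells],
                "neg_log10_p_adj": [c.neg_log10_p_adj for c in self.cells],
            }
        )

    def wide(self, bin_rank: int = 1) -> pd.DataFrame:
        """Disease x sample matrix of adjusted -log10 p for one bin rank."""
        df = self.to_frame()
        df = df[df["bin_rank"] == bin_rank]
        return df.pivot(index="disease_id", columns="sample_id", values="neg_log10_p_adj")


def enrich_matrix(
    bin_partitions: Mapping[str, BinPartition],
    disease_sets: Sequence[DiseaseGeneSet],
    open_gene_sets: Mapping[str, Set[str]],
    bh_family: str = "sample",
) -> EnrichmentMatrix:
    """Hypergeometric enrichment of every (sample, disease, bin) triple.

    ``bh_family`` controls the Benjamini-Hochberg family: ``sample`` (default;
    all disease x bin tests of one sample), ``global`` (everything at once) or
    ``per-disease`` (each sample x disease across its bins).  The zero-load
    bin is tested too, reported with bin_rank 0.  A disease set disjoint from
    a bin yields k = 0 and p = 1 (not an error).
    """
    if bh_family not in ("sample", "global", "per-disease"):
        raise ValueError(f"unknown bh_family {bh_family!r}")

    raw: List[Tuple[str, str, int, int, int, int, int, float]] = []
    for sample_id, partition in bin_partitions.items():
        population = set(open_gene_sets[sample_id]) & set(partition.population)
        N = len(population)
        bins = [(b.bin_rank, set(b.genes)) for b in partition.bins]
        if partition.zero_bin:
            bins.append((0, set(partition.zero_bin)))
        for ds in disease_sets:
            K = len(set(ds.genes) & population)
            for rank, genes in bins:
                n = len(genes)
                k = len(set(ds.genes) & genes)
                p = hypergeom_upper_tail(N, K, n, k)
                raw.append((sample_id, ds.disease_id, rank, N, K, n, k, float(p)))

    if bh_family == "global":
        groups = {"all": list(range(len(raw)))}
    elif bh_family == "sample":
        groups = defaultdict(list)
        for i, row in enumerate(raw):
            groups[row[0]].append(i)
    else:
        groups = defaultdict(list)
        for i, row in enumerate(raw):
            groups[(row[0], row[1])].append(i)

    p_adj = np.empty(len(raw))
    for idx in groups.values():
        p_adj[idx] = bh_adjust([raw[i][7] for i in idx])

    cells = [
        EnrichmentCell(
            sample_id=s, disease_id=d, bin_rank=r, N=N, K=K, n=n, k=k,
            p_raw=p, p_adj=float(pa), neg_log10_p_adj=float(-np.log10(max(pa, 1e-300))),
        )
        for (s, d, r, N, K, n, k, p), pa in zip(raw, p_adj)
    ]
    return EnrichmentMatrix(cells=cells)


def binarize(
    matrix: pd.DataFrame,
    threshold: float = BINARIZATION_THRESHOLD,
) -> Tuple[pd.DataFrame, List[str], List[str]]:
    """Binarize an adjusted -log10 p matrix at the significance threshold.

    A cell becomes 1 iff its value is >= ``threshold`` (the threshold itself
    is significant).  All-zero rows and columns are dropped; their labels are
    returned alongside the binary matrix.
    """
    binary = (matrix >= threshold).astype(int)
    dropped_rows = [str(i) for i in binary.index[(binary == 0).all(axis=1)]]
    dropped_cols = [str(c) for c in binary.columns[(binary == 0).all(axis=0)]]
    binary = binary.drop(index=dropped_rows, columns=dropped_cols)
    return binary, dropped_rows, dropped_cols
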
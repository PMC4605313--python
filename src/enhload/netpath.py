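"""Disease gene networks, betweenness centrality and resampling tests.

The disease network is the induced subgraph of a protein-protein interaction
(PPI) graph over the disease seed genes plus their one-step neighbours;
undirected and unweighted.  Betweenness follows the ordered-pair convention

    B(v) = sum over ordered pairs (s, t), s != v != t, of
           (# shortest s-t paths through v) / (# shortest s-t paths)

without normalization, so each unordered pair contributes twice.  The
resampling test compares the mean of a per-gene statistic (e.g. pathway
membership count, betweenness) over a target gene set against means of
equally sized random draws from a sampling pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple, Union

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class DiseaseNetwork:
    """Seed disease genes + one-step PPI neighbours with their interactions."""

    graph: nx.Graph
    seeds: Set[str]

    @property
    def neighbors(self) -> Set[str]:
        return set(self.graph.nodes) - self.seeds


def build_disease_network(
    seed_genes: Iterable[str],
    ppi_edges: Iterable[Tuple[str, str]],
) -> DiseaseNetwork:
    """Induced subgraph over seed genes present in the PPI and their direct
    interactors.  Self-loops are dropped and duplicate edges collapsed.
    """
    ppi = nx.Graph()
    for a, b in ppi_edges:
        if a != b:
            ppi.add_edge(a, b)
    seeds = set(seed_genes)
    seeds_in = seeds & set(ppi.nodes)
    if not seeds_in:
        raise ValueError("no seed gene is present in the PPI")
    missing = seeds - seeds_in
    if missing:
        logger.warning("%d seed genes absent from the PPI were excluded", len(missing))
    nodes = set(seeds_in)
    for s in seeds_in:
        nodes.update(ppi.neighbors(s))
    sub = ppi.subgraph(nodes).copy()
    nx.set_node_attributes(
        sub, {v: ("seed_disease_gene" if v in seeds_in else "neighbor") for v in sub.nodes},
        name="origin",
    )
    return DiseaseNetwork(graph=sub, seeds=seeds_in)


def betweenness(
    network: Union[DiseaseNetwork, nx.Graph],
    normalized: bool = False,
) -> Dict[str, float]:
    """Ordered-pair betweenness B(v) of every node.

    For an undirected graph the raw ordered-pair sum is twice the
    conventional unordered value; ``normalized=True`` instead applies the
    usual 2/((N-1)(N-2)) scaling.
    """
    graph = network.graph if isinstance(network, DiseaseNetwork) else network
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if normalized:
        return dict(nx.betweenness_centrality(graph, normalized=True))
    bc = nx.betweenness_centrality(graph, normalized=False)
    factor = 2.0 if not graph.is_directed() else 1.0
    return {v: factor * b for v, b in bc.items()}


@dataclass
class ResampleResult:
    observed_mean: float
    null_means: np.ndarray
    p: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_means))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_means, ddof=1))


def resample_mean_stat(
    per_gene_values: Mapping[str, float],
    target_set: Set[str],
    sampling_pool: Iterable[str],
    n_resamples: int = 10_000,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> ResampleResult:
    """Resampling null for the mean of a per-gene statistic.

    The observed mean is taken over target genes with a value; each of the
    ``n_resamples`` draws takes the same number of genes *without
    replacement* from the pool (restricted to genes with a value).  The
    p-value uses the add-one estimator (1 + #{null mean >= observed}) /
    (n_resamples + 1), so it is never exactly zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = sorted(set(sampling_pool) & set(per_gene_values))
    target = set(target_set) & set(per_gene_values)
    if not target:
        raise ValueError("target set has no genes with a value")
    if not set(target_set) <= set(sampling_pool):
        raise ValueError("target set must be a subset of the sampling pool")
    if len(target) > len(pool):
        raise ValueError("target larger than the sampling pool")

    values = np.array([per_gene_values[g] for g in pool], dtype=float)
    observed = float(np.mean([per_gene_values[g] for g in target]))
    size = len(target)
    null_means = np.empty(n_resamples)
    for i in range(n_resamples):
        idx = rng.choice(len(pool), size=size, replace=False)
        null_means[i] = values[idx].mean()
    b = int(np.sum(null_means >= observed))
    p = (1 + b) / (n_resamples + 1)
    return ResampleResult(observed_mean=observed, null_means=null_means, p=p)


def pathway_counts(
    gmt: Mapping[str, Set[str]],
    gene_set: Iterable[str],
) -> Tuple[Dict[str, int], float]:
    """Pathway membership counts per gene, and their mean over the gene set.

    The count of a gene is the number of pathways containing it; the mean is
    taken over gene_set intersected with the pathway universe (the union of
    all pathway genes), i.e. genes in no pathway do not enter the
    denominator.
    """
    universe: Dict[str, int] = {}
    for genes in gmt.values():
        for g in genes:
            universe[g] = universe.get(g, 0) + 1
    selected = {g: universe[g] for g in gene_set if g in universe}
    if not selected:
        raise ValueError("gene set is disjoint from the pathway universe")
    return selected, float(np.mean(list(selected.values())))
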
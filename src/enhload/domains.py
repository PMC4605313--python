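"""Regulatory domains, peak filtering and peak-to-gene assignment.

The central object is the GREAT-style *BasalPlusExtension* regulatory domain:
each gene gets a strand-aware basal window around its TSS (5 kb upstream /
1 kb downstream by default) which is then extended in both directions up to a
maximum distance (1 Mb), stopping at the nearest neighbouring gene's *basal*
domain.  The gene's own basal window is always part of the domain, so a
neighbour whose basal overlaps it never shrinks the domain below the basal.

Two different association rules are used downstream, mirroring the way the
consortium data were processed:

* openness (H3K4me3): a gene is "open" if any peak *overlaps* TSS +/- 1 kb by
  at least 1 bp;
* load (TF / H3K27ac): a peak counts for a gene only if it falls *completely
  within* the gene's regulatory domain.

The asymmetry (overlap vs containment) is intentional.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from .core import (
    AssignmentTable,
    ChromSizes,
    GeneRecord,
    GenomicInterval,
    PeakSet,
    RegulatoryDomain,
)

logger = logging.getLogger(__name__)

BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000


def basal_domain(gene: GeneRecord, chrom_length: int,
                 basal_up: int = BASAL_UPSTREAM,
                 basal_down: int = BASAL_DOWNSTREAM) -> Tuple[int, int]:
    """Strand-aware basal window around the TSS, clipped to the chromosome."""
    if gene.strand == "+":
        start, end = gene.tss - basal_up, gene.tss + basal_down
    else:
        start, end = gene.tss - basal_down, gene.tss + basal_up
    return max(0, start), min(chrom_length, end)


def create_regulatory_domains(
    genes: Sequence[GeneRecord],
    chrom_sizes: ChromSizes,
    basal_up: int = BASAL_UPSTREAM,
    basal_down: int = BASAL_DOWNSTREAM,
    max_ext: int = MAX_EXTENSION,
) -> List[RegulatoryDomain]:
    """Construct BasalPlusExtension regulatory domains for all genes.

    The extension of a gene reaches up to ``max_ext`` from the TSS but stops
    at the nearest upstream neighbour's basal end and the nearest downstream
    neighbour's basal start ("upstream"/"downstream" here in chromosome
    coordinates, i.e. by TSS order; ties of identical TSS are broken by
    gene_id).  The own basal window is unioned in afterwards.  Domains of
    adjacent genes may overlap.
    """
    by_chrom: Dict[str, List[GeneRecord]] = defaultdict(list)
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        if not (0 <= g.tss < chrom_sizes[g.chrom]):
            raise ValueError(
                f"gene {g.gene_id}: TSS {g.tss} outside chromosome {g.chrom} "
                f"of length {chrom_sizes[g.chrom]}"
            )
        by_chrom[g.chrom].append(g)

    out: Dict[str, RegulatoryDomain] = {}
    for chrom, chrom_genes in by_chrom.items():
        length = chrom_sizes[chrom]
        ordered = sorted(chrom_genes, key=lambda g: (g.tss, g.gene_id))
        basals = [basal_domain(g, length, basal_up, basal_down) for g in ordered]
        for i, g in enumerate(ordered):
            bs, be = basals[i]
            ext_start = max(g.tss - max_ext, 0)
            if i > 0:
                ext_start = max(ext_start, basals[i - 1][1])
            ext_end = min(g.tss + max_ext, length)
            if i + 1 < len(ordered):
                ext_end = min(ext_end, basals[i + 1][0])
            # the own basal always belongs to the domain
            ds, de = min(ext_start, bs), max(ext_end, be)
            out[g.gene_id] = RegulatoryDomain(g.gene_id, chrom, bs, be, ds, de)
    # preserve input order
    return [out[g.gene_id] for g in genes]


def filter_peaks(
    peaks: Iterable[GenomicInterval],
    min_fold_change: float = 3.0,
    min_neg_log10_q: float = 3.0,
) -> PeakSet:
    """Keep peaks with fold change AND -log10(q) at or above the thresholds."""
    kept: PeakSet = []
    for p in peaks:
        if p.fold_change is None or p.neg_log10_q is None:
            raise ValueError(
                f"peak {p.chrom}:{p.start}-{p.end} lacks fold_change/neg_log10_q; "
                "cannot apply the statistics filter"
            )
        if p.fold_change >= min_fold_change and p.neg_log10_q >= min_neg_log10_q:
            kept.append(p)
    return kept


def _merge_intervals(ivals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def consensus_replicates(replicate_peaksets: Sequence[PeakSet]) -> PeakSet:
    """Two-thirds replicate consensus.

    A peak from any replicate is retained iff at least ceil(2n/3) of the n
    replicates (its own included) contain a peak overlapping it by >= 1 bp.
    Retained peaks that overlap each other are merged by interval union.
    Peak statistics are not propagated onto merged consensus intervals.
    """
    n = len(replicate_peaksets)
    if n == 0:
        raise ValueError("empty replicate list")
    support_needed = math.ceil(2 * n / 3)

    merged_by_rep: List[Dict[str, List[Tuple[int, int]]]] = []
    for rep in replicate_peaksets:
        per_chrom: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
        for p in rep:
            per_chrom[p.chrom].append((p.start, p.end))
        merged_by_rep.append({c: _merge_intervals(v) for c, v in per_chrom.items()})

    retained: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for rep in replicate_peaksets:
        for p in rep:
            support = 0
            for other in merged_by_rep:
                ivals = other.get(p.chrom, [])
                if not ivals:
                    continue
                starts = np.array([s for s, _ in ivals])
                ends = np.array([e for _, e in ivals])
                j = int(np.searchsorted(starts, p.end, side="left"))
                if j > 0 and np.any(ends[:j] > p.start):
                    support += 1
            if support >= support_needed:
                retained[p.chrom].append((p.start, p.end))

    out: PeakSet = []
    for chrom in sorted(retained):
        for s, e in _merge_intervals(retained[chrom]):
            out.append(GenomicInterval(chrom, s, e))
    return out


def open_genes(
    genes: Sequence[GeneRecord],
    h3k4me3_peaksets: Sequence[PeakSet],
    window: int = 1_000,
) -> Set[str]:
    """Genes with >= 1 bp overlap between any H3K4me3 peak (any file) and
    the window [tss - window, tss + window + 1).

    Evidence from a single file is sufficient.
    """
    merged: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for peakset in h3k4me3_peaksets:
        for p in peakset:
            merged[p.chrom].append((p.start, p.end))
    merged = {c: _merge_intervals(v) for c, v in merged.items()}

    open_set: Set[str] = set()
    for g in genes:
        ivals = merged.get(g.chrom)
        if not ivals:
            continue
        ws, we = max(0, g.tss - window), g.tss + window + 1
        starts = [s for s, _ in ivals]
        j = int(np.searchsorted(np.array(starts), we, side="left"))
        if j > 0 and any(e > ws for _, e in ivals[:j]):
            open_set.add(g.gene_id)
    return open_set


def assign_peaks(
    domains: Sequence[RegulatoryDomain],
    peaks: Sequence[GenomicInterval],
) -> AssignmentTable:
    """Assign each peak to every gene whose regulatory domain fully contains it.

    Containment, not overlap: domain_start <= peak.start and
    peak.end <= domain_end.  A peak straddling a domain boundary is not
    assigned; peaks contained in several (overlapping) domains are assigned to
    all of them.  The number of peaks assigned to no gene is reported.
    """
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, p in enumerate(peaks):
        trees[p.chrom].addi(p.start, p.end, idx)

    assignments: Dict[str, List[int]] = {}
    assigned: Set[int] = set()
    for d in domains:
        hits: List[int] = []
        tree = trees.get(d.chrom)
        if tree is not None:
            for iv in tree.overlap(d.domain_start, d.domain_end):
                if d.domain_start <= iv.begin and iv.end <= d.domain_end:
                    hits.append(iv.data)
        hits.sort()
        assignments[d.gene_id] = hits
        assigned.update(hits)

    n_unassigned = len(peaks) - len(assigned)
    if peaks:
        logger.info(
            "assigned %d/%d peaks (%.1f%%) to >=1 regulatory domain",
            len(assigned), len(peaks), 100.0 * len(assigned) / len(peaks),
        )
    return AssignmentTable(assignments=assignments, n_peaks=len(peaks), n_unassigned=n_unassigned)
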
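"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the joint structure of the consortium
inputs the analysis was designed for:

* a genome with uniformly placed protein-coding genes (>= 2 kb TSS spacing);
* per-sample H3K4me3 peaks at open TSSs, H3K27ac enhancer peaks with
  overdispersed (negative-binomial) per-gene counts, and TF binding events
  drawn conditionally on the enhancer count so that TF load and enhancer
  load are positively correlated;
* a disease-association table in which, in planted mode, top-decile-load
  genes are over-represented among disease genes by a configurable odds
  multiplier (odds = 1 gives an exact null);
* pathway membership and a preferential-attachment PPI skewed toward
  high-load genes;
* lognormal 3'UTR lengths with a planted log-mean shift for high-load genes
  and Poisson-placed miRNA sites along the UTR.

Enhancer and TF peaks are placed inside each gene's *basal* domain.  The
basal window is part of the gene's regulatory domain but outside every
neighbour's extended domain (a neighbour's extension stops at this gene's
basal boundary), so the intended per-gene counts are exactly what
containment-based assignment recovers; this is what makes the generated
ground truth (truth ledger) sharp.  Real enhancers spread much further from
the TSS; the generator trades that realism for an exact truth set.

All generators are deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from . import io as eio
from .core import (
    EVIDENCE_TYPES,
    AssociationRecord,
    ChromSizes,
    GeneRecord,
    GenomicInterval,
    MirnaSiteRecord,
    PeakSet,
    SampleManifest,
    TranscriptAnnotation,
)
from .domains import create_regulatory_domains
from .load import LoadTable, bin_by_load, top_bin


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline inputs.

    Defaults are the conditions under which the package's statistical claims
    are made; see docs/methods.md for the reasoning behind each value.
    """

    n_chroms: int = 2
    chrom_length: int = 50_000_000
    n_genes: int = 2_000
    n_samples: int = 4
    n_tfs: int = 25
    # per-gene enhancer count ~ NegativeBinomial(mean, dispersion r)
    enhancer_mean: float = 8.0
    enhancer_dispersion: float = 2.0
    # expected TF binding events per enhancer peak
    tf_load_slope: float = 0.5
    open_fraction: float = 0.9
    n_diseases: int = 50
    genes_per_disease: Tuple[int, int] = (20, 40)
    # odds multiplier for a top-decile-load gene to be sampled as a disease
    # gene; 1.0 = null mode
    enrichment_odds: float = 4.0
    evidence_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "genetic variation": 0.35,
            "biomarker": 0.30,
            "altered expression": 0.20,
            "therapeutic": 0.10,
            "post-translational modification": 0.05,
        }
    )
    # fractions of association scores above the 0.08 and 0.2 cutoffs
    frac_score_above_min: float = 0.9
    frac_score_above_curated: float = 0.5
    n_pathways: int = 100
    pathway_size: Tuple[int, int] = (10, 60)
    pathway_load_bias: float = 3.0
    ppi_edges: int = 4_000
    ppi_load_bias: float = 3.0
    # lognormal 3'UTR lengths: background log-mean/sd and the additive
    # log-mean shift for top-decile genes (log 1.39 ~ a 39% longer mean)
    utr_log_mean: float = 6.6
    utr_log_sd: float = 1.0
    utr_highload_log_shift: float = math.log(1.39)
    mirna_site_rate_per_kb: float = 2.0
    peak_width: int = 400
    # minimum TSS spacing; >= 10 kb keeps the 5 kb/1 kb basal windows of
    # adjacent genes disjoint on any strand combination, so a peak placed in
    # a basal window is contained in exactly one regulatory domain
    tss_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms, self.n_genes, self.n_samples, self.n_tfs,
            self.n_diseases, self.n_pathways, self.ppi_edges, self.chrom_length,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be > 0")
        if not (0.0 < self.open_fraction <= 1.0):
            raise ValueError("open_fraction must be in (0, 1]")
        if self.enrichment_odds < 1.0:
            raise ValueError("enrichment_odds must be >= 1 (1 = null mode)")
        if self.genes_per_disease[0] > self.genes_per_disease[1]:
            raise ValueError("genes_per_disease range inverted")
        if self.genes_per_disease[1] > self.n_genes:
            raise ValueError("genes_per_disease exceeds n_genes")
        if self.tss_spacing < MIN_TSS_SPACING:
            raise ValueError(f"tss_spacing must be >= {MIN_TSS_SPACING}")


def _rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


MIN_TSS_SPACING = 2_000
_EDGE_MARGIN = 10_000


def generate_genome(
    config: SimConfig, seed: Union[int, np.random.Generator, None] = None
) -> Tuple[ChromSizes, List[GeneRecord]]:
    """Chromosome sizes plus uniformly placed genes with >= 2 kb TSS spacing."""
    rng = _rng(config.seed if seed is None else seed)
    sizes = ChromSizes({f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)})
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    genes: List[GeneRecord] = []
    gid = 0
    for ci, chrom in enumerate(sizes):
        k = per_chrom[ci]
        if k == 0:
            continue
        slack = config.chrom_length - 2 * _EDGE_MARGIN - (k - 1) * config.tss_spacing
        if slack <= 0:
            raise ValueError(
                f"cannot place {k} genes with {config.tss_spacing} bp spacing on a "
                f"{config.chrom_length} bp chromosome"
            )
        offsets = np.sort(rng.uniform(0, slack, size=k))
        tss = (_EDGE_MARGIN + offsets + np.arange(k) * config.tss_spacing).astype(int)
        strands = rng.choice(["+", "-"], size=k)
        for pos, strand in zip(tss, strands):
            gid += 1
            genes.append(GeneRecord(f"g{gid:05d}", chrom, str(strand), int(pos)))
    return sizes, genes


@dataclass
class SampleData:
    """Generated peaks and ground-truth counts for one sample."""

    sample_id: str
    cell_type: str
    source: str
    open_genes: FrozenSet[str]
    h3k4me3: PeakSet
    h3k27ac: PeakSet
    tf_peaks: Dict[str, PeakSet]
    enhancer_counts: Dict[str, int]
    tf_counts: Dict[str, int]


def _gene_rates(rng: np.random.Generator, mean: float, r: float, size: int) -> np.ndarray:
    """Per-gene enhancer rates; Poisson counts on top give NB(mean, r) marginals.

    Samples of one cell type share the same rates, so their loads are
    correlated while loads across cell types are independent.
    """
    if mean <= 0:
        return np.zeros(size)
    return rng.gamma(shape=r, scale=mean / r, size=size)


def _place_in_basal(
    rng: np.random.Generator, basal: Tuple[int, int], count: int, width: int, chrom: str,
    stats: bool,
) -> PeakSet:
    bs, be = basal
    w = min(width, max(1, (be - bs) // 2))
    span = be - bs - w
    if span <= 0:
        count = 0
    starts = rng.integers(bs, bs + max(span, 1), size=count)
    peaks = []
    for s in starts:
        fc = q = None
        if stats:
            fc = float(3.0 + rng.exponential(5.0))
            q = float(3.0 + rng.exponential(10.0))
        peaks.append(GenomicInterval(chrom, int(s), int(s) + w, fold_change=fc, neg_log10_q=q))
    return peaks


def generate_peaks(
    genes: Sequence[GeneRecord],
    chrom_sizes: ChromSizes,
    config: SimConfig,
    seed: Union[int, np.random.Generator, None] = None,
) -> Dict[str, SampleData]:
    """Per-sample H3K4me3 / H3K27ac / per-TF peak sets.

    Each open gene receives one H3K4me3 peak overlapping its TSS.  Enhancer
    counts are gamma-Poisson: samples of the same cell type share one
    per-gene rate vector (drawn from a gamma with the configured mean and
    dispersion), and per-sample counts are Poisson around it, so marginals
    are negative-binomial while loads within a cell type are correlated and
    across cell types independent.  The number of distinct bound TFs is
    Poisson with expectation tf_load_slope x enhancer count, capped at
    n_tfs.  Samples alternate between the 'unfiltered' tag (no peak
    statistics) and the 'filtered' tag, whose files carry fold-change /
    q-value columns and include sub-threshold decoy peaks that the
    statistics filter removes.
    """
    rng = _rng(config.seed if seed is None else seed)
    domains = {d.gene_id: d for d in create_regulatory_domains(genes, chrom_sizes)}

    n_cell_types = max(1, config.n_samples // 2)
    rates = {
        ct: _gene_rates(rng, config.enhancer_mean, config.enhancer_dispersion, len(genes))
        for ct in range(n_cell_types)
    }

    samples: Dict[str, SampleData] = {}
    for si in range(config.n_samples):
        sample_id = f"S{si + 1:02d}"
        cell_type = si % n_cell_types
        source = "filtered" if si % 2 == 1 else "unfiltered"
        with_stats = source == "filtered"
        open_mask = rng.random(len(genes)) < config.open_fraction
        enh_counts = rng.poisson(rates[cell_type])

        h3k4me3: PeakSet = []
        h3k27ac: PeakSet = []
        tf_peaks: Dict[str, PeakSet] = {f"TF{t + 1:02d}": [] for t in range(config.n_tfs)}
        enhancer_counts: Dict[str, int] = {}
        tf_counts: Dict[str, int] = {}
        open_set: Set[str] = set()

        for gi, gene in enumerate(genes):
            d = domains[gene.gene_id]
            basal = (d.basal_start, d.basal_end)
            if open_mask[gi]:
                open_set.add(gene.gene_id)
                s = max(0, gene.tss - 500)
                fc = float(3.0 + rng.exponential(5.0)) if with_stats else None
                q = float(3.0 + rng.exponential(10.0)) if with_stats else None
                h3k4me3.append(
                    GenomicInterval(gene.chrom, s, gene.tss + 500, fold_change=fc, neg_log10_q=q)
                )
            c = int(enh_counts[gi])
            placed = _place_in_basal(rng, basal, c, config.peak_width, gene.chrom, with_stats)
            if len(placed) < c:
                c = len(placed)
            enhancer_counts[gene.gene_id] = c
            h3k27ac.extend(placed)

            n_events = rng.poisson(config.tf_load_slope * c)
            n_distinct = int(min(n_events, config.n_tfs))
            tf_counts[gene.gene_id] = n_distinct
            if n_distinct:
                chosen = rng.choice(config.n_tfs, size=n_distinct, replace=False)
                for t in chosen:
                    tf_peaks[f"TF{t + 1:02d}"].extend(
                        _place_in_basal(rng, basal, 1, config.peak_width, gene.chrom, with_stats)
                    )

        if with_stats:
            # decoys failing the fc/q >= 3 filter, scattered over the genome
            n_decoys = max(1, len(h3k27ac) // 5)
            for _ in range(n_decoys):
                chrom = str(rng.choice(list(chrom_sizes)))
                s = int(rng.integers(0, chrom_sizes[chrom] - config.peak_width))
                fail_fc = rng.random() < 0.5
                fc = float(rng.uniform(0.5, 2.9)) if fail_fc else float(3.0 + rng.exponential(5.0))
                q = float(3.0 + rng.exponential(10.0)) if fail_fc else float(rng.uniform(0.1, 2.9))
                h3k27ac.append(
                    GenomicInterval(chrom, s, s + config.peak_width, fold_change=fc, neg_log10_q=q)
                )

        samples[sample_id] = SampleData(
            sample_id=sample_id,
            cell_type=f"celltype{cell_type + 1}",
            source=source,
            open_genes=frozenset(open_set),
            h3k4me3=h3k4me3,
            h3k27ac=h3k27ac,
            tf_peaks=tf_peaks,
            enhancer_counts=enhancer_counts,
            tf_counts=tf_counts,
        )
    return samples


def top_decile_by_load(
    loads: Mapping[str, int], open_gene_set: Set[str]
) -> FrozenSet[str]:
    """The tie-extended top decile of open genes by load (the planted set)."""
    table = LoadTable(loads=dict(loads), load_kind="enhancer",
                      open_genes=frozenset(open_gene_set))
    return top_bin(bin_by_load(table))


def _draw_score(rng: np.random.Generator, config: SimConfig) -> float:
    u = rng.random()
    below = 1.0 - config.frac_score_above_min
    mid = config.frac_score_above_min - config.frac_score_above_curated
    if u < below:
        return float(rng.uniform(0.0, 0.08))
    if u < below + mid:
        return float(rng.uniform(0.08, 0.2))
    return float(rng.uniform(0.2, 1.0))


def generate_disease_db(
    genes: Sequence[GeneRecord],
    planted_set: FrozenSet[str],
    config: SimConfig,
    seed: Union[int, np.random.Generator, None] = None,
) -> List[AssociationRecord]:
    """Disease-gene association table with an optional planted load effect.

    Each disease draws its genes without replacement with sampling weight
    ``enrichment_odds`` for genes in the planted (top-decile-load) set and 1
    otherwise; odds = 1 yields no systematic association with load.  Scores
    follow the configured band fractions; evidence types are drawn from the
    mixture, occasionally two per association.
    """
    rng = _rng(config.seed if seed is None else seed)
    lo, hi = config.genes_per_disease
    if hi > len(genes):
        raise ValueError("genes_per_disease exceeds the number of genes")
    gene_ids = [g.gene_id for g in genes]
    weights = np.array(
        [config.enrichment_odds if g in planted_set else 1.0 for g in gene_ids]
    )
    weights = weights / weights.sum()
    ev_labels = list(config.evidence_weights)
    ev_p = np.array([config.evidence_weights[l] for l in ev_labels])
    ev_p = ev_p / ev_p.sum()

    records: List[AssociationRecord] = []
    for di in range(config.n_diseases):
        disease_id = f"D{di + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False, p=weights)
        for mi in members:
            labels = {str(rng.choice(ev_labels, p=ev_p))}
            if rng.random() < 0.25:
                labels.add(str(rng.choice(ev_labels, p=ev_p)))
            records.append(
                AssociationRecord(
                    gene_id=gene_ids[int(mi)],
                    disease_id=disease_id,
                    score=_draw_score(rng, config),
                    evidence_types=frozenset(labels),
                )
            )
    return records


def generate_pathways_network(
    genes: Sequence[GeneRecord],
    planted_set: FrozenSet[str],
    config: SimConfig,
    seed: Union[int, np.random.Generator, None] = None,
) -> Tuple[Dict[str, Set[str]], Set[Tuple[str, str]]]:
    """Pathway membership (GMT mapping) and a preferential-attachment PPI.

    Pathway membership probability is multiplied by ``pathway_load_bias`` for
    planted genes; PPI edges are added one at a time with degree-proportional
    endpoint selection (hubs emerge), additionally weighted by
    ``ppi_load_bias`` for planted genes.  No self-loops, no duplicate edges.
    """
    rng = _rng(config.seed if seed is None else seed)
    gene_ids = [g.gene_id for g in genes]
    planted_mask = np.array([g in planted_set for g in gene_ids])

    pw_weights = np.where(planted_mask, config.pathway_load_bias, 1.0)
    pw_weights = pw_weights / pw_weights.sum()
    gmt: Dict[str, Set[str]] = {}
    lo, hi = config.pathway_size
    for pi in range(config.n_pathways):
        size = int(rng.integers(lo, min(hi, len(gene_ids)) + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False, p=pw_weights)
        gmt[f"P{pi + 1:03d}"] = {gene_ids[int(m)] for m in members}

    degree = np.zeros(len(gene_ids))
    bias = np.where(planted_mask, config.ppi_load_bias, 1.0)
    edges: Set[Tuple[int, int]] = set()
    attempts = 0
    while len(edges) < config.ppi_edges and attempts < 50 * config.ppi_edges:
        attempts += 1
        w = (degree + 1.0) * bias
        w = w / w.sum()
        a, b = rng.choice(len(gene_ids), size=2, replace=False, p=w)
        key = (int(min(a, b)), int(max(a, b)))
        if key in edges:
            continue
        edges.add(key)
        degree[key[0]] += 1
        degree[key[1]] += 1
    return gmt, {(gene_ids[a], gene_ids[b]) for a, b in edges}


MIRNA_SITE_LENGTH = 7
_N_MIRNA_FAMILIES = 80


def generate_utr_annotation(
    genes: Sequence[GeneRecord],
    planted_set: FrozenSet[str],
    config: SimConfig,
    seed: Union[int, np.random.Generator, None] = None,
) -> Tuple[Dict[str, TranscriptAnnotation], List[MirnaSiteRecord]]:
    """Transcript length table plus a miRNA site table.

    3'UTR lengths are lognormal with the planted log-mean shift for
    top-decile genes; sites are a Poisson process along the UTR with family
    labels, and a fraction of sites deliberately carry two family labels at
    identical coordinates to exercise the deduplication rule downstream.
    """
    rng = _rng(config.seed if seed is None else seed)
    annotation: Dict[str, TranscriptAnnotation] = {}
    sites: List[MirnaSiteRecord] = []
    for g in genes:
        shift = config.utr_highload_log_shift if g.gene_id in planted_set else 0.0
        utr3 = int(max(30, rng.lognormal(config.utr_log_mean + shift, config.utr_log_sd)))
        utr5 = int(max(10, rng.lognormal(5.3, 0.6)))
        cds = int(max(90, rng.lognormal(7.2, 0.5)))
        spliced = utr3 + utr5 + cds
        unspliced = int(spliced * rng.uniform(3.0, 15.0))
        annotation[g.gene_id] = TranscriptAnnotation(
            gene_id=g.gene_id, utr3_length=utr3, utr5_length=utr5,
            cds_length=cds, spliced_length=spliced, unspliced_length=unspliced,
        )
        if config.mirna_site_rate_per_kb <= 0 or utr3 <= MIRNA_SITE_LENGTH:
            continue
        n_sites = rng.poisson(config.mirna_site_rate_per_kb * utr3 / 1000.0)
        if n_sites == 0:
            continue
        starts = rng.integers(0, utr3 - MIRNA_SITE_LENGTH, size=n_sites)
        for s in starts:
            fam = f"miR-{int(rng.integers(1, _N_MIRNA_FAMILIES + 1))}"
            sites.append(
                MirnaSiteRecord(g.gene_id, int(s), int(s) + MIRNA_SITE_LENGTH, fam)
            )
            if rng.random() < 0.1:  # same coordinates, second family label
                fam2 = f"miR-{int(rng.integers(1, _N_MIRNA_FAMILIES + 1))}"
                sites.append(
                    MirnaSiteRecord(g.gene_id, int(s), int(s) + MIRNA_SITE_LENGTH, fam2)
                )
    return annotation, sites


@dataclass
class Simulation:
    """A complete set of pipeline inputs plus the ground-truth ledger."""

    config: SimConfig
    chrom_sizes: ChromSizes
    genes: List[GeneRecord]
    samples: Dict[str, SampleData]
    associations: List[AssociationRecord]
    gmt: Dict[str, Set[str]]
    ppi_edges: Set[Tuple[str, str]]
    transcripts: Dict[str, TranscriptAnnotation]
    mirna_sites: List[MirnaSiteRecord]
    planted_top_decile: FrozenSet[str]
    planted_diseases: List[str]


def simulate_all(config: SimConfig, seed: Optional[int] = None) -> Simulation:
    """Run every generator with sub-streams derived from one seed.

    The planted set is the tie-extended top decile of open genes by the
    enhancer load of sample 1; in null mode (odds = 1) no diseases are
    recorded as planted.
    """
    root = np.random.default_rng(config.seed if seed is None else seed)
    seeds = root.integers(0, 2**31 - 1, size=5)
    chrom_sizes, genes = generate_genome(config, int(seeds[0]))
    samples = generate_peaks(genes, chrom_sizes, config, int(seeds[1]))
    first = samples[sorted(samples)[0]]
    planted = top_decile_by_load(first.enhancer_counts, set(first.open_genes))
    associations = generate_disease_db(genes, planted, config, int(seeds[2]))
    gmt, ppi = generate_pathways_network(genes, planted, config, int(seeds[3]))
    transcripts, sites = generate_utr_annotation(genes, planted, config, int(seeds[4]))
    planted_diseases = (
        [] if config.enrichment_odds == 1.0
        else sorted({r.disease_id for r in associations})
    )
    return Simulation(
        config=config, chrom_sizes=chrom_sizes, genes=genes, samples=samples,
        associations=associations, gmt=gmt, ppi_edges=ppi,
        transcripts=transcripts, mirna_sites=sites,
        planted_top_decile=planted, planted_diseases=planted_diseases,
    )


def write_simulation(sim: Simulation, out_dir: Union[str, Path]) -> None:
    """Write every input file the CLI subcommands consume, plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_chrom_sizes(sim.chrom_sizes, out / "chrom.sizes")
    eio.write_gene_annotation(sim.genes, out / "genes.tsv")
    eio.write_associations(sim.associations, out / "associations.tsv")
    eio.write_gmt(sim.gmt, out / "pathways.gmt")
    eio.write_edge_list(sim.ppi_edges, out / "ppi.tsv")

    manifests = []
    for sid in sorted(sim.samples):
        s = sim.samples[sid]
        dialect = "peak_with_stats" if s.source == "filtered" else "bed3"
        k4 = f"{sid}_H3K4me3.bed"
        k27 = f"{sid}_H3K27ac.bed"
        eio.write_bed(s.h3k4me3, out / k4, dialect=dialect)
        eio.write_bed(s.h3k27ac, out / k27, dialect=dialect)
        tf_entries = {}
        for tf in sorted(s.tf_peaks):
            fname = f"{sid}_{tf}.bed"
            eio.write_bed(s.tf_peaks[tf], out / fname, dialect=dialect)
            tf_entries[tf] = [fname]
        manifests.append(
            SampleManifest(
                sample_id=sid, cell_type=s.cell_type,
                h3k4me3=[k4], h3k27ac=[k27], tf_peaks=tf_entries, source=s.source,
            )
        )
    eio.write_sample_manifests(manifests, out / "manifest.yaml")

    with open(out / "transcripts.tsv", "w") as fh:
        fh.write("gene_id\tutr3_length\tutr5_length\tcds_length\tspliced_length\tunspliced_length\n")
        for gid in sorted(sim.transcripts):
            t = sim.transcripts[gid]
            fh.write(
                f"{t.gene_id}\t{t.utr3_length}\t{t.utr5_length}\t{t.cds_length}"
                f"\t{t.spliced_length}\t{t.unspliced_length}\n"
            )
    with open(out / "mirna_sites.tsv", "w") as fh:
        fh.write("gene_id\tsite_start\tsite_end\tmirna_family\n")
        for rec in sim.mirna_sites:
            fh.write(f"{rec.gene_id}\t{rec.site_start}\t{rec.site_end}\t{rec.mirna_family}\n")

    truth = {
        "planted_top_decile": sorted(sim.planted_top_decile),
        "planted_diseases": sim.planted_diseases,
        "enrichment_odds": sim.config.enrichment_odds,
        "seed": sim.config.seed,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


def read_transcripts(path) -> Dict[str, TranscriptAnnotation]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return {
        r.gene_id: TranscriptAnnotation(
            gene_id=r.gene_id, utr3_length=int(r.utr3_length),
            utr5_length=int(r.utr5_length), cds_length=int(r.cds_length),
            spliced_length=int(r.spliced_length), unspliced_length=int(r.unspliced_length),
        )
        for r in df.itertuples(index=False)
    }


def read_mirna_sites(path) -> List[MirnaSiteRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "mirna_family": str})
    return [
        MirnaSiteRecord(r.gene_id, int(r.site_start), int(r.site_end), r.mirna_family)
        for r in df.itertuples(index=False)
    ]
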
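"""Shared domain types for the regulatory-load pipeline.

All genomic coordinates are 0-based half-open (BED convention); a gene's TSS
is a 0-based point.  Types validate their invariants at construction so that
malformed objects fail early rather than deep inside an analysis step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

EVIDENCE_TYPES = frozenset(
    {
        "altered expression",
        "biomarker",
        "genetic variation",
        "post-translational modification",
        "therapeutic",
    }
)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally carrying peak statistics.

    ``fold_change`` and ``neg_log10_q`` hold the peak-caller statistics used
    to filter consortium-style peak files (both thresholded at 3 by default
    downstream); they are ``None`` for plain BED records.
    """

    chrom: str
    start: int
    end: int
    score: Optional[float] = None
    fold_change: Optional[float] = None
    neg_log10_q: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        """True iff this interval overlaps [start, end) by >= 1 bp."""
        return self.start < end and start < self.end


PeakSet = List[GenomicInterval]


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp, with positive lengths."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        super().__init__(sizes)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")


@dataclass(frozen=True)
class AssociationRecord:
    """One gene-disease association with a confidence score and evidence types."""

    gene_id: str
    disease_id: str
    score: float
    evidence_types: FrozenSet[str]

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(
                f"association ({self.gene_id}, {self.disease_id}): "
                f"score {self.score} outside [0, 1]"
            )
        if not self.evidence_types:
            raise ValueError(
                f"association ({self.gene_id}, {self.disease_id}): empty evidence set"
            )


@dataclass
class SampleManifest:
    """Paths of the peak files of one ChIP-Seq sample.

    ``source`` distinguishes pre-filtered consortium data ('unfiltered': use
    peaks as-is) from data that still needs the fold-change / q-value filter
    ('filtered').
    """

    sample_id: str
    cell_type: str
    h3k4me3: List[str]
    h3k27ac: List[str] = field(default_factory=list)
    tf_peaks: Dict[str, List[str]] = field(default_factory=dict)
    source: str = "unfiltered"

    def __post_init__(self) -> None:
        if self.source not in ("filtered", "unfiltered"):
            raise ValueError(f"sample {self.sample_id}: unknown source tag {self.source!r}")
        if not self.h3k4me3:
            raise ValueError(f"sample {self.sample_id}: at least one H3K4me3 file required")
        if not self.h3k27ac and not self.tf_peaks:
            raise ValueError(
                f"sample {self.sample_id}: need H3K27ac or >=1 TF peak file"
            )


@dataclass(frozen=True)
class RegulatoryDomain:
    """Basal-plus-extension regulatory domain of one gene."""

    gene_id: str
    chrom: str
    basal_start: int
    basal_end: int
    domain_start: int
    domain_end: int

    def __post_init__(self) -> None:
        if not (self.domain_start <= self.basal_start < self.basal_end <= self.domain_end):
            raise ValueError(
                f"domain of {self.gene_id}: basal "
                f"[{self.basal_start},{self.basal_end}) not contained in "
                f"extended [{self.domain_start},{self.domain_end})"
            )
        if self.domain_start < 0:
            raise ValueError(f"domain of {self.gene_id}: negative start")

    def contains(self, start: int, end: int) -> bool:
        return self.domain_start <= start and end <= self.domain_end


@dataclass
class AssignmentTable:
    """Peak-to-gene assignment for one peak source (one TF, or H3K27ac).

    ``assignments`` maps every gene id (with a domain) to the indices of the
    peaks fully contained in that gene's regulatory domain.  A peak may appear
    under several genes because neighbouring domains can overlap.
    """

    assignments: Dict[str, List[int]]
    n_peaks: int
    n_unassigned: int

    @property
    def n_assigned(self) -> int:
        return self.n_peaks - self.n_unassigned


@dataclass
class LoadTable:
    """Per-gene integer regulatory load for one sample.

    ``load_kind`` is 'tf' (distinct bound TFs) or 'enhancer' (H3K27ac peak
    count).  Genes outside ``open_genes`` keep their load but are flagged
    closed and excluded from binning.
    """

    loads: Dict[str, int]
    load_kind: str
    open_genes: FrozenSet[str]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.load_kind not in ("tf", "enhancer"):
            raise ValueError(f"load_kind must be 'tf' or 'enhancer', got {self.load_kind!r}")
        bad = [g for g, v in self.loads.items() if v < 0]
        if bad:
            raise ValueError(f"negative loads for genes: {bad[:5]}")


@dataclass(frozen=True)
class LoadBin:
    bin_rank: int
    load_min: int
    load_max: int
    genes: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.load_min > self.load_max:
            raise ValueError("load_min > load_max")
        if not self.genes:
            raise ValueError("empty bin")


@dataclass
class BinPartition:
    """Ordered load bins (rank 1 = highest load) plus the separate zero bin.

    Validates the tie-consistency contract: the bins partition the open-gene
    population, their load ranges are disjoint and strictly decreasing with
    rank, and no load value occurs in two bins.
    """

    bins: List[LoadBin]
    zero_bin: FrozenSet[str]
    population: FrozenSet[str]

    def __post_init__(self) -> None:
        seen: set = set(self.zero_bin)
        prev_min: Optional[int] = None
        for i, b in enumerate(self.bins, start=1):
            if b.bin_rank != i:
                raise ValueError("bin ranks must be consecutive starting at 1")
            if prev_min is not None and b.load_max >= prev_min:
                raise ValueError("bin load ranges overlap or are out of order")
            prev_min = b.load_min
            if seen & b.genes:
                raise ValueError("a gene appears in more than one bin")
            seen |= b.genes
        if seen != set(self.population):
            raise ValueError("bins plus zero bin do not partition the population")


@dataclass(frozen=True)
class DiseaseGeneSet:
    disease_id: str
    genes: FrozenSet[str]
    min_score: float
    evidence_filter: Optional[FrozenSet[str]] = None


@dataclass(frozen=True)
class EnrichmentCell:
    """One hypergeometric test: one sample, one disease, one load bin.

    N = open genes (population), K = open disease genes (successes),
    n = bin size (draws), k = disease genes in the bin (observed).
    ``bin_rank`` 0 denotes the zero-load bin.
    """

    sample_id: str
    disease_id: str
    bin_rank: int
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_adj: float
    neg_log10_p_adj: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.n <= self.N and self.K <= self.N):
            raise ValueError("inconsistent hypergeometric counts")
        if not (0.0 < self.p_raw <= 1.0):
            raise ValueError("p_raw outside (0, 1]")
        if self.p_adj + 1e-12 < self.p_raw:
            raise ValueError("adjusted p below raw p")


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Length annotation of one representative transcript per gene (nt)."""

    gene_id: str
    utr3_length: int
    utr5_length: int
    cds_length: int
    spliced_length: int
    unspliced_length: int

    def __post_init__(self) -> None:
        lengths = (
            self.utr3_length,
            self.utr5_length,
            self.cds_length,
            self.spliced_length,
            self.unspliced_length,
        )
        if any(x < 0 for x in lengths):
            raise ValueError(f"transcript {self.gene_id}: negative length")
        if self.spliced_length > self.unspliced_length:
            raise ValueError(f"transcript {self.gene_id}: spliced > unspliced length")


@dataclass(frozen=True)
class MirnaSiteRecord:
    """A predicted miRNA target site inside a 3'UTR (nt offsets)."""

    gene_id: str
    site_start: int
    site_end: int
    mirna_family: str

    def __post_init__(self) -> None:
        if not (0 <= self.site_start < self.site_end):
            raise ValueError(f"site on {self.gene_id}: invalid coordinates")
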
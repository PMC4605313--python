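"""Readers and writers for the plain-text formats the pipeline touches.

BED3 / BED6+ / a narrowPeak-like dialect with declared statistic columns,
TSV gene annotations, association tables, GMT pathway files, 2-column edge
lists, chrom.sizes files and the wide enrichment matrix.  Every reader is an
identity on the output of its paired writer.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd
import yaml

from .core import (
    EVIDENCE_TYPES,
    AssociationRecord,
    ChromSizes,
    GeneRecord,
    GenomicInterval,
    PeakSet,
    SampleManifest,
)


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


# ---------------------------------------------------------------------------
# BED / peaks

#: default columns (0-based) of the narrowPeak-like dialect:
#: signalValue is taken as the fold change, column 8 as -log10(q).
DEFAULT_FC_COL = 6
DEFAULT_Q_COL = 8


def read_bed(
    path,
    dialect: str = "bed3",
    fc_col: int = DEFAULT_FC_COL,
    q_col: int = DEFAULT_Q_COL,
) -> PeakSet:
    """Read a BED-like file into a list of :class:`GenomicInterval`.

    ``dialect`` is one of ``bed3``, ``bed6plus`` (column 5 read as score when
    numeric) or ``peak_with_stats`` (``fc_col``/``q_col`` declare which
    columns hold the fold change and the -log10 q-value).
    """
    if dialect not in ("bed3", "bed6plus", "peak_with_stats"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    peaks: PeakSet = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            score = fc = q = None
            if dialect in ("bed6plus", "peak_with_stats") and len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            if dialect == "peak_with_stats":
                needed = max(fc_col, q_col)
                if len(fields) <= needed:
                    raise ParseError(
                        f"{path}:{lineno}: dialect peak_with_stats needs "
                        f"column {needed + 1}, found {len(fields)}"
                    )
                try:
                    fc, q = float(fields[fc_col]), float(fields[q_col])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric peak statistics") from exc
            peaks.append(
                GenomicInterval(chrom, start, end, score=score, fold_change=fc, neg_log10_q=q)
            )
    return peaks


def write_bed(peaks: Sequence[GenomicInterval], path, dialect: str = "bed3") -> None:
    """Write peaks; ``peak_with_stats`` emits a 10-column narrowPeak-like row."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            if dialect == "bed3":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
            elif dialect == "bed6plus":
                score = "0" if p.score is None else repr(p.score)
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{score}\t.\n")
            elif dialect == "peak_with_stats":
                score = "0" if p.score is None else repr(p.score)
                fc = "0" if p.fold_change is None else repr(p.fold_change)
                q = "0" if p.neg_log10_q is None else repr(p.neg_log10_q)
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{score}\t.\t{fc}\t-1\t{q}\t-1\n"
                )
            else:
                raise ValueError(f"unknown BED dialect {dialect!r}")


# ---------------------------------------------------------------------------
# chrom sizes and gene annotation


def read_chrom_sizes(path) -> ChromSizes:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            sizes[fields[0]] = int(fields[1])
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_gene_annotation(path) -> List[GeneRecord]:
    """Read the TSV gene annotation (header: gene_id, chrom, strand, tss)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = ["gene_id", "chrom", "strand", "tss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dup:
        raise ParseError(f"{path}: duplicate gene ids: {sorted(set(dup))}")
    return [
        GeneRecord(r.gene_id, r.chrom, r.strand, int(r.tss))
        for r in df.itertuples(index=False)
    ]


def write_gene_annotation(genes: Sequence[GeneRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene-disease associations


def read_associations(path) -> List[AssociationRecord]:
    """Read the association TSV (gene_id, disease_id, score, evidence_types).

    Evidence labels are semicolon-separated; labels outside the five
    canonical DisGeNET-style types raise a warning but are kept.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "disease_id": str},
        float_precision="round_trip",
    )
    records: List[AssociationRecord] = []
    for i, r in enumerate(df.itertuples(index=False), start=2):
        labels = frozenset(x.strip() for x in str(r.evidence_types).split(";") if x.strip())
        unknown = labels - EVIDENCE_TYPES
        if unknown:
            warnings.warn(
                f"{path}:{i}: unknown evidence labels {sorted(unknown)} kept as-is",
                stacklevel=2,
            )
        score = float(r.score)
        if not (0.0 <= score <= 1.0):
            raise ParseError(f"{path}:{i}: score {score} outside [0, 1]")
        records.append(AssociationRecord(r.gene_id, r.disease_id, score, labels))
    return records


def write_associations(records: Sequence[AssociationRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "disease_id": [r.disease_id for r in records],
            "score": [r.score for r in records],
            "evidence_types": [";".join(sorted(r.evidence_types)) for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# GMT, edge lists, matrices


def read_gmt(path) -> Dict[str, Set[str]]:
    pathways: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            pathways[fields[0]] = {g for g in fields[2:] if g}
    return pathways


def write_gmt(pathways: Dict[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_edge_list(path) -> Set[Tuple[str, str]]:
    """Read a 2-column edge list; undirected, self-loops dropped, duplicates collapsed."""
    edges: Set[Tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(f"{path}:{lineno}: edge needs two non-empty gene ids")
            a, b = fields[0], fields[1]
            if a == b:
                continue
            edges.add((min(a, b), max(a, b)))
    return edges


def write_edge_list(edges: Iterable[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted({(min(a, b), max(a, b)) for a, b in edges if a != b}):
            fh.write(f"{a}\t{b}\n")


def write_enrichment_matrix(matrix: pd.DataFrame, path) -> None:
    """Write the wide enrichment matrix (disease rows x sample columns) as TSV."""
    matrix.to_csv(path, sep="\t", index=True, index_label="disease_id", float_format="%.17g")


def read_enrichment_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="disease_id")


# ---------------------------------------------------------------------------
# sample manifests (YAML)


def read_sample_manifests(path) -> List[SampleManifest]:
    """Read a YAML manifest describing the peak files of each sample.

    Paths in the manifest are interpreted relative to the manifest file.
    """
    base = Path(path).parent
    with open(path) as fh:
        doc = yaml.safe_load(fh)

    def _resolve(paths):
        return [str(base / p) for p in paths]

    manifests = []
    for entry in doc["samples"]:
        manifests.append(
            SampleManifest(
                sample_id=entry["sample_id"],
                cell_type=entry.get("cell_type", ""),
                h3k4me3=_resolve(entry["h3k4me3"]),
                h3k27ac=_resolve(entry.get("h3k27ac", [])),
                tf_peaks={tf: _resolve(ps) for tf, ps in entry.get("tf_peaks", {}).items()},
                source=entry.get("source", "unfiltered"),
            )
        )
    return manifests


def write_sample_manifests(manifests: Sequence[SampleManifest], path) -> None:
    doc = {
        "samples": [
            {
                "sample_id": m.sample_id,
                "cell_type": m.cell_type,
                "h3k4me3": m.h3k4me3,
                "h3k27ac": m.h3k27ac,
                "tf_peaks": m.tf_peaks,
                "source": m.source,
            }
            for m in manifests
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
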
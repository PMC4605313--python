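"""3'UTR length comparisons and miRNA binding-site counting.

High-regulatory-load genes are compared against a background set with a
one-sided two-sample Kolmogorov-Smirnov test of the hypothesis that the
background lengths are stochastically *smaller* than the test lengths.  With
F_bg and F_test the empirical CDFs, the statistic is

    D+ = sup_x [ F_bg(x) - F_test(x) ]

(positive when the test sample is shifted toward larger values) and the
p-value uses the standard one-sided asymptotic formula
exp(-2 D+^2 m n / (m + n)).  Sign convention: "background smaller than test"
means F_bg >= F_test pointwise under the alternative, i.e. test values
stochastically larger.

miRNA target sites listed under several miRNA family labels at identical
3'UTR coordinates are counted once; overlapping but non-identical sites are
not merged.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .core import MirnaSiteRecord, TranscriptAnnotation


def ks_one_sided(
    background_values: Sequence[float],
    test_values: Sequence[float],
) -> Tuple[float, float]:
    """One-sided two-sample KS test that background < test (stochastically).

    Returns (D+, p) with D+ = sup_x [F_background(x) - F_test(x)] and the
    asymptotic p-value exp(-2 D+^2 m n / (m+n)), clipped to (0, 1].
    """
    bg = np.sort(np.asarray(background_values, dtype=float))
    ts = np.sort(np.asarray(test_values, dtype=float))
    if bg.size == 0 or ts.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([bg, ts])
    f_bg = np.searchsorted(bg, grid, side="right") / bg.size
    f_ts = np.searchsorted(ts, grid, side="right") / ts.size
    d_plus = float(np.max(f_bg - f_ts))
    d_plus = max(d_plus, 0.0)
    m, n = bg.size, ts.size
    p = math.exp(-2.0 * d_plus**2 * m * n / (m + n))
    return d_plus, min(p, 1.0)


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-test significance level alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def count_mirna_sites(
    site_table: Sequence[MirnaSiteRecord],
    utr3_lengths: Optional[Mapping[str, int]] = None,
) -> Dict[str, int]:
    """Deduplicated miRNA site count per gene.

    Sites with identical (gene_id, site_start, site_end) count once no matter
    how many family labels they carry.  If ``utr3_lengths`` is given, a site
    extending beyond its gene's 3'UTR raises an error.
    """
    positions: Dict[str, Set[Tuple[int, int]]] = defaultdict(set)
    for rec in site_table:
        if utr3_lengths is not None:
            limit = utr3_lengths.get(rec.gene_id)
            if limit is not None and rec.site_end > limit:
                raise ValueError(
                    f"site {rec.site_start}-{rec.site_end} on {rec.gene_id} "
                    f"extends beyond its 3'UTR of length {limit}"
                )
        positions[rec.gene_id].add((rec.site_start, rec.site_end))
    return {gene: len(pos) for gene, pos in positions.items()}


def site_family_correlation(site_table: Sequence[MirnaSiteRecord]) -> float:
    """Spearman correlation of per-gene site count vs distinct-family count.

    Computed across genes with >= 1 site; site counts are deduplicated by
    identical coordinates, family counts are distinct labels.
    """
    sites = count_mirna_sites(site_table)
    families: Dict[str, Set[str]] = defaultdict(set)
    for rec in site_table:
        families[rec.gene_id].add(rec.mirna_family)
    genes = sorted(sites)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes with sites for a correlation")
    x = [sites[g] for g in genes]
    y = [len(families[g]) for g in genes]
    rho = stats.spearmanr(x, y).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def compare_lengths(
    annotation: Mapping[str, TranscriptAnnotation],
    hrl_set: Set[str],
    background_set: Optional[Set[str]] = None,
    attribute: str = "utr3_length",
    exclude_test_from_background: bool = False,
) -> Tuple[float, float, float, float]:
    """KS comparison of a length attribute between high-load and background genes.

    Returns (D+, p, background mean, test mean).  By default the test genes
    remain part of the background sample (subset-inclusive convention).
    """
    background = set(background_set) if background_set is not None else set(annotation)
    test = set(hrl_set) & set(annotation)
    if exclude_test_from_background:
        background = background - test
    bg_vals = [getattr(annotation[g], attribute) for g in background if g in annotation]
    ts_vals = [getattr(annotation[g], attribute) for g in test]
    d, p = ks_one_sided(bg_vals, ts_vals)
    return d, p, float(np.mean(bg_vals)), float(np.mean(ts_vals))
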
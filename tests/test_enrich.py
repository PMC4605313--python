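"""Disease gene sets, hypergeometric upper tail, BH adjustment, binarization."""

import math
from fractions import Fraction

import numpy as np
import pytest

from enhload.core import AssociationRecord, LoadTable
from enhload.enrich import (
    BINARIZATION_THRESHOLD,
    bh_adjust,
    binarize,
    build_disease_sets,
    enrich_matrix,
    hypergeom_upper_tail,
    partition_by_evidence,
)
from enhload.load import bin_by_load


def exact_upper_tail(N, K, n, k):
    """Oracle: exact rational pmf enumeration of P(X >= k)."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(acc, total)


def assoc(gene, disease, score=0.5, ev=("biomarker",)):
    return AssociationRecord(gene, disease, score, frozenset(ev))


class TestBuildDiseaseSets:
    def test_min_genes_applied_before_background_intersection(self):
        records = [assoc(f"g{i}", "D1", score=0.1) for i in range(15)]
        background = {f"g{i}" for i in range(5)}  # only 5 in background
        sets = build_disease_sets(records, background, min_genes=15)
        assert len(sets) == 1 and len(sets[0].genes) == 5
        # post-intersection variant drops the disease
        assert build_disease_sets(
            records, background, min_genes=15, min_genes_after_background=True
        ) == []

    def test_score_threshold_drops_disease(self):
        records = [assoc(f"g{i}", "D1", score=0.1) for i in range(14)]
        records += [assoc("low", "D1", score=0.05)]  # 15th gene below cutoff
        assert build_disease_sets(records, {"g0"}, min_genes=15) == []

    def test_curated_tier_min_score(self):
        records = [assoc(f"g{i}", "D1", score=0.25) for i in range(10)]
        records += [assoc(f"h{i}", "D1", score=0.1) for i in range(10)]
        sets = build_disease_sets(
            records, {f"g{i}" for i in range(10)}, min_score=0.2, min_genes=10
        )
        assert len(sets) == 1 and len(sets[0].genes) == 10

    def test_set_sizes_match_hand_counts(self, rng):
        records = []
        for d in range(5):
            for g in rng.choice(100, size=30, replace=False):
                records.append(assoc(f"g{g}", f"D{d}", score=float(rng.uniform(0, 1))))
        background = {f"g{i}" for i in range(100)}
        sets = build_disease_sets(records, background, min_score=0.3, min_genes=5)
        expected = {}
        for d in range(5):
            genes = {r.gene_id for r in records if r.disease_id == f"D{d}" and r.score >= 0.3}
            if len(genes) >= 5:
                expected[f"D{d}"] = genes
        assert {s.disease_id: set(s.genes) for s in sets} == expected

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            build_disease_sets([], set(), 0.08, 15)


class TestEvidencePartition:
    def test_genetic_variation_has_priority(self):
        records = [
            assoc("g1", "D1", ev=("genetic variation", "biomarker")),
            assoc("g2", "D1", ev=("therapeutic",)),
        ]
        parts = partition_by_evidence(records, {"g1", "g2", "g3"})
        assert parts["genetic_variation"] == {"g1"}
        assert parts["other_evidence"] == {"g2"}
        assert parts["non_disease"] == {"g3"}

    def test_below_score_goes_to_non_disease(self):
        records = [assoc("g1", "D1", score=0.05)]
        parts = partition_by_evidence(records, {"g1"})
        assert parts["non_disease"] == {"g1"}

    def test_three_sets_partition_background(self, rng):
        background = {f"g{i}" for i in range(50)}
        labels = ["genetic variation", "biomarker", "therapeutic", "altered expression"]
        records = [
            assoc(f"g{int(rng.integers(0, 60))}", f"D{int(rng.integers(0, 5))}",
                  score=float(rng.uniform(0, 1)),
                  ev=tuple(rng.choice(labels, size=int(rng.integers(1, 3)), replace=False)))
            for _ in range(200)
        ]
        parts = partition_by_evidence(records, background)
        union = parts["genetic_variation"] | parts["other_evidence"] | parts["non_disease"]
        assert union == background
        assert not parts["genetic_variation"] & parts["other_evidence"]
        assert not parts["genetic_variation"] & parts["non_disease"]
        assert not parts["other_evidence"] & parts["non_disease"]


class TestHypergeomUpperTail:
    def test_exact_fraction_example(self):
        # N=20, K=5, n=5, k=3: (C(5,3)C(15,2)+C(5,4)C(15,1)+C(5,5))/C(20,5)
        assert exact_upper_tail(20, 5, 5, 3) == Fraction(1126, 15504)
        assert hypergeom_upper_tail(20, 5, 5, 3) == pytest.approx(1126 / 15504, rel=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(50, 10, 5, 0) == 1.0

    def test_exhaustive_draw(self):
        assert hypergeom_upper_tail(10, 4, 10, 4) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 4, 10, 5)

    def test_matches_enumeration_on_random_parameters(self, rng):
        for _ in range(200):
            N = int(rng.integers(1, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            expected = float(exact_upper_tail(N, K, n, k))
            assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(expected, abs=1e-12)


class TestBH:
    def test_hand_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(adj, [0.04, 0.04, 0.05, 0.05])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_test_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_monotone_geq_raw_and_step_up_decisions(self, rng):
        p = rng.uniform(0, 1, size=100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        # defining property: adj <= alpha iff the classic step-up rejects
        for alpha in (0.05, 0.2, 0.5):
            m = len(p)
            sorted_p = np.sort(p)
            passing = np.nonzero(sorted_p <= alpha * np.arange(1, m + 1) / m)[0]
            cutoff = sorted_p[passing.max()] if passing.size else -1.0
            assert np.array_equal(adj <= alpha, p <= cutoff)


class TestEnrichMatrix:
    def make_inputs(self, rng):
        loads = {f"g{i}": int(v) for i, v in enumerate(rng.poisson(5, size=200))}
        table = LoadTable(loads=loads, load_kind="enhancer", open_genes=frozenset(loads))
        part = bin_by_load(table)
        disease = frozenset(rng.choice(sorted(loads), size=30, replace=False))
        from enhload.core import DiseaseGeneSet

        ds = [DiseaseGeneSet("D1", disease, 0.08)]
        return {"S1": part}, ds, {"S1": set(loads)}

    def test_cells_consistent_and_bh_applied(self, rng):
        parts, ds, opens = self.make_inputs(rng)
        mat = enrich_matrix(parts, ds, opens)
        df = mat.to_frame()
        assert (df["N"] == 200).all()
        assert (df["K"] == 30).all()
        assert (df["p_adj"] >= df["p_raw"] - 1e-12).all()
        assert df["k"].sum() == 30  # bins partition the population
        assert df["n"].sum() == 200

    def test_disjoint_disease_yields_p_one(self):
        loads = {"a": 3, "b": 2, "c": 1, "d": 0}
        table = LoadTable(loads=loads, load_kind="enhancer", open_genes=frozenset(loads))
        part = bin_by_load(table)
        from enhload.core import DiseaseGeneSet

        ds = [DiseaseGeneSet("D1", frozenset({"x"}), 0.08)]
        mat = enrich_matrix({"S1": part}, ds, {"S1": set(loads)})
        assert all(c.p_raw == 1.0 and c.k == 0 for c in mat.cells)


class TestBinarize:
    def test_threshold_inclusive(self):
        import pandas as pd

        mat = pd.DataFrame([[1.301, 1.300]], index=["D1"], columns=["S1", "S2"])
        binary, dropped_rows, dropped_cols = binarize(mat)
        assert binary.loc["D1", "S1"] == 1
        assert dropped_cols == ["S2"]
        assert BINARIZATION_THRESHOLD == 1.301

    def test_all_zero_rows_and_columns_dropped(self):
        import pandas as pd

        mat = pd.DataFrame(
            [[2.0, 0.0], [0.5, 0.2]], index=["D1", "D2"], columns=["S1", "S2"]
        )
        binary, dropped_rows, dropped_cols = binarize(mat)
        assert dropped_rows == ["D2"] and dropped_cols == ["S2"]
        assert binary.shape == (1, 1)

    def test_two_by_two_hand_case(self):
        import pandas as pd

        mat = pd.DataFrame(
            [[3.2, 1.0], [1.5, 2.0]], index=["D1", "D2"], columns=["S1", "S2"]
        )
        binary, _, _ = binarize(mat)
        assert binary.values.tolist() == [[1, 0], [1, 1]]
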
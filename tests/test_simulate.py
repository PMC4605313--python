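"""Determinism and statistical structure of the synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats

from enhload import simulate as sim
from enhload.core import LoadTable
from enhload.domains import create_regulatory_domains, open_genes
from enhload.load import bin_by_load


SMALL = dict(n_chroms=1, chrom_length=20_000_000, n_genes=300, n_samples=2, n_tfs=10)


class TestGenerateGenome:
    def test_small_genome_placement(self):
        cfg = sim.SimConfig(n_chroms=1, chrom_length=1_000_000, n_genes=10, seed=1,
                            genes_per_disease=(2, 5))
        sizes, genes = sim.generate_genome(cfg)
        assert len(genes) == 10
        assert all(0 <= g.tss < 1_000_000 for g in genes)
        assert sizes == {"chr1": 1_000_000}

    def test_same_seed_identical(self):
        cfg = sim.SimConfig(**SMALL, seed=7)
        assert sim.generate_genome(cfg) == sim.generate_genome(cfg)

    def test_minimum_tss_spacing_over_seeds(self):
        for seed in range(100):
            cfg = sim.SimConfig(n_chroms=1, chrom_length=2_000_000, n_genes=50, seed=seed)
            _, genes = sim.generate_genome(cfg)
            tss = sorted(g.tss for g in genes)
            assert min(np.diff(tss)) >= sim.MIN_TSS_SPACING

    def test_genes_that_cannot_fit_rejected(self):
        cfg = sim.SimConfig(n_chroms=1, chrom_length=200_000, n_genes=100, seed=0)
        with pytest.raises(ValueError, match="cannot place"):
            sim.generate_genome(cfg)


class TestGeneratePeaks:
    def test_open_fraction_one_all_genes_pass_h3k4me3_filter(self):
        cfg = sim.SimConfig(**SMALL, open_fraction=1.0, seed=3)
        sizes, genes = sim.generate_genome(cfg)
        samples = sim.generate_peaks(genes, sizes, cfg)
        for sd in samples.values():
            called = open_genes(genes, [sd.h3k4me3])
            assert called == {g.gene_id for g in genes}

    def test_zero_enhancer_mean_all_loads_zero(self):
        cfg = sim.SimConfig(**SMALL, enhancer_mean=0.0, seed=3)
        sizes, genes = sim.generate_genome(cfg)
        samples = sim.generate_peaks(genes, sizes, cfg)
        sd = samples["S01"]
        assert all(v == 0 for v in sd.enhancer_counts.values())
        table = LoadTable(loads=dict(sd.enhancer_counts), load_kind="enhancer",
                          open_genes=sd.open_genes)
        part = bin_by_load(table)
        assert part.bins == [] and part.zero_bin == frozenset(sd.open_genes)

    def test_tf_enhancer_load_correlation(self):
        cfg = sim.SimConfig(seed=11, n_samples=1, tf_load_slope=0.5)
        sizes, genes = sim.generate_genome(cfg)
        samples = sim.generate_peaks(genes, sizes, cfg)
        sd = samples["S01"]
        ids = [g.gene_id for g in genes]
        rho = stats.spearmanr(
            [sd.tf_counts[g] for g in ids], [sd.enhancer_counts[g] for g in ids]
        ).statistic
        assert rho > 0.4

    def test_determinism(self):
        cfg = sim.SimConfig(**SMALL, seed=5)
        sizes, genes = sim.generate_genome(cfg)
        a = sim.generate_peaks(genes, sizes, cfg, 9)
        b = sim.generate_peaks(genes, sizes, cfg, 9)
        assert a["S01"].h3k27ac == b["S01"].h3k27ac
        assert a["S02"].tf_peaks == b["S02"].tf_peaks

    def test_peaks_lie_inside_own_regulatory_domain(self):
        cfg = sim.SimConfig(**SMALL, seed=13)
        sizes, genes = sim.generate_genome(cfg)
        doms = {d.gene_id: d for d in create_regulatory_domains(genes, sizes)}
        samples = sim.generate_peaks(genes, sizes, cfg)
        sd = samples["S01"]  # unfiltered: no decoys
        trees = {}
        for g in genes:
            d = doms[g.gene_id]
            trees.setdefault(g.chrom, []).append(d)
        for p in sd.h3k27ac:
            assert any(d.contains(p.start, p.end) for d in trees[p.chrom])


class TestGenerateDiseaseDb:
    def plant(self, odds, seed, **kw):
        cfg = sim.SimConfig(**SMALL, enrichment_odds=odds, seed=seed, **kw)
        sizes, genes = sim.generate_genome(cfg)
        samples = sim.generate_peaks(genes, sizes, cfg)
        sd = samples["S01"]
        planted = sim.top_decile_by_load(sd.enhancer_counts, set(sd.open_genes))
        assoc = sim.generate_disease_db(genes, planted, cfg)
        return genes, planted, assoc

    def test_planted_mode_raises_top_decile_proportion(self):
        genes, planted, assoc = self.plant(4.0, 21)
        disease_genes = [r.gene_id for r in assoc]
        frac_in_disease = np.mean([g in planted for g in disease_genes])
        frac_overall = len(planted) / len(genes)
        # analytic expectation: odds*s/(odds*s + 1 - s) with s the planted share
        s = frac_overall
        expected = 4 * s / (4 * s + 1 - s)
        assert frac_in_disease > frac_overall
        assert frac_in_disease == pytest.approx(expected, abs=0.08)

    def test_null_mode_proportion_matches_background(self):
        genes, planted, assoc = self.plant(1.0, 22, n_diseases=100)
        disease_genes = [r.gene_id for r in assoc]
        frac = np.mean([g in planted for g in disease_genes])
        s = len(planted) / len(genes)
        assert frac == pytest.approx(s, abs=0.05)

    def test_seed_determinism(self):
        a = self.plant(4.0, 23)[2]
        b = self.plant(4.0, 23)[2]
        assert a == b

    def test_oversized_diseases_rejected(self):
        cfg = sim.SimConfig(**SMALL, seed=1)
        sizes, genes = sim.generate_genome(cfg)
        cfg2 = sim.SimConfig(**{**SMALL, "n_genes": 300}, seed=1,
                             genes_per_disease=(250, 299))
        with pytest.raises(ValueError):
            sim.generate_disease_db(genes[:100], frozenset(), cfg2)

    def test_score_band_fractions(self):
        _, _, assoc = self.plant(1.0, 24, n_diseases=100)
        scores = np.array([r.score for r in assoc])
        assert (scores >= 0.08).mean() == pytest.approx(0.9, abs=0.05)
        assert (scores >= 0.2).mean() == pytest.approx(0.5, abs=0.05)


class TestGeneratePathwaysNetwork:
    def build(self, bias, seed):
        cfg = sim.SimConfig(**SMALL, pathway_load_bias=bias, ppi_load_bias=bias,
                            ppi_edges=600, n_pathways=40, seed=seed)
        sizes, genes = sim.generate_genome(cfg)
        planted = frozenset(g.gene_id for g in genes[:30])
        gmt, edges = sim.generate_pathways_network(genes, planted, cfg)
        return genes, planted, gmt, edges

    def test_edge_count_no_self_loops_no_duplicates(self):
        genes, planted, gmt, edges = self.build(3.0, 31)
        assert len(edges) == 600
        assert all(a != b for a, b in edges)
        assert len({(min(a, b), max(a, b)) for a, b in edges}) == 600

    def test_unbiased_mode_equal_membership(self):
        genes, planted, gmt, edges = self.build(1.0, 32)
        counts = {g.gene_id: 0 for g in genes}
        for members in gmt.values():
            for g in members:
                counts[g] += 1
        top = np.mean([counts[g] for g in planted])
        rest = np.mean([counts[g.gene_id] for g in genes if g.gene_id not in planted])
        assert top == pytest.approx(rest, abs=3 * np.std(list(counts.values())) / np.sqrt(30))

    def test_biased_mode_skews_membership_toward_planted(self):
        genes, planted, gmt, edges = self.build(3.0, 33)
        counts = {g.gene_id: 0 for g in genes}
        for members in gmt.values():
            for g in members:
                counts[g] += 1
        top = np.mean([counts[g] for g in planted])
        rest = np.mean([counts[g.gene_id] for g in genes if g.gene_id not in planted])
        assert top > 1.5 * rest


class TestGenerateUtrAnnotation:
    def build(self, shift, seed, rate=2.0, n=400):
        cfg = sim.SimConfig(**{**SMALL, "n_genes": n}, utr_highload_log_shift=shift,
                            mirna_site_rate_per_kb=rate, seed=seed)
        sizes, genes = sim.generate_genome(cfg)
        planted = frozenset(g.gene_id for g in genes[: n // 10])
        ann, sites = sim.generate_utr_annotation(genes, planted, cfg)
        return genes, planted, ann, sites

    def test_zero_rate_no_sites(self):
        *_, sites = self.build(0.0, 41, rate=0.0)
        assert sites == []

    def test_site_count_tracks_utr_length(self):
        genes, planted, ann, sites = self.build(0.0, 42, rate=2.0, n=600)
        per_gene = {}
        for rec in sites:
            per_gene[rec.gene_id] = per_gene.get(rec.gene_id, 0) + 1
        lengths = np.array([ann[g.gene_id].utr3_length for g in genes])
        counts = np.array([per_gene.get(g.gene_id, 0) for g in genes])
        # Poisson expectation: counts ~ rate * length / 1000 (plus ~10% dual labels)
        ratio = counts.sum() / (2.0 * lengths.sum() / 1000)
        assert ratio == pytest.approx(1.1, abs=0.1)
        assert stats.spearmanr(lengths, counts).statistic > 0.7

    def test_planted_shift_lengthens_high_load_utrs(self):
        genes, planted, ann, _ = self.build(np.log(1.39), 43, n=1000)
        top = np.mean([ann[g].utr3_length for g in planted])
        rest = np.mean([ann[g.gene_id].utr3_length
                        for g in genes if g.gene_id not in planted])
        assert top > rest

    def test_lengths_internally_consistent(self):
        genes, planted, ann, _ = self.build(0.0, 44)
        for t in ann.values():
            assert t.spliced_length == t.utr3_length + t.utr5_length + t.cds_length
            assert t.unspliced_length >= t.spliced_length


class TestSimulationBundle:
    def test_full_determinism_and_round_trip(self, tmp_path):
        cfg = sim.SimConfig(**SMALL, seed=17)
        a = sim.simulate_all(cfg)
        b = sim.simulate_all(cfg)
        assert a.planted_top_decile == b.planted_top_decile
        assert a.associations == b.associations
        assert a.ppi_edges == b.ppi_edges
        sim.write_simulation(a, tmp_path)
        from enhload import io as eio

        genes = eio.read_gene_annotation(tmp_path / "genes.tsv")
        assert genes == a.genes
        assert eio.read_edge_list(tmp_path / "ppi.tsv") == {
            (min(x, y), max(x, y)) for x, y in a.ppi_edges
        }
        assert sim.read_transcripts(tmp_path / "transcripts.tsv") == a.transcripts
        assert sim.read_mirna_sites(tmp_path / "mirna_sites.tsv") == a.mirna_sites
        import json

        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth["planted_top_decile"]) == set(a.planted_top_decile)
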
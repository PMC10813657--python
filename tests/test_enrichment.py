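"""Hypergeometric mid-p, star labels, landscapes, CFS/GWAS intersection."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from difcir import (
    CfsAnnotation, EccDnaRecord, GeneModel, HomologMap, HypergeomQuery,
    annotate_cfs, cfs_enrichment, chromosome_enrichment, gwas_intersect,
    hypergeom_midp, intersect_profiles, set_enrichment, significance_stars,
)


def midp_oracle(k, n, K, N):
    """Exact mid-p by hypergeometric pmf built from binomial coefficients."""
    pmf = lambda j: Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    upper = sum(pmf(j) for j in range(k + 1, min(n, K) + 1))
    return float(upper + Fraction(1, 2) * pmf(k))


class TestHypergeomMidp:
    def test_known_values(self):
        assert hypergeom_midp(HypergeomQuery(4, 4, 5, 10)) == pytest.approx(2.5 / 210, rel=1e-12)
        assert hypergeom_midp(HypergeomQuery(0, 4, 0, 10)) == pytest.approx(0.5)
        assert hypergeom_midp(HypergeomQuery(10, 10, 10, 20)) == pytest.approx(
            0.5 / 184756, rel=1e-9)

    def test_equals_draw_enumeration_small_populations(self):
        """Mid-p agrees with literally enumerating every n-subset of the population."""
        for N, K, n in [(8, 3, 4), (9, 5, 3), (10, 5, 4), (7, 7, 2), (6, 0, 3)]:
            population = [1] * K + [0] * (N - K)
            draws = list(itertools.combinations(range(N), n))
            for k in range(max(0, n + K - N), min(n, K) + 1):
                gt = sum(1 for d in draws if sum(population[i] for i in d) > k)
                eq = sum(1 for d in draws if sum(population[i] for i in d) == k)
                expected = (gt + 0.5 * eq) / len(draws)
                assert hypergeom_midp(HypergeomQuery(k, n, K, N)) == pytest.approx(
                    expected, abs=1e-12)

    def test_midp_is_tail_minus_half_point_mass(self):
        from scipy import stats
        rng = np.random.default_rng(2)
        for _ in range(200):
            N = int(rng.integers(2, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            std_upper = stats.hypergeom(N, K, n).sf(k - 1)  # P(X >= k)
            mp = hypergeom_midp(HypergeomQuery(k, n, K, N))
            assert mp == pytest.approx(std_upper - 0.5 * stats.hypergeom(N, K, n).pmf(k),
                                       abs=1e-12)

    def test_rejects_invalid_query(self):
        with pytest.raises(ValueError):
            HypergeomQuery(k=5, n_draws=4, K=5, N=10)
        with pytest.raises(ValueError):
            HypergeomQuery(k=1, n_draws=4, K=11, N=10)


class TestSignificanceStars:
    @pytest.mark.parametrize("p,expected", [
        (0.5, ""), (0.011, ""), (0.01, "*"), (0.005, "*"), (0.0011, "*"),
        (0.001, "**"), (0.0005, "**"), (0.0001, "***"), (8.1695e-9, "*" * 7),
    ])
    def test_decade_brackets(self, p, expected):
        assert significance_stars(p) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            significance_stars(0.0)


class TestChromosomeEnrichment:
    def _setup(self, nd_per_chrom, n_per_chrom):
        genes, records, dppgc = [], [], []
        for chrom, nd in nd_per_chrom.items():
            for i in range(nd):
                sym = f"{chrom}_g{i}"
                genes.append(GeneModel(sym, sym, chrom, 100 * i, 100 * i + 50))
                dppgc.append(sym)
        for chrom, n in n_per_chrom.items():
            for i in range(n):
                records.append(EccDnaRecord("s1", chrom, 10 * i, 10 * i + 5, 2))
        return dppgc, records, genes

    def test_delta_formula(self):
        dppgc, records, genes = self._setup({"chr1": 2, "chr2": 2},
                                            {"chr1": 10, "chr2": 90})
        rows = {r.chrom: r for r in chromosome_enrichment(dppgc, records, genes)}
        # Nd_c=2, N_c=10, Nd_g=4, N_g=100 -> 100*(0.2 - 0.04)
        assert rows["chr1"].delta_c == pytest.approx(16.0)

    def test_uniform_case_all_zero(self):
        dppgc, records, genes = self._setup({"chr1": 2, "chr2": 2},
                                            {"chr1": 50, "chr2": 50})
        for row in chromosome_enrichment(dppgc, records, genes):
            assert row.delta_c == pytest.approx(0.0)

    def test_single_chromosome_degenerate(self):
        dppgc, records, genes = self._setup({"chr1": 3}, {"chr1": 20})
        (row,) = chromosome_enrichment(dppgc, records, genes)
        assert row.delta_c == pytest.approx(0.0)
        assert row.mid_p == pytest.approx(0.5)  # P(X = Nd_g) = 1 in the degenerate draw

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError, match="Mystery"):
            chromosome_enrichment(["Mystery"], [], [])

    def test_conservation_sum_nc_delta_zero(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            chroms = [f"chr{i}" for i in range(1, int(rng.integers(2, 8)))]
            n_per = {c: int(rng.integers(5, 40)) for c in chroms}
            nd_per = {c: int(rng.integers(0, min(5, n_per[c]) + 1)) for c in chroms}
            dppgc, records, genes = self._setup(nd_per, n_per)
            rows = chromosome_enrichment(dppgc, records, genes)
            assert sum(r.n_c * r.delta_c for r in rows) == pytest.approx(0.0, abs=1e-9)


class TestSetEnrichment:
    def test_percentage_matches_hand_counts(self):
        universe = [f"g{i}" for i in range(500)]
        hits = universe[:13]
        target = universe[:2] + universe[100:140]
        res = set_enrichment(hits, universe, target)
        assert res.k == 2 and res.n_draws == 13
        assert res.percentage == pytest.approx(15.38, abs=5e-3)

    def test_disjoint_target(self):
        universe = [f"g{i}" for i in range(50)]
        res = set_enrichment(universe[:5], universe, universe[40:])
        assert res.percentage == 0.0 and res.mid_p >= 0.5

    def test_empty_hits_flagged(self):
        res = set_enrichment([], ["a", "b"], ["a"])
        assert res.flagged and res.mid_p == 1.0 and res.percentage == 0.0

    def test_order_invariance(self):
        universe = [f"g{i}" for i in range(100)]
        hits, target = universe[10:30], universe[20:60]
        a = set_enrichment(hits, universe, target)
        b = set_enrichment(reversed(hits), reversed(universe), reversed(target))
        assert (a.k, a.K, a.N, a.mid_p) == (b.k, b.K, b.N, b.mid_p)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="not contained"):
            set_enrichment(["x"], ["a"], ["a"])


class TestCfsAnnotation:
    def setup_method(self):
        self.cfs = [CfsAnnotation("DAB1", "FRA1B", "chr1", "aphidicolin"),
                    CfsAnnotation("DAB1", "FRA1X", "chr1", "BrdU"),
                    CfsAnnotation("AUTS2", "FRA7J", "chr7", "folic acid")]
        self.map = HomologMap([("Dab1", "DAB1"), ("Auts2", "AUTS2")])

    def test_homolog_mapped_label(self):
        labels = annotate_cfs(["Dab1"], self.cfs, self.map)
        assert ("FRA1B", "aphidicolin") in labels["Dab1"]

    def test_unmapped_gene_unlabeled(self):
        assert annotate_cfs(["Nope"], self.cfs, self.map)["Nope"] == []

    def test_two_sites_two_labels_one_pooled_membership(self):
        labels = annotate_cfs(["Dab1"], self.cfs, self.map)
        assert len(labels["Dab1"]) == 2
        universe = ["Dab1", "Auts2", "Other1", "Other2", "Other3"]
        res = cfs_enrichment(["Dab1", "Other1"], universe, self.cfs, self.map)
        assert res.k == 1  # pooled membership counts once

    def test_identity_map_within_species(self):
        labels = annotate_cfs(["dab1"], self.cfs, None)  # case-insensitive match
        assert labels["dab1"] == [("FRA1B", "aphidicolin"), ("FRA1X", "BrdU")]


class TestGwasIntersect:
    def make_table(self):
        return pd.DataFrame({
            "DISEASE/TRAIT": ["systemic lupus erythematosus"] * 3 + ["other trait"],
            "MAPPED_GENE": ["JAZF1, TSPAN14", "DOCK10", "BACH2; IRF4", "XYZ1"],
        })

    def test_three_common_genes(self):
        common, res = gwas_intersect(
            ["JAZF1", "DOCK10", "BACH2", "NOPE"], self.make_table(),
            "systemic lupus erythematosus",
            universe=["JAZF1", "DOCK10", "BACH2", "NOPE", "A", "B"])
        assert common == ["JAZF1", "DOCK10", "BACH2"]
        assert res.k == 3

    def test_cell_splitting(self):
        from difcir.enrichment import split_mapped_genes
        assert split_mapped_genes("JAZF1, TSPAN14") == ["JAZF1", "TSPAN14"]
        assert split_mapped_genes("A - B") == ["A", "B"]
        assert split_mapped_genes("HLA-DQB1") == ["HLA-DQB1"]  # hyphenated name intact

    def test_absent_trait_flagged_empty(self):
        common, res = gwas_intersect(["JAZF1"], self.make_table(), "no such trait",
                                     universe=["JAZF1", "A"])
        assert common == [] and res.flagged

    def test_empty_query(self):
        common, _ = gwas_intersect([], self.make_table(),
                                   "systemic lupus erythematosus", universe=["A"])
        assert common == []


class TestIntersectProfiles:
    def test_rank_order_and_dedup(self):
        homologs = HomologMap([("Rorb", "RORB"), ("Fto", "FTO"), ("Tnik", "TNIK")])
        pairs = intersect_profiles(["Fto", "Rorb", "Tnik", "Fto"],
                                   ["RORB", "FTO", "OTHER"], homologs)
        assert pairs == [("Fto", "FTO"), ("Rorb", "RORB")]

    def test_disjoint_empty(self):
        assert intersect_profiles(["A"], ["B"], HomologMap([("A", "AA")])) == []

    def test_identity_single_gene(self):
        assert intersect_profiles(["G"], ["G"], HomologMap.identity()) == [("G", "G")]
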
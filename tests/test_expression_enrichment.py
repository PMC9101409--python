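import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import oracles
from eccatlas import expression_enrichment as ee
from eccatlas.gene_content import ClassifiedCohort
from eccatlas.io_formats import Circle, GenomicInterval, ValidationError


def _classified(circle_genes_by_tumor, all_genes):
    """Minimal ClassifiedCohort: one pseudo-circle per tumor holding its genes."""
    with_genes, without_genes, cg, gg = {}, {}, {}, {}
    for tumor, genes in circle_genes_by_tumor.items():
        c = Circle(GenomicInterval("chr1", 0, 10), tumor, f"{tumor}_c0")
        with_genes[tumor] = [c] if genes else []
        without_genes[tumor] = [] if genes else [c]
        if genes:
            cg[(tumor, c.circle_id)] = set(genes)
        gg[tumor] = set(all_genes) - set(genes)
    return ClassifiedCohort(with_genes, without_genes, cg, gg, set(all_genes))


class TestTumorStats:
    def test_percent_and_mean_over_expressed_only(self):
        genes = ["A", "B", "C", "D", "E", "F"]
        cl = _classified({"T0": {"A", "B", "C", "D"}}, genes)
        expr = pd.DataFrame({"T0": [1.0, 2.0, 0.0, 4.0, 5.0, 0.0]}, index=genes)
        (s,) = ee.tumor_expression_stats(cl, expr)
        assert s.pct_expressed_circle == pytest.approx(75.0)
        assert s.mean_fpkm_circle == pytest.approx(7 / 3)
        assert s.pct_expressed_genome == pytest.approx(50.0)
        assert s.mean_fpkm_genome == pytest.approx(5.0)

    def test_identical_compositions_give_p_one(self):
        genes = [f"G{i}" for i in range(8)]
        cl = _classified({"T0": set(genes[:4])}, genes)
        expr = pd.DataFrame({"T0": [1, 0, 2, 0, 3, 0, 4, 0]}, index=genes,
                            dtype=float)
        (s,) = ee.tumor_expression_stats(cl, expr)
        assert s.fisher_p == pytest.approx(1.0)

    def test_missing_tumor_skipped(self):
        cl = _classified({"T0": {"A"}, "T1": {"B"}}, ["A", "B"])
        expr = pd.DataFrame({"T0": [1.0, 2.0]}, index=["A", "B"])
        out = ee.tumor_expression_stats(cl, expr)
        assert [s.tumor_id for s in out] == ["T0"]

    def test_no_circle_genes_flagged_not_fabricated(self):
        cl = _classified({"T0": set()}, ["A", "B"])
        expr = pd.DataFrame({"T0": [1.0, 2.0]}, index=["A", "B"])
        (s,) = ee.tumor_expression_stats(cl, expr)
        assert np.isnan(s.pct_expressed_circle)
        assert np.isnan(s.fisher_p)


class TestFisherOracles:
    def test_two_sided_example(self):
        p = float(sps.fisher_exact([[8, 2], [2, 8]])[1])
        assert p == pytest.approx(oracles.fisher_two_sided(8, 2, 2, 8))
        assert p == pytest.approx(0.0230, abs=5e-4)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            assert float(sps.fisher_exact([[a, b], [c, d]])[1]) == pytest.approx(
                oracles.fisher_two_sided(a, b, c, d), rel=1e-9)
            assert float(
                sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            ) == pytest.approx(oracles.fisher_greater(a, b, c, d), rel=1e-9)


class TestCombinePvalues:
    def test_single_p_identity(self):
        for p in (0.01, 0.5, 0.999):
            assert ee.combine_pvalues_fisher([p]) == pytest.approx(p)

    def test_two_halves_closed_form(self):
        # X2 = -2*2*ln(0.5) = 2.7726, df 4 -> exp(-x/2) * (1 + x/2)
        assert ee.combine_pvalues_fisher([0.5, 0.5]) == pytest.approx(
            0.5966, abs=1e-4)
        assert ee.combine_pvalues_fisher([0.5, 0.5]) == pytest.approx(
            oracles.fisher_combined([0.5, 0.5]))

    def test_all_ones(self):
        assert ee.combine_pvalues_fisher([1.0, 1.0]) == pytest.approx(1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            ee.combine_pvalues_fisher([0.0, 0.5])


class TestPerType:
    def _stats(self, deltas, type_map):
        out = []
        rng = np.random.default_rng(0)
        for i, d in enumerate(deltas):
            base = 50 + rng.normal(0, 2)
            out.append(ee.TumorExpressionStats(
                tumor_id=f"T{i}", n_circle_genes=10, n_genome_genes=100,
                pct_expressed_circle=base + d, pct_expressed_genome=base,
                mean_fpkm_circle=5 + d, mean_fpkm_genome=5.0,
                fisher_p=0.5))
        return out, type_map

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(1)
        deltas = 1 + rng.normal(0, 0.3, size=20)
        stats_list, tmap = self._stats(deltas, {f"T{i}": "BRCA" for i in range(20)})
        df = ee.per_type_comparison(stats_list, tmap)
        assert df.loc[df["type"] == "BRCA", "p_pct"].iloc[0] < 0.05

    def test_single_tumor_type_skipped(self):
        stats_list, tmap = self._stats([1.0], {"T0": "LONE"})
        assert ee.per_type_comparison(stats_list, tmap).empty


class TestSdThreshold:
    def test_hand_computed_cutoff(self):
        # mean 3.25, sample SD 4.5, cutoff 7.75
        assert ee.sd_threshold_list({"A": 1, "B": 1, "C": 1, "D": 10}, 1) == ["D"]

    def test_all_equal_is_empty(self):
        assert ee.sd_threshold_list({"A": 2, "B": 2, "C": 2}, 1) == []

    def test_k_zero_is_strictly_above_mean(self):
        assert ee.sd_threshold_list({"A": 1, "B": 2, "C": 3}, 0) == ["C"]

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20, unique=True),
           st.floats(0.1, 10), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, values, scale, shift):
        names = [f"g{i}" for i in range(len(values))]
        base = dict(zip(names, values))
        scaled = {k: scale * v + shift for k, v in base.items()}
        assert ee.sd_threshold_list(base, 1.5) == ee.sd_threshold_list(scaled, 1.5)


class TestCommonality:
    def test_conjunction_of_circle_and_expressed(self):
        cl = _classified({"T0": {"A"}, "T1": {"A"}, "T2": {"A"}, "T3": {"B"}},
                         ["A", "B"])
        expr = pd.DataFrame(
            {"T0": [1.0, 0.0], "T1": [2.0, 0.0], "T2": [0.0, 1.0],
             "T3": [0.0, 0.0]},
            index=["A", "B"])
        counts = ee.commonality_ranking(cl, expr)
        assert counts["A"] == 2  # in circles of 3 tumors, expressed in 2
        assert counts["B"] == 0


class TestGeneSetEnrichment:
    UNIVERSE = [f"G{i}" for i in range(20)]
    GMT = {"HIT": set(f"G{i}" for i in range(5)),
           "MISS": set(f"G{i}" for i in range(15, 20))}

    def test_standard_matches_hypergeometric_tail(self):
        df = ee.gene_set_enrichment(
            ["G0", "G1", "G2", "G3", "G15"], self.UNIVERSE, self.GMT,
            mode="standard").set_index("set_name")
        # universe 20, list 5, set 5, overlap 4
        assert df.loc["HIT", "p"] == pytest.approx(
            oracles.fisher_greater(4, 1, 1, 14))
        assert df.loc["HIT", "p"] == pytest.approx(76 / 15504)
        assert df.loc["HIT", "overlap_count"] == 4

    def test_zero_overlap_gives_p_one(self):
        df = ee.gene_set_enrichment(["G10", "G11"], self.UNIVERSE,
                                    {"S": {"G0", "G1"}}, mode="standard")
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_perfect_overlap_is_top_ranked(self):
        gmt = {"PERFECT": set(self.UNIVERSE[:10]), **self.GMT}
        df = ee.gene_set_enrichment(self.UNIVERSE[:10], self.UNIVERSE, gmt,
                                    mode="standard")
        assert df["set_name"].iloc[0] == "PERFECT"

    def test_ease_mode_is_more_conservative(self):
        std = ee.gene_set_enrichment(
            ["G0", "G1", "G2", "G3", "G15"], self.UNIVERSE, self.GMT,
            mode="standard").set_index("set_name")
        ease = ee.gene_set_enrichment(
            ["G0", "G1", "G2", "G3", "G15"], self.UNIVERSE, self.GMT,
            mode="ease").set_index("set_name")
        assert ease.loc["HIT", "p"] >= std.loc["HIT", "p"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            ee.gene_set_enrichment([], self.UNIVERSE, self.GMT)


class TestTally:
    def _per_tumor(self, ps_by_tumor):
        return {
            t: pd.DataFrame([{"set_name": name, "p": p}
                             for name, p in ps.items()])
            for t, ps in ps_by_tumor.items()
        }

    def test_counts_tumors_below_alpha(self):
        per = self._per_tumor({
            "T0": {"S": 0.01}, "T1": {"S": 0.04}, "T2": {"S": 0.2},
            "T3": {"S": 0.001}})
        tally = ee.tally_pathways(per, alpha=0.05)
        assert tally["S"] == 3

    def test_alpha_zero_counts_nothing(self):
        per = self._per_tumor({"T0": {"S": 1e-10}})
        assert ee.tally_pathways(per, alpha=0.0)["S"] == 0


def test_null_fisher_p_is_superuniform():
    """Under a true null the exact test is conservative: P(p <= a) <= a."""
    rng = np.random.default_rng(17)
    ps = []
    for _ in range(400):
        c = int(rng.binomial(150, 0.5))
        g = int(rng.binomial(150, 0.5))
        ps.append(float(sps.fisher_exact([[c, 150 - c], [g, 150 - g]])[1]))
    ps = np.array(ps)
    for alpha in (0.01, 0.05, 0.1, 0.25):
        # three-sigma Monte-Carlo slack on 400 draws
        slack = 3 * np.sqrt(alpha * (1 - alpha) / ps.size)
        assert (ps <= alpha).mean() <= alpha + slack
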
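import itertools

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_dna
from eccatlas import breakpoint_homology as bh
from eccatlas import null_controls as nc
from eccatlas.io_formats import Circle, GenomicInterval


class TestWindowExtraction:
    def test_window_coordinates(self, planted_scenario):
        ref = planted_scenario.reference
        circle = Circle(GenomicInterval("chr1", 10_000, 12_000), "T0", "c0")
        pair = bh.extract_window_pair(circle, ref, 500)
        assert pair.start_window == ref.fetch("chr1", 9_500, 10_500)
        assert pair.end_window == ref.fetch("chr1", 11_500, 12_500)

    def test_circle_equal_to_twice_flank_is_filtered(self, planted_scenario):
        circle = Circle(GenomicInterval("chr1", 10_000, 11_000), "T0", "c0")
        assert bh.extract_window_pair(circle, planted_scenario.reference,
                                      500) is None

    def test_201_bp_circle_accepted_in_microhomology_mode(self, planted_scenario):
        circle = Circle(GenomicInterval("chr1", 10_000, 10_201), "T0", "c0")
        pair = bh.extract_window_pair(circle, planted_scenario.reference, 100)
        assert pair is not None and len(pair.start_window) == 200

    def test_window_off_chromosome_is_skipped(self, planted_scenario):
        circle = Circle(GenomicInterval("chr1", 100, 2000), "T0", "c0")
        assert bh.extract_window_pair(circle, planted_scenario.reference,
                                      500) is None


class TestLocalAlign:
    def test_identical_sequences_single_full_hit(self, rng):
        seq = random_dna(rng, 100)
        params = bh.AlignerParams(word_size=4)
        hits = bh.local_align(seq, seq, params)
        assert len(hits) == 1
        h = hits[0]
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (0, 100, 0, 100)
        assert h.length == 100 and h.n_mismatch == 0 and h.score == 200

    def test_planted_exact_30mer_found_with_word_28(self, rng):
        core = random_dna(rng, 30)
        q = random_dna(rng, 35) + core + random_dna(rng, 35)
        s = random_dna(rng, 50) + core + random_dna(rng, 20)
        hits = bh.local_align(q, s, bh.AlignerParams.homology())
        assert hits and hits[0].length >= 30
        assert hits[0].q_start <= 35 and hits[0].q_end >= 65

    def test_no_shared_word_no_hits(self):
        params = bh.AlignerParams(word_size=4, both_strands=False)
        assert bh.local_align("A" * 50, "C" * 50, params) == []

    def test_n_never_matches(self):
        params = bh.AlignerParams(word_size=4, both_strands=False)
        assert bh.local_align("N" * 50, "N" * 50, params) == []

    def test_reverse_complement_hit_found_and_mapped(self, rng):
        core = random_dna(rng, 40)
        q = random_dna(rng, 30) + core + random_dna(rng, 30)
        from eccatlas._swalign import revcomp
        s = random_dna(rng, 10) + revcomp(core) + random_dna(rng, 50)
        hits = bh.local_align(q, s, bh.AlignerParams(word_size=28))
        assert hits and hits[0].strand == "-"
        # the hit covers the planted core (chance extension by a base is fine)
        assert hits[0].s_start <= 10 and hits[0].s_end >= 50
        assert hits[0].length >= 40

    def test_matches_exhaustive_smith_waterman_on_small_pairs(self, rng):
        params = bh.AlignerParams(word_size=1, both_strands=False)
        strings = ["".join(t) for L in range(1, 5)
                   for t in itertools.product("AC", repeat=L)]
        for q in strings[::3]:
            for s in strings[::3]:
                hits = bh.local_align(q, s, params)
                got = hits[0].score if hits else 0
                assert got == oracles.smith_waterman_score(q, s)
        for _ in range(300):
            q = random_dna(rng, int(rng.integers(1, 13)))
            s = random_dna(rng, int(rng.integers(1, 13)))
            hits = bh.local_align(q, s, params)
            got = hits[0].score if hits else 0
            assert got == oracles.smith_waterman_score(q, s)

    def test_self_alignment_maximality(self, rng):
        params = bh.AlignerParams(word_size=4, both_strands=False)
        x = random_dna(rng, 60)
        self_score = bh.local_align(x, x, params)[0].score
        for _ in range(20):
            y = nc.scramble_sequence(x, rng)
            hits = bh.local_align(x, y, params)
            assert (hits[0].score if hits else 0) <= self_score


class TestEvalue:
    def test_strictly_decreasing_in_score(self):
        p = bh.AlignerParams()
        es = [p.evalue(s, 1000, 1000) for s in range(10, 100)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_scales_with_search_space(self):
        p = bh.AlignerParams()
        assert p.evalue(50, 2000, 1000) == pytest.approx(
            2 * p.evalue(50, 1000, 1000))
        assert p.evalue(50, 1000, 2000) == pytest.approx(
            2 * p.evalue(50, 1000, 1000))

    def test_lambda_solver_reproduces_published_scale(self):
        # ungapped lambda for +2/-3 at uniform composition
        lam = bh.karlin_altschul_lambda(2, -3)
        assert lam == pytest.approx(0.634, abs=5e-3)
        # the expected-score condition must hold at the solution
        assert 0.25 * np.exp(lam * 2) + 0.75 * np.exp(-lam * 3) == pytest.approx(1)


class TestCohortScan:
    def test_planted_homology_recovered(self, planted_scenario):
        s = planted_scenario
        res = bh.scan_cohort(s.cohort, s.reference, "homology")
        planted = set(s.truth["homologous_circle_ids"])
        sub = res[res.circle_id.isin(planted)]
        assert len(sub) > 100
        assert sub.has_hit.all()
        assert (sub.loc[sub.has_hit, "length"] >= 100).all()

    def test_scrambled_windows_lose_all_homology(self, planted_scenario):
        s = planted_scenario
        pairs = bh.collect_window_pairs(s.cohort, s.reference, 500)
        scram = bh.scramble_window_pairs(pairs, seed=99)
        res = bh.scan_windows(scram, bh.AlignerParams.homology())
        assert len(res) > 500
        assert res.has_hit.sum() == 0

    def test_short_plants_visible_only_in_microhomology_mode(self, planted_scenario):
        s = planted_scenario
        planted = set(s.truth["microhomologous_circle_ids"])
        micro = bh.scan_cohort(s.cohort, s.reference, "microhomology")
        sub = micro[micro.circle_id.isin(planted)]
        assert sub.has_hit.mean() >= 0.95
        hom = bh.scan_cohort(s.cohort, s.reference, "homology")
        subh = hom[hom.circle_id.isin(planted)]
        # 12-bp plants cannot seed a 28-bp word; residual hits can only come
        # from genuine overlap homology between co-located circles
        assert subh.has_hit.mean() < 0.10

    def test_trace_peaks_on_breakpoint(self, planted_scenario):
        s = planted_scenario
        res = bh.scan_cohort(s.cohort, s.reference, "homology")
        planted = res[res.circle_id.isin(set(s.truth["homologous_circle_ids"]))]
        trace = bh.position_trace(planted, 500)
        assert trace.value_at(0) == trace.values.max()
        # nearly every best hit covers the breakpoint (a circle overlapping
        # another planted circle can have a longer off-center best hit)
        assert trace.value_at(0) >= 0.99 * trace.n_contributing


class TestGroupSummary:
    def _df(self, tumor_hits):
        rows = []
        for tumor, hits in tumor_hits.items():
            for i, (has, length) in enumerate(hits):
                rows.append({"tumor_id": tumor, "circle_id": f"{tumor}_c{i}",
                             "has_hit": has, "length": length,
                             "q_start": 0, "q_end": length})
        return pd.DataFrame(rows)

    def test_identical_groups_f_zero_p_one(self):
        df = self._df({"T0": [(True, 10), (False, 0)],
                       "T1": [(True, 10), (False, 0)]})
        comp = bh.summarize_groups({"a": df, "b": df.copy(), "c": df.copy()})
        assert comp.anova_pct == (0.0, 1.0)

    def test_tukey_flags_only_shifted_group(self):
        (f, p), tukey = bh._anova(
            [np.array([1.0, 2, 3]), np.array([11.0, 12, 13]),
             np.array([1.0, 2, 3])],
            ["a", "b", "c"])
        assert p < 1e-3
        tuk = tukey.set_index(["group_a", "group_b"])["p"]
        assert tuk[("a", "b")] < 0.01
        assert tuk[("b", "c")] < 0.01
        assert tuk[("a", "c")] > 0.9

    def test_planted_fraction_separates_real_from_controls(self, planted_scenario):
        s = planted_scenario
        real = bh.scan_cohort(s.cohort, s.reference, "homology")
        rand_cohort = nc.generate_random_circles(
            s.cohort, s.layout, nc.RandomizationSpec(seed=13))
        rand = bh.scan_cohort(rand_cohort, s.reference, "homology")
        pairs = bh.collect_window_pairs(s.cohort, s.reference, 500)
        scram = bh.scan_windows(bh.scramble_window_pairs(pairs, 14),
                                bh.AlignerParams.homology())
        comp = bh.summarize_groups(
            {"real": real, "random_control": rand, "scrambled": scram})
        by_group = {g.group: g for g in comp.summaries}
        assert by_group["real"].pct_with_hit > 25
        assert by_group["real"].pct_with_hit > by_group["random_control"].pct_with_hit
        assert by_group["scrambled"].pct_with_hit == 0.0
        assert comp.anova_pct[1] < 1e-6
        tuk = comp.tukey_pct.set_index(["group_a", "group_b"])["p"]
        assert tuk[("real", "random_control")] < 0.001
        assert tuk[("real", "scrambled")] < 0.001


class TestPositionTrace:
    def _df(self, spans):
        rows = []
        for i, (qs, qe) in enumerate(spans):
            rows.append({"tumor_id": "T0", "circle_id": f"c{i}", "has_hit": True,
                         "length": qe - qs, "q_start": qs, "q_end": qe})
        return pd.DataFrame(rows,
                            columns=["tumor_id", "circle_id", "has_hit",
                                     "length", "q_start", "q_end"])

    def test_offset_arithmetic(self):
        trace = bh.position_trace(self._df([(490, 511)]), 500)
        assert trace.values.sum() == 21
        assert trace.value_at(-10) == 1 and trace.value_at(10) == 1
        assert trace.value_at(-11) == 0 and trace.value_at(11) == 0

    def test_no_hits_all_zero(self):
        df = self._df([])
        trace = bh.position_trace(df, 500)
        assert trace.values.sum() == 0 and trace.n_contributing == 0

    def test_trace_mass_equals_total_hit_length(self):
        spans = [(0, 100), (450, 700), (990, 1000)]
        trace = bh.position_trace(self._df(spans), 500)
        assert trace.values.sum() == sum(e - s for s, e in spans)
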
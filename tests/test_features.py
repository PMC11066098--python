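"""Peak/gene integration statistics: overlaps, significance, metagenes,
enhancer distances, super-enhancers, DE summaries, qPCR arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spherotad.features import (PeakSet, overlap_peaks, overlap_counts,
                                overlap_significance, peak_density_by_tad_class,
                                tss_metagene, enhancer_distance,
                                call_super_enhancers, assign_se_genes,
                                tangent_cutoff_index, de_summary, classify_de,
                                chip_qpcr_enrichment)
from spherotad.tads import boundaries_to_tads
from spherotad.tadcompare import compare_tads


def _peaks(intervals, name="p", chrom="c"):
    df = pd.DataFrame(intervals, columns=["start", "end"])
    df.insert(0, "chrom", chrom)
    df["score"] = 1.0
    return PeakSet(name=name, intervals=df.sort_values("start").reset_index(drop=True))


class TestOverlap:
    def test_identical_sets_fully_shared(self):
        a = _peaks([(0, 10), (20, 30)])
        ov = overlap_peaks(a, a)
        assert ov["pct_shared_a"] == 100.00 and ov["pct_shared_b"] == 100.00

    def test_printed_count_mode_percentage(self):
        ov = overlap_counts(93_850, 38_542, 37_342, 37_342)
        assert ov["pct_shared_b"] == 96.88

    def test_random_toys_match_all_pairs_scan(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            mk = lambda: _peaks([(s, s + rng.integers(5, 30))
                                 for s in rng.integers(0, 500, size=10)])
            a, b = mk(), mk()
            ov = overlap_peaks(a, b)
            sa = sum(1 for ra in a.intervals.itertuples()
                     if any(ra.start < rb.end and rb.start < ra.end
                            for rb in b.intervals.itertuples()))
            sb = sum(1 for rb in b.intervals.itertuples()
                     if any(ra.start < rb.end and rb.start < ra.end
                            for ra in a.intervals.itertuples()))
            assert ov["shared_a"] == sa and ov["shared_b"] == sb

    def test_unsorted_input_warns_and_sorts(self):
        df = pd.DataFrame({"chrom": "c", "start": [50, 0], "end": [60, 10]})
        with pytest.warns(UserWarning, match="unsorted"):
            ps = PeakSet("x", df)
        assert list(ps.intervals["start"]) == [0, 50]


class TestOverlapSignificance:
    def test_saturated_set_gives_p_one(self):
        w = 10
        a = _peaks([(i * w, (i + 1) * w) for i in range(20)])
        b = _peaks([(30, 40), (100, 110)])
        res = overlap_significance(a, b, universe=(0, 200))
        assert res["fold"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_exact_enumeration_small_universes(self):
        # hit-bin configurations checked against first-principles tail sums
        w = 10
        for M, nA, nB, k in [(20, 5, 8, 4), (25, 10, 10, 3), (12, 4, 6, 1),
                             (15, 7, 5, 5)]:
            a_bins = list(range(nA))
            b_bins = list(range(nA - k, nA - k + nB))
            a = _peaks([(i * w, (i + 1) * w) for i in a_bins])
            b = _peaks([(i * w, (i + 1) * w) for i in b_bins])
            res = overlap_significance(a, b, universe=(0, M * w))
            inter = len(set(a_bins) & set(b_bins))
            assert res["observed"] == inter

            def hyp(i):
                return (math.comb(nA, i) * math.comb(M - nA, nB - i)
                        / math.comb(M, nB))

            if res["tail"] == "enrichment":
                exact = sum(hyp(i) for i in range(inter, min(nA, nB) + 1))
            else:
                exact = sum(hyp(i) for i in range(0, inter + 1))
            assert res["p"] == pytest.approx(exact, rel=1e-10)

    def test_disjoint_sets_depleted(self):
        w = 10
        a = _peaks([(i * w, (i + 1) * w) for i in range(5)])
        b = _peaks([(i * w, (i + 1) * w) for i in range(10, 18)])
        res = overlap_significance(a, b, universe=(0, 200))
        assert res["fold"] < 1 and res["tail"] == "depletion"

    def test_peak_outside_universe_raises(self):
        a = _peaks([(0, 10)])
        b = _peaks([(500, 600)])
        with pytest.raises(ValueError):
            overlap_significance(a, b, universe=(0, 100))

    def test_permutation_mode_runs(self):
        rng = np.random.default_rng(0)
        a = _peaks([(s, s + 20) for s in rng.integers(0, 10_000, size=30)])
        b = _peaks([(s, s + 20) for s in rng.integers(0, 10_000, size=30)])
        res = overlap_significance(a, b, universe=(0, 11_000),
                                   method="permutation", n_perm=200, seed=1)
        assert 0 < res["p"] <= 1


class TestDensityAndMetagene:
    def test_uniform_peaks_similar_density_across_classes(self):
        a = boundaries_to_tads([(20, 1.0), (40, 1.0)], 60, min_tad_bins=1)
        ch = compare_tads(a, a)
        peaks = _peaks([(s, s + 100) for s in range(0, 6_000_000, 50_000)])
        res = peak_density_by_tad_class(peaks, ch)
        d = res["densities"]["conserved"]
        assert np.allclose(d, d[0], rtol=0.1)

    def test_empty_class_absent(self):
        a = boundaries_to_tads([(10, 1.0)], 20, min_tad_bins=1)
        ch = compare_tads(a, a)
        res = peak_density_by_tad_class(_peaks([(5, 10)]), ch)
        assert set(res["densities"]) == {"conserved"}

    @staticmethod
    def _genes(tss, strand):
        return pd.DataFrame({"chrom": "c", "tss": tss, "strand": strand},
                            index=[f"g{i}" for i in range(len(tss))])

    def test_no_peaks_zero_profile(self):
        prof = tss_metagene(_peaks([]), self._genes([10_000], ["+"]),
                            flank_bp=1000, bin_bp=100)
        assert np.all(prof["profile"] == 0)

    def test_peaks_at_tss_separate_sets(self):
        gs = self._genes([10_000, 50_000], ["+", "+"])
        gr = self._genes([200_000], ["+"])
        peaks = _peaks([(9_950, 10_050), (49_950, 50_050)])
        prof = tss_metagene(peaks, gs, flank_bp=1000, bin_bp=100,
                            random_genes=gr)
        n = len(prof["profile"])
        assert prof["profile"][n // 2] == 1.0
        assert prof["profile_random"][n // 2] == 0.0

    def test_minus_strand_orientation(self):
        # peak 1 kb downstream of a minus-strand TSS appears at +1 kb
        g = self._genes([100_000], ["-"])
        peaks = _peaks([(98_950, 99_050)])   # downstream = lower coords on minus
        prof = tss_metagene(peaks, g, flank_bp=2000, bin_bp=100)
        pos = prof["positions_bp"][prof["profile"] > 0]
        assert (pos > 0).all() and (np.abs(pos - 1000) <= 100).any()

    def test_strand_mirror_property(self):
        rng = np.random.default_rng(2)
        tss = list(rng.integers(10_000, 500_000, size=8))
        peaks = _peaks([(s, s + 200) for s in rng.integers(0, 510_000, size=40)])
        plus = tss_metagene(peaks, self._genes(tss, ["+"] * 8),
                            flank_bp=2000, bin_bp=100)
        minus = tss_metagene(peaks, self._genes(tss, ["-"] * 8),
                             flank_bp=2000, bin_bp=100)
        np.testing.assert_allclose(minus["profile"], plus["profile"][::-1])


class TestEnhancerDistance:
    @staticmethod
    def _gene_table(tss, de_class):
        return pd.DataFrame({"chrom": "c", "tss": tss, "de_class": de_class},
                            index=[f"g{i}" for i in range(len(tss))])

    def test_null_when_set_equals_universe(self):
        rng = np.random.default_rng(12)
        tss = rng.integers(0, 10_000_000, size=400)
        genes = self._gene_table(tss, ["ns"] * 400)
        peaks = _peaks([(s, s + 200) for s in rng.integers(0, 10_000_000, size=100)])
        res = enhancer_distance(peaks, peaks, genes, genes, n_random=400, seed=3)
        assert 0.05 < res["p"] < 0.95

    def test_planted_proximity_highly_significant(self):
        rng = np.random.default_rng(7)
        set_tss = np.arange(200) * 2_000_000 + 500_000
        far_tss = set_tss + 1_000_000
        genes = self._gene_table(np.concatenate([set_tss, far_tss]),
                                 ["down"] * 200 + ["ns"] * 200)
        gene_set = genes[genes["de_class"] == "down"]
        enh = _peaks([(t + 5_000, t + 6_000) for t in set_tss])
        res = enhancer_distance(enh, enh, genes, gene_set, seed=5)
        assert res["p"] < 1e-6
        assert res["median_set"] < res["median_random"]

    def test_zero_enhancers_warns(self):
        genes = self._gene_table([1000], ["ns"])
        peaks = _peaks([(0, 100)])
        acetyl = _peaks([(5_000, 6_000)])
        with pytest.warns(UserWarning, match="no enhancer"):
            res = enhancer_distance(peaks, acetyl, genes, genes)
        assert res["n_enhancers"] == 0


class TestSuperEnhancers:
    def test_distant_peaks_not_stitched(self):
        ps = _peaks([(0, 1000), (50_000, 51_000), (100_000, 101_000)])
        se = call_super_enhancers(ps, stitch_bp=12_500)
        assert len(se.regions) == 3

    def test_geometric_series_cutoff_matches_slope_scan(self):
        signals = [2.0 ** k for k in range(13)]
        ps = _peaks([(i * 100_000, i * 100_000 + 1000) for i in range(13)])
        ps.intervals["score"] = signals
        se = call_super_enhancers(ps, stitch_bp=1000)
        # independent brute-force slope scan on the rescaled curve
        y = np.sort(signals) / max(signals)
        x = np.arange(13) / 12.0
        idx = next(i for i in range(12) if (y[i + 1] - y[i]) / (x[i + 1] - x[i]) >= 1)
        assert se.cutoff_rank == idx
        assert tangent_cutoff_index(np.sort(np.array(signals))) == idx

    def test_cutoff_invariant_under_scaling(self):
        rng = np.random.default_rng(9)
        scores = np.sort(rng.lognormal(2, 1.2, size=50))
        ps = _peaks([(i * 100_000, i * 100_000 + 1000) for i in range(50)])
        ps.intervals["score"] = scores
        se1 = call_super_enhancers(ps, stitch_bp=1000)
        ps.intervals["score"] = scores * 1000
        se2 = call_super_enhancers(ps, stitch_bp=1000)
        assert se1.cutoff_rank == se2.cutoff_rank
        assert se1.n_super == se2.n_super

    def test_identical_inputs_full_overlap(self):
        rng = np.random.default_rng(3)
        ps = _peaks([(i * 50_000, i * 50_000 + 2000) for i in range(30)])
        ps.intervals["score"] = rng.lognormal(2, 1, size=30)
        se_a = call_super_enhancers(ps)
        se_b = call_super_enhancers(ps)
        pd.testing.assert_frame_equal(se_a.regions, se_b.regions)

    def test_too_few_regions_warns_none_super(self):
        ps = _peaks([(0, 1000), (500_000, 501_000)])
        with pytest.warns(UserWarning, match="fewer than 3"):
            se = call_super_enhancers(ps)
        assert se.n_super == 0

    def test_gene_assignment_window(self):
        ps = _peaks([(i * 200_000, i * 200_000 + 2000) for i in range(10)])
        ps.intervals["score"] = [1.0] * 9 + [1000.0]
        se = call_super_enhancers(ps, stitch_bp=1000)
        assert se.n_super == 1
        top = se.supers().iloc[0]
        genes = pd.DataFrame({
            "chrom": "c",
            "tss": [top["start"] - 10_000, top["start"] - 200_000],
        }, index=["near", "far"])
        mapping = assign_se_genes(se, genes, window_bp=50_000)
        assert list(mapping["gene_id"]) == ["near"]


class TestDeSummary:
    @staticmethod
    def _table(n_up, n_down, n_ns, lfc=2.0, p=0.05, rng=None):
        rng = rng or np.random.default_rng(0)
        rows = []
        rows += [{"log2FC": lfc + rng.uniform(0, 3), "padj": p * rng.uniform(0, 0.99)}
                 for _ in range(n_up)]
        rows += [{"log2FC": -(lfc + rng.uniform(0, 3)), "padj": p * rng.uniform(0, 0.99)}
                 for _ in range(n_down)]
        rows += [{"log2FC": rng.uniform(-lfc * 0.9, lfc * 0.9), "padj": rng.uniform(p, 1)}
                 for _ in range(n_ns)]
        return pd.DataFrame(rows)

    def test_reported_transcript_totals(self):
        t = self._table(619, 1758, 500)
        res = de_summary(t, lfc_thresh=2.0, p_thresh=0.05)
        assert res == {"n_up": 619, "n_down": 1758, "n_total": 2377}

    def test_empty_table_zeroes(self):
        t = pd.DataFrame({"log2FC": [], "padj": []})
        assert de_summary(t) == {"n_up": 0, "n_down": 0, "n_total": 0}

    def test_matches_row_by_row_filter(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame({"log2FC": rng.normal(0, 2, 500),
                          "padj": rng.uniform(0, 1, 500)})
        res = de_summary(t, lfc_thresh=1.0, p_thresh=0.05)
        up = sum(1 for _, r in t.iterrows()
                 if r.log2FC >= 1.0 and r.padj < 0.05)
        down = sum(1 for _, r in t.iterrows()
                   if r.log2FC <= -1.0 and r.padj < 0.05)
        assert res["n_up"] == up and res["n_down"] == down
        assert res["n_total"] == up + down

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        t = pd.DataFrame({"log2FC": rng.normal(0, 2, 400),
                          "padj": rng.uniform(0, 1, 400)})
        totals = [de_summary(t, lfc_thresh=l, p_thresh=0.05)["n_total"]
                  for l in (0.5, 1.0, 2.0, 3.0)]
        assert totals == sorted(totals, reverse=True)
        totals_p = [de_summary(t, lfc_thresh=1.0, p_thresh=p)["n_total"]
                    for p in (0.2, 0.05, 0.01)]
        assert totals_p == sorted(totals_p, reverse=True)

    def test_classify_consistent_with_summary(self):
        t = self._table(10, 20, 30)
        cls = classify_de(t, lfc_thresh=2.0, p_thresh=0.05)
        assert (cls == "up").sum() == 10 and (cls == "down").sum() == 20


class TestQpcr:
    def test_equal_ct_unity(self):
        assert chip_qpcr_enrichment(25.0, 25.0) == 1.0

    def test_one_cycle_doubles(self):
        assert chip_qpcr_enrichment(24.0, 25.0) == 2.0

    def test_fractional_exponent(self):
        assert chip_qpcr_enrichment(22.0, 25.3) == pytest.approx(2 ** 3.3, abs=1e-6)


class TestMannWhitneyAgreement:
    def test_scipy_matches_hand_rank_sum(self):
        """5+5 toy samples: U from first-principles rank sums equals scipy's,
        and the exact p equals full enumeration over all 252 splits."""
        x = [1.2, 3.4, 2.2, 5.0, 4.1]
        y = [0.5, 2.0, 1.0, 0.9, 3.0]
        u_hand = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        u_scipy, p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided",
                                              method="exact")
        assert u_scipy == u_hand
        pooled = x + y
        count = 0
        total = 0
        for combo in itertools.combinations(range(10), 5):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(10) if i not in combo]
            u = sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)
            total += 1
            if abs(u - 12.5) >= abs(u_hand - 12.5):
                count += 1
        assert p_scipy == pytest.approx(count / total, rel=1e-9)
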
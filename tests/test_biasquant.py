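"""Motif counting, OBV computation, ranking, enrichment, correlation."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import primebias as pb
from primebias import biasquant, kmers

W4, W6, W8 = pb.WINDOWS["w4"], pb.WINDOWS["w6"], pb.WINDOWS["w8"]


def _table(window, count_map, filler_motif=None, filler_count=0):
    counts = np.zeros(window.n_motifs, dtype=np.int64)
    for motif, c in count_map.items():
        counts[kmers.kmer_to_index(motif)] = c
    if filler_motif is not None:
        counts[kmers.kmer_to_index(filler_motif)] += filler_count
    return pb.MotifCountTable(window, counts)


class TestCountWindows:
    def test_repeated_insert(self):
        table = pb.count_windows(["A" * 12, "A" * 12], W6)
        assert table.to_dict() == {"AAAAAA": 2}
        assert table.total == 2

    def test_full_hexamer_enumeration_counts_once_each(self):
        inserts = [h + "AAAAAA" for h in kmers.all_kmers(6)]
        table = pb.count_windows(inserts, W6)
        assert table.total == 4096
        assert np.all(table.counts == 1)

    @pytest.mark.parametrize("window", [W4, W6, W8])
    def test_matches_brute_force_tally(self, window):
        rng = np.random.default_rng(17)
        inserts = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(100)]
        oracle = Counter(i[window.start:window.end] for i in inserts)
        table = pb.count_windows(inserts, window)
        assert table.to_dict() == dict(oracle)

    def test_rejects_N_and_wrong_length(self):
        table = pb.count_windows(["ACGTNCGTACGT", "ACGT", "A" * 13, "A" * 12], W6)
        assert table.n_rejected == 3
        assert table.total == 1

    def test_empty_input(self):
        table = pb.count_windows([], W8)
        assert table.total == 0 and table.n_rejected == 0


class TestNormalize:
    def test_proportional_scaling(self):
        sample = _table(W4, {"AAAA": 20}, filler_motif="TTTT", filler_count=180)
        background = _table(W4, {"AAAA": 5}, filler_motif="TTTT", filler_count=95)
        nr = pb.normalize_counts(sample, background)
        assert nr["AAAA"] == pytest.approx(10.0)

    def test_self_normalization_is_identity(self):
        sample = _table(W4, {"AAAA": 3, "ACGT": 7})
        nr = pb.normalize_counts(sample, sample)
        assert nr["AAAA"] == pytest.approx(3.0)
        assert nr["ACGT"] == pytest.approx(7.0)

    @given(st.lists(st.integers(0, 1000), min_size=256, max_size=256),
           st.lists(st.integers(0, 1000), min_size=256, max_size=256))
    def test_conservation(self, sample_counts, bg_counts):
        if sum(sample_counts) == 0 or sum(bg_counts) == 0:
            return
        sample = pb.MotifCountTable(W4, np.array(sample_counts))
        background = pb.MotifCountTable(W4, np.array(bg_counts))
        nr = pb.normalize_counts(sample, background)
        assert nr.sum() == pytest.approx(background.total, rel=1e-9)

    def test_zero_sample_total_rejected(self):
        empty = pb.MotifCountTable(W4, np.zeros(256, dtype=np.int64))
        full = _table(W4, {"AAAA": 5})
        with pytest.raises(ValueError, match="zero total"):
            pb.normalize_counts(empty, full)

    def test_window_mismatch_rejected(self):
        with pytest.raises(ValueError, match="window"):
            pb.normalize_counts(_table(W4, {"AAAA": 1}), _table(W6, {"AAAAAA": 1}))


class TestComputeOBV:
    def test_worked_example(self):
        """Background 10 reads, sample normalizing to 20 -> OBV exactly 2."""
        background = _table(W6, {"ATCGAT": 10}, filler_motif="TTTTTT", filler_count=90)
        sample = _table(W6, {"ATCGAT": 20}, filler_motif="TTTTTT", filler_count=80)
        obv = pb.compute_obv(sample, background)
        assert obv.value("ATCGAT") == 2.0

    def test_self_comparison_is_one_everywhere(self):
        rng = np.random.default_rng(5)
        table = pb.MotifCountTable(W4, rng.integers(1, 50, size=256))
        obv = pb.compute_obv(table, table)
        assert np.all(obv.obv[obv.scored] == 1.0)
        assert obv.n_scored == 256

    def test_sample_absent_motif_scores_zero(self):
        background = _table(W4, {"AAAA": 5, "CCCC": 5})
        sample = _table(W4, {"AAAA": 10})
        obv = pb.compute_obv(sample, background)
        assert obv.value("CCCC") == 0.0

    def test_background_zero_motifs_excluded(self):
        background = _table(W4, {"AAAA": 10})
        sample = _table(W4, {"AAAA": 5, "GGGG": 5})
        obv = pb.compute_obv(sample, background)
        assert obv.n_scored == 1
        assert kmers.kmer_to_index("GGGG") in obv.background_zero
        with pytest.raises(KeyError):
            obv.value("GGGG")

    def test_csv_roundtrip(self, tmp_path):
        background = _table(W4, {"AAAA": 4, "ACGT": 8})
        sample = _table(W4, {"AAAA": 6, "ACGT": 6})
        obv = pb.compute_obv(sample, background)
        path = tmp_path / "obv.csv"
        obv.to_csv(path)
        back = pb.OBVTable.from_csv(path, W4)
        np.testing.assert_array_equal(back.scored, obv.scored)
        np.testing.assert_allclose(back.obv[back.scored], obv.obv[obv.scored])


class TestRanking:
    def test_descending_with_ranks(self):
        obv = pb.OBVTable.from_values(W4, np.linspace(0.1, 2.0, 256))
        ranked = pb.rank_motifs(obv)
        assert list(ranked["rank"]) == list(range(1, 257))
        assert ranked["obv"].is_monotonic_decreasing
        assert ranked.iloc[0]["obv"] == pytest.approx(2.0)

    def test_ties_break_lexicographically(self):
        obv = pb.OBVTable.from_values(W4, np.ones(256))
        ranked = pb.rank_motifs(obv)
        assert list(ranked["motif"]) == kmers.all_kmers(4)
        assert list(ranked["rank"]) == list(range(1, 257))

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(23)
        values = rng.uniform(0, 3, size=256).round(2)  # rounding forces some ties
        ranked = pb.rank_motifs(pb.OBVTable.from_values(W4, values))
        oracle = sorted(zip(kmers.all_kmers(4), values), key=lambda kv: (-kv[1], kv[0]))
        assert list(ranked["motif"]) == [m for m, _ in oracle]

    def test_top_fraction_sizes(self):
        ranked = pb.rank_motifs(pb.OBVTable.from_values(W8, np.linspace(1, 2, 4 ** 8)))
        assert len(pb.top_fraction(ranked, 0.01)) == 655
        ranked6 = pb.rank_motifs(pb.OBVTable.from_values(W6, np.ones(4096)))
        assert len(pb.top_fraction(ranked6, 0.01)) == 40  # floor(40.96)
        ranked4 = pb.rank_motifs(pb.OBVTable.from_values(W4, np.ones(256)))
        assert len(pb.top_fraction(ranked4, 1.0)) == 256

    @given(fraction=st.floats(0.001, 1.0))
    def test_top_fraction_floor_property(self, fraction):
        ranked = pb.rank_motifs(pb.OBVTable.from_values(W4, np.linspace(0, 1, 256)))
        assert len(pb.top_fraction(ranked, fraction)) == math.floor(fraction * 256)

    def test_invalid_fraction_rejected(self):
        ranked = pb.rank_motifs(pb.OBVTable.from_values(W4, np.ones(256)))
        with pytest.raises(ValueError):
            pb.top_fraction(ranked, 0.0)


class TestEnrichment:
    def test_universe_background_is_combinatorial(self):
        # any fixed dimer slot: 2 of 16 dimers -> 12.5% exactly
        assert pb.motif_enrichment(kmers.all_kmers(8), ("GC", "CG"),
                                   biasquant.PRIMER3_DIMER_START) == 12.5

    def test_single_matching_motif(self):
        assert pb.motif_enrichment(["GGGGGCGG"], ("GC", "CG"), 4) == 100.0

    def test_gc_favoring_top_percent_enriched(self, deep_sim):
        ranked = pb.rank_motifs(deep_sim.obv8_rep1)
        top = pb.top_fraction(ranked, 0.01)
        enrichment = pb.motif_enrichment(top["motif"], ("GC", "CG"),
                                         biasquant.PRIMER3_DIMER_START)
        oracle = 100 * sum(m[4:6] in ("GC", "CG") for m in top["motif"]) / len(top)
        assert enrichment == pytest.approx(oracle)
        assert enrichment > 30.0  # far above the 12.5% background

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pb.motif_enrichment([], ("GC",), 0)

    def test_out_of_window_slot_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            pb.motif_enrichment(["ACGTACGT"], ("GC",), 7)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        obv = pb.OBVTable.from_values(W4, np.linspace(0.5, 2, 256))
        res = pb.correlate_obv(obv, obv)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.n == 256

    def test_scale_invariance(self):
        a = pb.OBVTable.from_values(W4, np.linspace(0.5, 2, 256))
        b = pb.OBVTable.from_values(W4, 2 * np.linspace(0.5, 2, 256))
        assert pb.correlate_obv(a, b).pearson_r == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.2, 0.8, 1.5, 2.0, 0.5, 1.1, 0.9, 1.8, 1.3, 0.7])
        y = np.array([1.0, 0.9, 1.6, 1.7, 0.6, 1.2, 1.1, 1.5, 1.2, 0.8])
        pad_x, pad_y = np.ones(246), np.ones(246)
        a = pb.OBVTable.from_values(W4, np.concatenate([x, pad_x]))
        b = pb.OBVTable.from_values(W4, np.concatenate([y, pad_y]))
        full_x, full_y = np.concatenate([x, pad_x]), np.concatenate([y, pad_y])
        # hand-computed Pearson r and its t-test p-value
        xc, yc = full_x - full_x.mean(), full_y - full_y.mean()
        r = (xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        n = 256
        t = r * math.sqrt((n - 2) / (1 - r ** 2))
        from scipy.stats import t as tdist
        p = 2 * tdist.sf(abs(t), n - 2)
        res = pb.correlate_obv(a, b)
        assert res.pearson_r == pytest.approx(r, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_too_few_motifs_rejected(self):
        obv = pb.OBVTable(W4, np.full(256, np.nan), np.zeros(256, bool), 0, 0)
        with pytest.raises(ValueError, match="at least 3"):
            pb.correlate_obv(obv, obv)


class TestGCOrder:
    def test_example(self):
        assert pb.gc_order(["GG", "AT", "AC"]) == ["AT", "AC", "GG"]

    def test_all_dimers_match_oracle(self):
        dimers = kmers.all_kmers(2)
        rank = {"A": 0, "T": 1, "C": 2, "G": 3}
        oracle = sorted(dimers, key=lambda m: (sum(b in "GC" for b in m),
                                               [rank[b] for b in m]))
        assert pb.gc_order(dimers) == oracle

    def test_singleton(self):
        assert pb.gc_order(["ACGT"]) == ["ACGT"]

    @given(st.lists(st.text("ACGT", min_size=4, max_size=4), min_size=1, max_size=30))
    def test_is_permutation_and_gc_sorted(self, motifs):
        ordered = pb.gc_order(motifs)
        assert sorted(ordered) == sorted(motifs)
        gcs = [sum(b in "GC" for b in m) for m in ordered]
        assert gcs == sorted(gcs)

    def test_mean_gc_percent(self):
        assert pb.mean_gc_percent(["GGCC", "AATT"]) == 50.0
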
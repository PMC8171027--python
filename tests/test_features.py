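"""Feature construction: windows, one-hot maps, window scores, composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sslvar.features import (
    BoundaryError,
    Preprocessor,
    TABULAR_COLUMNS,
    build_feature_map,
    composition,
    extract_window,
    max_score,
    one_hot,
    peak_score,
    sum_score,
)
from sslvar.genomic_io import Genome, GenomicLocus, MARKS
from tests.conftest import dense_profile, make_track


class TestExtractWindow:
    def test_window_is_centred_half_open(self, toy_genome):
        w = extract_window(toy_genome, GenomicLocus("chr1", 100, 1))
        assert (w.start, w.end) == (25, 175)
        assert len(w.seq) == 150
        assert w.seq[75] == toy_genome["chr1"][100]  # variant base at row 75

    def test_out_of_bounds_names_the_locus(self, toy_genome):
        with pytest.raises(BoundaryError, match="chr1:10"):
            extract_window(toy_genome, GenomicLocus("chr1", 10, 0))

    def test_all_a_chromosome(self):
        genome = Genome({"chrA": "A" * 300})
        w = extract_window(genome, GenomicLocus("chrA", 150, 1))
        assert w.seq == "A" * 150


class TestOneHot:
    @pytest.mark.parametrize("base,row", [
        ("A", [1, 0, 0, 0]), ("T", [0, 1, 0, 0]),
        ("C", [0, 0, 1, 0]), ("G", [0, 0, 0, 1]),
        ("N", [0, 0, 0, 0]),
    ])
    def test_base_rows(self, base, row):
        assert one_hot(base).tolist() == [row]

    def test_rejects_other_characters(self):
        with pytest.raises(ValueError, match="'X'"):
            one_hot("AXG")

    def test_row_sums_binary(self):
        m = one_hot("ACGTNNACGT")
        assert set(m.sum(axis=1)) <= {0.0, 1.0}


class TestWindowScores:
    def test_peak_inside_and_half_open_boundary(self, toy_track):
        assert peak_score(toy_track, GenomicLocus("chr1", 18, 1)) == 1
        assert peak_score(toy_track, GenomicLocus("chr1", 20, 1)) == 0
        assert peak_score(toy_track, GenomicLocus("chr3", 18, 1)) == 0

    def test_max_and_sum_on_partial_overlap(self, toy_genome, toy_track):
        w = extract_window(toy_genome, GenomicLocus("chr1", 90, 1), width=20)
        # window [80,100): no overlap with [10,20) or [30,40)
        assert max_score(toy_track, w) == 0.0
        assert sum_score(toy_track, w) == 0.0
        w2 = extract_window(toy_genome, GenomicLocus("chr1", 25, 1), width=20)
        # window [15,35): 5 bases at 3.0 plus 5 bases at 5.0
        assert max_score(toy_track, w2) == 5.0
        assert sum_score(toy_track, w2) == 5 * 3.0 + 5 * 5.0

    def test_window_fully_inside_interval(self, toy_genome):
        track = make_track("H3K4me1", [("chr1", 0, 500, 2.5)])
        w = extract_window(toy_genome, GenomicLocus("chr1", 250, 1))
        assert max_score(track, w) == 2.5
        assert sum_score(track, w) == 150 * 2.5

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(st.tuples(st.integers(0, 180), st.integers(1, 40),
                           st.floats(0.1, 9)), min_size=0, max_size=6),
        st.integers(20, 180),
    )
    def test_scores_equal_per_base_bruteforce(self, raw, center):
        """Max and Sum equal a dense per-base scan on random toy tracks."""
        intervals = [("chr1", s, s + l, round(v, 3)) for s, l, v in raw]
        track = make_track("DNase", intervals)
        genome = Genome({"chr1": "A" * 300})
        w = extract_window(genome, GenomicLocus("chr1", center, 1), width=40)
        dense = dense_profile([(s, e, v) for _, s, e, v in intervals], 300)
        window_dense = dense[w.start:w.end]
        assert max_score(track, w) == pytest.approx(window_dense.max())
        assert sum_score(track, w) == pytest.approx(window_dense.sum())
        # peak inside an interval implies positive max for that window
        if peak_score(track, GenomicLocus("chr1", center, 1)):
            assert max_score(track, w) > 0


class TestComposition:
    def test_hand_enumerated_ggca(self):
        c = composition("GGCA")
        assert (c["a_count"], c["t_count"], c["g_count"], c["c_count"]) == (1, 0, 2, 1)
        # adjacent pairs GG, GC, CA: only GC counts; GG does not
        assert (c["gc_dinuc_count"], c["gt_dinuc_count"], c["ga_dinuc_count"]) == (1, 0, 0)
        assert c["at_skew"] == 1.0
        assert c["gc_skew"] == pytest.approx(1 / 3)
        assert c["skew_ratio"] == pytest.approx(1 / 3)

    def test_zero_denominator_conventions(self):
        c = composition("CCCC")
        assert c["at_skew"] == 0.0          # 0/0 -> 0 by convention
        assert c["gc_skew"] == -1.0
        assert c["skew_ratio"] == 0.0       # x/0 -> 0 by convention

    def test_duplication_doubles_counts_keeps_skews(self):
        seq = "GGCATTAC"
        c1, c2 = composition(seq), composition(seq + seq)
        assert c2["a_count"] == 2 * c1["a_count"]
        assert c2["at_skew"] == pytest.approx(c1["at_skew"])
        assert c2["gc_skew"] == pytest.approx(c1["gc_skew"])

    def test_n_bases_excluded_from_counts(self):
        c = composition("ANNA")
        assert c["a_count"] == 2
        assert c["t_count"] + c["g_count"] + c["c_count"] == 0


class TestBuildFeatureMap:
    def test_tabular_length_and_order(self, toy_genome):
        tracks = {m: make_track(m, [("chr1", 90, 110, 2.0)]) for m in MARKS}
        onehot, tab = build_feature_map(toy_genome, tracks, GenomicLocus("chr1", 100, 1))
        assert onehot.shape == (150, 4)
        assert tab.shape == (43,)
        assert len(TABULAR_COLUMNS) == 43
        # locus 100 inside every mark's [90,110) peak
        peak_cols = [i for i, c in enumerate(TABULAR_COLUMNS) if c.endswith("_peak")]
        assert all(tab[i] == 1.0 for i in peak_cols)

    def test_missing_mark_requires_flag(self, toy_genome):
        tracks = {m: make_track(m, []) for m in MARKS if m != "DNase"}
        with pytest.raises(KeyError, match="DNase"):
            build_feature_map(toy_genome, tracks, GenomicLocus("chr1", 100, 1))
        _, tab = build_feature_map(
            toy_genome, tracks, GenomicLocus("chr1", 100, 1), allow_missing=True
        )
        dnase = [i for i, c in enumerate(TABULAR_COLUMNS) if c.startswith("DNase")]
        assert all(tab[i] == 0.0 for i in dnase)

    def test_track_dict_order_irrelevant(self, toy_genome):
        tracks = {m: make_track(m, [("chr1", 50, 150, 1.5)]) for m in MARKS}
        shuffled = dict(reversed(list(tracks.items())))
        locus = GenomicLocus("chr1", 100, 1)
        _, tab1 = build_feature_map(toy_genome, tracks, locus)
        _, tab2 = build_feature_map(toy_genome, shuffled, locus)
        assert np.array_equal(tab1, tab2)

    def test_empty_tracks_all_a_window(self):
        genome = Genome({"chr1": "A" * 300})
        tracks = {m: make_track(m, []) for m in MARKS}
        _, tab = build_feature_map(genome, tracks, GenomicLocus("chr1", 150, 1))
        assert np.all(tab[:33] == 0.0)
        comp = composition("A" * 150)
        assert tab[33] == comp["a_count"] == 150


class TestPreprocessor:
    def test_training_table_standardized(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=(200, 43))
        prep = Preprocessor().fit(x)
        z = prep.transform(x)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(z.std(axis=0), 1, atol=1e-10)

    def test_constant_column_becomes_zero_with_warning(self, caplog):
        x = np.ones((50, 43))
        with caplog.at_level("WARNING"):
            z = Preprocessor().fit_transform(x)
        assert np.allclose(z, 0.0, atol=1e-12)
        assert "zero-variance" in caplog.text

    def test_validation_scaled_with_training_stats_differs(self):
        rng = np.random.default_rng(1)
        train, val = rng.lognormal(size=(100, 43)), 2 + rng.lognormal(size=(100, 43))
        z_train_stats = Preprocessor().fit(train).transform(val)
        z_own_stats = Preprocessor().fit(val).transform(val)
        assert not np.allclose(z_train_stats, z_own_stats)

    def test_log1p_applied_to_max_and_sum_columns_only(self):
        x = np.zeros((10, 43))
        x[:, :] = np.e - 1  # log1p -> exactly 1
        prep = Preprocessor().fit(x)
        logged = prep._log(x)
        for i, col in enumerate(TABULAR_COLUMNS):
            expected = 1.0 if col.endswith(("_max", "_sum")) else np.e - 1
            assert logged[0, i] == pytest.approx(expected)

    def test_round_trip_through_dict(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(size=(60, 43))
        prep = Preprocessor().fit(x)
        clone = Preprocessor.from_dict(prep.to_dict())
        assert np.allclose(prep.transform(x), clone.transform(x))
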
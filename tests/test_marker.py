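"""Band-matrix statistics: frequencies, informativeness, EMR/MI, summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import germdiv as g
from germdiv._util import round_half_up

from conftest import PRIMER_COUNTS


class TestBandMatrixIO:
    def test_roundtrip_and_shape(self, tmp_path, small_band_matrix):
        path = tmp_path / "bands.tsv"
        g.write_band_matrix(small_band_matrix, path)
        back = g.read_band_matrix(path)
        assert back.accession_ids == small_band_matrix.accession_ids
        assert back.band_ids == small_band_matrix.band_ids
        assert back.primer_of_band == small_band_matrix.primer_of_band
        np.testing.assert_array_equal(back.values, small_band_matrix.values)

    def test_simulated_default_matrix_matches_study_dimensions(self, tmp_path):
        bm = g.simulate_band_matrix(g.MarkerSimConfig(seed=7))
        assert bm.n_accessions == 12
        assert len(bm.band_ids) == 97
        assert len(bm.primers) == 11
        path = tmp_path / "sim.tsv"
        g.write_band_matrix(bm, path)
        assert g.read_band_matrix(path).to_frame().equals(bm.to_frame())

    def test_transpose_flag(self, tmp_path, small_band_matrix):
        path = tmp_path / "bands.tsv"
        g.write_band_matrix(small_band_matrix, path)
        text = path.read_text()
        rows = [line.split("\t") for line in text.splitlines()]
        flipped = "\n".join("\t".join(col) for col in zip(*rows))
        tpath = tmp_path / "bandsT.tsv"
        tpath.write_text(flipped)
        back = g.read_band_matrix(tpath, transpose=True)
        np.testing.assert_array_equal(back.values, small_band_matrix.values)

    def test_single_cell_matrix_is_valid(self, tmp_path):
        path = tmp_path / "one.tsv"
        path.write_text("accession\tb1\nprimer\tP1\nacc1\t1\n")
        bm = g.read_band_matrix(path)
        assert bm.values.tolist() == [[1]]

    def test_non_binary_cell_names_offender(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("accession\tb1\tb2\nprimer\tP1\tP1\nacc1\t1\t2\n")
        with pytest.raises(g.ValidationError, match="acc1.*b2|b2.*acc1"):
            g.read_band_matrix(path)

    def test_duplicate_and_unassigned_labels_rejected(self):
        with pytest.raises(g.ValidationError, match="duplicate"):
            g.BandMatrix(["a", "a"], ["b1"], {"b1": "P"}, [[1], [0]])
        with pytest.raises(g.ValidationError, match="primer"):
            g.BandMatrix(["a"], ["b1"], {}, [[1]])


class TestBandStatistics:
    @pytest.mark.parametrize(
        "band, expected_p", [("b1", 1.0), ("b2", 0.5), ("b3", 0.25), ("b5", 0.0)]
    )
    def test_band_frequency(self, small_band_matrix, band, expected_p):
        assert g.band_frequency(small_band_matrix, band) == expected_p

    def test_unknown_band_and_primer(self, small_band_matrix):
        with pytest.raises(g.ValidationError):
            g.band_frequency(small_band_matrix, "nope")
        with pytest.raises(g.ValidationError):
            g.resolving_power(small_band_matrix, "nope")

    @pytest.mark.parametrize(
        "p, ib", [(0.5, 1.0), (1.0, 0.0), (0.0, 0.0), (1 / 6, pytest.approx(1 / 3)), (0.25, 0.5)]
    )
    def test_band_informativeness(self, p, ib):
        assert g.band_informativeness(p) == ib

    def test_informativeness_domain(self):
        with pytest.raises(g.ValidationError):
            g.band_informativeness(1.2)

    @given(st.integers(1, 200).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n))))
    def test_informativeness_bounds_and_extremes(self, nk):
        n, k = nk
        p = k / n  # band frequencies are exact accession-count ratios
        ib = g.band_informativeness(p)
        assert 0.0 <= ib <= 1.0
        assert (ib == 1.0) == (p == 0.5)
        assert (ib == 0.0) == (p in (0.0, 1.0))

    def test_resolving_power_sums_band_informativeness(self, small_band_matrix):
        # P1 bands have p = 1, .5, .25 -> Ib = 0, 1, .5
        assert g.resolving_power(small_band_matrix, "P1") == pytest.approx(1.5)
        # P2 bands p = .75, 0 -> Ib = .5, 0
        assert g.resolving_power(small_band_matrix, "P2") == pytest.approx(0.5)


class TestEmrPercentMi:
    @pytest.mark.parametrize("n, np_, pct", [(9, 8, 89), (3, 1, 33), (7, 7, 100)])
    def test_percent_polymorphism_reported(self, n, np_, pct):
        assert round_half_up(g.percent_polymorphism(n, np_)) == pct

    @pytest.mark.parametrize(
        "n, np_, expected", [(9, 8, 7.11), (13, 10, 7.69), (3, 1, 0.33), (5, 0, 0.0)]
    )
    def test_emr_published_values(self, n, np_, expected):
        assert round_half_up(g.emr(n, np_), 2) == expected

    def test_emr_bounds_and_monotonicity(self):
        for n in range(1, 12):
            prev = -1.0
            for k in range(n + 1):
                val = g.emr(n, k)
                assert val <= k + 1e-12
                assert (val == k) == (k in (0, n))
                assert val >= prev
                prev = val

    def test_domain_errors(self):
        with pytest.raises(g.ValidationError):
            g.emr(0, 0)
        with pytest.raises(g.ValidationError):
            g.percent_polymorphism(0, 0)
        with pytest.raises(g.ValidationError):
            g.emr(3, 4)

    @pytest.mark.parametrize(
        "pic, emr_, mi", [(0.28, 1.0, 0.28), (0.5, 4.0, 2.0), (0.9, 0.0, 0.0)]
    )
    def test_marker_index(self, pic, emr_, mi):
        assert g.marker_index(pic, emr_) == pytest.approx(mi)


class TestPic:
    def test_monomorphic_primer_zero_under_both_variants(self):
        bm = g.BandMatrix(["a", "b", "c"], ["b1", "b2"], {"b1": "P", "b2": "P"},
                          np.ones((3, 2), dtype=int))
        assert g.pic(bm, "P", "pattern_diversity") == 0.0
        assert g.pic(bm, "P", "mean_band_heterozygosity") == 0.0

    def test_all_distinct_patterns_closed_form(self):
        n = 12
        values = np.array([[int(b) for b in f"{i:04b}"] for i in range(n)])
        bands = ["b1", "b2", "b3", "b4"]
        bm = g.BandMatrix([f"a{i}" for i in range(n)], bands,
                          {b: "P" for b in bands}, values)
        assert g.pic(bm, "P", "pattern_diversity") == pytest.approx(1 - 12 * (1 / 12) ** 2)

    def test_single_band_heterozygosity(self):
        bm = g.BandMatrix(["a", "b"], ["b1"], {"b1": "P"}, [[1], [0]])
        assert g.pic(bm, "P", "mean_band_heterozygosity") == pytest.approx(0.5)

    def test_unknown_variant(self, small_band_matrix):
        with pytest.raises(g.ValidationError):
            g.pic(small_band_matrix, "P1", "nope")

    @settings(max_examples=60, deadline=None)
    @given(st.integers(2, 4), st.integers(1, 4), st.integers(0, 2**16 - 1))
    def test_pattern_diversity_matches_enumeration_oracle(self, n_acc, n_bands, seed):
        """Brute-force oracle: explicit pattern counting on tiny matrices."""
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 2, size=(n_acc, n_bands))
        bands = [f"b{j}" for j in range(n_bands)]
        bm = g.BandMatrix([f"a{i}" for i in range(n_acc)], bands,
                          {b: "P" for b in bands}, values)
        patterns = [tuple(row) for row in values]
        expected = 1.0 - sum(
            (patterns.count(pat) / n_acc) ** 2 for pat in set(patterns)
        )
        assert g.pic(bm, "P", "pattern_diversity") == pytest.approx(expected)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**16 - 1), st.sampled_from(g.marker.PIC_VARIANTS))
    def test_pic_invariant_to_row_and_column_order(self, seed, variant):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 2, size=(5, 4))
        bands = [f"b{j}" for j in range(4)]
        bm = g.BandMatrix([f"a{i}" for i in range(5)], bands,
                          {b: "P" for b in bands}, values)
        rows = rng.permutation(5)
        cols = rng.permutation(4)
        bm2 = g.BandMatrix([f"a{i}" for i in rows], [bands[j] for j in cols],
                           {b: "P" for b in bands}, values[np.ix_(rows, cols)])
        assert g.pic(bm2, "P", variant) == pytest.approx(g.pic(bm, "P", variant))


class TestSummaries:
    def test_primer_summary_counts(self, small_band_matrix):
        s = g.primer_summary(small_band_matrix, "P1")
        assert (s.n_total, s.n_mono, s.n_poly) == (3, 1, 2)
        assert s.pct_poly == pytest.approx(200 / 3)
        assert s.emr == pytest.approx(2 * 2 / 3)
        assert s.mi == pytest.approx(s.pic * s.emr)

    def test_fixed_band_primer_all_zero(self):
        bm = g.BandMatrix(["a", "b"], ["b1"], {"b1": "P"}, [[1], [1]])
        s = g.primer_summary(bm, "P")
        assert (s.n_total, s.n_mono, s.n_poly) == (1, 1, 0)
        assert s.pic == s.rp == s.emr == s.mi == 0.0

    def test_band_partition_over_primers(self, small_band_matrix):
        summaries = [g.primer_summary(small_band_matrix, p) for p in small_band_matrix.primers]
        assert sum(s.n_total for s in summaries) == len(small_band_matrix.band_ids)
        assert all(s.n_mono + s.n_poly == s.n_total for s in summaries)

    def test_overall_summary_reproduces_published_counts(self):
        """The 11-primer amplicon counts yield 97 total, 85 polymorphic,
        87.6% pooled polymorphism, 7.7 polymorphic bands/primer and a
        mean EMR of 7.05."""
        summaries = [
            g.PrimerSummary(
                primer=name, n_total=tna, n_mono=ma, n_poly=pa,
                pct_poly=g.percent_polymorphism(tna, pa),
                pic=0.0, rp=0.0, emr=g.emr(tna, pa), mi=0.0,
            )
            for name, tna, ma, pa, _, _ in PRIMER_COUNTS
        ]
        overall = g.overall_summary(summaries)
        assert overall.total_bands == 97
        assert overall.total_poly == 85
        assert round_half_up(overall.overall_pct_poly, 1) == 87.6
        assert round_half_up(overall.mean_poly, 1) == 7.7
        assert round_half_up(overall.mean_emr, 2) == 7.05
        assert round_half_up(overall.mean_pct_poly, 2) == 79.73

    def test_per_primer_reported_cells_match_published(self):
        for name, tna, ma, pa, pct, emr_val in PRIMER_COUNTS:
            assert round_half_up(g.percent_polymorphism(tna, pa)) == pct
            assert round_half_up(g.emr(tna, pa), 2) == emr_val

    def test_overall_summary_empty_error(self):
        with pytest.raises(g.ValidationError):
            g.overall_summary([])

    def test_summary_table_layout(self, small_band_matrix):
        table = g.summary_table(small_band_matrix)
        assert list(table["primer"]) == ["P1", "P2", "Total", "Mean"]
        total = table[table["primer"] == "Total"].iloc[0]
        assert total["TNA"] == 5 and total["PA"] == 3
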
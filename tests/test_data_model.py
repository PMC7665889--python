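"""Container invariants, file round-trips, CPM, expression filter, BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from imprintcall.data import (AlleleCountMatrix, FormatError, GeneAnnotation,
                              IntegrityError, bh_adjust, cpm, filter_expressed,
                              read_allele_counts, read_gene_annotation,
                              write_allele_counts, write_gene_annotation)

from conftest import make_genes, make_matrix


class TestAlleleCountMatrix:
    def test_library_size_is_column_sum(self):
        m = make_matrix([[3, 0], [1, 5], [2, 2]], [[1, 1], [0, 2], [3, 3]])
        assert m.library_size.tolist() == [10, 13]

    def test_allelic_counts_exceeding_total_raise_with_cell_named(self):
        with pytest.raises(IntegrityError, match=r"g0.*s1"):
            make_matrix([[1, 5]], [[1, 7]], total=np.array([[4, 10]]))

    def test_negative_count_is_a_format_error(self):
        with pytest.raises(FormatError, match="negative"):
            make_matrix([[-1]], [[2]], total=np.array([[5]]))

    def test_noninformative_cells_ignore_the_invariant(self):
        m = make_matrix([[5]], [[7]], total=np.array([[10]]),
                        informative=np.array([[False]]))
        assert not m.informative[0, 0]
        assert np.isnan(m.haplotyped()[0, 0])

    def test_gene_coordinates_must_be_ordered(self):
        with pytest.raises(IntegrityError):
            GeneAnnotation("g", "1", 100, 100)


class TestRoundTrip:
    def test_write_read_is_identity(self, tmp_path):
        informative = np.array([[True, False], [True, True], [False, True]])
        m = make_matrix([[3, 0], [1, 5], [2, 2]], [[1, 1], [0, 2], [3, 3]],
                        total=np.array([[9, 4], [2, 9], [7, 6]]),
                        informative=informative)
        write_allele_counts(m, tmp_path / "c.tsv")
        write_gene_annotation(m.genes, tmp_path / "g.tsv")
        genes = read_gene_annotation(tmp_path / "g.tsv")
        back = read_allele_counts(tmp_path / "c.tsv", genes)
        assert back.samples == m.samples
        assert (back.informative == informative).all()
        assert (back.total == m.total).all()
        mask = informative
        assert (back.maternal[mask] == m.maternal[mask]).all()
        assert (back.paternal[mask] == m.paternal[mask]).all()

    def test_missing_allelic_fields_keep_totals(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\ts0.maternal\ts0.paternal\ts0.total\n"
                        "g0\t.\t.\t7\n")
        m = read_allele_counts(path, make_genes(1))
        assert not m.informative[0, 0]
        assert m.total[0, 0] == 7

    def test_inconsistent_cell_raises_on_read(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("gene_id\ts0.maternal\ts0.paternal\ts0.total\n"
                        "g0\t5\t7\t10\n")
        with pytest.raises(IntegrityError):
            read_allele_counts(path, make_genes(1))


class TestCpm:
    @pytest.mark.parametrize("count,libsize,expected", [
        (1, 10**6, 1.0),
        (0, 10**6, 0.0),
        (50, 2 * 10**7, 2.5),
    ])
    def test_definition(self, count, libsize, expected):
        assert cpm(np.array([[count]]), np.array([libsize]))[0, 0] == expected

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            cpm(np.array([[1]]), np.array([0]))

    def test_scales_linearly_in_counts(self):
        lib = np.array([10**6, 3 * 10**6])
        c = np.array([[10, 30]])
        assert np.allclose(cpm(2 * c, lib), 2 * cpm(c, lib))


class TestExpressionFilter:
    def _matrix_with_cpm_pattern(self, n_pass, n_samples):
        """Gene g0 at exactly 1 cpm in n_pass libraries, 0 elsewhere;
        a filler gene pads every library to 3e6 reads."""
        lib = 3 * 10**6
        g0 = np.array([3 if j < n_pass else 0 for j in range(n_samples)])
        filler = lib - g0
        total = np.vstack([g0, filler])
        zeros = np.zeros_like(total)
        return make_matrix(zeros, zeros, total=total)

    def test_exactly_a_third_of_libraries_is_retained(self, config):
        m = self._matrix_with_cpm_pattern(2, 6)
        assert "g0" in filter_expressed(m, config)

    def test_below_a_third_is_dropped(self, config):
        m = self._matrix_with_cpm_pattern(2, 7)
        assert "g0" not in filter_expressed(m, config)

    def test_all_zero_gene_dropped(self, config):
        m = self._matrix_with_cpm_pattern(0, 6)
        assert "g0" not in filter_expressed(m, config)
        assert "g1" in filter_expressed(m, config)  # the filler


class TestBHAdjust:
    def test_step_up_with_monotone_enforcement(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_nan_passthrough_excluded_from_family(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        # the family has m=2, so the smallest p is adjusted by 2/1
        assert adj[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_statsmodels_and_dominates_input(self, pvals):
        adj = bh_adjust(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(adj, ref)
        assert (adj >= np.asarray(pvals) - 1e-12).all()

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        direct = bh_adjust([pvals[i] for i in perm])
        permuted = bh_adjust(pvals)[perm]
        assert np.allclose(direct, permuted)


class TestBundledResources:
    def test_known_imprinted_list_covers_the_major_clusters(self):
        from imprintcall.resources import example_known_imprinted_genes
        genes = example_known_imprinted_genes()
        ids = {g.gene_id for g in genes}
        assert {"Snrpn", "Kcnq1ot1", "Igf2r", "Jade1", "Sfmbt2",
                "Gatm"} <= ids
        clusters = {g.cluster for g in genes if g.cluster}
        assert {"Snrpn", "Kcnq1", "Airn/Igf2r"} <= clusters
        assert all(g.is_known_imprinted for g in genes)

    def test_dmr_regions_are_valid_and_classed(self):
        from imprintcall.resources import example_imprinted_dmrs
        regions = example_imprinted_dmrs()
        assert (regions["end"] > regions["start"]).all()
        assert {"germline_DMR", "secondary_DMR"} == set(regions["region_class"])
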
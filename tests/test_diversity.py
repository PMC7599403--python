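"""Community analysis: filtering, rarefaction, alpha/beta diversity, PCoA.

Alpha metrics and weighted UniFrac are cross-checked against scikit-bio as
an independent reference implementation.
"""

import io
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity import alpha as skbio_alpha

from rusitec.diversity import (
    AlphaRecord,
    DistanceMatrix,
    OtuTable,
    PhyloTree,
    ace,
    aggregate_taxa,
    alpha_diversity,
    alpha_frame,
    chao1,
    filter_low_count_otus,
    pcoa,
    rarefy,
    weighted_unifrac,
)


def make_table(counts, **kw):
    counts = np.atleast_2d(np.asarray(counts))
    n_s, n_o = counts.shape
    return OtuTable(counts=counts,
                    sample_ids=kw.get("sample_ids", [f"S{i}" for i in range(n_s)]),
                    otu_ids=kw.get("otu_ids", [f"O{j}" for j in range(n_o)]),
                    taxonomy=kw.get("taxonomy", {}))


class TestOtuTable:
    def test_negative_count_names_cell(self):
        with pytest.raises(ValueError, match="S0.*O1"):
            make_table([[1, -2]])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_table([[1, 2]], otu_ids=["A", "A"])

    def test_missing_taxonomy_defaults_to_unclassified(self):
        table = make_table([[1, 2]])
        assert table.taxonomy["O0"] == ("unclassified", "unclassified")


class TestFilter:
    def test_threshold_is_strictly_below(self):
        # totals 9 -> removed, 10 -> kept
        table = make_table([[9, 10]])
        out = filter_low_count_otus(table, 10)
        assert out.otu_ids == ["O1"]

    def test_zero_threshold_is_identity(self):
        table = make_table([[5, 0, 3], [1, 0, 2]])
        out = filter_low_count_otus(table, 0)
        assert out.otu_ids == table.otu_ids
        np.testing.assert_array_equal(out.counts, table.counts)

    def test_totals_pooled_across_samples(self):
        table = make_table([[3, 6, 250], [2, 4, 250]])  # totals 5, 10, 500
        out = filter_low_count_otus(table, 10)
        assert out.n_otus == 2
        assert out.sample_ids == table.sample_ids


class TestRarefy:
    def test_requires_explicit_seed(self):
        with pytest.raises(ValueError, match="seed"):
            rarefy(make_table([[50, 50]]), depth=10)

    def test_boundary_sample_kept_exactly(self):
        table = make_table([[60, 40]])
        out = rarefy(table, depth=100, seed=0)
        np.testing.assert_array_equal(out.counts, [[60, 40]])

    def test_shallow_sample_dropped_with_warning(self):
        table = make_table([[60, 40], [5, 3]])
        with pytest.warns(UserWarning, match="below rarefaction depth"):
            out = rarefy(table, depth=50, seed=0)
        assert out.sample_ids == ["S0"]

    def test_all_samples_shallow_errors(self):
        with pytest.raises(ValueError, match="no sample"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rarefy(make_table([[5, 3]]), depth=100, seed=0)

    def test_same_seed_reproduces(self):
        table = make_table([[900, 100, 50]])
        a = rarefy(table, depth=200, seed=7)
        b = rarefy(table, depth=200, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_hypergeometric_expectation(self):
        # (900, 100) rarefied to 100: E[OTU0] = 90
        table = make_table([[900, 100]])
        rng = np.random.default_rng(123)
        draws = [rarefy(table, depth=100, rng=rng).counts[0, 0]
                 for _ in range(1000)]
        assert np.mean(draws) == pytest.approx(90.0, abs=0.5)

    def test_preserves_zero_pattern_and_depth(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 300, size=(4, 30))
        counts[:, ::3] = 0
        table = make_table(counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = rarefy(table, depth=int(counts.sum(axis=1).min()), seed=1)
        assert (out.counts[:, ::3] == 0).all()
        assert (out.counts <= table.counts[:len(out.sample_ids)]).all()
        assert set(out.sample_sums()) == {counts.sum(axis=1).min()}


class TestAlpha:
    def test_single_otu(self):
        rec = alpha_diversity(np.array([20]))
        assert rec.shannon == 0.0
        assert rec.simpson == 0.0
        assert rec.observed == 1

    def test_uniform_four_otus(self):
        rec = alpha_diversity(np.array([5, 5, 5, 5]))
        assert rec.shannon == pytest.approx(2.0)
        assert rec.simpson == pytest.approx(0.75)

    def test_hand_computed_2_1_1(self):
        rec = alpha_diversity(np.array([2, 1, 1]))
        assert rec.shannon == pytest.approx(1.5)
        assert rec.simpson == pytest.approx(0.625)
        assert rec.singles == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity(np.zeros(4, dtype=int))

    def test_simpson_variants(self):
        counts = np.array([5, 3, 2])
        d = sum((counts / 10) ** 2)
        assert alpha_diversity(counts, simpson_variant="d").simpson == \
            pytest.approx(d)
        assert alpha_diversity(counts, simpson_variant="inverse").simpson == \
            pytest.approx(1 / d)

    def test_shannon_maximal_at_uniform(self):
        uniform = alpha_diversity(np.array([10, 10, 10, 10, 10])).shannon
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.integers(1, 50, size=5)
            assert alpha_diversity(c).shannon <= uniform + 1e-12

    def test_ace_hand_formula(self):
        # frozen by independent evaluation of the ACE formula
        assert ace(np.array([1, 1, 2, 3, 12])) == pytest.approx(
            6.786666666666666)

    def test_ace_no_rare_otus_equals_observed(self):
        assert ace(np.array([50, 30, 20])) == 3.0

    def test_ace_all_singletons_falls_back_to_chao1(self):
        counts = np.array([1, 1, 1, 20])
        with pytest.warns(UserWarning, match="Chao1"):
            got = ace(counts)
        assert got == pytest.approx(chao1(counts))

    def test_agrees_with_reference_on_random_vectors(self):
        """ACE, Shannon, Simpson, singles vs scikit-bio, 100 vectors, 1e-6."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(5, 60)
            counts = rng.integers(0, 40, size=n)
            if counts.sum() == 0 or (counts[counts > 0] == 1).all():
                counts[0] = 5
            rec = alpha_diversity(counts)
            assert rec.ace == pytest.approx(skbio_alpha.ace(counts), abs=1e-6)
            assert rec.shannon == pytest.approx(
                skbio_alpha.shannon(counts, base=2), abs=1e-6)
            assert rec.simpson == pytest.approx(
                skbio_alpha.simpson(counts), abs=1e-6)
            assert rec.singles == skbio_alpha.singles(counts)
            assert rec.observed == skbio_alpha.observed_features(counts)
            assert rec.ace >= rec.observed - 1e-9

    def test_alpha_frame_indexes_samples(self, small_table):
        frame = alpha_frame(small_table)
        assert list(frame.index) == small_table.sample_ids
        assert {"ace", "shannon", "simpson", "observed", "singles"} <= \
            set(frame.columns)


class TestWeightedUnifrac:
    def test_identical_samples_distance_zero(self, small_tree):
        table = make_table([[5, 5, 2, 1], [10, 10, 4, 2]],
                           otu_ids=["O1", "O2", "O3", "O4"])
        dm = weighted_unifrac(small_tree, table)
        assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_tip_star_tree(self):
        tree = PhyloTree.from_newick("(A:1,B:1):0;")
        table = make_table([[10, 0], [0, 7]], otu_ids=["A", "B"])
        dm = weighted_unifrac(tree, table)
        assert dm.data[0, 1] == pytest.approx(2.0)

    def test_invariant_to_sample_scaling(self, small_tree):
        t1 = make_table([[10, 5, 0, 1], [3, 3, 3, 3]],
                        otu_ids=["O1", "O2", "O3", "O4"])
        t2 = make_table([[50, 25, 0, 5], [3, 3, 3, 3]],
                        otu_ids=["O1", "O2", "O3", "O4"])
        d1 = weighted_unifrac(small_tree, t1).data[0, 1]
        d2 = weighted_unifrac(small_tree, t2).data[0, 1]
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_missing_tip_lists_offenders(self, small_tree):
        table = make_table([[1, 2]], otu_ids=["O1", "OX"])
        with pytest.raises(ValueError, match="OX"):
            weighted_unifrac(small_tree, table)

    def test_matches_reference_implementation(self, small_tree, small_table):
        ours = weighted_unifrac(small_tree, small_table)
        sk_tree = TreeNode.read(io.StringIO(
            "((O1:0.5,O2:0.5):1.0,(O3:0.8,O4:1.2):0.7):0.0;"))
        ref = beta_diversity("weighted_unifrac", small_table.counts,
                             ids=small_table.sample_ids,
                             taxa=small_table.otu_ids, tree=sk_tree,
                             normalized=False)
        np.testing.assert_allclose(ours.data, ref.data, atol=1e-10)

    def test_normalized_variant_bounded(self, small_tree, small_table):
        dm = weighted_unifrac(small_tree, small_table, normalized=True)
        assert (dm.data <= 1.0 + 1e-12).all()

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_symmetry_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        n_otus = int(rng.integers(3, 10))
        otu_ids = [f"T{j}" for j in range(n_otus)]
        # random caterpillar topology with random lengths
        newick = f"{otu_ids[0]}:{rng.uniform(0.1, 2):.3f}"
        for name in otu_ids[1:]:
            newick = f"({newick},{name}:{rng.uniform(0.1, 2):.3f}):" \
                     f"{rng.uniform(0.1, 2):.3f}"
        tree = PhyloTree.from_newick(newick + ";")
        counts = rng.integers(0, 50, size=(4, n_otus))
        counts[counts.sum(axis=1) == 0, 0] = 1
        dm = weighted_unifrac(tree, make_table(counts, otu_ids=otu_ids))
        d = dm.data
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestPcoa:
    def test_collinear_points_explained_by_pc1(self):
        d = squareform([1.0, 1.0, 2.0][::-1][::-1])  # pairwise 1,1,2 on a line
        dm = DistanceMatrix(data=np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]],
                                          dtype=float), ids=["a", "b", "c"])
        out = pcoa(dm)
        assert out.explained[0] == pytest.approx(100.0)
        assert out.coordinates.shape[1] == 1

    def test_roundtrip_distances(self):
        rng = np.random.default_rng(8)
        points = rng.normal(size=(6, 3))
        d = squareform(pdist(points))
        out = pcoa(DistanceMatrix(data=d, ids=[str(i) for i in range(6)]))
        recon = squareform(pdist(out.coordinates.to_numpy()))
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_duplicated_sample_has_identical_coordinates(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        out = pcoa(DistanceMatrix(data=d, ids=["a", "a2", "b"]))
        np.testing.assert_allclose(out.coordinates.loc["a"],
                                   out.coordinates.loc["a2"], atol=1e-10)

    def test_explained_non_increasing(self):
        rng = np.random.default_rng(9)
        points = rng.normal(size=(8, 4))
        d = squareform(pdist(points))
        out = pcoa(DistanceMatrix(data=d, ids=[str(i) for i in range(8)]))
        assert (np.diff(out.explained) <= 1e-9).all()
        assert out.explained.sum() == pytest.approx(100.0)

    def test_fewer_than_three_samples_rejected(self):
        dm = DistanceMatrix(data=np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            pcoa(dm)

    def test_matches_reference_implementation(self, small_tree, small_table):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        import skbio
        dm = weighted_unifrac(small_tree, small_table)
        ours = pcoa(dm)
        ref = skbio_pcoa(skbio.DistanceMatrix(dm.data, ids=dm.ids))
        n = ours.coordinates.shape[1]
        ref_explained = 100 * ref.proportion_explained.to_numpy()[:n]
        # our denominator drops negative eigenvalues; compare on positive part
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :n]), atol=1e-8)


class TestAggregateTaxa:
    def test_single_genus_column_of_one(self):
        table = make_table([[3, 4], [1, 1]],
                           taxonomy={"O0": ("P", "G"), "O1": ("P", "G")})
        rel = aggregate_taxa(table, "genus")
        np.testing.assert_allclose(rel["G"], 1.0)

    def test_proportions(self):
        table = make_table([[75, 25]],
                           taxonomy={"O0": ("P", "A"), "O1": ("P", "B")})
        rel = aggregate_taxa(table, "genus")
        assert rel.loc["S0", "A"] == pytest.approx(0.75)
        assert rel.loc["S0", "B"] == pytest.approx(0.25)

    def test_rows_sum_to_one_and_sorted(self, small_table):
        for rank in ("phylum", "genus"):
            rel = aggregate_taxa(small_table, rank)
            np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-9)
            means = rel.mean(axis=0).to_numpy()
            assert (np.diff(means) <= 1e-12).all()

    def test_conservation_of_reads(self, small_table):
        rel = aggregate_taxa(small_table, "genus")
        totals = small_table.sample_sums()
        recon = (rel.to_numpy() * totals[:, None]).sum(axis=1)
        np.testing.assert_allclose(recon, totals)

    def test_unknown_rank(self, small_table):
        with pytest.raises(ValueError, match="rank"):
            aggregate_taxa(small_table, "order")
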
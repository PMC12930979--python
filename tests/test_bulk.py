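import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_oracle, tau_oracle
from tissue_atlas import bulk
from tissue_atlas.bulk import EnrichmentThresholds, TissueMeans
from tissue_atlas.core import ExpressionMatrix, GeneAnnotation, SampleTable


def means_from(values: dict[str, list[float]], genes: list[str]) -> TissueMeans:
    return TissueMeans(pd.DataFrame(values, index=genes))


class TestSelectRikProteinCoding:
    def test_keeps_only_protein_coding_rik(self, expression):
        out = bulk.select_rik_protein_coding(expression)
        # g1 and g4 are protein-coding Riks; g2 non-Rik, g3 pseudogene Rik,
        # g5 protein-coding non-Rik
        assert out.gene_ids == ["g1", "g4"]

    def test_empty_input(self, expression):
        empty = expression.subset_genes([])
        with pytest.warns(UserWarning):
            out = bulk.select_rik_protein_coding(empty)
        assert out.gene_ids == []

    def test_all_pass_is_identity(self, sample_table):
        ann = GeneAnnotation.from_records(
            [("a", "x1Rik", "protein_coding"), ("b", "x2Rik", "protein_coding")]
        )
        values = pd.DataFrame(
            np.ones((2, 6)), index=["a", "b"], columns=sample_table.sample_ids
        )
        m = ExpressionMatrix(values, sample_table, ann)
        assert bulk.select_rik_protein_coding(m).gene_ids == ["a", "b"]

    def test_requires_annotation(self, expression):
        m = ExpressionMatrix(expression.values, expression.sample_table, None)
        with pytest.raises(ValueError):
            bulk.select_rik_protein_coding(m)


class TestTissueMeans:
    def test_replicate_mean(self, expression):
        means = bulk.tissue_means(expression)
        assert means.values.loc["g1", "retina"] == pytest.approx(11.0)

    def test_pair_mean(self, sample_table):
        values = pd.DataFrame(
            [[2.0, 4.0, 0, 0, 0, 0]], index=["g"], columns=sample_table.sample_ids
        )
        m = ExpressionMatrix(values, sample_table)
        assert bulk.tissue_means(m).values.loc["g", "retina"] == 3.0

    def test_all_zero_gene(self, sample_table):
        values = pd.DataFrame(
            np.zeros((1, 6)), index=["g"], columns=sample_table.sample_ids
        )
        m = ExpressionMatrix(values, sample_table)
        assert (bulk.tissue_means(m).values.loc["g"] == 0).all()


class TestLog2FC:
    def test_equal_means_zero(self):
        means = means_from({"retina": [3.0], "brain": [3.0], "liver": [3.0]}, ["g"])
        assert bulk.log2fc_one_vs_rest(means, "retina").loc["g"] == 0.0

    def test_derived_value(self):
        means = means_from({"retina": [1.0], "brain": [0.0]}, ["g"])
        fc = bulk.log2fc_one_vs_rest(means, "retina", pseudocount=0.01)
        assert fc.loc["g"] == pytest.approx(np.log2(1.01 / 0.01), abs=1e-9)
        assert fc.loc["g"] == pytest.approx(6.658, abs=1e-3)

    def test_antisymmetry_two_tissues(self):
        means = means_from({"a": [5.0], "b": [1.0]}, ["g"])
        fa = bulk.log2fc_one_vs_rest(means, "a").loc["g"]
        fb = bulk.log2fc_one_vs_rest(means, "b").loc["g"]
        assert fa == pytest.approx(-fb)

    def test_single_tissue_fatal(self):
        means = means_from({"retina": [1.0]}, ["g"])
        with pytest.raises(ValueError):
            bulk.log2fc_one_vs_rest(means, "retina")


class TestEnrichmentTest:
    @pytest.mark.parametrize("method", ["welch", "moderated"])
    def test_identical_values_p_one(self, sample_table, method):
        values = pd.DataFrame(
            [[5.0] * 6], index=["g"], columns=sample_table.sample_ids
        )
        m = ExpressionMatrix(values, sample_table)
        p = bulk.enrichment_test(m, "retina", method=method)
        assert p.loc["g"] == 1.0

    def test_strong_signal_significant(self, sample_table):
        rng = np.random.default_rng(0)
        jitter = rng.uniform(0, 1e-3, (1, 4))
        values = pd.DataFrame(
            np.hstack([[[10.0, 10.0]], jitter]),
            index=["g"],
            columns=sample_table.sample_ids,
        )
        m = ExpressionMatrix(values, sample_table)
        assert bulk.enrichment_test(m, "retina", method="welch").loc["g"] < 0.05

    @pytest.mark.parametrize("method", ["welch", "moderated"])
    def test_label_permutation_within_group(self, expression, method):
        p1 = bulk.enrichment_test(expression, "retina", method=method)
        # swap the two brain samples (within the "rest" group)
        perm = expression.values.rename(
            columns={"brain_1": "brain_2", "brain_2": "brain_1"}
        )
        m2 = ExpressionMatrix(
            perm[expression.sample_ids], expression.sample_table,
            expression.annotation,
        )
        p2 = bulk.enrichment_test(m2, "retina", method=method)
        pd.testing.assert_series_equal(p1, p2)

    def test_too_few_samples_fatal(self):
        table = SampleTable.from_records(
            [("r1", "retina", 1), ("r2", "retina", 2), ("b1", "brain", 1)]
        )
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["g"], columns=["r1", "r2", "b1"]
        )
        m = ExpressionMatrix(values, table)
        with pytest.raises(ValueError):
            bulk.enrichment_test(m, "retina")


class TestBHAdjust:
    def test_hand_computed(self):
        out = bulk.bh_adjust(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_array_equal(bulk.bh_adjust(np.array([0.2])), [0.2])

    def test_all_ones(self):
        np.testing.assert_array_equal(
            bulk.bh_adjust(np.ones(5)), np.ones(5)
        )

    def test_padj_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        assert (bulk.bh_adjust(p) >= p).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bulk.bh_adjust(np.array([0.5, 1.5]))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle(self, pvals):
        ours = bulk.bh_adjust(np.array(pvals))
        np.testing.assert_array_equal(ours, np.array(bh_oracle(pvals)))


class TestTau:
    def test_single_tissue_expression_is_one(self):
        means = means_from(
            {f"t{i}": [10.0 if i == 0 else 0.0] for i in range(10)}, ["g"]
        )
        assert bulk.compute_tau(means).loc["g"] == 1.0

    def test_uniform_expression_is_zero(self):
        means = means_from({f"t{i}": [7.0] for i in range(10)}, ["g"])
        assert bulk.compute_tau(means).loc["g"] == 0.0

    def test_derived_profile(self):
        # transformed profile (1, 0.5, 0) -> (0 + 0.5 + 1) / 2 = 0.75
        means = means_from({"a": [1.0], "b": [0.5], "c": [0.0]}, ["g"])
        tau = bulk.compute_tau(means, transform="none")
        assert tau.loc["g"] == pytest.approx(0.75)

    def test_all_zero_gene_missing(self):
        means = means_from({"a": [0.0], "b": [0.0]}, ["g"])
        assert np.isnan(bulk.compute_tau(means).loc["g"])

    @given(st.lists(st.floats(min_value=0.0, max_value=1e4), min_size=2,
                    max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_range_and_oracle(self, profile):
        means = means_from(
            {f"t{i}": [v] for i, v in enumerate(profile)}, ["g"]
        )
        tau = bulk.compute_tau(means).loc["g"]
        expected = tau_oracle(np.log2(np.asarray(profile) + 1.0))
        if np.isnan(expected):
            assert np.isnan(tau)
        else:
            assert tau == pytest.approx(expected, abs=1e-12)
            assert -1e-12 <= tau <= 1 + 1e-12

    def test_monotone_in_max_tissue(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            profile = rng.uniform(0, 100, 8)
            means1 = means_from({f"t{i}": [v] for i, v in enumerate(profile)}, ["g"])
            jmax = int(np.argmax(profile))
            profile2 = profile.copy()
            profile2[jmax] *= 1.0 + rng.uniform(0.1, 2.0)
            means2 = means_from({f"t{i}": [v] for i, v in enumerate(profile2)}, ["g"])
            assert (
                bulk.compute_tau(means2).loc["g"]
                >= bulk.compute_tau(means1).loc["g"] - 1e-12
            )


class TestFilterEnriched:
    def _records(self, log2fc, padj, fpkm):
        return pd.DataFrame(
            {"log2fc": [log2fc], "padj": [padj], "mean_target_fpkm": [fpkm]},
            index=["g"],
        )

    def test_pass(self):
        assert bulk.filter_enriched(self._records(1.0, 0.01, 0.5)) == ["g"]

    def test_boundary_log2fc_fails(self):
        assert bulk.filter_enriched(self._records(0.58, 0.01, 0.5)) == []

    def test_boundary_padj_fails(self):
        assert bulk.filter_enriched(self._records(1.0, 0.05, 0.5)) == []

    def test_boundary_fpkm_fails(self):
        assert bulk.filter_enriched(self._records(1.0, 0.01, 0.1)) == []


class TestZScoreRows:
    def test_basic_row(self):
        z = bulk.zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_zeros(self):
        z = bulk.zscore_rows(pd.DataFrame([[4.0, 4.0, 4.0]]))
        np.testing.assert_array_equal(z.to_numpy(), [[0.0, 0.0, 0.0]])

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(5, 8)))
        once = bulk.zscore_rows(x)
        twice = bulk.zscore_rows(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


class TestGeneSetScore:
    def test_constant_genes_zero_profile(self):
        means = means_from({"a": [2.0, 3.0], "b": [2.0, 3.0]}, ["g1", "g2"])
        score = bulk.gene_set_score(means, ["g1", "g2"])
        np.testing.assert_array_equal(score.to_numpy(), [0.0, 0.0])

    def test_argmax_at_shared_peak(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(20)]
        base = rng.uniform(1, 5, size=(20, 6))
        base[:, 2] += 20.0  # all genes peak in tissue t2
        means = TissueMeans(
            pd.DataFrame(base, index=genes, columns=[f"t{j}" for j in range(6)])
        )
        score = bulk.gene_set_score(means, genes)
        assert score.idxmax() == "t2"

    def test_singleton_equals_z_row(self):
        rng = np.random.default_rng(4)
        means = TissueMeans(
            pd.DataFrame(rng.uniform(0, 10, (3, 5)),
                         index=["g1", "g2", "g3"],
                         columns=[f"t{j}" for j in range(5)])
        )
        z = bulk.zscore_rows(np.log2(means.values + 1.0))
        score = bulk.gene_set_score(means, ["g2"])
        np.testing.assert_allclose(score.to_numpy(), z.loc["g2"].to_numpy())

    def test_profile_sums_to_zero(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        means = TissueMeans(
            pd.DataFrame(rng.uniform(0, 50, (30, 10)), index=genes,
                         columns=[f"t{j}" for j in range(10)])
        )
        score = bulk.gene_set_score(means, genes)
        assert abs(score.sum()) < 1e-6 * len(genes)

    def test_empty_set_fatal(self):
        means = means_from({"a": [1.0], "b": [2.0]}, ["g"])
        with pytest.raises(ValueError):
            bulk.gene_set_score(means, [])


class TestPCA:
    def test_duplicated_samples_identical(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(4, 10))
        x[1] = x[0]
        emb = bulk.pca_embed(pd.DataFrame(x, index=list("abcd")))
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[1],
                                   atol=1e-10)

    def test_explained_variance_sums_below_one(self):
        rng = np.random.default_rng(8)
        emb = bulk.pca_embed(pd.DataFrame(rng.normal(size=(6, 12))), 3)
        assert emb.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_rank_one_matrix(self):
        rng = np.random.default_rng(9)
        u = rng.normal(size=(7, 1))
        v = rng.normal(size=(1, 9))
        emb = bulk.pca_embed(pd.DataFrame(u @ v), 2)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_distances_preserved_at_full_rank(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(5, 8))
        frame = pd.DataFrame(x)
        emb = bulk.pca_embed(frame, n_components=8)
        xc = x - x.mean(axis=0, keepdims=True)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(
            pdist(emb.coordinates), pdist(xc), atol=1e-9
        )


class TestSelectTopGenes:
    def _records(self):
        return pd.DataFrame(
            {"log2fc": [2.0, 3.0, 3.0, 1.0]},
            index=["gB", "gD", "gC", "gA"],
        )

    def test_n_exceeds_count(self):
        assert len(bulk.select_top_genes(self._records(), 10)) == 4

    def test_top_one(self):
        assert bulk.select_top_genes(self._records(), 1) == ["gC"]

    def test_tie_break_lexicographic(self):
        assert bulk.select_top_genes(self._records(), 2) == ["gC", "gD"]


def test_compute_enrichment_recovers_obvious_gene(expression):
    records = bulk.compute_enrichment(expression, "retina")
    assert bool(records.loc["g5", "enriched"]) is True
    assert bool(records.loc["g2", "enriched"]) is False
    assert (records["padj"] >= records["pvalue"] - 1e-15).all()
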
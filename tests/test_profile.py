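"""Functional-profile construction and its single-cell treatment."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gocellmap.annotations import AnnotationRecord, BinaryAnnotationMatrix, build_binary_matrix
from gocellmap.errors import DataError, UsageError
from gocellmap.profile import (
    ExpressionMatrix,
    build_profile,
    embed_and_cluster,
    normalize,
    scale,
    select_variable_terms,
    standardized_dispersion,
    zscore_columns,
)

from conftest import dag_from_parents


def make_expr(counts, cells=None, genes=None, cell_types=None):
    counts = np.asarray(counts, dtype=float)
    cells = cells or [f"c{i}" for i in range(counts.shape[0])]
    genes = genes or [f"g{j}" for j in range(counts.shape[1])]
    meta = pd.DataFrame(index=pd.Index(cells, name="cell"))
    if cell_types is not None:
        meta["cell_type"] = cell_types
    return ExpressionMatrix(cells=cells, genes=genes, counts=sp.csr_matrix(counts), cell_meta=meta)


def make_bam(indicator, genes, terms):
    return BinaryAnnotationMatrix(
        genes=list(genes), terms=list(terms),
        matrix=sp.csr_matrix(np.asarray(indicator, dtype=np.int8)),
    )


class TestBuildProfile:
    def test_product_definition(self):
        expr = make_expr([[3, 2]], genes=["geneX", "geneY"])
        bam = make_bam([[1, 0], [1, 1]], ["geneX", "geneY"], ["t1", "t2"])
        prof = build_profile(expr, bam)
        row = dict(zip(prof.terms, prof.layer("raw")[0]))
        assert row == {"t1": 5.0, "t2": 2.0}

    def test_no_shared_genes_or_all_zero_raises(self):
        expr = make_expr([[1, 2]], genes=["a", "b"])
        with pytest.raises(DataError):
            build_profile(expr, make_bam([[1]], ["zz"], ["t1"]))
        bam0 = make_bam([[0], [0]], ["a", "b"], ["t1"])
        with pytest.raises(DataError):
            build_profile(expr, bam0)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 9, size=(6, 5))
        genes = [f"g{j}" for j in range(5)]
        indic = rng.integers(0, 2, size=(5, 4))
        indic[:, 0] = 1  # no all-zero column
        expr1 = make_expr(counts, genes=genes)
        perm = rng.permutation(5)
        expr2 = make_expr(counts[:, perm], genes=[genes[j] for j in perm])
        bam = make_bam(indic, genes, [f"t{k}" for k in range(4)])
        p1, p2 = build_profile(expr1, bam), build_profile(expr2, bam)
        assert np.array_equal(p1.layer("raw"), p2.layer("raw"))
        assert p1.terms == p2.terms

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_summation(self, seed):
        rng = np.random.default_rng(seed)
        n_cells, n_genes, n_terms = rng.integers(2, [51, 31, 21])
        counts = rng.integers(0, 20, size=(n_cells, n_genes))
        indic = rng.integers(0, 2, size=(n_genes, n_terms))
        genes = [f"g{j}" for j in range(n_genes)]
        terms = [f"t{k}" for k in range(n_terms)]
        try:
            prof = build_profile(make_expr(counts), make_bam(indic, genes, terms))
        except DataError:
            return  # degenerate draw: empty product
        raw = prof.layer("raw")
        t_idx = {t: k for k, t in enumerate(terms)}
        kept_cells = [int(c[1:]) for c in prof.cells]
        for i, ci in enumerate(kept_cells):
            for j, t in enumerate(prof.terms):
                expected = sum(
                    counts[ci, g] * indic[g, t_idx[t]] for g in range(n_genes)
                )
                assert raw[i, j] == expected

    def test_raw_column_sums_conserved(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 10, size=(20, 8))
        indic = rng.integers(0, 2, size=(8, 5))
        indic[0, :] = 1
        genes = [f"g{j}" for j in range(8)]
        prof = build_profile(make_expr(counts), make_bam(indic, genes, [f"t{k}" for k in range(5)]))
        raw = prof.layer("raw")
        col_counts = counts.sum(axis=0)
        for j, t in enumerate(prof.terms):
            k = int(t[1:])
            assert raw[:, j].sum() == (col_counts * indic[:, k]).sum()


class TestNormalize:
    def test_single_feature_forced_value(self):
        expr = make_expr([[100]], genes=["g0"])
        prof = build_profile(expr, make_bam([[1]], ["g0"], ["t1"]))
        out = normalize(prof, total=1e4)
        assert out.layer("normalized")[0, 0] == pytest.approx(np.log1p(10000))

    def test_proportional_rows_normalize_identically(self):
        expr = make_expr([[2, 4, 6], [1, 2, 3]])
        bam = make_bam(np.eye(3, dtype=int), [f"g{j}" for j in range(3)], ["t0", "t1", "t2"])
        out = normalize(build_profile(expr, bam))
        x = out.layer("normalized")
        assert np.allclose(x[0], x[1])

    def test_depth_rescaling_invariance(self):
        """Multiplying each cell's counts by a positive scalar leaves the
        normalized layer unchanged — the cross-species correlation upstream
        is therefore depth-invariant."""
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 30, size=(10, 6)).astype(float)
        scalars = rng.uniform(0.5, 4.0, size=(10, 1))
        genes = [f"g{j}" for j in range(6)]
        bam = make_bam(rng.integers(0, 2, size=(6, 4)) | np.eye(6, 4, dtype=int),
                       genes, [f"t{k}" for k in range(4)])
        a = normalize(build_profile(make_expr(counts), bam))
        b = normalize(build_profile(make_expr(counts * scalars), bam))
        assert np.allclose(a.layer("normalized"), b.layer("normalized"))


class TestScale:
    def test_hand_computed_zscore_with_sample_sd(self):
        col = np.array([[1.0], [2.0], [3.0]])
        assert np.allclose(zscore_columns(col).ravel(), [-1.0, 0.0, 1.0])

    def test_constant_column_becomes_zero(self):
        assert np.all(zscore_columns(np.full((4, 1), 3.7)) == 0)

    def test_clip_bound_holds(self):
        x = np.zeros((50, 1))
        x[0] = 1000.0
        out = zscore_columns(x, clip=10.0)
        assert np.abs(out).max() <= 10.0

    def test_scaled_columns_centered_unit_sd(self, small_profiles):
        x = small_profiles["species_a"].layer("scaled")
        sd = x.std(axis=0, ddof=1)
        nonconstant = sd > 0
        assert np.abs(x.mean(axis=0)[nonconstant]).max() < 1e-8
        unclipped = nonconstant & (np.abs(x).max(axis=0) < 10)
        assert np.allclose(sd[unclipped], 1.0, atol=1e-6)


class TestSelectVariableTerms:
    def _profile(self, normalized, terms):
        import anndata as ad
        from gocellmap.profile import FunctionalProfile

        adata = ad.AnnData(
            X=np.asarray(normalized, dtype=float),
            var=pd.DataFrame(index=pd.Index(terms, name="term")),
            layers={"normalized": np.asarray(normalized, dtype=float)},
        )
        return FunctionalProfile(adata)

    def test_top_n_matches_brute_force_ranking(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(2, 1, size=(30, 3))
        terms = ["tA", "tB", "tC"]
        prof = self._profile(x, terms)
        top2 = select_variable_terms(prof, n=2)
        stat = standardized_dispersion(x)
        expected = [t for _, t in sorted(zip(-stat, terms))][:2]
        assert top2 == expected

    def test_n_larger_than_terms_returns_all(self):
        prof = self._profile(np.random.default_rng(0).gamma(2, 1, (10, 4)),
                             ["a", "b", "c", "d"])
        assert sorted(select_variable_terms(prof, n=100)) == ["a", "b", "c", "d"]

    def test_ties_broken_lexically(self):
        x = np.tile([[1.0, 1.0], [2.0, 2.0]], (5, 1))
        prof = self._profile(x, ["zz", "aa"])
        assert select_variable_terms(prof, n=1) == ["aa"]


@pytest.fixture(scope="module")
def planted_profile():
    """Two well-separated populations in GO space."""
    rng = np.random.default_rng(42)
    n_per, n_genes = 60, 40
    counts = rng.poisson(2, size=(2 * n_per, n_genes)).astype(float)
    counts[:n_per, : n_genes // 2] += rng.poisson(20, size=(n_per, n_genes // 2))
    counts[n_per:, n_genes // 2 :] += rng.poisson(20, size=(n_per, n_genes // 2))
    genes = [f"g{j}" for j in range(n_genes)]
    terms = [f"t{k}" for k in range(10)]
    indic = np.zeros((n_genes, 10), dtype=int)
    for j in range(n_genes):
        indic[j, rng.choice(10, size=2, replace=False)] = 1
    expr = make_expr(counts, genes=genes,
                     cell_types=["p0"] * n_per + ["p1"] * n_per)
    dag = dag_from_parents({t: set() for t in terms})
    bam = build_binary_matrix(
        [AnnotationRecord(g, t) for g in genes for t in np.array(terms)[indic[genes.index(g)] == 1]],
        dag, gene_universe=genes,
    )
    return scale(normalize(build_profile(expr, bam)))



class TestEmbedAndCluster:
    def test_planted_bipartition_recovered(self, planted_profile):
        from sklearn.metrics import adjusted_rand_score

        prof = embed_and_cluster(planted_profile.copy(), n_pcs=5, k_neighbors=15,
                                 resolution=0.5, seed=0)
        truth = prof.adata.obs["cell_type"]
        ari = adjusted_rand_score(truth, prof.adata.obs["cluster"])
        assert ari >= 0.9

    def test_same_seed_identical_labels_and_embedding(self, planted_profile):
        a = embed_and_cluster(planted_profile.copy(), n_pcs=5, seed=3)
        b = embed_and_cluster(planted_profile.copy(), n_pcs=5, seed=3)
        assert (a.adata.obs["cluster"] == b.adata.obs["cluster"]).all()
        assert np.array_equal(a.adata.obsm["X_umap"], b.adata.obsm["X_umap"])

    def test_low_resolution_single_cluster(self):
        rng = np.random.default_rng(9)
        x = rng.poisson(5, size=(40, 20)).astype(float)
        expr = make_expr(x)
        bam = make_bam(np.eye(20, 8, dtype=int) | rng.integers(0, 2, (20, 8)),
                       [f"g{j}" for j in range(20)], [f"t{k}" for k in range(8)])
        prof = scale(normalize(build_profile(expr, bam)))
        out = embed_and_cluster(prof, n_pcs=4, resolution=0.01, seed=0)
        assert out.adata.obs["cluster"].nunique() == 1

    def test_n_pcs_bound_enforced(self, planted_profile):
        with pytest.raises(UsageError):
            embed_and_cluster(planted_profile.copy(), n_pcs=10_000, seed=0)
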
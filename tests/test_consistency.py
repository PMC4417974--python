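"""Correlation maps, R2E seriation, dendrogram flipping, correlation PCA."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import to_tree

from phytosig import consistency as cons
from phytosig import preprocess as pp


def _corr(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"s{i}" for i in range(values.shape[0])]
    return cons.CorrelationMatrix(labels, values)


def _block_matrix(sizes=(3, 3), within=0.9, between=0.1):
    n = sum(sizes)
    r = np.full((n, n), between)
    start = 0
    for s in sizes:
        r[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(r, 1.0)
    return r


class TestPearson:
    def test_identical_and_negated_samples(self):
        x = np.random.default_rng(0).normal(size=10)
        m = np.column_stack([x, x, -x])
        corr = cons.pearson_matrix(m, axis="samples")
        assert corr.values[0, 1] == pytest.approx(1.0)
        assert corr.values[0, 2] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(10, 6))
        corr = cons.pearson_matrix(m, axis="samples").values
        for i, j in itertools.combinations(range(6), 2):
            x, y = m[:, i], m[:, j]
            expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_sample_rejected(self):
        m = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            cons.pearson_matrix(m, axis="samples")


class TestPairwiseConsistency:
    @pytest.mark.parametrize("n", list(range(2, 11)))
    def test_pair_count_is_n_choose_2(self, n):
        rng = np.random.default_rng(n)
        m = rng.normal(size=(20, n))
        table, summary = cons.pairwise_consistency(m)
        assert summary["n_pairs"] == len(table) == n * (n - 1) // 2

    def test_sixteen_samples_give_120_pairs(self):
        m = np.random.default_rng(1).normal(size=(50, 16))
        _, summary = cons.pairwise_consistency(m)
        assert summary["n_pairs"] == 120

    def test_extreme_pairs_reported(self):
        x = np.random.default_rng(2).normal(size=30)
        m = np.column_stack([x, x + 0.01 * np.random.default_rng(3).normal(size=30), -x])
        _, summary = cons.pairwise_consistency(m)
        assert set(summary["max_pair"]) == {"0", "1"}
        assert summary["min_r"] < 0


class TestR2ESeriation:
    def test_two_blocks_contiguous(self):
        corr = _corr(_block_matrix())
        order = cons.r2e_seriation(corr).order
        positions = [order.index(f"s{i}") for i in range(3)]
        assert max(positions) - min(positions) == 2  # first block contiguous
        positions = [order.index(f"s{i}") for i in range(3, 6)]
        assert max(positions) - min(positions) == 2

    def test_gradient_recovered_up_to_reversal(self):
        n = 8
        r = np.array([[0.8 ** abs(i - j) for j in range(n)] for i in range(n)])
        order = cons.r2e_seriation(_corr(r)).order
        expected = [f"s{i}" for i in range(n)]
        assert order == expected or order == expected[::-1]

    def test_degenerate_map_stable_order(self, caplog):
        n = 5
        r = np.full((n, n), 0.5)
        np.fill_diagonal(r, 1.0)
        with caplog.at_level("WARNING"):
            res = cons.r2e_seriation(_corr(r))
        assert res.order == [f"s{i}" for i in range(n)]

    def test_invariant_to_label_permutation(self):
        # a gradient gives every object a distinct angle, so the recovered
        # order must not depend on input order (exchangeable objects would
        # legitimately fall back to index tie-breaks)
        n = 7
        r = np.array([[0.8 ** abs(i - j) for j in range(n)] for i in range(n)])
        labels = [f"s{i}" for i in range(n)]
        base = cons.r2e_seriation(_corr(r, labels)).order
        perm = [3, 0, 6, 1, 5, 2, 4]
        r2 = r[np.ix_(perm, perm)]
        shuffled = cons.r2e_seriation(_corr(r2, [labels[i] for i in perm])).order
        assert shuffled == base or shuffled == base[::-1]


class TestHctR2E:
    def test_two_clusters_contiguous_and_heights_unchanged(self):
        corr = _corr(_block_matrix(sizes=(4, 4), within=0.9, between=0.0))
        res = cons.hct_r2e(corr)
        first = {res.order.index(f"s{i}") for i in range(4)}
        assert max(first) - min(first) == 3
        # flipping only permutes leaves; merge heights come from the linkage
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        d = 1.0 - corr.values
        np.fill_diagonal(d, 0.0)
        expected = linkage(squareform(d, checks=False), method="average")
        np.testing.assert_allclose(res.dendrogram[:, 2], expected[:, 2])

    def test_leaf_order_consistent_with_tree(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(30, 9))
        corr = cons.pearson_matrix(m, axis="samples")
        res = cons.hct_r2e(corr)
        tree = to_tree(res.dendrogram)
        pos = {lab: i for i, lab in enumerate(res.order)}

        def check(node):
            if node.is_leaf():
                return {pos[corr.labels[node.id]]}
            left, right = check(node.left), check(node.right)
            span = left | right
            assert max(span) - min(span) == len(span) - 1  # contiguous block
            return span

        check(tree)

    def test_treated_samples_form_one_block(self, adjusted_matrix):
        """On the default design the 11 treated samples are contiguous in the
        HCT_R2E leaf order of the 16-sample correlation map."""
        qc = adjusted_matrix.subset_samples(
            [s for s, g in adjusted_matrix.groups().items() if g in ("treated", "comparator")]
        )
        rel = pp.relative_expression(qc)
        corr = cons.pearson_matrix(rel, axis="samples")
        res = cons.hct_r2e(corr)
        groups = dict(qc.groups())
        positions = [i for i, s in enumerate(res.order) if groups[s] == "treated"]
        assert max(positions) - min(positions) == len(positions) - 1

    def test_cluster_separation(self, adjusted_matrix):
        """min within-treated r exceeds max treated-vs-comparator r."""
        qc = adjusted_matrix.subset_samples(
            [s for s, g in adjusted_matrix.groups().items() if g in ("treated", "comparator")]
        )
        rel = pp.relative_expression(qc)
        corr = cons.pearson_matrix(rel, axis="samples").to_frame()
        groups = dict(qc.groups())
        treated = [s for s in qc.sample_ids if groups[s] == "treated"]
        comp = [s for s in qc.sample_ids if groups[s] == "comparator"]
        within = min(corr.loc[a, b] for a, b in itertools.combinations(treated, 2))
        across = max(corr.loc[a, b] for a in treated for b in comp)
        assert within > across


class TestPCA:
    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        m = np.column_stack([x, x, rng.normal(size=20), rng.normal(size=20)])
        res = cons.pca_correlation(m)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-10)

    def test_eigenvalues_sum_to_n_samples(self):
        m = np.random.default_rng(6).normal(size=(40, 7))
        res = cons.pca_correlation(m)
        assert res.eigenvalues.sum() == pytest.approx(7.0, abs=1e-9)

    def test_matches_direct_eigendecomposition(self):
        m = np.random.default_rng(8).normal(size=(25, 6))
        res = cons.pca_correlation(m)
        corr = np.corrcoef(m.T)
        lam, vec = np.linalg.eigh(corr)
        lam, vec = lam[::-1], vec[:, ::-1]
        for k in range(2):
            expected = vec[:, k] * np.sqrt(lam[k])
            got = res.coordinates[:, k]
            assert np.allclose(got, expected, atol=1e-10) or np.allclose(
                got, -expected, atol=1e-10
            )


class TestRenderMatrixMap:
    def test_deterministic_bytes_and_permutation(self, tmp_path):
        r = _block_matrix()
        labels = [f"s{i}" for i in range(6)]
        order = ["s3", "s1", "s2", "s0", "s4", "s5"]  # mixes the two blocks
        cons.render_matrix_map(r, labels, labels, tmp_path / "a.png")
        cons.render_matrix_map(r, labels, labels, tmp_path / "a2.png")
        cons.render_matrix_map(r, labels, order, tmp_path / "b.png")
        assert (tmp_path / "a.png").read_bytes() == (tmp_path / "a2.png").read_bytes()
        assert (tmp_path / "a.png").read_bytes() != (tmp_path / "b.png").read_bytes()

    def test_two_blocks_visible_under_seriation_order(self, tmp_path):
        from matplotlib import image as mimage

        interleaved = [0, 3, 1, 4, 2, 5]  # blocks {0,1,2} and {3,4,5} interleaved
        r = _block_matrix(within=1.0, between=0.0)[np.ix_(interleaved, interleaved)]
        labels = [f"s{i}" for i in interleaved]
        corr = cons.CorrelationMatrix(labels, r)
        order = cons.hct_r2e(corr).order
        cons.render_matrix_map(r, labels, order, tmp_path / "m.png", cmap="gray")
        img = mimage.imread(tmp_path / "m.png")[:, :, 0]
        # after seriation the map is exactly 2 diagonal blocks of 3x3
        hi = img > 0.9
        expected = np.zeros((6, 6), dtype=bool)
        expected[:3, :3] = expected[3:, 3:] = True
        assert np.array_equal(hi, expected) or np.array_equal(hi, expected[::-1, ::-1])
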
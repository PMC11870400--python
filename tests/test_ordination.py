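"""Distance registry, PCoA, PCA, and their cross-consistency.

Every registered metric is checked against an independent double-loop
evaluation of its published formula; PCoA is checked against closed forms,
against PCA on Euclidean distances, and against scikit-bio.
"""

import math

import numpy as np
import pandas as pd
import pytest

from metord.ordination import (
    BINARY_METRICS,
    METRICS,
    DistanceMatrix,
    pairwise_distances,
    pca,
    pcoa,
)
from metord.tables import FeatureTable

from conftest import make_table


def _table(values, sample_ids=None):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[0])]
    cols = [f"f{j}" for j in range(values.shape[1])]
    return FeatureTable(pd.DataFrame(values, index=sample_ids, columns=cols))


# ---------------------------------------------------------------------------
# hand-written formula oracles (double loops, no scipy)
# ---------------------------------------------------------------------------

def _binary_counts(x, y):
    a = [v > 0 for v in x]
    b = [v > 0 for v in y]
    ntt = sum(1 for i, j in zip(a, b) if i and j)
    ntf = sum(1 for i, j in zip(a, b) if i and not j)
    nft = sum(1 for i, j in zip(a, b) if not i and j)
    nff = sum(1 for i, j in zip(a, b) if not i and not j)
    return ntt, ntf, nft, nff


def _kl(p, m):
    return sum(pi * math.log(pi / mi) for pi, mi in zip(p, m) if pi > 0)


def make_oracles(X):
    """Per-pair distance formulas, closed over the full table where needed."""
    var = X.var(axis=0, ddof=1)
    VI = np.linalg.pinv(np.cov((X > 0).T.astype(float)))  # for binarized mahalanobis
    VI_cont = np.linalg.pinv(np.cov(X.T))

    def braycurtis(x, y):
        return sum(abs(a - b) for a, b in zip(x, y)) / sum(a + b for a, b in zip(x, y))

    def euclidean(x, y):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))

    def sqeuclidean(x, y):
        return sum((a - b) ** 2 for a, b in zip(x, y))

    def cityblock(x, y):
        return sum(abs(a - b) for a, b in zip(x, y))

    def chebyshev(x, y):
        return max(abs(a - b) for a, b in zip(x, y))

    def canberra(x, y):
        return sum(
            abs(a - b) / (abs(a) + abs(b))
            for a, b in zip(x, y)
            if abs(a) + abs(b) > 0
        )

    def cosine(x, y):
        num = sum(a * b for a, b in zip(x, y))
        return 1 - num / (euclidean(x, [0] * len(x)) * euclidean(y, [0] * len(y)))

    def correlation(x, y):
        xc = x - np.mean(x)
        yc = y - np.mean(y)
        return 1 - float(xc @ yc) / (np.linalg.norm(xc) * np.linalg.norm(yc))

    def minkowski(x, y):
        return sum(abs(a - b) ** 3 for a, b in zip(x, y)) ** (1 / 3)

    def seuclidean(x, y):
        return math.sqrt(sum((a - b) ** 2 / v for a, b, v in zip(x, y, var)))

    def jensenshannon(x, y):
        p = [a / sum(x) for a in x]
        q = [b / sum(y) for b in y]
        m = [(a + b) / 2 for a, b in zip(p, q)]
        return math.sqrt((_kl(p, m) + _kl(q, m)) / 2)

    def mahalanobis(x, y):
        d = np.asarray(x) - np.asarray(y)
        return math.sqrt(float(d @ VI_cont @ d))

    def hamming(x, y):
        ntt, ntf, nft, nff = _binary_counts(x, y)
        return (ntf + nft) / len(x)

    def jaccard(x, y):
        ntt, ntf, nft, nff = _binary_counts(x, y)
        denom = ntt + ntf + nft
        return (ntf + nft) / denom if denom else 0.0

    def dice(x, y):
        ntt, ntf, nft, nff = _binary_counts(x, y)
        return (ntf + nft) / (2 * ntt + ntf + nft)

    def russellrao(x, y):
        ntt, ntf, nft, nff = _binary_counts(x, y)
        return (len(x) - ntt) / len(x)

    def rogerstanimoto(x, y):
        ntt, ntf, nft, nff = _binary_counts(x, y)
        r = 2 * (ntf + nft)
        return r / (ntt + nff + r)

    def sokalsneath(x, y):
        ntt, ntf, nft, nff = _binary_counts(x, y)
        r = 2 * (ntf + nft)
        return r / (ntt + r)

    def yule(x, y):
        ntt, ntf, nft, nff = _binary_counts(x, y)
        r = 2 * ntf * nft
        return r / (ntt * nff + ntf * nft) if r else 0.0

    return {
        "braycurtis": braycurtis,
        "euclidean": euclidean,
        "sqeuclidean": sqeuclidean,
        "cityblock": cityblock,
        "chebyshev": chebyshev,
        "canberra": canberra,
        "cosine": cosine,
        "correlation": correlation,
        "minkowski": minkowski,
        "seuclidean": seuclidean,
        "jensenshannon": jensenshannon,
        "mahalanobis": mahalanobis,
        "hamming": hamming,
        "jaccard": jaccard,
        "dice": dice,
        "russellrao": russellrao,
        "rogerstanimoto": rogerstanimoto,
        "sokalsneath": sokalsneath,
        "yule": yule,
        "matching": hamming,
    }


class TestDistanceEngine:
    def test_registry_has_twenty_metrics(self):
        assert len(METRICS) == 20

    def test_braycurtis_hand_example(self):
        t = _table([[1, 0, 3], [2, 1, 1]])
        dm = pairwise_distances(t, "braycurtis")
        assert dm.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_jaccard_hand_example(self):
        t = _table([[1, 1, 0], [1, 0, 1]])
        dm = pairwise_distances(t, "jaccard")
        assert dm.values[0, 1] == pytest.approx(2 / 3, abs=1e-12)

    @pytest.mark.parametrize("metric", sorted(METRICS))
    def test_self_distance_is_zero(self, metric, rng):
        t = make_table(rng, 5, 8, sparsity=0.3)
        dm = pairwise_distances(t, metric)
        np.testing.assert_allclose(np.diag(dm.values), 0.0, atol=1e-12)
        np.testing.assert_allclose(dm.values, dm.values.T, atol=1e-12)

    @pytest.mark.parametrize("metric", sorted(METRICS))
    def test_matches_formula_oracle(self, metric, rng):
        t = make_table(rng, 20, 10, sparsity=0.25)
        X = t.values
        oracle = make_oracles(X)[metric]
        dm = pairwise_distances(t, metric)
        for i in range(20):
            for j in range(i + 1, 20):
                expected = oracle(X[i], X[j])
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-10), (
                    metric, i, j,
                )

    def test_unknown_metric_lists_valid_names(self, rng):
        t = make_table(rng, 3, 3)
        with pytest.raises(ValueError, match="braycurtis.*yule"):
            pairwise_distances(t, "manhattan")

    def test_allzero_pair_named(self):
        t = _table([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]], ["za", "zb", "ok"])
        with pytest.raises(ValueError, match="'za'.*'zb'"):
            pairwise_distances(t, "braycurtis")

    def test_negative_values_warn_for_abundance_metrics(self, rng):
        t = make_table(rng, 4, 5)
        t = t.with_values(t.values - t.values.mean(axis=0))
        with pytest.warns(UserWarning, match="non-negative"):
            pairwise_distances(t, "braycurtis")


class TestPcoa:
    def test_equilateral_closed_form(self):
        dm = DistanceMatrix(
            ids=["a", "b", "c"],
            values=np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
        )
        res = pcoa(dm)
        np.testing.assert_allclose(res.eigenvalues, [0.5, 0.5, 0.0], atol=1e-12)
        np.testing.assert_allclose(res.proportion_explained, [0.5, 0.5], atol=1e-12)
        out = res.coordinates
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.linalg.norm(out[i] - out[j])
                assert d == pytest.approx(1.0, abs=1e-12)

    def test_two_points_closed_form(self):
        dm = DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, 2.0], [2.0, 0.0]]))
        res = pcoa(dm)
        assert res.num_axes == 1
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(sorted(res.coordinates[:, 0]), [-1.0, 1.0],
                                   atol=1e-12)

    def test_duplicate_samples_coincide(self, rng):
        t = make_table(rng, 5, 6)
        v = t.values.copy()
        v[1] = v[0]
        dm = pairwise_distances(t.with_values(v), "braycurtis")
        res = pcoa(dm)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_eigenvalue_sum_equals_trace(self, rng):
        t = make_table(rng, 10, 7)
        dm = pairwise_distances(t, "euclidean")
        D = dm.values
        n = dm.n
        J = np.eye(n) - np.full((n, n), 1 / n)
        B = J @ (-0.5 * D * D) @ J
        res = pcoa(dm)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(B), rel=1e-9)

    def test_euclidean_distances_preserved(self, rng):
        t = make_table(rng, 9, 6)
        dm = pairwise_distances(t, "euclidean")
        res = pcoa(dm, num_axes="all")
        emb = res.coordinates
        for i in range(dm.n):
            for j in range(dm.n):
                d = np.linalg.norm(emb[i] - emb[j])
                assert d == pytest.approx(dm.values[i, j], abs=1e-8)

    def test_negative_eigenvalues_diagnosed_not_embedded(self):
        # triangle-inequality violation forces a non-Euclidean spectrum
        v = np.array(
            [[0, 4, 1, 1], [4, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]], dtype=float
        )
        res = pcoa(DistanceMatrix(ids=list("abcd"), values=v))
        assert res.negative_eigenvalue_mass > 0
        assert (res.eigenvalues[: res.num_axes] > 0).all()
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_deterministic_including_sign(self, rng):
        t = make_table(rng, 8, 5)
        dm = pairwise_distances(t, "braycurtis")
        a = pcoa(dm)
        b = pcoa(DistanceMatrix(ids=dm.ids, values=dm.values.copy()))
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa

        t = make_table(rng, 12, 30, sparsity=0.3)
        dm = pairwise_distances(t, "braycurtis")
        ours = pcoa(dm, num_axes=3)
        theirs = sk_pcoa(skbio.DistanceMatrix(dm.values, ids=dm.ids))
        np.testing.assert_allclose(
            np.abs(ours.coordinates),
            np.abs(theirs.samples.to_numpy()[:, :3]),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            ours.eigenvalues[:3], theirs.eigvals.to_numpy()[:3], rtol=1e-8
        )

    def test_rejects_invalid_matrix(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="hollow"):
            DistanceMatrix(ids=["a", "b"], values=np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestPca:
    def test_collinear_data_single_axis(self):
        t = _table([[0, 0], [1, 2], [2, 4], [3, 6]])
        res = pca(t)
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_by_two_hand_svd(self):
        res = pca(_table([[0.0, 0.0], [2.0, 0.0]]))
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(sorted(res.coordinates[:, 0]), [-1.0, 1.0],
                                   atol=1e-12)

    def test_trace_identity(self, rng):
        t = make_table(rng, 10, 6)
        res = pca(t)
        total = t.values.var(axis=0, ddof=1).sum() * (10 - 1)
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pca(_table([[1.0, 2.0]]))


class TestPcoaPcaEquivalence:
    def test_euclidean_pcoa_equals_pca(self):
        """Classical result: PCoA of Euclidean distances reproduces PCA."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            t = make_table(rng, 12, 8)
            rp = pca(t)
            rq = pcoa(pairwise_distances(t, "euclidean"))
            k = min(rp.num_axes, rq.num_axes)
            for a in range(k):
                x, y = rp.coordinates[:, a], rq.coordinates[:, a]
                assert min(np.abs(x - y).max(), np.abs(x + y).max()) < 1e-8
            np.testing.assert_allclose(
                rp.eigenvalues[:k], rq.eigenvalues[:k], rtol=1e-8, atol=1e-8
            )
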
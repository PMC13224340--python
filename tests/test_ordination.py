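"""Distances, PCoA (with PCA and skbio cross-checks), NMDS, envfit."""

import numpy as np
import pandas as pd
import pytest

from ecotyper.containers import CommunityTable, DistanceMatrix
from ecotyper.ordination import envfit, nmds, pairwise_distance, pcoa


def _table(values, state="hellinger"):
    values = np.asarray(values, dtype=float)
    return CommunityTable(
        pd.DataFrame(values,
                     index=[f"S{i}" for i in range(values.shape[0])],
                     columns=[f"A{j}" for j in range(values.shape[1])]),
        state=state,
    )


class TestPairwiseDistance:
    def test_bray_disjoint_is_one(self):
        d = pairwise_distance(_table([[1, 0], [0, 1]], state="relative"), "bray_curtis")
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_identical_rows_zero(self):
        d = pairwise_distance(_table([[1, 2], [1, 2]], state="relative"), "bray_curtis")
        assert d.matrix[0, 1] == pytest.approx(0.0)

    def test_matches_brute_force(self, rng):
        x = rng.uniform(0, 3, size=(8, 5))
        d = pairwise_distance(_table(x, state="relative"), "bray_curtis")
        for i in range(8):
            for j in range(8):
                expected = np.abs(x[i] - x[j]).sum() / (x[i] + x[j]).sum()
                assert d.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_two_zero_rows_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            pairwise_distance(_table([[0, 0], [0, 0], [1, 1]], state="raw"),
                              "bray_curtis")

    def test_unknown_metric(self):
        with pytest.raises(ValueError, match="metric"):
            pairwise_distance(_table([[1, 0]]), "manhattan")


class TestPcoa:
    def test_collinear_points_single_axis(self):
        x = np.array([[0.0], [1.0], [3.0]])
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix(squareform(pdist(x)), ids=list("abc"))
        with pytest.warns(UserWarning, match="fewer axes"):
            result = pcoa(d, n_axes=2)
        assert len(result.eigenvalues) == 1
        coords = result.coordinates.to_numpy().ravel()
        centered = (x - x.mean()).ravel()
        assert np.allclose(np.abs(coords), np.abs(centered), atol=1e-9)

    def test_equals_pca_on_euclidean_distances(self, rng):
        from sklearn.decomposition import PCA
        for _ in range(5):
            raw = rng.uniform(0.05, 4.0, size=(30, 12))
            t = CommunityTable(pd.DataFrame(
                np.sqrt(raw / raw.sum(axis=1, keepdims=True)),
                index=[f"S{i}" for i in range(30)],
                columns=[f"A{j}" for j in range(12)]), state="hellinger")
            d = pairwise_distance(t, "euclidean")
            result = pcoa(d, n_axes=4)
            scores = PCA(n_components=4).fit_transform(
                t.values - t.values.mean(axis=0)
            )
            ours = result.coordinates.to_numpy()
            for ax in range(4):
                sign = np.sign(scores[np.argmax(np.abs(scores[:, ax])), ax])
                ref = scores[:, ax] * sign
                assert np.abs(ours[:, ax] - ref).max() < 1e-8

    def test_matches_skbio(self, rng):
        import skbio
        x = rng.standard_normal((15, 6))
        from scipy.spatial.distance import pdist, squareform
        dm = squareform(pdist(x))
        ids = [f"S{i}" for i in range(15)]
        ours = pcoa(DistanceMatrix(dm, ids=ids), n_axes=3)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dm, ids=ids),
                                          method="eigh")
        ref_coords = ref.samples.to_numpy()[:, :3]
        for ax in range(3):
            ref_ax = ref_coords[:, ax]
            sign = np.sign(ref_ax[np.argmax(np.abs(ref_ax))])
            assert np.allclose(ours.coordinates.to_numpy()[:, ax],
                               ref_ax * sign, atol=1e-8)
        assert np.allclose(ours.eigenvalues[:3], ref.eigvals.to_numpy()[:3], atol=1e-8)

    def test_variance_explained_sums_to_one(self, rng):
        x = rng.standard_normal((12, 5))
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(12)])
        result = pcoa(d, n_axes=2)
        assert result.variance_explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(result.eigenvalues) <= 1e-12)


class TestNmds:
    def _dm(self, x):
        from scipy.spatial.distance import pdist, squareform
        return DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(len(x))])

    def test_perfect_embedding_low_stress(self, rng):
        x = rng.standard_normal((12, 2))
        result = nmds(self._dm(x), d_target=2, n_starts=4, seed=0)
        assert result.stress < 0.01

    def test_deterministic_under_seed(self, rng):
        x = rng.standard_normal((10, 4))
        a = nmds(self._dm(x), seed=3, n_starts=3)
        b = nmds(self._dm(x), seed=3, n_starts=3)
        assert a.stress == b.stress
        assert np.array_equal(a.coordinates.to_numpy(), b.coordinates.to_numpy())

    def test_stress_trace_non_increasing(self, rng):
        x = rng.standard_normal((15, 6))
        result = nmds(self._dm(x), d_target=2, n_starts=2, seed=1)
        trace = np.array(result.stress_trace)
        assert (np.diff(trace) <= 1e-12).all()

    def test_more_dimensions_never_worse(self, rng):
        x = rng.standard_normal((12, 6))
        d = self._dm(x)
        low = nmds(d, d_target=2, n_starts=4, seed=0).stress
        high = nmds(d, d_target=len(x) - 1, n_starts=4, seed=0).stress
        assert high <= low + 1e-9

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            nmds(self._dm(rng.standard_normal((3, 2))))


class TestEnvfit:
    def _ordination(self, rng, n=25):
        x = rng.standard_normal((n, 5))
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix(squareform(pdist(x)), ids=[f"S{i}" for i in range(n)])
        return pcoa(d, n_axes=2)

    def test_axis_coordinate_has_r2_one(self, rng):
        ordination = self._ordination(rng)
        cov = pd.DataFrame({"ax1": ordination.coordinates["axis1"]})
        result = envfit(ordination, cov, n_permutations=99, seed=0)
        assert result.table.loc["ax1", "r_squared"] == pytest.approx(1.0)
        assert result.table.loc["ax1", "p_value"] <= 0.05

    def test_constant_covariate_flagged(self, rng):
        ordination = self._ordination(rng)
        cov = pd.DataFrame({"const": np.ones(25)}, index=ordination.coordinates.index)
        result = envfit(ordination, cov, n_permutations=99, seed=0)
        row = result.table.loc["const"]
        assert row["flagged"] and row["r_squared"] == 0.0 and row["p_value"] == 1.0

    def test_r2_invariant_to_affine_rescaling(self, rng):
        ordination = self._ordination(rng)
        y = rng.standard_normal(25)
        idx = ordination.coordinates.index
        a = envfit(ordination, pd.DataFrame({"y": y}, index=idx),
                   n_permutations=49, seed=5)
        b = envfit(ordination, pd.DataFrame({"y": 3.5 * y - 11.0}, index=idx),
                   n_permutations=49, seed=5)
        assert a.table.loc["y", "r_squared"] == pytest.approx(
            b.table.loc["y", "r_squared"], abs=1e-12)
        assert a.table.loc["y", "p_value"] == b.table.loc["y", "p_value"]
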
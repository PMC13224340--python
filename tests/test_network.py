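"""Signed adjacency, TOM, module detection, eigengenes, kME, merging."""

import numpy as np
import pandas as pd
import pytest

from ecotyper.containers import CommunityTable
from ecotyper.network import (
    NetworkConfig,
    NetworkModel,
    detect_modules,
    kme_and_trait_stats,
    merge_modules,
    module_eigengenes,
    pick_soft_power,
    scale_free_fit,
    signed_adjacency,
    tom,
)


def _table(values, state="hellinger"):
    values = np.asarray(values, dtype=float)
    if values.min() < 0:  # global shift preserves all correlations
        values = values - values.min()
    return CommunityTable(
        pd.DataFrame(values,
                     index=[f"S{i}" for i in range(values.shape[0])],
                     columns=[f"A{j}" for j in range(values.shape[1])]),
        state=state,
    )


def _model_from_adjacency(a: np.ndarray) -> NetworkModel:
    n = a.shape[0]
    return NetworkModel(asv_ids=[f"A{j}" for j in range(n)],
                        correlation=np.eye(n), adjacency=a, beta=8.0)


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.eye(n)
    k = np.array([a[i].sum() - a[i, i] for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestSignedAdjacency:
    def test_closed_forms(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        table = _table(np.column_stack([x, x, -x]))
        model = signed_adjacency(table, beta=8.0)
        assert model.adjacency[0, 1] == pytest.approx(1.0)      # cor = +1
        assert model.adjacency[0, 2] == pytest.approx(0.0, abs=1e-12)  # cor = -1

    def test_zero_correlation_value(self):
        assert ((1 + 0.0) / 2) ** 8 == 0.00390625  # the β=8 midpoint

    def test_matches_brute_force_formula(self, rng):
        x = rng.standard_normal((15, 10))
        model = signed_adjacency(_table(x), beta=6.0)
        cor = np.corrcoef(x, rowvar=False)
        for i in range(10):
            for j in range(10):
                expected = 1.0 if i == j else ((1 + cor[i, j]) / 2) ** 6
                assert model.adjacency[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_named(self, rng):
        x = rng.standard_normal((10, 3))
        x[:, 1] = 2.0
        with pytest.raises(ValueError, match="A1"):
            signed_adjacency(_table(x))

    def test_higher_beta_shrinks_offdiagonal(self, rng):
        x = rng.standard_normal((20, 8))
        low = signed_adjacency(_table(x), beta=4.0).adjacency
        high = signed_adjacency(_table(x), beta=8.0).adjacency
        off = ~np.eye(8, dtype=bool)
        assert (high[off] < low[off]).all()


class TestScaleFree:
    def test_power_law_connectivity_high_fit(self):
        # exact power law: frequency(k) ~ k^-2 at bin centers 1..8; the
        # additive construction a_ij = x_i + x_j realises any target
        # connectivity sequence exactly: sum_{j!=i} a_ij = (n-2) x_i + S
        centers = np.arange(1, 9, dtype=float)
        counts = np.round(256 * centers**-2).astype(int)
        k = np.repeat(centers, counts)
        n = len(k)
        s_x = k.sum() / (2 * n - 2)
        x = (k - s_x) / (n - 2)
        a = x[:, None] + x[None, :]
        np.fill_diagonal(a, 1.0)
        model = _model_from_adjacency(a)
        assert np.allclose(model.connectivity, k, atol=1e-9)
        fit, slope, _ = scale_free_fit(model, n_bins=8)
        assert fit >= 0.99
        assert slope == pytest.approx(-2.0, rel=0.05)

    def test_equal_connectivity_flagged(self):
        a = np.full((30, 30), 0.5)
        np.fill_diagonal(a, 1.0)
        with pytest.warns(UserWarning, match="undefined"):
            fit, slope, mean_k = scale_free_fit(_model_from_adjacency(a), n_bins=5)
        assert np.isnan(fit)
        assert mean_k == pytest.approx(0.5 * 29)

    def test_fit_index_bounded(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.standard_normal((15, 30))
            model = signed_adjacency(_table(x), beta=4.0)
            fit, _, _ = scale_free_fit(model, n_bins=5)
            if not np.isnan(fit):
                assert -1.0 <= fit <= 1.0


class TestPickSoftPower:
    def test_tiny_target_returns_first_qualifying(self, default_tables):
        _, hel = default_tables
        from ecotyper.preprocess import network_qc
        qc, _ = network_qc(hel, n_keep=80)
        config = NetworkConfig(r2_target=1e-9, candidate_powers=(2, 4, 6))
        beta, diag = pick_soft_power(qc, config)
        assert list(diag.index) == [2, 4, 6]
        qualifying = diag.index[diag["fit_index"] >= 1e-9]
        expected = qualifying[0] if len(qualifying) else diag["fit_index"].idxmax()
        assert beta == float(expected)

    def test_contract_fit_reaches_target(self, default_tables):
        _, hel = default_tables
        from ecotyper.preprocess import network_qc
        qc, _ = network_qc(hel, n_keep=80)
        config = NetworkConfig(r2_target=0.3, candidate_powers=tuple(range(1, 13)))
        beta, diag = pick_soft_power(qc, config)
        if (diag["fit_index"] >= 0.3).any():
            assert diag.loc[beta, "fit_index"] >= 0.3
            below = diag.loc[: beta - 1, "fit_index"] if beta > 1 else pd.Series(dtype=float)
            assert (below < 0.3).all()


class TestTom:
    def test_matches_triple_loop(self, rng):
        for _ in range(3):
            a = rng.uniform(0, 1, (20, 20))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            model = tom(_model_from_adjacency(a))
            assert np.abs(model.tom - brute_force_tom(a)).max() < 1e-12

    def test_isolated_pair_tom_one(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 1.0
        model = tom(_model_from_adjacency(a))
        assert model.tom[0, 1] == pytest.approx(1.0)

    def test_empty_network_zero_overlap(self):
        model = tom(_model_from_adjacency(np.eye(5)))
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(model.tom[off], 0.0)

    def test_bounds_and_symmetry(self, rng):
        a = rng.uniform(0, 1, (25, 25))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        model = tom(_model_from_adjacency(a))
        assert model.tom.min() >= 0.0 and model.tom.max() <= 1.0
        assert np.allclose(model.tom, model.tom.T)
        assert np.allclose(np.diag(model.diss_tom), 0.0)


class TestModules:
    def _block_table(self, rng, n_samples=40, block=8):
        s1 = rng.standard_normal(n_samples)
        s2 = rng.standard_normal(n_samples)
        cols = [s1 + 0.05 * rng.standard_normal(n_samples) for _ in range(block)]
        cols += [s2 + 0.05 * rng.standard_normal(n_samples) for _ in range(block)]
        return _table(np.column_stack(cols))

    def test_two_blocks_recovered_exactly(self, rng):
        table = self._block_table(rng)
        model = tom(signed_adjacency(table, beta=6.0))
        labels = detect_modules(model, 2, seed=0)
        from sklearn.metrics import adjusted_rand_score
        truth = [0] * 8 + [1] * 8
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_deterministic(self, rng):
        table = self._block_table(rng)
        model = tom(signed_adjacency(table, beta=6.0))
        a = detect_modules(model, 2, seed=4)
        b = detect_modules(model, 2, seed=4)
        assert a.equals(b)

    def test_k_bounds(self, rng):
        table = self._block_table(rng)
        model = tom(signed_adjacency(table, beta=6.0))
        with pytest.raises(ValueError, match="k must satisfy"):
            detect_modules(model, 16)

    def test_labels_sorted_by_size(self, rng):
        table = self._block_table(rng, block=6)
        extra = _table(np.column_stack(
            [rng.standard_normal(40) for _ in range(3)]))
        merged = _table(np.hstack([table.values, extra.values]))
        model = tom(signed_adjacency(merged, beta=6.0))
        labels = detect_modules(model, 3, seed=0)
        sizes = labels.value_counts()
        assert list(sizes.index) == sorted(sizes.index, key=lambda m: -sizes[m])


class TestEigengenes:
    def test_identical_profiles_give_standardized_profile(self, rng):
        profile = rng.standard_normal(30)
        table = _table(np.column_stack([profile] * 4))
        labels = pd.Series([1] * 4, index=table.asv_ids)
        eig = module_eigengenes(table, labels)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(np.abs(eig["ME1"]), np.abs(z), atol=1e-9)
        assert np.corrcoef(eig["ME1"], profile)[0, 1] > 0  # sign orientation

    def test_unit_variance(self, default_tables, default_dataset):
        _, hel = default_tables
        from ecotyper.preprocess import network_qc
        qc, _ = network_qc(hel, n_keep=200)
        labels = default_dataset.truth.module_of_asv.loc[qc.asv_ids]
        eig = module_eigengenes(qc, labels[labels > 0].reindex(qc.asv_ids, fill_value=0))
        assert np.allclose(eig.std(ddof=1), 1.0, atol=1e-9)

    def test_planted_module_tracks_latent_signal(self, default_dataset, default_tables):
        _, hel = default_tables
        truth = default_dataset.truth
        labels = truth.module_of_asv.loc[hel.asv_ids]
        eig = module_eigengenes(hel, labels)
        signal = truth.latent_signals["module_1"]
        r = np.corrcoef(eig["ME1"], signal.loc[eig.index])[0, 1]
        assert abs(r) >= 0.9


class TestKmeAndTraits:
    def test_kme_of_self_module(self, rng):
        profile = rng.standard_normal(25)
        table = _table(profile[:, None])
        labels = pd.Series([1], index=table.asv_ids)
        with pytest.warns(UserWarning, match="singleton"):
            eig = module_eigengenes(table, labels)
        traits = pd.DataFrame({"doubling_time": rng.uniform(1, 2, 25)},
                              index=table.sample_ids)
        kme, _, _, _ = kme_and_trait_stats(table, eig, traits)
        assert kme.loc["A0", "ME1"] == pytest.approx(1.0)

    def test_kme_bounded(self, default_dataset, default_tables):
        _, hel = default_tables
        labels = default_dataset.truth.module_of_asv.loc[hel.asv_ids]
        eig = module_eigengenes(hel, labels)
        traits = default_dataset.traits
        kme, mt_r, mt_p, gs = kme_and_trait_stats(hel, eig, traits)
        assert np.nanmax(np.abs(kme.to_numpy())) <= 1.0
        assert ((mt_p.to_numpy() >= 0) & (mt_p.to_numpy() <= 1)).all()

    def test_fast_module_negatively_tracks_doubling_time(
        self, default_dataset, default_tables
    ):
        # the bloom module is planted with the shortest doubling time, so
        # its eigengene must anti-correlate with sample doubling time
        _, hel = default_tables
        truth = default_dataset.truth
        bloom = int(truth.trait_means.iloc[1:5]["doubling_time"].idxmin())
        labels = truth.module_of_asv.loc[hel.asv_ids]
        eig = module_eigengenes(hel, labels)
        _, mt_r, mt_p, _ = kme_and_trait_stats(hel, eig, default_dataset.traits)
        assert mt_r.loc[f"ME{bloom}", "doubling_time"] < 0
        assert mt_p.loc[f"ME{bloom}", "doubling_time"] < 0.05


class TestMerging:
    def test_duplicate_modules_merged(self, rng):
        latent = np.sin(np.linspace(0, 6, 50))
        cols, labels = [], []
        for m, shift in ((1, 0.0), (2, 0.05)):  # near-identical latents
            for _ in range(6):
                cols.append(latent + shift + 0.1 * rng.standard_normal(50))
                labels.append(m)
        table = _table(np.column_stack(cols))
        labels = pd.Series(labels, index=table.asv_ids)
        eig = module_eigengenes(table, labels)
        assert np.corrcoef(eig["ME1"], eig["ME2"])[0, 1] > 0.7
        merged, eig_merged = merge_modules(table, labels, merge_threshold=0.7)
        assert merged.nunique() == 1
        assert list(eig_merged.columns) == ["ME1"]

    def test_uncorrelated_modules_untouched(self, rng):
        a = rng.standard_normal(60)
        b = rng.standard_normal(60)
        cols = [a + 0.05 * rng.standard_normal(60) for _ in range(5)]
        cols += [b + 0.05 * rng.standard_normal(60) for _ in range(5)]
        table = _table(np.column_stack(cols))
        labels = pd.Series([1] * 5 + [2] * 5, index=table.asv_ids)
        merged, _ = merge_modules(table, labels, merge_threshold=0.7)
        assert merged.nunique() == 2

    def test_merging_never_increases_count(self, default_dataset, default_tables):
        _, hel = default_tables
        labels = default_dataset.truth.module_of_asv.loc[hel.asv_ids]
        merged, _ = merge_modules(hel, labels[labels > 0].reindex(hel.asv_ids, fill_value=0))
        assert merged[merged > 0].nunique() <= labels[labels > 0].nunique()
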
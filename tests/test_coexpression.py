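"""Normalisation, soft threshold, TOM, module cutting and seeded hubs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from growthnet import (
    build_seeded_subnetwork,
    cut_modules,
    pick_soft_threshold,
    preprocess_counts,
    quantile_normalize,
    select_seeded_modules,
    simulate_expression,
    simulate_genotypes,
    tom_matrix,
)


def _planted_matrix(module_sizes, cor, n_samples, seed, n_background=0):
    G, truth = simulate_genotypes(max(n_samples, 10), [(4, 0.8)], seed=seed,
                                  missing_rate=0.0)
    counts, _ = simulate_expression(
        G, truth, len(module_sizes), module_sizes, cor, n_samples,
        seed=seed + 1, n_background=n_background,
    )
    return preprocess_counts(counts).normalized, truth


def _exact_correlated_pair(r, n=24):
    """Two vectors with Pearson correlation exactly r (Gram-Schmidt)."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x
    z /= z.std()
    y = r * x + np.sqrt(1 - r**2) * z
    return x, y


class TestPreprocess:
    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame(
            [[0, 0, 0], [50, 60, 40], [900, 800, 1000]],
            index=["dead", "low", "high"],
        )
        em = preprocess_counts(counts, min_cpm=10)
        assert "dead" not in em.counts.index

    def test_quantile_normalized_columns_share_sorted_values(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 2000, (60, 5)))
        em = preprocess_counts(counts, min_cpm=0.0)
        arr = em.normalized.to_numpy()
        for j in range(1, arr.shape[1]):
            assert np.allclose(np.sort(arr[:, 0]), np.sort(arr[:, j]))

    def test_quantile_normalization_is_idempotent(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((40, 6)))
        once = quantile_normalize(X)
        twice = quantile_normalize(once)
        assert np.allclose(once, twice)

    def test_library_scaling_leaves_retained_set_unchanged(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(0, 500, (80, 4)))
        a = preprocess_counts(counts, min_cpm=10)
        b = preprocess_counts(counts * 10, min_cpm=10)
        assert list(a.counts.index) == list(b.counts.index)

    def test_zero_library_size_names_the_sample(self):
        counts = pd.DataFrame({"ok": [5, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            preprocess_counts(counts)


class TestSoftThreshold:
    def test_scale_free_fixture_reaches_target_fit(self):
        # exact single-factor correlation with power-law loadings: the
        # connectivity profile is a noiseless power law, so the log-log
        # degree regression must certify scale-free topology
        rng = np.random.default_rng(4)
        n, ns = 200, 220
        w = 0.95 * np.arange(1, n + 1) ** (-0.35)
        C = np.outer(w, w)
        np.fill_diagonal(C, 1.0)
        L = np.linalg.cholesky(C)
        M = np.column_stack([np.ones(ns), rng.standard_normal((ns, n))])
        Q, _ = np.linalg.qr(M)
        X = pd.DataFrame(L @ Q[:, 1 : 1 + n].T)  # empirical cor == C exactly
        beta, fits = pick_soft_threshold(X)
        assert fits.loc[fits["beta"] == beta, "fit_r2"].iloc[0] >= 0.85

    def test_mean_connectivity_strictly_decreases_in_beta(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((50, 30)))
        with pytest.warns(UserWarning):
            _, fits = pick_soft_threshold(X)
        assert (np.diff(fits["mean_connectivity"]) < 0).all()

    def test_white_noise_falls_back_to_argmax_with_warning(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.standard_normal((60, 20)))
        with pytest.warns(UserWarning, match="argmax"):
            beta, fits = pick_soft_threshold(X)
        assert beta == int(fits.loc[fits["fit_r2"].idxmax(), "beta"])

    def test_constant_gene_rows_rejected(self):
        X = pd.DataFrame(np.vstack([np.ones(10), np.random.default_rng(7)
                                    .standard_normal((39, 10))]))
        with pytest.raises(ValueError, match="constant"):
            pick_soft_threshold(X)


class TestTom:
    def test_perfectly_correlated_pair_has_tom_one(self):
        x = np.linspace(0, 1, 12)
        X = pd.DataFrame([x, 2 * x + 1], index=["g1", "g2"])
        T = tom_matrix(X, beta=7)
        assert T.loc["g1", "g2"] == pytest.approx(1.0)

    def test_independent_genes_have_vanishing_tom(self):
        x, y = _exact_correlated_pair(0.0, n=40)
        X = pd.DataFrame([x, y], index=["g1", "g2"])
        T = tom_matrix(X, beta=6)
        assert T.loc["g1", "g2"] < 1e-6

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((5, 15)))
        beta = 3
        A = np.abs(np.corrcoef(X.to_numpy())) ** beta
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        n = len(A)
        expected = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l_ij = sum(A[i, u] * A[u, j] for u in range(n))
                expected[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
        T = tom_matrix(X, beta)
        assert np.abs(T.to_numpy() - expected).max() < 1e-12

    def test_symmetric_unit_diagonal_in_unit_interval(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((30, 20)))
        T = tom_matrix(X, 6).to_numpy()
        assert np.allclose(T, T.T)
        assert np.allclose(np.diag(T), 1.0)
        assert T.min() >= 0.0 and T.max() <= 1.0 + 1e-12


class TestCutModules:
    def test_two_planted_blocks_recovered_exactly(self):
        # two independent 50-gene blocks at within-correlation 0.95
        rng = np.random.default_rng(31)
        rows, planted = [], []
        for m in range(2):
            f = rng.standard_normal(60)
            for _ in range(50):
                rows.append(
                    np.sqrt(0.95) * f + np.sqrt(0.05) * rng.standard_normal(60)
                )
                planted.append(f"PM{m + 1}")
        X = pd.DataFrame(rows, index=[f"g{i}" for i in range(100)])
        part = cut_modules(1.0 - tom_matrix(X, 6))
        labels = [part[g] for g in X.index]
        assert len(set(labels) - {"unassigned"}) == 2
        assert adjusted_rand_score(planted, labels) > 0.9

    def test_white_noise_yields_no_modules_in_most_seeds(self):
        zero = 0
        for s in range(10):
            X = pd.DataFrame(
                np.random.default_rng(40 + s).standard_normal((100, 40))
            )
            part = cut_modules(1.0 - tom_matrix(X, 6))
            if set(part.values()) == {"unassigned"}:
                zero += 1
        assert zero >= 8

    def test_reported_modules_respect_min_size(self):
        X, _ = _planted_matrix([50, 50, 50], 0.95, 60, seed=32, n_background=300)
        part = cut_modules(1.0 - tom_matrix(X, 6), min_module_size=30)
        sizes = pd.Series(part).value_counts().drop("unassigned", errors="ignore")
        assert (sizes >= 30).all()

    def test_fewer_genes_than_min_size_all_unassigned(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((10, 8)))
        with pytest.warns(UserWarning, match="unassigned"):
            part = cut_modules(1.0 - tom_matrix(X, 2), min_module_size=30)
        assert set(part.values()) == {"unassigned"}


class TestSeededSelection:
    def test_seed_selects_only_its_module(self):
        part = {"a": "M1", "b": "M2", "c": "M3", "d": "unassigned"}
        assert select_seeded_modules(part, ["c"]) == ["M3"]

    def test_two_seeds_same_module_return_one(self):
        part = {"a": "M1", "b": "M1"}
        assert select_seeded_modules(part, ["a", "b"]) == ["M1"]

    def test_planted_five_of_eight_modules_selected(self):
        part = {f"g{i}": f"M{i % 8 + 1}" for i in range(40)}
        seeds = [f"g{i}" for i in range(5)]  # fall in M1..M5
        assert select_seeded_modules(part, seeds) == ["M1", "M2", "M3", "M4", "M5"]

    def test_no_seed_in_any_module_warns_empty(self):
        with pytest.warns(UserWarning):
            assert select_seeded_modules({"a": "unassigned"}, ["a"]) == []


class TestSeededSubnetwork:
    def _star(self, n_spokes=10, r=0.9, n=60):
        rng = np.random.default_rng(11)
        hub = rng.standard_normal(n)
        rows = [hub]
        for _ in range(n_spokes):
            rows.append(r * hub + np.sqrt(1 - r**2) * rng.standard_normal(n))
        idx = ["hub"] + [f"s{i}" for i in range(n_spokes)]
        return pd.DataFrame(rows, index=idx)

    def test_star_center_scores_one(self):
        X = self._star()
        part = {g: "M1" for g in X.index}
        sub = build_seeded_subnetwork(X, part, ["M1"], ["hub"], min_abs_r=0.5)
        assert sub.hub_scores["hub"] == pytest.approx(1.0)
        assert max(sub.hub_scores.values()) == 1.0

    def test_r_below_cutoff_never_creates_edge(self):
        x, y = _exact_correlated_pair(0.49)
        X = pd.DataFrame([x, y], index=["a", "b"])
        part = {"a": "M1", "b": "M1"}
        sub = build_seeded_subnetwork(X, part, ["M1"], ["a"], min_abs_r=0.5)
        assert sub.graph.number_of_edges() == 0
        x, y = _exact_correlated_pair(0.51)
        X = pd.DataFrame([x, y], index=["a", "b"])
        sub = build_seeded_subnetwork(X, part, ["M1"], ["a"], min_abs_r=0.5)
        assert sub.graph.number_of_edges() == 1

    def test_hub_vector_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.standard_normal((8, 30)))
        part = {g: "M1" for g in X.index}
        sub = build_seeded_subnetwork(X, part, ["M1"], [X.index[0]], min_abs_r=0.1)
        nodes = sorted(sub.graph.nodes)
        A = np.zeros((8, 8))
        for u, v, d in sub.graph.edges(data=True):
            i, j = nodes.index(u), nodes.index(v)
            A[i, j] = A[j, i] = abs(d["weight"])
        v = np.ones(8)
        for _ in range(10_000):
            v_new = A.T @ (A @ v)
            v_new /= np.linalg.norm(v_new)
            if np.linalg.norm(v_new - v) < 1e-12:
                break
            v = v_new
        v = v / v.max()
        ours = np.array([sub.hub_scores[n] for n in nodes])
        assert np.abs(ours - v).max() < 1e-8

    def test_scores_invariant_to_uniform_weight_scaling(self):
        X = self._star()
        part = {g: "M1" for g in X.index}
        sub = build_seeded_subnetwork(X, part, ["M1"], ["hub"], min_abs_r=0.5)
        # rescaling all |r| weights uniformly cannot change the eigenvector
        from growthnet.coexpression import _hits_hub_scores

        A = np.zeros((len(X), len(X)))
        nodes = list(sub.graph.nodes)
        for u, v, d in sub.graph.edges(data=True):
            i, j = nodes.index(u), nodes.index(v)
            A[i, j] = A[j, i] = abs(d["weight"])
        assert np.allclose(_hits_hub_scores(A), _hits_hub_scores(5.0 * A))

    def test_empty_node_set_rejected(self):
        X = pd.DataFrame(np.ones((2, 5)), index=["a", "b"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="empty"):
                build_seeded_subnetwork(X, {}, [], ["zzz"])
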
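import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from metabopipe import (
    NetworkParams,
    compute_kme,
    detect_modules,
    eigenmetabolite,
    export_network,
    hubs,
    iterative_wgcna,
    pick_soft_threshold,
    simulate_dataset,
    tom_matrix,
)
from metabopipe.errors import ParameterError
from metabopipe.wgcna import GREY, ModuleResult, adjacency


def tom_bruteforce(X, power, network_type="unsigned"):
    """Naive O(n^3) topological overlap, straight from the definition."""
    a = adjacency(X, power, network_type)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=0)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTom:
    def test_identical_profiles_give_all_ones(self):
        base = np.random.default_rng(0).standard_normal(10)
        X = np.column_stack([base, base * 2 + 1, base * -1])
        # |cor| = 1 between all pairs
        tom = tom_matrix(X, power=6)
        np.testing.assert_allclose(tom, np.ones((3, 3)), atol=1e-12)

    @pytest.mark.parametrize("network_type", ["unsigned", "signed"])
    @pytest.mark.parametrize("power", [1, 6])
    def test_matches_brute_force_oracle(self, power, network_type):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((12, 7))
        tom = tom_matrix(X, power, network_type)
        oracle = tom_bruteforce(X, power, network_type)
        np.testing.assert_allclose(tom, oracle, atol=1e-10)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 15))
        tom = tom_matrix(X, 6)
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_independent_profiles_vanish_at_large_power(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 10))
        tom = tom_matrix(X, 12)
        off = tom[~np.eye(10, dtype=bool)]
        assert off.max() < 0.05

    def test_too_few_features_rejected(self):
        with pytest.raises(ParameterError):
            tom_matrix(np.ones((5, 2)), 6)


class TestSoftThreshold:
    def test_degenerate_grid_returns_single_power(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 20))
        beta, fit = pick_soft_threshold(X, powers=[1])
        assert beta == 1 and list(fit["power"]) == [1]

    def test_mean_connectivity_decreases_with_power(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 30))
        _, fit = pick_soft_threshold(X, powers=range(1, 11))
        ks = fit["mean_k"].to_numpy()
        assert (np.diff(ks) < 0).all()

    def test_preferential_attachment_profiles_reach_scale_free_fit(self):
        # profiles whose correlation graph mirrors a Barabasi-Albert network:
        # each edge carries a shared latent factor, nodes sum their edges
        import networkx as nx

        rng = np.random.default_rng(0)
        G = nx.barabasi_albert_graph(150, 2, seed=1)
        n_samples = 80
        edge_factors = {e: rng.standard_normal(n_samples) for e in G.edges}
        X = np.zeros((n_samples, G.number_of_nodes()))
        for i in G.nodes:
            for e in G.edges(i):
                key = e if e in edge_factors else (e[1], e[0])
                X[:, i] += edge_factors[key]
            X[:, i] += 0.5 * rng.standard_normal(n_samples)
        beta, fit = pick_soft_threshold(X)
        chosen = fit.loc[fit["power"] == beta, "signed_rsq"].iloc[0]
        assert chosen >= 0.8
        # smallest qualifying power is returned
        assert (fit.loc[fit["power"] < beta, "signed_rsq"] < 0.8).all()


class TestModulesAndEigen:
    def _blocks(self, seed=6, n_per=20, cor=0.9):
        ds, truth = simulate_dataset(n_features=2 * n_per, n_samples=60,
                                     n_modules=2, module_size=n_per,
                                     within_cor=cor, seed=seed)
        X = np.log2(ds.expression[ds.subject_sample_ids].T.to_numpy())
        return X, truth

    def test_two_planted_blocks_fully_recovered(self):
        X, _ = self._blocks()
        tom = tom_matrix(X, 6)
        labels, eig = detect_modules(tom, X, min_module_size=5)
        assert len(eig) == 2
        assert (labels != 0).all()
        # block structure: first 20 features together, last 20 together
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_min_module_size_above_n_gives_all_grey(self):
        X, _ = self._blocks()
        tom = tom_matrix(X, 6)
        labels, eig = detect_modules(tom, X, min_module_size=100)
        assert (labels == 0).all() and eig == {}

    def test_eigenmetabolite_matches_first_principal_component(self):
        X, _ = self._blocks()
        sub = X[:, :20]
        e = eigenmetabolite(sub)
        Z = (sub - sub.mean(0)) / sub.std(0)
        # PC1 via eigendecomposition of the sample covariance
        cov = Z @ Z.T
        w, v = np.linalg.eigh(cov)
        pc1 = v[:, -1]
        assert abs(np.corrcoef(e, pc1)[0, 1]) > 0.999

    def test_eigenmetabolite_invariant_to_member_order(self):
        X, _ = self._blocks()
        sub = X[:, :20]
        perm = np.random.default_rng(0).permutation(20)
        np.testing.assert_allclose(eigenmetabolite(sub), eigenmetabolite(sub[:, perm]),
                                   atol=1e-9)

    def test_kme_identities_and_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 6))
        e = X[:, 0].copy()
        eig = {1: e, 2: -e}
        kme = compute_kme(X, eig)
        assert kme[0, 0] == pytest.approx(1.0, abs=1e-12)   # feature == eigen
        assert kme[0, 1] == pytest.approx(-1.0, abs=1e-12)  # negated eigen
        for f in range(6):
            for j, m in enumerate(sorted(eig)):
                oracle = np.corrcoef(X[:, f], eig[m])[0, 1]
                assert kme[f, j] == pytest.approx(oracle, abs=1e-12)


class TestIterativeWgcna:
    def test_planted_modules_recovered_noise_dropped(self):
        ds, truth = simulate_dataset(n_features=300, n_samples=100, n_modules=5,
                                     module_size=40, within_cor=0.9, seed=7)
        X = np.log2(ds.expression[ds.subject_sample_ids].T)
        res = iterative_wgcna(X, NetworkParams())
        planted = [f for f in X.columns if truth.module_labels[f] != "noise"]
        noise = [f for f in X.columns if truth.module_labels[f] == "noise"]
        ari = adjusted_rand_score([truth.module_labels[f] for f in planted],
                                  [res.assignments[f] for f in planted])
        assert ari >= 0.9
        dropped = sum(res.assignments[f] == GREY for f in noise) / len(noise)
        assert dropped >= 0.9
        assert res.converged

    def test_pure_noise_converges_to_nothing(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((60, 80)))
        res = iterative_wgcna(X, NetworkParams(power=6))
        assert res.converged
        assert all(m == GREY for m in res.assignments.values())
        assert res.modules == []

    def test_feature_set_strictly_decreases_until_convergence(self):
        ds, _ = simulate_dataset(n_features=200, n_samples=60, n_modules=3,
                                 module_size=30, within_cor=0.8, seed=9)
        X = np.log2(ds.expression[ds.subject_sample_ids].T)
        res = iterative_wgcna(X, NetworkParams())
        sizes = [r.n_input for r in res.rounds]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert res.rounds[-1].n_dropped == 0

    def test_raising_kme_cutoff_never_assigns_more(self):
        ds, _ = simulate_dataset(n_features=150, n_samples=60, n_modules=3,
                                 module_size=30, within_cor=0.8, seed=10)
        X = np.log2(ds.expression[ds.subject_sample_ids].T)
        res_lo = iterative_wgcna(X, NetworkParams(kme_cutoff=0.3, power=6))
        res_hi = iterative_wgcna(X, NetworkParams(kme_cutoff=0.8, power=6))
        n_lo = sum(m != GREY for m in res_lo.assignments.values())
        n_hi = sum(m != GREY for m in res_hi.assignments.values())
        assert n_hi <= n_lo

    def test_own_module_kme_meets_cutoff_at_convergence(self):
        ds, _ = simulate_dataset(n_features=150, n_samples=60, n_modules=3,
                                 module_size=30, within_cor=0.85, seed=11)
        X = np.log2(ds.expression[ds.subject_sample_ids].T)
        params = NetworkParams(kme_cutoff=0.5)
        res = iterative_wgcna(X, params)
        assert res.converged
        for f, m in res.assignments.items():
            if m != GREY:
                assert res.kme.loc[f, m] >= params.kme_cutoff

    def test_param_validation(self):
        with pytest.raises(ParameterError):
            NetworkParams(power=99)
        with pytest.raises(ParameterError):
            NetworkParams(kme_cutoff=1.5)


class TestHubsAndExport:
    def _result(self):
        ds, _ = simulate_dataset(n_features=120, n_samples=80, n_modules=3,
                                 module_size=30, within_cor=0.9, seed=12)
        X = np.log2(ds.expression[ds.subject_sample_ids].T)
        return iterative_wgcna(X, NetworkParams())

    def test_kme_exactly_at_cutoff_excluded(self):
        res = self._result()
        module = res.modules[0]
        f0 = res.members(module)[0]
        cutoff = float(res.kme.loc[f0, module])
        hub_map = hubs(res, hub_kme=cutoff)  # strict '>' excludes the boundary
        assert f0 not in [f for f, _ in hub_map[module]]

    def test_empty_result_empty_map(self):
        empty = ModuleResult(assignments={}, kme=pd.DataFrame(),
                             eigenmetabolites=pd.DataFrame(), rounds=[],
                             tom=pd.DataFrame(), power=6)
        assert hubs(empty) == {}

    def test_hubs_sorted_descending_and_above_threshold(self):
        res = self._result()
        for module, lst in hubs(res, hub_kme=0.8).items():
            ks = [k for _, k in lst]
            assert ks == sorted(ks, reverse=True)
            assert all(k > 0.8 for k in ks)

    def test_weight_above_one_gives_empty_edges_full_nodes(self):
        res = self._result()
        module = res.modules[0]
        edges, nodes = export_network(res, module, weight_min=1.1)
        assert len(edges) == 0
        assert len(nodes) == len(res.members(module))

    def test_weight_zero_gives_complete_graph(self):
        res = self._result()
        module = res.modules[0]
        n = len(res.members(module))
        edges, _ = export_network(res, module, weight_min=0.0)
        assert len(edges) == n * (n - 1) // 2

    def test_edge_weights_equal_tom_entries(self):
        res = self._result()
        module = res.modules[0]
        edges, _ = export_network(res, module, weight_min=0.0)
        for _, row in edges.head(25).iterrows():
            assert row["weight"] == pytest.approx(
                float(res.tom.loc[row["source"], row["target"]]), abs=1e-12
            )

    def test_unknown_module_rejected(self):
        res = self._result()
        with pytest.raises(ParameterError, match="unknown module"):
            export_network(res, "no-such-module")
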
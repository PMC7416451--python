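import itertools

import numpy as np
import pandas as pd
import pytest

from gravimet.network import (
    assemble_network,
    graphical_lasso,
    pairwise_covariance,
    partial_correlations,
    residualise,
    spinglass_communities,
    spinglass_hamiltonian,
)
from gravimet.qc import MetaboliteMatrix


def _matrix(values):
    meta = pd.DataFrame(
        {"class": ["amino acid"] * values.shape[1], "arm": ["targeted"] * values.shape[1]},
        index=values.columns,
    )
    return MetaboliteMatrix(values=values, meta=meta, timepoint="fasting", transform="transformed")


class TestResidualise:
    def test_orthogonal_confounder_leaves_centred_values(self):
        rng = np.random.default_rng(0)
        n = 4000
        idx = [f"S{i}" for i in range(n)]
        met = rng.normal(3.0, 1.0, n)
        conf = pd.DataFrame({"c": rng.normal(0, 1, n)}, index=idx)
        m = _matrix(pd.DataFrame({"a": met}, index=idx))
        resid, dropped = residualise(m, conf)
        assert dropped == []
        centred = met - met.mean()
        corr = np.corrcoef(resid["a"], centred)[0, 1]
        assert corr > 0.999

    def test_exactly_linear_metabolite_residuals_vanish(self):
        idx = [f"S{i}" for i in range(50)]
        c = np.linspace(0, 1, 50)
        conf = pd.DataFrame({"c": c}, index=idx)
        m = _matrix(pd.DataFrame({"a": 2.0 + 3.0 * c}, index=idx))
        resid, _ = residualise(m, conf)
        assert np.nanmax(np.abs(resid["a"])) < 1e-8 or np.all(np.isnan(resid["a"]))

    def test_conditional_covariance_matches_schur_complement(self):
        """Residual covariance of (Y1,Y2) on C equals the analytic
        conditional covariance Sigma_yy - Sigma_yc Sigma_cc^-1 Sigma_cy."""
        rng = np.random.default_rng(1)
        n = 20000
        cov = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
        z = rng.multivariate_normal(np.zeros(3), cov, n)
        idx = [f"S{i}" for i in range(n)]
        conf = pd.DataFrame({"c": z[:, 2]}, index=idx)
        m = _matrix(pd.DataFrame({"y1": z[:, 0], "y2": z[:, 1]}, index=idx))
        resid, _ = residualise(m, conf)
        schur = cov[:2, :2] - np.outer(cov[:2, 2], cov[2, :2]) / cov[2, 2]
        # residuals are standardised: compare correlation structure
        r_expected = schur[0, 1] / np.sqrt(schur[0, 0] * schur[1, 1])
        r_obs = np.corrcoef(resid["y1"], resid["y2"])[0, 1]
        assert r_obs == pytest.approx(r_expected, abs=0.03)

    def test_sparse_metabolite_dropped_with_warning(self):
        idx = [f"S{i}" for i in range(20)]
        vals = pd.DataFrame({"a": [1.0, 2.0] + [np.nan] * 18}, index=idx)
        conf = pd.DataFrame({"c": np.arange(20.0)}, index=idx)
        _, dropped = residualise(_matrix(vals), conf)
        assert dropped == ["a"]


class TestGraphicalLasso:
    def _chain_cov(self, n=2000, seed=2):
        # known chain precision: X,Z conditionally independent given Y,
        # adjacent partial correlations 0.4
        rng = np.random.default_rng(seed)
        theta_true = np.array([[1.0, -0.4, 0.0], [-0.4, 1.0, -0.4], [0.0, -0.4, 1.0]])
        z = rng.multivariate_normal(np.zeros(3), np.linalg.inv(theta_true), n)
        df = pd.DataFrame(z, columns=["x", "y", "z"])
        df = (df - df.mean()) / df.std()  # penalty acts on the correlation scale
        return pd.DataFrame(np.cov(df.T), index=df.columns, columns=df.columns)

    def test_unpenalised_limit_matches_direct_inverse(self):
        S = self._chain_cov()
        theta = graphical_lasso(S, lam=0.0)
        direct = np.linalg.inv(S.to_numpy())
        assert np.max(np.abs(theta.to_numpy() - direct) / np.abs(direct).max()) < 1e-6

    def test_full_shrinkage_gives_diagonal_precision(self):
        S = self._chain_cov()
        theta = graphical_lasso(S, lam=10.0)
        off = theta.to_numpy() - np.diag(np.diag(theta))
        assert np.max(np.abs(off)) < 1e-8

    def test_chain_structure_recovered(self):
        S = self._chain_cov()
        theta = graphical_lasso(S, lam=0.1).to_numpy()
        assert abs(theta[0, 1]) > 1e-4 and abs(theta[1, 2]) > 1e-4  # X-Y, Y-Z edges
        assert abs(theta[0, 2]) < 1e-6  # no X-Z edge

    def test_edge_sets_nested_as_penalty_grows(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(500, 6))
        z[:, 1] += 0.7 * z[:, 0]
        z[:, 2] += 0.5 * z[:, 1]
        z[:, 4] += 0.6 * z[:, 3]
        S = pd.DataFrame(np.cov(z.T))
        prev_edges = None
        for lam in (0.01, 0.05, 0.1, 0.2, 0.4):
            theta = graphical_lasso(S, lam).to_numpy()
            edges = {
                (i, j)
                for i in range(6)
                for j in range(i + 1, 6)
                if abs(theta[i, j]) > 1e-8
            }
            if prev_edges is not None:
                assert edges <= prev_edges
            prev_edges = edges

    def test_precision_spd_and_partial_correlations_bounded(self):
        S = self._chain_cov()
        theta = graphical_lasso(S, lam=0.05)
        w = np.linalg.eigvalsh(theta.to_numpy())
        assert w.min() > 0
        rho = partial_correlations(theta).to_numpy()
        off = rho[~np.eye(3, dtype=bool)]
        assert np.all(off > -1) and np.all(off < 1)

    def test_non_psd_covariance_rejected(self):
        S = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            graphical_lasso(S, 0.1)

    def test_pairwise_covariance_is_psd_under_missingness(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(200, 8))
        z[rng.random((200, 8)) < 0.3] = np.nan
        S = pairwise_covariance(pd.DataFrame(z))
        assert np.linalg.eigvalsh(S.to_numpy()).min() >= 0


def _brute_force_best_partition(adj, gamma=1.0):
    """Exhaustive Potts-Hamiltonian minimisation over all set partitions."""
    n = adj.shape[0]

    def partitions(collection):
        if len(collection) == 1:
            yield [collection]
            return
        first = collection[0]
        for smaller in partitions(collection[1:]):
            for k, subset in enumerate(smaller):
                yield smaller[:k] + [[first] + subset] + smaller[k + 1 :]
            yield [[first]] + smaller

    best_h, best = np.inf, None
    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for lab, block in enumerate(part):
            labels[block] = lab
        h = spinglass_hamiltonian(adj, labels, gamma)
        if h < best_h - 1e-12:
            best_h, best = h, labels.copy()
    return best_h, best


class TestSpinglass:
    def _two_cliques(self):
        a = np.zeros((10, 10))
        a[:5, :5] = 1.0
        a[5:, 5:] = 1.0
        np.fill_diagonal(a, 0.0)
        a[4, 5] = a[5, 4] = 1.0  # bridge
        return pd.DataFrame(a, index=[f"n{i}" for i in range(10)], columns=[f"n{i}" for i in range(10)])

    def test_two_cliques_split_into_two_communities(self):
        comms = spinglass_communities(self._two_cliques(), seed=1)
        assert comms.nunique() == 2
        assert comms.iloc[:5].nunique() == 1 and comms.iloc[5:].nunique() == 1

    def test_complete_graph_single_community(self):
        a = 1.0 - np.eye(6)
        comms = spinglass_communities(pd.DataFrame(a), seed=1)
        assert comms.nunique() == 1

    def test_empty_graph_gives_singletons(self):
        a = np.zeros((4, 4))
        comms = spinglass_communities(pd.DataFrame(a), seed=1)
        assert comms.nunique() == 4

    def test_matches_exhaustive_optimum_on_small_graphs(self):
        rng = np.random.default_rng(5)
        for trial in range(3):
            n = 8
            blocks = np.array([0] * 4 + [1] * 4)
            p = np.where(blocks[:, None] == blocks[None, :], 0.9, 0.1)
            a = (rng.random((n, n)) < p).astype(float)
            a = np.triu(a, 1)
            a = a + a.T
            if a.sum() == 0:
                continue
            adj = pd.DataFrame(a)
            comms = spinglass_communities(adj, seed=trial).to_numpy()
            h_best, _ = _brute_force_best_partition(a)
            h_found = spinglass_hamiltonian(a, comms)
            assert h_found == pytest.approx(h_best, abs=1e-9)

    def test_seed_reproducible(self):
        adj = self._two_cliques()
        a = spinglass_communities(adj, seed=3)
        b = spinglass_communities(adj, seed=3)
        pd.testing.assert_series_equal(a, b)


class TestAssembleNetwork:
    def _theta(self, names, edges):
        n = len(names)
        t = np.eye(n)
        for i, j in edges:
            t[i, j] = t[j, i] = -0.3
        return pd.DataFrame(t, index=names, columns=names)

    def _results(self, names, qs):
        return pd.DataFrame({"metabolite": names, "fdr_q": qs})

    def test_no_significant_metabolites_gives_empty_network(self):
        names = list("abcd")
        net = assemble_network(
            self._theta(names, [(0, 1)]), self._results(names, [0.5] * 4),
            pd.Series("amino acid", index=names),
        )
        assert len(net.nodes) == 0 and len(net.edges) == 0

    def test_significant_hub_keeps_neighbours(self):
        names = list("abcde")
        theta = self._theta(names, [(0, 1), (0, 2), (0, 3)])
        net = assemble_network(
            theta, self._results(names, [0.01, 0.9, 0.9, 0.9, 0.9]),
            pd.Series("amino acid", index=names),
        )
        assert sorted(net.nodes.index) == ["a", "b", "c", "d"]
        assert len(net.edges) == 3
        assert bool(net.nodes.loc["a", "significant"]) is True
        assert net.edges["partial_corr"].between(-1, 1).all()

    def test_communities_partition_node_set(self):
        names = [f"m{i}" for i in range(8)]
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3), (6, 7)]
        theta = self._theta(names, edges)
        net = assemble_network(
            theta, self._results(names, [0.01] * 8), pd.Series("lipid", index=names), seed=2
        )
        assert set(net.communities.index) == set(names)
        assert (net.communities >= 0).all()
        intra = net.edges[net.edges["intra_community"]]
        for _, row in intra.iterrows():
            assert net.communities[row["source"]] == net.communities[row["target"]]
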
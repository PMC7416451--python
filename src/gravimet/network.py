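"""Partial-correlation metabolite networks with spinglass communities.

Metabolites are first residualised on confounders; a sparse precision
matrix is then estimated from the residual covariance by the graphical
lasso, whose nonzero off-diagonal entries define conditional-dependence
edges with partial correlations rho_ij = -Theta_ij / sqrt(Theta_ii
Theta_jj).  Communities are found by spinglass (Potts-model) clustering
run per connected component.  Because non-targeted metabolites carry
censored cells, the covariance is estimated pairwise-complete and
projected to the PSD cone by eigenvalue clipping when needed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_glasso

from .qc import MetaboliteMatrix

__all__ = [
    "MetaboliteNetwork",
    "residualise",
    "pairwise_covariance",
    "graphical_lasso",
    "partial_correlations",
    "spinglass_communities",
    "spinglass_hamiltonian",
    "assemble_network",
]


@dataclass
class MetaboliteNetwork:
    """Sparse conditional-dependence network over metabolites."""

    nodes: pd.DataFrame
    edges: pd.DataFrame
    communities: pd.Series
    penalty: float
    resolution: float = 1.0


def residualise(m: MetaboliteMatrix, confounders: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-metabolite OLS residuals on a confounder design, standardised.

    Censored cells stay absent (NaN).  Metabolites with fewer complete
    cases than confounders + 2 are dropped and reported.
    """
    X_full = pd.concat([pd.Series(1.0, index=confounders.index, name="intercept"), confounders], axis=1)
    vals = m.values.reindex(X_full.index)
    out = {}
    dropped = []
    Xa = X_full.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise ValueError("confounder design is rank deficient")
    for col in vals.columns:
        y = vals[col].to_numpy(dtype=float)
        obs = np.isfinite(y) & np.isfinite(Xa).all(axis=1)
        if obs.sum() < Xa.shape[1] + 2:
            dropped.append(col)
            continue
        coef, *_ = np.linalg.lstsq(Xa[obs], y[obs], rcond=None)
        r = np.full_like(y, np.nan)
        r[obs] = y[obs] - Xa[obs] @ coef
        sd = np.nanstd(r, ddof=1)
        # degenerate (exactly fitted) metabolites are left unscaled
        out[col] = r / sd if sd > 1e-10 else r
    return pd.DataFrame(out, index=X_full.index), dropped


def pairwise_covariance(residuals: pd.DataFrame, clip: float = 1e-8) -> pd.DataFrame:
    """Pairwise-complete covariance with PSD projection by eigenvalue clipping."""
    S = residuals.cov(min_periods=3).to_numpy()
    if np.any(~np.isfinite(S)):
        raise ValueError("covariance undefined for some metabolite pair (too few shared cases)")
    S = 0.5 * (S + S.T)
    w, v = np.linalg.eigh(S)
    if w.min() < clip:
        S = (v * np.maximum(w, clip)) @ v.T
        S = 0.5 * (S + S.T)
    return pd.DataFrame(S, index=residuals.columns, columns=residuals.columns)


def graphical_lasso(S: pd.DataFrame, lam: float, tol: float = 1e-4, max_iter: int = 1000) -> pd.DataFrame:
    """L1-penalised precision-matrix estimate.

    Maximises log det(Theta) - tr(S Theta) - lam * sum_{i!=j} |Theta_ij|
    over positive-definite Theta.  ``lam = 0`` is the unpenalised limit,
    computed as the direct inverse of S (requires S nonsingular).
    """
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    arr = np.asarray(S, dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    w = np.linalg.eigvalsh(arr)
    if w.min() < -1e-10:
        raise ValueError("covariance must be positive semi-definite")
    if lam == 0:
        theta = np.linalg.inv(arr)
    else:
        _, theta = _sk_glasso(arr, alpha=lam, tol=tol, max_iter=max_iter)
    theta = 0.5 * (theta + theta.T)
    idx = S.index if isinstance(S, pd.DataFrame) else None
    return pd.DataFrame(theta, index=idx, columns=idx)


def partial_correlations(theta: pd.DataFrame) -> pd.DataFrame:
    """rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj), unit diagonal."""
    t = np.asarray(theta, dtype=float)
    d = np.sqrt(np.diag(t))
    rho = -t / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=theta.index, columns=theta.columns)


def spinglass_hamiltonian(adj: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Potts Hamiltonian under the configuration null model.

    H = -sum_{i<j} (A_ij - gamma * k_i k_j / (2m)) * delta(sigma_i, sigma_j).
    """
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    null = gamma * np.outer(k, k) / two_m
    same = labels[:, None] == labels[None, :]
    h = -(a - null)[same].sum() + np.trace(a - null)  # remove i=j, count i<j once
    return float(h / 2.0)


def _partitions(items):
    """All set partitions (restricted-growth enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in _partitions(items[1:]):
        for k, subset in enumerate(smaller):
            yield smaller[:k] + [[first] + subset] + smaller[k + 1 :]
        yield [[first]] + smaller


def _exact_small_component(adj: np.ndarray, gamma: float) -> np.ndarray:
    """Exhaustive Potts-Hamiltonian minimisation; exact on small graphs."""
    n = adj.shape[0]
    best_h, best = np.inf, np.zeros(n, dtype=int)
    for part in _partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for lab, block in enumerate(part):
            labels[block] = lab
        h = spinglass_hamiltonian(adj, labels, gamma)
        if h < best_h - 1e-12:
            best_h, best = h, labels.copy()
    return best


#: components at or below this size are solved by exact enumeration
#: (the annealing heuristic is unreliable and may stall on tiny graphs)
EXACT_COMPONENT_SIZE = 6


def spinglass_communities(
    adjacency: pd.DataFrame, gamma: float = 1.0, seed: int = 0, spins: int = 25,
    n_restarts: int = 5,
) -> pd.Series:
    """Spinglass community labels, run per connected component.

    Simulated-annealing minimisation of the Potts Hamiltonian (start
    T=1, geometric cooling 0.99, stop T=0.01) for components larger
    than ``EXACT_COMPONENT_SIZE``; smaller components get the exact
    enumeration optimum.  The annealer is restarted ``n_restarts``
    times per component and the lowest-Hamiltonian partition kept
    (single runs can stall in local minima).  Isolated nodes each form
    their own community, and labels from different components never
    collide.  Seed-reproducible.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    names = list(adjacency.index)
    np.fill_diagonal(a, 0.0)
    a = np.abs(a)
    g = ig.Graph.Weighted_Adjacency(a.tolist(), mode="undirected", attr="weight", loops=False)
    labels = np.full(len(names), -1, dtype=int)
    next_label = 0
    ig.set_random_number_generator(random.Random(seed))
    try:
        for comp in g.connected_components():
            comp = list(comp)
            sub_a = a[np.ix_(comp, comp)]
            if len(comp) == 1 or sub_a.sum() == 0:
                for v in comp:
                    labels[v] = next_label
                    next_label += 1
                continue
            if len(comp) <= EXACT_COMPONENT_SIZE:
                membership = _exact_small_component(sub_a, gamma)
            else:
                sub = g.induced_subgraph(comp)
                best_h, membership = np.inf, None
                for restart in range(n_restarts):
                    ig.set_random_number_generator(random.Random(seed + 1000003 * restart))
                    cl = sub.community_spinglass(
                        weights="weight",
                        spins=min(spins, len(comp)),
                        gamma=gamma,
                        start_temp=1.0,
                        stop_temp=0.01,
                        cool_fact=0.99,
                        update_rule="config",
                    )
                    cand = np.asarray(cl.membership)
                    h = spinglass_hamiltonian(sub_a, cand, gamma)
                    if h < best_h - 1e-12:
                        best_h, membership = h, cand
            for local, v in enumerate(comp):
                labels[v] = next_label + membership[local]
            next_label += int(membership.max()) + 1
    finally:
        ig.set_random_number_generator(random)
    return pd.Series(labels, index=names, name="community")


def assemble_network(
    theta: pd.DataFrame,
    results: pd.DataFrame,
    classes: pd.Series,
    alpha: float = 0.05,
    gamma: float = 1.0,
    seed: int = 0,
    penalty: float = np.nan,
    edge_tol: float = 1e-8,
) -> MetaboliteNetwork:
    """Sub-network of significant metabolites plus their neighbours.

    ``results`` must have a ``metabolite`` column and an ``fdr_q``
    column; a node is significant when its q-value is below ``alpha``.
    The retained node set is the significant metabolites together with
    their direct conditional-dependence neighbours; edges are annotated
    intra/inter community.
    """
    rho = partial_correlations(theta)
    q = results.set_index("metabolite")["fdr_q"].reindex(theta.index)
    sig = q < alpha
    adj = (np.abs(np.asarray(theta)) > edge_tol) & ~np.eye(len(theta), dtype=bool)
    keep = sig.to_numpy().copy()
    keep |= adj[:, sig.to_numpy()].any(axis=1)
    names = theta.index[keep]
    if len(names) == 0:
        empty = pd.DataFrame(columns=["source", "target", "partial_corr", "intra_community"])
        return MetaboliteNetwork(
            nodes=pd.DataFrame(columns=["class", "fdr_q", "significant", "community"]),
            edges=empty,
            communities=pd.Series(dtype=int),
            penalty=penalty,
            resolution=gamma,
        )
    sub_rho = rho.loc[names, names]
    sub_adj = pd.DataFrame(adj, index=theta.index, columns=theta.index).loc[names, names]
    weights = sub_rho.where(sub_adj, 0.0)
    comms = spinglass_communities(weights.abs(), gamma=gamma, seed=seed)
    rows = []
    for i, u in enumerate(names):
        for j in range(i + 1, len(names)):
            v = names[j]
            if sub_adj.iloc[i, j]:
                rows.append(
                    {
                        "source": u,
                        "target": v,
                        "partial_corr": float(sub_rho.iloc[i, j]),
                        "intra_community": bool(comms[u] == comms[v]),
                    }
                )
    nodes = pd.DataFrame(
        {
            "class": classes.reindex(names),
            "fdr_q": q.reindex(names),
            "significant": sig.reindex(names),
            "community": comms,
        }
    )
    return MetaboliteNetwork(
        nodes=nodes,
        edges=pd.DataFrame(rows, columns=["source", "target", "partial_corr", "intra_community"]),
        communities=comms,
        penalty=penalty,
        resolution=gamma,
    )
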
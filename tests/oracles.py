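"""Independent oracles used by the test suite.

Everything here recomputes quantities by a route deliberately different
from the package implementation: brute-force enumeration over internal
states, numerical matrix exponentials, adaptive quadrature, permutation
tests.  Oracles stay loop-based and simple; they are the reference, not
the product.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate, linalg, stats

from thermotrace.core_io import Alignment, RootedTree
from thermotrace.substitution_model import (
    GGParams,
    discretize_gamma,
    stationary_frequencies,
    t92_rate_matrix,
    T92Params,
)


# ---------------------------------------------------------------------------
# Rooted topology enumeration
# ---------------------------------------------------------------------------

def all_rooted_topologies(labels: list[str]):
    """All rooted binary leaf-labelled topologies as nested tuples.

    Counts follow (2n-3)!!: 1, 1, 3, 15, 105 for n = 1..5.
    """
    if len(labels) == 1:
        return [labels[0]]
    trees = [labels[0]]
    for label in labels[1:]:
        trees = [t2 for t in trees for t2 in _insert_leaf(t, label)]
    return trees


def _insert_leaf(tree, label):
    out = [(tree, label)]
    if isinstance(tree, tuple):
        left, right = tree
        out += [(l2, right) for l2 in _insert_leaf(left, label)]
        out += [(left, r2) for r2 in _insert_leaf(right, label)]
    return out


def topology_to_newick(tree, rng: np.random.Generator,
                       min_len: float = 0.05, max_len: float = 0.5) -> str:
    def fmt(node):
        if isinstance(node, tuple):
            inner = ",".join(fmt(c) for c in node)
            core = f"({inner})"
        else:
            core = str(node)
        return core + f":{rng.uniform(min_len, max_len):.6f}"

    inner = ",".join(fmt(c) for c in tree)
    return f"({inner});"


# ---------------------------------------------------------------------------
# Brute-force likelihood / posteriors by enumeration
# ---------------------------------------------------------------------------

def _edge_matrices(tree: RootedTree, params: GGParams):
    """Per-edge (K,4,5) matrices; 5th column sums states (missing data)."""
    from thermotrace.substitution_model import t92_transition_probs_array

    rates = discretize_gamma(params.alpha, params.n_categories).rates
    mats = {}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        P = t92_transition_probs_array(
            params.theta_branch[v], params.kappa, tree.lengths[v] * rates
        )
        mats[v] = np.concatenate([P, P.sum(axis=2, keepdims=True)], axis=2)
    return mats, rates


def enum_site_logliks(aln: Alignment, tree: RootedTree, params: GGParams
                      ) -> np.ndarray:
    """Per-site log-likelihood by summing over all internal-state
    assignments and rate categories."""
    codes = aln.to_codes(taxa_order=[tree.labels[v] for v in tree.leaves()])
    leaf_row = {v: i for i, v in enumerate(tree.leaves())}
    internals = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    mats, _ = _edge_matrices(tree, params)
    pi = stationary_frequencies(params.theta_root)
    K = params.n_categories
    S = aln.sites
    assigns = np.array(list(itertools.product(range(4), repeat=len(internals))))
    int_idx = {v: i for i, v in enumerate(internals)}
    lik = np.zeros(S)
    for k in range(K):
        factor = pi[assigns[:, int_idx[tree.root]]]          # (A,)
        site_factor = np.ones((assigns.shape[0], S))
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            par_states = assigns[:, int_idx[tree.parent[v]]]
            if tree.is_leaf(v):
                child_codes = codes[leaf_row[v]]              # (S,)
                site_factor *= mats[v][k][par_states][:, child_codes]
            else:
                factor = factor * mats[v][k][par_states, assigns[:, int_idx[v]]]
        lik += (factor[:, None] * site_factor).sum(axis=0) / K
    return np.log(lik)


def enum_node_posteriors(aln: Alignment, tree: RootedTree, params: GGParams
                         ) -> dict[int, np.ndarray]:
    """Marginal ancestral-state posteriors by brute-force Bayes."""
    codes = aln.to_codes(taxa_order=[tree.labels[v] for v in tree.leaves()])
    leaf_row = {v: i for i, v in enumerate(tree.leaves())}
    internals = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    mats, _ = _edge_matrices(tree, params)
    pi = stationary_frequencies(params.theta_root)
    K = params.n_categories
    S = aln.sites
    post = {v: np.zeros((S, 4)) for v in internals}
    for s in range(S):
        joint = {}
        total = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            st = dict(zip(internals, assign))
            for v, row in leaf_row.items():
                st[v] = codes[row, s]
            for k in range(K):
                p = pi[st[tree.root]] / K
                for v in range(tree.n_nodes):
                    if v == tree.root:
                        continue
                    p *= mats[v][k][st[tree.parent[v]], st[v]]
                total += p
                for v in internals:
                    post[v][s, st[v]] += p
        for v in internals:
            post[v][s] /= total
    return post


# ---------------------------------------------------------------------------
# Independent homogeneous T92+gamma likelihood (expm-based pruning)
# ---------------------------------------------------------------------------

def homogeneous_loglik(aln: Alignment, tree: RootedTree, theta: float,
                       kappa: float, alpha: float, K: int) -> float:
    """Stationary T92+gamma likelihood via a separate, simple pruning pass
    built on numerical matrix exponentials (no scaling, no compression)."""
    Q = t92_rate_matrix(T92Params(theta, kappa))
    rates = discretize_gamma(alpha, K).rates
    codes = aln.to_codes(taxa_order=[tree.labels[v] for v in tree.leaves()])
    leaf_row = {v: i for i, v in enumerate(tree.leaves())}
    pi = stationary_frequencies(theta)
    S = aln.sites
    total = np.zeros(S)
    for r in rates:
        partial = {}
        for v in tree.postorder():
            if tree.is_leaf(v):
                L = np.zeros((S, 4))
                c = codes[leaf_row[v]]
                miss = c == 4
                L[np.arange(S)[~miss], c[~miss]] = 1.0
                L[miss] = 1.0
            else:
                L = np.ones((S, 4))
                for child in tree.children[v]:
                    P = linalg.expm(Q * tree.lengths[child] * r)
                    L *= partial[child] @ P.T
            partial[v] = L
        total += (partial[tree.root] @ pi) / len(rates)
    return float(np.log(total).sum())


# ---------------------------------------------------------------------------
# Gamma discretization by adaptive quadrature
# ---------------------------------------------------------------------------

def quadrature_gamma_rates(alpha: float, K: int) -> np.ndarray:
    edges = stats.gamma.ppf(np.arange(K + 1) / K, a=alpha, scale=1.0 / alpha)
    rates = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = integrate.quad(
            lambda x: x * stats.gamma.pdf(x, a=alpha, scale=1.0 / alpha),
            lo, hi, limit=200,
        )
        rates.append(val * K)
    rates = np.asarray(rates)
    return rates / rates.mean()


# ---------------------------------------------------------------------------
# Brownian (GLS) check for independent contrasts
# ---------------------------------------------------------------------------

def brownian_tip_covariance(tree: RootedTree) -> np.ndarray:
    """Tip covariance under Brownian motion: shared root-to-MRCA path."""
    leaves = tree.leaves()
    n = len(leaves)
    paths = {}
    for v in leaves:
        path = []
        u = v
        while u >= 0:
            path.append(u)
            u = tree.parent[u]
        paths[v] = path
    depths = tree.depths()
    C = np.zeros((n, n))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            shared = set(paths[a]) & set(paths[b])
            mrca = max(shared, key=lambda u: depths[u])
            C[i, j] = depths[mrca]
    return C


def contrast_weight_matrix(tree: RootedTree) -> np.ndarray:
    """Extract the linear map tips -> contrasts by probing with unit traits."""
    from thermotrace.thermometry import pic_contrasts

    leaves = tree.leaves()
    labels = [tree.labels[v] for v in leaves]
    cols = []
    for i in range(len(leaves)):
        trait = {lab: float(i == j) for j, lab in enumerate(labels)}
        cols.append(pic_contrasts(tree, trait).contrasts)
    return np.stack(cols, axis=1)      # (n_contrasts, n_tips)


# ---------------------------------------------------------------------------
# Permutation rank-sum test
# ---------------------------------------------------------------------------

def permutation_ranksum_pvalue(a: np.ndarray, b: np.ndarray,
                               n_perm: int = 10000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the rank-sum of sample a."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = len(a)
    obs = ranks[:na].sum()
    center = na * (len(pooled) + 1) / 2.0
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        if abs(perm[:na].sum() - center) >= abs(obs - center) - 1e-9:
            count += 1
    return count / n_perm
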
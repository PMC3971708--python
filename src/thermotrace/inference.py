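"""Likelihood inference under the branch-wise non-homogeneous T92 model.

The likelihood is computed by Felsenstein pruning with a branch-specific
transition matrix ``P_b = exp(Q(theta_b, kappa) * t_b * r_k)`` for each
branch ``b`` and gamma rate category ``k``, and the root state distribution
``pi(theta_root)``.  Site likelihoods mix the K equal-weight categories.
Gaps and ``N`` are missing data (all-ones partial vectors).  Alignment
columns are pattern-compressed, and partial likelihoods are rescaled per
node to avoid underflow.

Parameter fitting maximizes the log-likelihood over all branch
equilibrium-GC values, the root GC, kappa, and the gamma shape alpha
(branch lengths stay fixed by default).  Because the likelihood is
multilinear in the set of per-branch transition matrices, the derivative
with respect to any parameter reduces to contractions of per-edge
"flow" tensors (outer products of downward and upward partials) with
dP/dparameter; a single up-down pass therefore yields the whole gradient
at roughly three times the cost of one likelihood evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .core_io import (
    Alignment,
    RootedTree,
    SiteMask,
    check_pairing,
)
from .substitution_model import (
    GGParams,
    discretize_gamma,
    stationary_frequencies,
    t92_transition_probs_array,
)

_LOG = logging.getLogger(__name__)

__all__ = [
    "LikelihoodResult",
    "SiteRateProfile",
    "SitePartition",
    "FitOptions",
    "loglikelihood",
    "fit_gg",
    "fit_homogeneous",
    "site_rates",
    "partition_sites",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class LikelihoodResult:
    """Log-likelihood (total and per site) with the parameters that produced it."""

    loglik: float
    per_site_logliks: np.ndarray
    params: GGParams
    n_free_params: int
    converged: bool = True
    n_iterations: int = 0
    grad_norm: float = float("nan")

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_params - 2.0 * self.loglik


@dataclass
class SiteRateProfile:
    """Per-site posterior over rate categories and posterior-mean rates."""

    category_posterior: np.ndarray   # (sites, K)
    mean_rate: np.ndarray            # (sites,)
    rates: np.ndarray                # (K,) category rates


@dataclass
class SitePartition:
    """Exhaustive, disjoint slow/fast split of alignment sites."""

    slow: SiteMask
    fast: SiteMask
    threshold: float


@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit_gg` / :func:`fit_homogeneous`.

    Convergence requires the log-likelihood change to fall below
    ``loglik_tol`` and the max gradient component (on the transformed
    scale) below ``grad_tol``.
    """

    n_starts: int = 3
    max_iter: int = 500
    loglik_tol: float = 1e-6
    grad_tol: float = 1e-3
    seed: int = 0
    optimize_branch_lengths: bool = False


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------

_LOG_EPS = 1e-300


class PruningEngine:
    """Pattern-compressed pruning machinery bound to one (alignment, tree).

    Internal workhorse shared by the likelihood, the fitters, the site-rate
    posteriors and the ancestral reconstruction; public entry points wrap
    it.
    """

    def __init__(self, aln: Alignment, tree: RootedTree, n_categories: int = 8):
        check_pairing(aln, tree)
        self.tree = tree
        self.K = int(n_categories)
        self.leaf_ids = tree.leaves()
        order = [tree.labels[v] for v in self.leaf_ids]
        codes = aln.to_codes(taxa_order=order)
        patterns, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns                  # (n_leaves, P)
        self.pattern_of_site = inverse.ravel()    # (sites,)
        self.weights = counts.astype(float)       # (P,)
        self.n_sites = codes.shape[1]
        self.n_patterns = patterns.shape[1]
        # leaf partials: one-hot, all-ones for missing  -> (P, 4) per leaf
        self.tip = {}
        eye5 = np.vstack([np.eye(4), np.ones(4)])
        for row, v in enumerate(self.leaf_ids):
            self.tip[v] = eye5[patterns[row]]
        # edges keyed by child node, in post-order
        self.edges = [v for v in tree.postorder() if v != tree.root]
        self.edge_index = {v: i for i, v in enumerate(self.edges)}
        self.edge_lengths = np.array([tree.lengths[v] for v in self.edges])

    # -- transition tensors -------------------------------------------------

    def edge_probs(self, params: GGParams, rates: np.ndarray | None = None,
                   lengths: np.ndarray | None = None,
                   thetas: np.ndarray | None = None,
                   kappa: float | None = None) -> np.ndarray:
        """(B, K, 4, 4) transition matrices for every edge x category."""
        if rates is None:
            rates = params.rate_classes().rates
        if lengths is None:
            lengths = self.edge_lengths
        if thetas is None:
            thetas = np.array([params.theta_branch[v] for v in self.edges])
        if kappa is None:
            kappa = params.kappa
        dist = lengths[:, None] * rates[None, :]
        return t92_transition_probs_array(thetas[:, None], kappa, dist)

    # -- upward (pruning) pass ----------------------------------------------

    def up_pass(self, P: np.ndarray, pi_root: np.ndarray):
        """Post-order pass returning partials, scalers and messages.

        Returns ``(L, C, M, ll_k)`` where ``L[v]`` is the scaled conditional
        likelihood at node v ((K,P,4); (P,4) at leaves), ``C[v]`` the
        accumulated log-scaler ((K,P); 0.0 at leaves), ``M[v]`` the message
        ``P_v @ L_v`` sent from v to its parent, and ``ll_k`` the (K, P)
        per-category pattern log-likelihoods.
        """
        tree, K = self.tree, self.K
        n = tree.n_nodes
        L: list = [None] * n
        C: list = [0.0] * n
        M: list = [None] * n
        for v in tree.postorder():
            if tree.is_leaf(v):
                L[v] = self.tip[v]
            else:
                c1, c2 = tree.children[v]
                prod = M[c1] * M[c2]
                # a zero partial is legal (e.g. a zero-length branch or a
                # zero-rate category with mismatching tips); it only becomes
                # an error if the site is impossible in *every* category
                m = prod.max(axis=2)
                m_safe = np.where(m > 0.0, m, 1.0)
                L[v] = prod / m_safe[..., None]
                C[v] = C[c1] + C[c2] + np.log(m_safe)
            if v != tree.root:
                Pv = P[self.edge_index[v]]           # (K,4,4)
                Lv = L[v]
                if Lv.ndim == 2:                     # leaf: (P,4)
                    M[v] = np.matmul(Lv[None], Pv.transpose(0, 2, 1))
                else:
                    M[v] = np.matmul(Lv, Pv.transpose(0, 2, 1))
        root = tree.root
        vals = L[root] @ pi_root
        with np.errstate(divide="ignore"):
            ll_k = np.where(vals > 0.0, np.log(np.maximum(vals, _LOG_EPS)), -np.inf)
        ll_k = ll_k + C[root]
        return L, C, M, ll_k

    def pattern_logliks(self, ll_k: np.ndarray) -> np.ndarray:
        """Mix equal-weight categories: (K,P) -> (P,) pattern log-likelihoods."""
        return special.logsumexp(ll_k, axis=0) - np.log(self.K)

    def loglik(self, params: GGParams) -> tuple[float, np.ndarray]:
        params.validate_for(self.tree)
        P = self.edge_probs(params)
        pi_root = stationary_frequencies(params.theta_root)
        *_, ll_k = self.up_pass(P, pi_root)
        sll = self.pattern_logliks(ll_k)
        total = float(self.weights @ sll)
        if not np.isfinite(total):
            bad = int(np.flatnonzero(~np.isfinite(sll))[0])
            site = int(np.flatnonzero(self.pattern_of_site == bad)[0])
            raise FloatingPointError(
                f"site {site} has zero likelihood in every rate category "
                "(data impossible under the model, e.g. a mismatch across "
                "a zero-length branch)"
            )
        return total, sll[self.pattern_of_site]

    # -- downward pass -------------------------------------------------------

    def down_pass(self, P: np.ndarray, pi_root: np.ndarray, L, C, M):
        """Pre-order pass computing per-edge flow tensors.

        For the edge above node v (parent u, sibling w) the flow is
        ``A[v] = D_u * M_w`` with log-scaler ``SA[v]``, where ``D_u`` is the
        probability of all data outside u's subtree jointly with the state
        at u.  ``A[v] . P_v . L_v`` recovers the site likelihood, so A is
        both the gradient kernel and the outside term of marginal ancestral
        posteriors.
        """
        tree = self.tree
        n = tree.n_nodes
        D: list = [None] * n
        E: list = [0.0] * n
        A: list = [None] * n
        SA: list = [None] * n
        D[tree.root] = np.broadcast_to(
            pi_root, (self.K, self.n_patterns, 4)
        )
        for u in tree.preorder():
            if tree.is_leaf(u):
                continue
            c1, c2 = tree.children[u]
            for v, w in ((c1, c2), (c2, c1)):
                A[v] = D[u] * M[w]
                SA[v] = E[u] + C[w]
                if not tree.is_leaf(v):
                    Dv = np.matmul(A[v], P[self.edge_index[v]])
                    m = np.maximum(Dv.max(axis=2), _LOG_EPS)
                    D[v] = Dv / m[..., None]
                    E[v] = SA[v] + np.log(m)
        return A, SA

    # -- gradient ------------------------------------------------------------

    def loglik_and_grad(self, params: GGParams,
                        with_branch_lengths: bool = False,
                        lengths: np.ndarray | None = None):
        """Log-likelihood and its gradient w.r.t. all model parameters.

        Returns ``(loglik, grad)`` with ``grad`` a dict holding
        ``theta_root``, ``theta_branch`` (array over ``self.edges``),
        ``kappa``, ``alpha`` and optionally ``lengths``.
        """
        params.validate_for(self.tree)
        if lengths is None:
            lengths = self.edge_lengths
        rc = params.rate_classes()
        rates = rc.rates
        thetas = np.array([params.theta_branch[v] for v in self.edges])
        P = self.edge_probs(params, rates=rates, lengths=lengths, thetas=thetas)
        pi_root = stationary_frequencies(params.theta_root)
        L, C, M, ll_k = self.up_pass(P, pi_root)
        sll = self.pattern_logliks(ll_k)
        total = float(self.weights @ sll)
        A, SA = self.down_pass(P, pi_root, L, C, M)

        # per-edge contraction tensors G[v][k,i,j] = sum_s w_s R A_i L_j
        logK = np.log(self.K)
        G = np.empty((len(self.edges), self.K, 4, 4))
        for b, v in enumerate(self.edges):
            Cv = C[v]
            R = np.exp(SA[v] + Cv - sll[None, :] - logK) * self.weights[None, :]
            T = A[v] * R[..., None]                     # (K,P,4)
            Lv = L[v]
            if Lv.ndim == 2:
                G[b] = np.matmul(T.transpose(0, 2, 1), Lv[None])
            else:
                G[b] = np.matmul(T.transpose(0, 2, 1), Lv)

        kappa = params.kappa
        grad: dict = {}

        # d/d theta_b : central difference on the closed form, per edge
        h = 1e-6
        dist = lengths[:, None] * rates[None, :]
        Pp = t92_transition_probs_array((thetas + h)[:, None], kappa, dist)
        Pm = t92_transition_probs_array((thetas - h)[:, None], kappa, dist)
        dP = (Pp - Pm) / (2 * h)
        grad["theta_branch"] = np.einsum("bkij,bkij->b", G, dP)

        # d/d kappa : all edges share kappa
        hk = 1e-6 * max(1.0, kappa)
        Pp = t92_transition_probs_array(thetas[:, None], kappa + hk, dist)
        Pm = t92_transition_probs_array(thetas[:, None], kappa - hk, dist)
        grad["kappa"] = float(np.einsum("bkij,bkij->", G, (Pp - Pm) / (2 * hk)))

        # d/d alpha : rates move, every edge/category matrix moves
        if self.K > 1:
            ha = 1e-6 * max(1.0, params.alpha)
            rp = discretize_gamma(params.alpha + ha, self.K).rates
            rm = discretize_gamma(params.alpha - ha, self.K).rates
            Pp = t92_transition_probs_array(
                thetas[:, None], kappa, lengths[:, None] * rp[None, :])
            Pm = t92_transition_probs_array(
                thetas[:, None], kappa, lengths[:, None] * rm[None, :])
            grad["alpha"] = float(np.einsum("bkij,bkij->", G, (Pp - Pm) / (2 * ha)))
        else:
            grad["alpha"] = 0.0

        # d/d theta_root : root frequency vector only
        dpi = np.array([-0.5, 0.5, 0.5, -0.5])
        root = self.tree.root
        num = (L[root] @ dpi) * np.exp(C[root] - sll[None, :] - logK)
        grad["theta_root"] = float(self.weights @ num.sum(axis=0))

        if with_branch_lengths:
            ht = 1e-7
            lo = np.maximum(lengths - ht, 0.0)
            Pp = t92_transition_probs_array(
                thetas[:, None], kappa, (lengths + ht)[:, None] * rates[None, :])
            Pm = t92_transition_probs_array(
                thetas[:, None], kappa, lo[:, None] * rates[None, :])
            denom = (lengths + ht) - lo
            grad["lengths"] = np.einsum(
                "bkij,bkij->b", G, (Pp - Pm) / denom[:, None, None, None])
        return total, grad

    # -- posteriors ----------------------------------------------------------

    def category_posteriors(self, params: GGParams) -> tuple[np.ndarray, np.ndarray]:
        """(sites, K) posterior over rate categories, and the category rates."""
        P = self.edge_probs(params)
        pi_root = stationary_frequencies(params.theta_root)
        *_, ll_k = self.up_pass(P, pi_root)
        post = special.softmax(ll_k, axis=0).T        # (P, K); equal priors
        return post[self.pattern_of_site], params.rate_classes().rates

    def state_posteriors(self, params: GGParams) -> dict[int, np.ndarray]:
        """Marginal posterior state probabilities, node -> (sites, 4).

        Rate categories are marginalized with their site-specific
        posterior weight (joint normalization over state x category).
        """
        P = self.edge_probs(params)
        pi_root = stationary_frequencies(params.theta_root)
        L, C, M, ll_k = self.up_pass(P, pi_root)
        sll = self.pattern_logliks(ll_k)
        A, SA = self.down_pass(P, pi_root, L, C, M)
        logK = np.log(self.K)
        out: dict[int, np.ndarray] = {}
        tree = self.tree
        for v in range(tree.n_nodes):
            if tree.is_leaf(v):
                continue
            if v == tree.root:
                num = pi_root[None, None, :] * L[v]
                scale = np.asarray(C[v]) - sll[None, :] - logK
            else:
                Dv = np.matmul(A[v], P[self.edge_index[v]])
                num = Dv * L[v]
                scale = SA[v] + np.asarray(C[v]) - sll[None, :] - logK
            post = (num * np.exp(scale)[..., None]).sum(axis=0)   # (P, 4)
            post /= post.sum(axis=1, keepdims=True)
            out[v] = post[self.pattern_of_site]
        return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def loglikelihood(aln: Alignment, tree: RootedTree, params: GGParams
                  ) -> LikelihoodResult:
    """Non-homogeneous T92 log-likelihood of an alignment on a rooted tree."""
    engine = PruningEngine(aln, tree, params.n_categories)
    total, per_site = engine.loglik(params)
    n_free = len(engine.edges) + 3
    return LikelihoodResult(total, per_site, params, n_free)


def _auto_init(aln: Alignment, tree: RootedTree, n_categories: int) -> GGParams:
    """Documented default initialization: every theta at the observed global
    GC, kappa = 2, alpha = 0.5."""
    gc = float(np.clip(aln.gc_content().mean(), 0.02, 0.98))
    return GGParams.homogeneous(tree, gc, 2.0, 0.5, n_categories)


def _logit(x):
    return np.log(x) - np.log1p(-x)


def _expit(x):
    return special.expit(x)


class _Objective:
    """Negative log-likelihood on transformed parameters for one model family."""

    def __init__(self, engine: PruningEngine, n_categories: int,
                 homogeneous: bool, optimize_bl: bool):
        self.engine = engine
        self.K = n_categories
        self.homogeneous = homogeneous
        self.optimize_bl = optimize_bl
        self.B = len(engine.edges)
        self.n_evals = 0

    # vector layout (GG):   [logit th_root, logit th_b * B, log kappa, log alpha, (log t_b * B)]
    # vector layout (hom.): [logit theta, log kappa, log alpha, (log t_b * B)]

    def pack(self, params: GGParams, lengths: np.ndarray | None = None) -> np.ndarray:
        if self.homogeneous:
            head = [_logit(params.theta_root)]
        else:
            head = [_logit(params.theta_root)] + [
                _logit(params.theta_branch[v]) for v in self.engine.edges
            ]
        x = np.array(head + [np.log(params.kappa), np.log(params.alpha)])
        if self.optimize_bl:
            if lengths is None:
                lengths = self.engine.edge_lengths
            x = np.concatenate([x, np.log(np.maximum(lengths, 1e-8))])
        return x

    def unpack(self, x: np.ndarray) -> tuple[GGParams, np.ndarray]:
        if self.homogeneous:
            theta = float(_expit(x[0]))
            thetas = {v: theta for v in self.engine.edges}
            kappa, alpha = np.exp(x[1]), np.exp(x[2])
            tail = x[3:]
        else:
            theta = float(_expit(x[0]))
            tb = _expit(x[1 : 1 + self.B])
            thetas = {v: float(t) for v, t in zip(self.engine.edges, tb)}
            kappa, alpha = np.exp(x[1 + self.B]), np.exp(x[2 + self.B])
            tail = x[3 + self.B :]
        lengths = np.exp(tail) if self.optimize_bl else self.engine.edge_lengths
        params = GGParams(theta, thetas, float(kappa), float(alpha), self.K)
        return params, lengths

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        self.n_evals += 1
        try:
            params, lengths = self.unpack(x)
            ll, grad = self.engine.loglik_and_grad(
                params, with_branch_lengths=self.optimize_bl, lengths=lengths
            )
        except (ValueError, FloatingPointError):
            # infeasible trial point during line search (parameter at a
            # boundary or an impossible-site configuration): step back
            return 1e10, np.zeros_like(x)
        if not np.isfinite(ll):
            return 1e10, np.zeros_like(x)
        # chain rule through logit / log transforms
        th_r = params.theta_root
        g_root = grad["theta_root"] * th_r * (1 - th_r)
        if self.homogeneous:
            tb = np.array([params.theta_branch[self.engine.edges[0]]])
            g_theta = float(grad["theta_branch"].sum()) * tb[0] * (1 - tb[0]) + g_root
            g = [g_theta]
        else:
            tb = np.array([params.theta_branch[v] for v in self.engine.edges])
            g = [g_root] + list(grad["theta_branch"] * tb * (1 - tb))
        g += [grad["kappa"] * params.kappa, grad["alpha"] * params.alpha]
        if self.optimize_bl:
            g += list(grad["lengths"] * lengths)
        return -ll, -np.asarray(g)


def _fit(aln: Alignment, tree: RootedTree, init: GGParams | str,
         options: FitOptions | None, n_categories: int, homogeneous: bool
         ) -> LikelihoodResult:
    opts = options or FitOptions()
    if isinstance(init, GGParams):
        n_categories = init.n_categories
    engine = PruningEngine(aln, tree, n_categories)
    if isinstance(init, str):
        if init != "auto":
            raise ValueError(f"init must be GGParams or 'auto', got {init!r}")
        init_params = _auto_init(aln, tree, n_categories)
    else:
        init_params = init
        init_params.validate_for(tree)
    obj = _Objective(engine, n_categories, homogeneous, opts.optimize_branch_lengths)
    x0 = obj.pack(init_params)
    rng = np.random.default_rng(opts.seed)
    f0, _ = obj(x0)
    ftol = opts.loglik_tol / max(1.0, abs(f0))

    best = None
    for start in range(max(1, opts.n_starts)):
        x_start = x0 if start == 0 else x0 + rng.normal(0.0, 0.4, size=x0.size)
        res = optimize.minimize(
            obj, x_start, jac=True, method="L-BFGS-B",
            options={"maxiter": opts.max_iter, "ftol": ftol, "gtol": opts.grad_tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    params, lengths = obj.unpack(best.x)
    grad_norm = float(np.max(np.abs(best.jac)))
    converged = bool(best.success) or grad_norm < opts.grad_tol
    if not converged:
        _LOG.warning(
            "optimizer did not converge after %d iterations (|grad|=%.3g): %s",
            best.nit, grad_norm, best.message,
        )
    if opts.optimize_branch_lengths:
        new_lengths = tree.lengths.copy()
        for v, t in zip(engine.edges, lengths):
            new_lengths[v] = t
        tree = tree.with_lengths(new_lengths)
        engine = PruningEngine(aln, tree, n_categories)
    total, per_site = engine.loglik(params)
    n_free = (3 if homogeneous else len(engine.edges) + 3) + (
        len(engine.edges) if opts.optimize_branch_lengths else 0
    )
    return LikelihoodResult(
        total, per_site, params, n_free,
        converged=converged, n_iterations=int(best.nit), grad_norm=grad_norm,
    )


def fit_gg(aln: Alignment, tree: RootedTree, init: GGParams | str = "auto",
           options: FitOptions | None = None, n_categories: int = 8
           ) -> LikelihoodResult:
    """ML fit of the branch-wise non-homogeneous T92 (Galtier-Gouy) model.

    Maximizes over every branch's equilibrium GC, the root GC, kappa and
    the gamma shape (thetas on the logit scale, kappa/alpha on the log
    scale); branch lengths stay fixed unless
    ``options.optimize_branch_lengths``.  Deterministic given ``init`` and
    ``options.seed``; multi-start count via ``options.n_starts``.
    """
    return _fit(aln, tree, init, options, n_categories, homogeneous=False)


def fit_homogeneous(aln: Alignment, tree: RootedTree,
                    options: FitOptions | None = None, n_categories: int = 8,
                    init: GGParams | str = "auto") -> LikelihoodResult:
    """ML fit of the stationary (single-theta) T92 + gamma model."""
    return _fit(aln, tree, init, options, n_categories, homogeneous=True)


def site_rates(aln: Alignment, tree: RootedTree, params: GGParams
               ) -> SiteRateProfile:
    """Posterior rate-category membership and posterior-mean rate per site."""
    engine = PruningEngine(aln, tree, params.n_categories)
    post, rates = engine.category_posteriors(params)
    return SiteRateProfile(post, post @ rates, rates)


def partition_sites(profile: SiteRateProfile, quantile: float = 0.5
                    ) -> SitePartition:
    """Split sites into slow/fast at an empirical quantile of the
    posterior-mean rate.

    Slow sites are those with rate <= the quantile; ties are broken by site
    index (lower index goes slow) so the split is deterministic and
    exhaustive.  If every rate is identical the split falls back to index
    order while honoring the quantile proportion (with a warning).
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError(f"quantile must be in (0,1), got {quantile}")
    rates = np.asarray(profile.mean_rate, dtype=float)
    n = rates.size
    if n < 2:
        raise ValueError("need at least 2 sites to partition")
    threshold = float(np.quantile(rates, quantile))
    n_slow = int(np.sum(rates <= threshold))
    if np.all(rates == rates[0]) or n_slow in (0, n):
        _LOG.warning("degenerate rate distribution; splitting by site index")
        n_slow = int(np.clip(round(quantile * n), 1, n - 1))
    order = np.lexsort((np.arange(n), rates))
    slow_idx = np.sort(order[:n_slow])
    fast_idx = np.sort(order[n_slow:])
    return SitePartition(SiteMask(slow_idx), SiteMask(fast_idx), threshold)
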
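"""Tamura (1992) nucleotide model, branch-wise GC parameterization, and
discrete-gamma rate classes.

The T92 model is a reversible 4-state substitution process parameterized by
the equilibrium G+C content ``theta`` and a transition/transversion rate
parameter ``kappa``.  Its stationary distribution (state order A, C, G, T,
fixed throughout the package) is::

    pi_A = pi_T = (1 - theta) / 2,   pi_C = pi_G = theta / 2

The branch-wise non-homogeneous (Galtier-Gouy style) extension keeps T92
dynamics but gives every branch its own equilibrium GC ``theta_b``, plus an
independent GC content ``theta_root`` for the root state distribution;
``kappa`` and the gamma shape ``alpha`` are shared across branches.

Rate matrices are scaled so one unit of branch length is one expected
substitution per site *at that branch's own equilibrium* — branch lengths
keep their substitutions/site meaning branch by branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import special

from .core_io import RootedTree

__all__ = [
    "T92Params",
    "GGParams",
    "RateClasses",
    "stationary_frequencies",
    "t92_rate_matrix",
    "t92_transition_probs",
    "t92_transition_probs_array",
    "discretize_gamma",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class T92Params:
    """Homogeneous T92 parameters: equilibrium GC and kappa."""

    theta: float
    kappa: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta must be in (0,1), got {self.theta}")
        if not (self.kappa > 0.0):
            raise ValueError(f"kappa must be > 0, got {self.kappa}")


@dataclass(frozen=True)
class RateClasses:
    """K positive rates with probabilities, normalized to unit mean rate."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if r.shape != w.shape or r.ndim != 1:
            raise ValueError("rates and weights must be 1-D and equal length")
        if np.any(r <= 0) or np.any(w < 0):
            raise ValueError("rates must be positive, weights non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if abs(float(w @ r) - 1.0) > 1e-9:
            raise ValueError("rate classes must have unit mean")
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "weights", w)

    @property
    def n_categories(self) -> int:
        return int(self.rates.size)


@dataclass(frozen=True)
class GGParams:
    """Branch-wise non-homogeneous T92 parameters on a rooted tree.

    ``theta_branch[v]`` is the equilibrium GC of the branch *above* node
    ``v`` (keyed by child-node ID, so the root has no entry); ``theta_root``
    is the GC content of the root state distribution; ``kappa`` and the
    gamma shape ``alpha`` are shared across branches.
    """

    theta_root: float
    theta_branch: Mapping[int, float]
    kappa: float
    alpha: float
    n_categories: int = 8

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_root < 1.0):
            raise ValueError(f"theta_root must be in (0,1), got {self.theta_root}")
        for v, th in self.theta_branch.items():
            if not (0.0 < th < 1.0):
                raise ValueError(f"theta for branch above node {v} out of (0,1): {th}")
        if not (self.kappa > 0.0):
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if not (self.alpha > 0.0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    def validate_for(self, tree: RootedTree) -> None:
        want = {v for v in range(tree.n_nodes) if v != tree.root}
        have = set(self.theta_branch)
        if want != have:
            raise ValueError(
                "theta_branch keys do not match tree branches; missing: "
                f"{sorted(want - have)}, extra: {sorted(have - want)}"
            )

    def rate_classes(self) -> RateClasses:
        return discretize_gamma(self.alpha, self.n_categories)

    @classmethod
    def homogeneous(cls, tree: RootedTree, theta: float, kappa: float,
                    alpha: float, n_categories: int = 8) -> "GGParams":
        branches = {v: theta for v in range(tree.n_nodes) if v != tree.root}
        return cls(theta, branches, kappa, alpha, n_categories)


# ---------------------------------------------------------------------------
# T92 matrices
# ---------------------------------------------------------------------------

def stationary_frequencies(theta: float | np.ndarray) -> np.ndarray:
    """Stationary frequencies [pi_A, pi_C, pi_G, pi_T] for equilibrium GC."""
    theta = np.asarray(theta, dtype=float)
    at = (1.0 - theta) / 2.0
    gc = theta / 2.0
    return np.stack(np.broadcast_arrays(at, gc, gc, at), axis=-1)


def _t92_scale(theta: float | np.ndarray, kappa: float) -> np.ndarray:
    # expected unscaled substitution rate: -sum_i pi_i q_ii
    theta = np.asarray(theta, dtype=float)
    return kappa * theta * (1.0 - theta) + 0.5


def t92_rate_matrix(p: T92Params) -> np.ndarray:
    """T92 rate matrix Q (state order A,C,G,T), scaled to unit mean rate.

    Off-diagonals are ``kappa * pi_j`` for transitions (A<->G, C<->T) and
    ``pi_j`` for transversions; the matrix is then divided by the expected
    substitution rate so branch lengths are in substitutions/site.
    """
    pi = stationary_frequencies(p.theta)
    q = np.tile(pi, (4, 1))
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # transitions
        q[i, j] *= p.kappa
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q / _t92_scale(p.theta, p.kappa)


def t92_transition_probs_array(theta, kappa, distance) -> np.ndarray:
    """Closed-form T92 transition probabilities, broadcasting over inputs.

    ``distance`` is the evolutionary distance t*r in expected
    substitutions/site.  ``theta`` and ``distance`` broadcast against each
    other; the result has shape ``broadcast(theta, distance).shape + (4, 4)``.

    The closed form follows from the TN93 spectral decomposition with the
    T92 constraint pi_A + pi_G = pi_C + pi_T = 1/2: with d the unscaled
    time, e2 = exp(-d) is the transversion eigenmode and
    e3 = exp(-d (kappa+1)/2) the transition eigenmode.
    """
    theta = np.asarray(theta, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise ValueError("branch length * rate must be non-negative")
    theta, distance = np.broadcast_arrays(theta, distance)
    d = distance / _t92_scale(theta, kappa)
    e2 = np.exp(-d)
    e3 = np.exp(-d * (kappa + 1.0) / 2.0)
    pa = (1.0 - theta) / 2.0   # = pi_T
    pg = theta / 2.0           # = pi_C
    out = np.empty(theta.shape + (4, 4))
    # rows in state order A, C, G, T
    out[..., 0, 0] = pa + pa * e2 + 2 * pg * e3
    out[..., 0, 1] = pg * (1 - e2)
    out[..., 0, 2] = pg + pg * e2 - 2 * pg * e3
    out[..., 0, 3] = pa * (1 - e2)
    out[..., 1, 0] = pa * (1 - e2)
    out[..., 1, 1] = pg + pg * e2 + 2 * pa * e3
    out[..., 1, 2] = pg * (1 - e2)
    out[..., 1, 3] = pa + pa * e2 - 2 * pa * e3
    out[..., 2, 0] = pa + pa * e2 - 2 * pa * e3
    out[..., 2, 1] = pg * (1 - e2)
    out[..., 2, 2] = pg + pg * e2 + 2 * pa * e3
    out[..., 2, 3] = pa * (1 - e2)
    out[..., 3, 0] = pa * (1 - e2)
    out[..., 3, 1] = pg + pg * e2 - 2 * pg * e3
    out[..., 3, 2] = pg * (1 - e2)
    out[..., 3, 3] = pa + pa * e2 + 2 * pg * e3
    return out


def t92_transition_probs(p: T92Params, t: float, r: float = 1.0,
                         method: str = "closed_form") -> np.ndarray:
    """Transition probability matrix P = exp(Q t r) for the T92 model.

    ``method`` is ``closed_form`` (default) or ``expm`` (numerical matrix
    exponential of :func:`t92_rate_matrix`); both agree to ~1e-12 and the
    numerical route exists as an internal cross-check.
    """
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    if r <= 0:
        raise ValueError(f"rate multiplier must be positive, got {r}")
    if method == "closed_form":
        return t92_transition_probs_array(p.theta, p.kappa, t * r)
    if method == "expm":
        from scipy.linalg import expm

        return expm(t92_rate_matrix(p) * (t * r))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Discrete gamma
# ---------------------------------------------------------------------------

def discretize_gamma(alpha: float, n_categories: int,
                     representation: str = "mean") -> RateClasses:
    """Discretize a unit-mean gamma into K equal-weight rate categories.

    The continuous distribution is Gamma(shape=alpha, rate=alpha) (mean 1).
    With ``representation='mean'`` (default) each category's rate is the
    conditional mean of the density over that category's quantile interval;
    ``'median'`` uses the interval midpoint quantile instead.  Rates are
    renormalized so the (equal-weight) mean is exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    k = int(n_categories)
    if k == 1:
        return RateClasses(np.ones(1), np.ones(1))
    probs = np.arange(k + 1) / k
    if representation == "mean":
        # E[X 1{X<=q}] for Gamma(a, rate=a) is the regularized incomplete
        # gamma P(a+1, a q); category mean = K * increment of that integral.
        edges = special.gammaincinv(alpha, probs[1:-1]) / alpha
        cum = np.concatenate(([0.0], special.gammainc(alpha + 1.0, alpha * edges), [1.0]))
        rates = np.diff(cum) * k
    elif representation == "median":
        mids = (probs[:-1] + probs[1:]) / 2.0
        rates = special.gammaincinv(alpha, mids) / alpha
    else:
        raise ValueError(f"unknown representation {representation!r}")
    weights = np.full(k, 1.0 / k)
    # floor keeps extreme-alpha categories strictly positive
    rates = np.maximum(rates, 1e-10)
    rates = rates / float(weights @ rates)
    return RateClasses(rates, weights)
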
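"""Molecular thermometers: composition -> optimal growth temperature.

Across Bacteria and Archaea the G+C content of rRNA stem regions (and, for
proteins, leading axes of a correspondence analysis of amino-acid
composition) correlates strongly with optimal growth temperature (OGT).
An ordinary least-squares regression of tip OGT on tip composition — the
"molecular thermometer" — converts reconstructed ancestral compositions
into ancestral temperature estimates.  Phylogenetically independent
contrasts guard the correlation against phylogenetic inertia, and
two-sample Wilcoxon rank-sum tests compare the posterior OGT sample sets
of two ancestors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import RootedTree
from .ancestral import CompositionSummary

_LOG = logging.getLogger(__name__)

__all__ = [
    "Thermometer",
    "OGTEstimate",
    "ContrastSet",
    "build_thermometer",
    "pic_contrasts",
    "pic_correlation",
    "estimate_ancestral_ogt",
    "compare_nodes",
    "correspondence_axes",
]


# ---------------------------------------------------------------------------
# Thermometer regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Thermometer:
    """Fitted linear map OGT = intercept + slope * composition."""

    slope: float          # degrees C per unit composition
    intercept: float      # degrees C
    residual_sd: float    # degrees C
    n: int                # tips used
    spearman_rho: float
    spearman_p: float
    pearson_r: float

    def predict(self, composition: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(composition, dtype=float)


def build_thermometer(comps: pd.Series | Mapping[str, float],
                      ogts: pd.Series | Mapping[str, float]) -> Thermometer:
    """OLS regression of tip OGT on tip composition.

    Taxa present in only one of the two inputs are excluded (logged).
    Spearman's rank correlation (and Pearson's r) are reported as
    diagnostics.  Requires >= 3 matched taxa and non-constant composition.
    """
    comps = pd.Series(comps, dtype=float)
    ogts = pd.Series(ogts, dtype=float)
    shared = comps.index.intersection(ogts.index)
    dropped = sorted(set(comps.index).symmetric_difference(ogts.index))
    if dropped:
        _LOG.info("taxa excluded from thermometer (present in one input): %s",
                  dropped)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 taxa with both composition and OGT, have {len(shared)}"
        )
    x = comps.loc[shared].to_numpy()
    y = ogts.loc[shared].to_numpy()
    if np.ptp(x) == 0.0:
        raise ValueError("composition has zero variance; thermometer undefined")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    dof = max(len(shared) - 2, 1)
    residual_sd = float(np.sqrt((resid @ resid) / dof))
    rho, rho_p = stats.spearmanr(x, y)
    return Thermometer(
        slope=float(fit.slope), intercept=float(fit.intercept),
        residual_sd=residual_sd, n=int(len(shared)),
        spearman_rho=float(rho), spearman_p=float(rho_p),
        pearson_r=float(fit.rvalue),
    )


# ---------------------------------------------------------------------------
# Phylogenetically independent contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts (one per informative internal node)."""

    node_ids: np.ndarray
    contrasts: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.contrasts)):
            raise ValueError("non-finite contrast")


#: Floor applied to branch lengths in the contrast recursion.
PIC_BRANCH_EPSILON = 1e-8


def pic_contrasts(tree: RootedTree, trait: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts for one trait.

    At each internal node with children values x_i, x_j and (updated)
    branch lengths v_i, v_j the contrast is (x_i - x_j)/sqrt(v_i + v_j);
    the node's value is the variance-weighted mean of its children and its
    parent branch is lengthened by v_i v_j/(v_i + v_j).  Zero-length
    branches are floored at :data:`PIC_BRANCH_EPSILON`.
    """
    x = np.full(tree.n_nodes, np.nan)
    v = np.full(tree.n_nodes, np.nan)
    for leaf in tree.leaves():
        label = tree.labels[leaf]
        if label not in trait:
            raise ValueError(f"missing trait value for leaf {label!r}")
        x[leaf] = float(trait[label])
    node_ids, contrasts = [], []
    for node in tree.postorder():
        length = tree.lengths[node]
        v[node] = max(length, PIC_BRANCH_EPSILON) if np.isfinite(length) else 0.0
        if tree.is_leaf(node):
            continue
        c1, c2 = tree.children[node]
        v1, v2 = v[c1], v[c2]
        contrasts.append((x[c1] - x[c2]) / np.sqrt(v1 + v2))
        node_ids.append(node)
        x[node] = (x[c1] / v1 + x[c2] / v2) / (1.0 / v1 + 1.0 / v2)
        v[node] += v1 * v2 / (v1 + v2)
    return ContrastSet(np.asarray(node_ids), np.asarray(contrasts))


def pic_correlation(tree: RootedTree, trait_x: Mapping[str, float],
                    trait_y: Mapping[str, float]) -> tuple[float, float]:
    """Correlation of two traits' independent contrasts, through the origin.

    Returns (rho, p); p is from the t statistic with (n_contrasts - 1)
    degrees of freedom.
    """
    cx = pic_contrasts(tree, trait_x).contrasts
    cy = pic_contrasts(tree, trait_y).contrasts
    denom = np.sqrt((cx @ cx) * (cy @ cy))
    if denom == 0.0:
        raise ValueError("zero-variance contrasts; correlation undefined")
    rho = float((cx @ cy) / denom)
    df = cx.size - 1
    if df < 1:
        raise ValueError("need at least 2 contrasts for a correlation test")
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        return rho_c, 0.0
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho_c, p


# ---------------------------------------------------------------------------
# Ancestral OGT estimation and comparison
# ---------------------------------------------------------------------------

@dataclass
class OGTEstimate:
    """Per-node OGT posterior samples with mean and 95% interval."""

    samples: dict[int, np.ndarray]      # node -> per-sample OGT (deg C)
    mean: dict[int, float]
    lower: dict[int, float]
    upper: dict[int, float]

    def summary(self, tree: RootedTree | None = None) -> pd.DataFrame:
        rows = []
        for v in self.samples:
            name = (tree.labels[v] or f"node{v}") if tree is not None else f"node{v}"
            rows.append((name, v, self.mean[v], self.lower[v], self.upper[v]))
        return pd.DataFrame(
            rows, columns=["node", "node_id", "ogt_mean", "ogt_lo95", "ogt_hi95"]
        )


def estimate_ancestral_ogt(comp: CompositionSummary, thermometer: Thermometer,
                           convolve_residual: bool = True, seed: int = 0
                           ) -> OGTEstimate:
    """Map sampled ancestral compositions to OGTs through the thermometer.

    Each sampled composition is pushed through the regression; with
    ``convolve_residual`` (default) a Gaussian draw with the regression's
    residual SD is added to each prediction so the interval reflects
    thermometer scatter as well as reconstruction uncertainty.  The 95%
    interval is the empirical 2.5-97.5 percentile range of the per-sample
    predictions.
    """
    rng = np.random.default_rng(seed)
    samples: dict[int, np.ndarray] = {}
    mean: dict[int, float] = {}
    lo: dict[int, float] = {}
    hi: dict[int, float] = {}
    for v, gcs in comp.gc_samples.items():
        if gcs.size < 1:
            raise ValueError(f"node {v} has no composition samples")
        pred = thermometer.predict(gcs)
        if convolve_residual and thermometer.residual_sd > 0:
            pred = pred + rng.normal(0.0, thermometer.residual_sd, size=pred.shape)
        samples[v] = pred
        mean[v] = float(pred.mean())
        lo[v] = float(np.percentile(pred, 2.5))
        hi[v] = float(np.percentile(pred, 97.5))
    return OGTEstimate(samples, mean, lo, hi)


def compare_nodes(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    """Two-sample Wilcoxon rank-sum test between two nodes' OGT samples.

    Returns (U statistic, two-sided p, direction), direction being
    ``'b_hotter'``, ``'a_hotter'`` or ``'tied'`` by comparison of medians.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise ValueError("need >= 10 samples per node for the rank-sum test")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    med_a, med_b = np.median(a), np.median(b)
    direction = "tied" if med_a == med_b else ("a_hotter" if med_a > med_b else "b_hotter")
    return float(res.statistic), float(res.pvalue), direction


# ---------------------------------------------------------------------------
# Correspondence analysis
# ---------------------------------------------------------------------------

def correspondence_axes(table: np.ndarray | pd.DataFrame, n_axes: int | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Row scores of a correspondence analysis of a non-negative count table.

    The standardized residual matrix S = (P - r c^T)/sqrt(r c^T) (with P
    the table normalized to sum 1, r/c its margins) is decomposed by SVD;
    row scores in principal coordinates are U Sigma / sqrt(r).  Returns
    ``(row_scores, inertias)`` where ``inertias`` are the squared singular
    values (their sum is chi-square / grand total).

    Used to build amino-acid-style thermometers on any composition table
    (e.g. OGT against the second CA axis).
    """
    if isinstance(table, pd.DataFrame):
        index = table.index
        N = table.to_numpy(dtype=float)
    else:
        index = None
        N = np.asarray(table, dtype=float)
    if N.ndim != 2 or np.any(N < 0):
        raise ValueError("need a non-negative 2-D count table")
    if np.any(N.sum(axis=1) == 0) or np.any(N.sum(axis=0) == 0):
        raise ValueError("table has an all-zero row or column")
    total = N.sum()
    if total <= 0:
        raise ValueError("empty table")
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(N.shape) - 1
    if n_axes is not None:
        k = min(k, int(n_axes))
    if k < 1:
        raise ValueError("degenerate table: no non-trivial axis")
    scores = (U[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
    if index is not None:
        scores = pd.DataFrame(
            scores, index=index, columns=[f"axis{i+1}" for i in range(k)]
        )
    return scores, sv[:k] ** 2
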
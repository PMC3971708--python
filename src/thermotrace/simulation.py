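"""Sequence simulation and the synthetic-study generator.

Three generative tools back the test suite and the control experiments:

* :func:`simulate_gg` evolves an alignment down a rooted tree under the
  branch-wise non-homogeneous T92 process with discrete-gamma rate
  variation (root states from pi(theta_root); per-branch equilibrium GC).
* :func:`bias_experiment` reproduces the classic rate/composition
  confound control: sites are binned into rate categories under a
  *time-homogeneous* fit, each category is re-simulated with a homogeneous
  T92 process pinned to the category's observed GC (branch lengths scaled
  by the category rate), the categories are concatenated, and the
  non-homogeneous model is fitted to the concatenate.  When slow
  categories are GC-rich, the fitted root GC is pulled above the fitted
  GC of the root's two child lineages (the Gowri-Shankar-Rattray bias);
  with no rate-GC correlation the root estimate sits between them.
* :func:`make_synthetic_study` builds a complete miniature study — a
  rooted tree with a cool (low-GC) root and two independently GC-enriched
  clades, sequences, tip OGTs generated from a known linear thermometer,
  and a stem mask — with every ground truth recorded for recovery tests.

Character evolution along a branch is sampled from the closed-form
transition matrix directly (exact in distribution).  All simulators are
deterministic given their seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    STATE_ORDER,
    Alignment,
    RootedTree,
    SiteMask,
    write_alignment,
    write_ogt_table,
    write_site_mask,
    write_tree,
)
from .inference import (
    FitOptions,
    LikelihoodResult,
    fit_gg,
    fit_homogeneous,
    site_rates,
)
from .substitution_model import (
    GGParams,
    stationary_frequencies,
    t92_transition_probs_array,
)

_LOG = logging.getLogger(__name__)

__all__ = [
    "simulate_gg",
    "simulate_rate_gc_process",
    "BiasExperimentResult",
    "bias_experiment",
    "StudyConfig",
    "SyntheticStudy",
    "make_synthetic_study",
]


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _draw_states(rng: np.random.Generator, probs_by_site: np.ndarray) -> np.ndarray:
    """One categorical draw per site from per-site probability rows."""
    cum = np.cumsum(probs_by_site, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(probs_by_site.shape[0])
    return (u[:, None] > cum).sum(axis=1).astype(np.int8)


def simulate_gg(tree: RootedTree, params: GGParams, n_sites: int, seed: int
                ) -> Alignment:
    """Simulate an alignment under the branch-wise non-homogeneous model.

    Root states are drawn from pi(theta_root); each site draws one gamma
    rate category; along each branch states evolve under that branch's
    T92(theta_b, kappa) for duration t_b * r.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    params.validate_for(tree)
    rng = np.random.default_rng(seed)
    rc = params.rate_classes()
    cat = rng.integers(0, rc.n_categories, size=n_sites)
    pi_root = stationary_frequencies(params.theta_root)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    root = tree.root
    states[root] = _draw_states(rng, np.broadcast_to(pi_root, (n_sites, 4)))
    for v in tree.preorder():
        if v == root:
            continue
        P = t92_transition_probs_array(
            params.theta_branch[v], params.kappa,
            tree.lengths[v] * rc.rates,
        )                                               # (K, 4, 4)
        rows = P[cat, states[tree.parent[v]], :]        # (n_sites, 4)
        states[v] = _draw_states(rng, rows)
    lut = np.array(list(STATE_ORDER))
    leaves = tree.leaves()
    taxa = tuple(tree.labels[v] for v in leaves)
    seqs = tuple("".join(lut[states[v]]) for v in leaves)
    return Alignment(taxa, seqs)


def simulate_rate_gc_process(tree: RootedTree, category_thetas: np.ndarray,
                             category_rates: np.ndarray, sites_per_category,
                             kappa: float, seed: int) -> Alignment:
    """Simulate a *time-homogeneous* process with rate-class-specific GC.

    Every site in category k evolves under a single stationary T92 model
    with equilibrium GC ``category_thetas[k]`` on the tree with branch
    lengths scaled by ``category_rates[k]`` — composition varies across
    sites but never across branches.  This is the regime in which
    branch-wise non-homogeneous models can mistake across-site composition
    variation for composition change in time.
    """
    category_thetas = np.asarray(category_thetas, dtype=float)
    category_rates = np.asarray(category_rates, dtype=float)
    sizes = np.asarray(sites_per_category, dtype=int)
    if not (category_thetas.size == category_rates.size == sizes.size):
        raise ValueError("category arrays must have equal length")
    rng = np.random.default_rng(seed)
    blocks = []
    for k, (theta, rate, n_k) in enumerate(
            zip(category_thetas, category_rates, sizes)):
        if n_k == 0:
            continue
        scaled = tree.with_lengths(tree.lengths * rate)
        params = GGParams.homogeneous(scaled, theta, kappa, 1.0, n_categories=1)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        blocks.append(simulate_gg(scaled, params, int(n_k), sub_seed))
    taxa = blocks[0].taxa
    seqs = tuple(
        "".join(b.sequence(t) for b in blocks) for t in taxa
    )
    return Alignment(taxa, seqs)


# ---------------------------------------------------------------------------
# Bias experiment
# ---------------------------------------------------------------------------

@dataclass
class BiasExperimentResult:
    """Replicate-level fitted GC contents from the rate/composition control.

    ``theta_root`` / ``theta_left`` / ``theta_right`` hold one fitted value
    per replicate (left/right = the root's two child lineages);
    ``category_gc`` and ``category_sizes`` record the observed per-category
    compositions used for the homogeneous re-simulations.
    """

    theta_root: np.ndarray
    theta_left: np.ndarray
    theta_right: np.ndarray
    category_gc: np.ndarray
    category_sizes: np.ndarray
    category_rates: np.ndarray
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        n = self.n_replicates
        return pd.DataFrame({
            "replicate": np.arange(n),
            "theta_root": self.theta_root,
            "theta_left": self.theta_left,
            "theta_right": self.theta_right,
        })

    def root_exceeds_children(self) -> bool:
        """True when the median fitted root GC exceeds both child medians."""
        mr = np.median(self.theta_root)
        return bool(mr > np.median(self.theta_left)
                    and mr > np.median(self.theta_right))


def bias_experiment(aln: Alignment, tree: RootedTree, n_categories: int = 8,
                    reps: int = 100, seed: int = 0,
                    homogeneous_fit: LikelihoodResult | None = None,
                    fit_options: FitOptions | None = None
                    ) -> BiasExperimentResult:
    """Rate/composition confound control for the non-homogeneous model.

    (1) fit a stationary T92 + gamma model and assign each site to its MAP
    rate category; (2) measure each category's observed G+C across taxa
    and sites; (3) simulate a homogeneous T92 alignment per category with
    theta pinned to that GC and branch lengths scaled by the category
    rate; (4) concatenate; (5) fit the branch-wise non-homogeneous model
    and record the fitted root GC and the GCs of the root's two child
    branches.  Steps 3-5 repeat ``reps`` times with fresh seeds.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    opts = fit_options or FitOptions(n_starts=1)
    hom = homogeneous_fit or fit_homogeneous(aln, tree, options=opts,
                                             n_categories=n_categories)
    profile = site_rates(aln, tree, hom.params)
    map_cat = np.argmax(profile.category_posterior, axis=1)
    codes = aln.to_codes()
    rates = profile.rates
    sizes = np.zeros(n_categories, dtype=int)
    gcs = np.full(n_categories, np.nan)
    for k in range(n_categories):
        cols = np.flatnonzero(map_cat == k)
        sizes[k] = cols.size
        if cols.size == 0:
            _LOG.warning("rate category %d is empty; skipped", k)
            continue
        sub = codes[:, cols]
        present = sub != 4
        gcs[k] = ((sub == 1) | (sub == 2)).sum() / present.sum()
    keep = sizes > 0
    gcs_kept = np.clip(gcs[keep], 0.02, 0.98)
    rates_kept = rates[keep]
    sizes_kept = sizes[keep]
    root_children = tree.children[tree.root]

    rng = np.random.default_rng(seed)
    th_root = np.empty(reps)
    th_left = np.empty(reps)
    th_right = np.empty(reps)
    for rep in range(reps):
        sim_seed = int(rng.integers(0, 2**31 - 1))
        sim = simulate_rate_gc_process(
            tree, gcs_kept, rates_kept, sizes_kept, hom.params.kappa, sim_seed
        )
        fit = fit_gg(sim, tree, options=opts, n_categories=n_categories)
        th_root[rep] = fit.params.theta_root
        th_left[rep] = fit.params.theta_branch[root_children[0]]
        th_right[rep] = fit.params.theta_branch[root_children[1]]
    return BiasExperimentResult(
        th_root, th_left, th_right, gcs, sizes, rates, reps
    )


# ---------------------------------------------------------------------------
# Synthetic study generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Study conditions for the synthetic stand-in dataset.

    Defaults emulate the structure of a universal rRNA study: a rooted
    bipartition into a Bacteria-like and an Archaea-like clade, a low-GC
    (cool) root, GC-enriched (hot) descendants, gamma rate variation, and
    tip OGTs generated from a linear stem-GC thermometer with Gaussian
    noise.
    """

    n_taxa: int = 24
    n_sites: int = 1500
    theta_root: float = 0.45
    theta_clade_a: float = 0.68       # Bacteria-like clade target GC
    theta_clade_b: float = 0.64       # Archaea-like clade target GC
    kappa: float = 2.0
    alpha: float = 0.5
    n_categories: int = 8
    slope: float = 150.0              # deg C per unit GC
    intercept: float = -20.0          # deg C
    noise_sd: float = 5.0             # deg C
    stem_fraction: float = 0.5
    tip_theta_jitter: float = 0.05    # uniform half-width around clade target
    stem_branch_length: float = 0.25  # root -> clade-ancestor branches
    inner_branch_length: float = 0.08
    tip_branch_length: float = 0.12

    def __post_init__(self) -> None:
        if self.n_taxa < 4 or self.n_taxa % 2:
            raise ValueError("n_taxa must be an even integer >= 4")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("theta_root", "theta_clade_a", "theta_clade_b"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not 0.0 < self.stem_fraction <= 1.0:
            raise ValueError("stem_fraction must be in (0,1]")
        if self.noise_sd < 0 or self.tip_theta_jitter < 0:
            raise ValueError("noise_sd and tip_theta_jitter must be >= 0")


@dataclass
class SyntheticStudy:
    """A complete synthetic dataset with all generating truths recorded."""

    alignment: Alignment
    tree: RootedTree
    ogt_table: pd.Series
    site_mask: SiteMask
    params: GGParams                     # true generating parameters
    node_theta: dict[int, float]         # lineage GC target per node
    true_ancestral_ogt: dict[int, float] # thermometer truth at internal nodes
    thermometer_truth: tuple[float, float, float]  # slope, intercept, noise sd
    config: StudyConfig
    seed: int

    @property
    def root_label(self) -> str:
        return "LUCA"

    def clade_ancestors(self) -> tuple[int, int]:
        c = self.tree.children[self.tree.root]
        return c[0], c[1]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignment, out / "alignment.fasta")
        write_tree(self.tree, out / "tree.nwk")
        write_ogt_table(self.ogt_table, out / "ogt.tsv")
        write_site_mask(self.site_mask, out / "stem.mask")
        truth = {
            "seed": self.seed,
            "config": asdict(self.config),
            "theta_root": self.params.theta_root,
            "kappa": self.params.kappa,
            "alpha": self.params.alpha,
            "node_theta": {str(k): v for k, v in self.node_theta.items()},
            "true_ancestral_ogt": {
                str(k): v for k, v in self.true_ancestral_ogt.items()
            },
            "thermometer_truth": list(self.thermometer_truth),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


def _balanced_newick(labels: list[str], branch: float, tip_branch: float) -> str:
    """Balanced binary Newick subtree over the given tips."""
    if len(labels) == 1:
        return f"{labels[0]}:{tip_branch:.10g}"
    half = (len(labels) + 1) // 2
    left = _balanced_newick(labels[:half], branch, tip_branch)
    right = _balanced_newick(labels[half:], branch, tip_branch)
    return f"({left},{right}):{branch:.10g}"


def make_balanced_tree(n_taxa: int, stem_branch_length: float = 0.25,
                       inner_branch_length: float = 0.08,
                       tip_branch_length: float = 0.12) -> RootedTree:
    """Balanced rooted tree split into Bacteria-like / Archaea-like clades.

    The root is labelled ``LUCA`` and its two children ``AncBacteria`` /
    ``AncArchaea``; the two root branches get ``stem_branch_length``.
    """
    if n_taxa < 4 or n_taxa % 2:
        raise ValueError("n_taxa must be an even integer >= 4")
    half = n_taxa // 2
    bac = [f"Bac{i:02d}" for i in range(half)]
    arc = [f"Arc{i:02d}" for i in range(n_taxa - half)]
    nwk = (
        "("
        + _balanced_newick(bac, inner_branch_length, tip_branch_length)
        + ","
        + _balanced_newick(arc, inner_branch_length, tip_branch_length)
        + ")LUCA;"
    )
    tree = RootedTree.from_newick(nwk)
    for child in tree.children[tree.root]:
        tree.lengths[child] = stem_branch_length
    anc_a, anc_b = tree.children[tree.root]
    tree.labels[anc_a] = "AncBacteria"
    tree.labels[anc_b] = "AncArchaea"
    return tree


def make_synthetic_study(config: StudyConfig | None = None, seed: int = 0
                         ) -> SyntheticStudy:
    """Generate a complete synthetic study with known ground truth.

    The tree is a balanced rooted bipartition into a Bacteria-like and an
    Archaea-like clade.  Branch equilibrium-GC values interpolate linearly
    (in root-to-node distance) from the root GC toward the clade target;
    terminal branches get the clade target plus a small per-tip jitter so
    tip compositions spread.  Tip OGTs apply the thermometer truth to each
    tip's lineage GC target and add Gaussian noise; eukaryote-style tips
    without OGT are not generated (every tip gets one).
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)
    tree = make_balanced_tree(
        cfg.n_taxa, cfg.stem_branch_length, cfg.inner_branch_length,
        cfg.tip_branch_length,
    )
    anc_a, anc_b = tree.children[tree.root]

    # Branch GC targets: composition moves from the root GC to the clade
    # target along the two deep root branches (the parallel GC enrichment
    # of the domain ancestors), and holds the clade target within each
    # clade; terminal branches add a small per-tip jitter so tip
    # compositions spread for the thermometer regression.
    clade_target = {anc_a: cfg.theta_clade_a, anc_b: cfg.theta_clade_b}
    node_theta: dict[int, float] = {tree.root: cfg.theta_root}
    theta_branch: dict[int, float] = {}
    for anc in (anc_a, anc_b):
        target = clade_target[anc]
        members = [v for v in range(tree.n_nodes)
                   if v != tree.root and _is_descendant(tree, v, anc)]
        for v in members:
            theta = target
            if tree.is_leaf(v):
                jitter = rng.uniform(-cfg.tip_theta_jitter, cfg.tip_theta_jitter)
                theta = float(np.clip(target + jitter, 0.02, 0.98))
            node_theta[v] = float(theta)
            theta_branch[v] = float(theta)
    params = GGParams(cfg.theta_root, theta_branch, cfg.kappa, cfg.alpha,
                      cfg.n_categories)
    aln_seed = int(rng.integers(0, 2**31 - 1))
    aln = simulate_gg(tree, params, cfg.n_sites, aln_seed)

    # stem mask: random subset of columns standing in for paired positions
    n_stem = max(1, int(round(cfg.stem_fraction * cfg.n_sites)))
    mask = SiteMask(np.sort(rng.choice(cfg.n_sites, size=n_stem, replace=False)))

    # tip OGTs from the thermometer truth on lineage GC targets
    ogt = {}
    for v in tree.leaves():
        mu = cfg.intercept + cfg.slope * node_theta[v]
        ogt[tree.labels[v]] = mu + rng.normal(0.0, cfg.noise_sd)
    ogt_table = pd.Series(ogt, name="ogt_celsius")

    true_anc_ogt = {
        v: cfg.intercept + cfg.slope * node_theta[v]
        for v in range(tree.n_nodes) if not tree.is_leaf(v)
    }
    return SyntheticStudy(
        alignment=aln, tree=tree, ogt_table=ogt_table, site_mask=mask,
        params=params, node_theta=node_theta, true_ancestral_ogt=true_anc_ogt,
        thermometer_truth=(cfg.slope, cfg.intercept, cfg.noise_sd),
        config=cfg, seed=seed,
    )


def _is_descendant(tree: RootedTree, v: int, anc: int) -> bool:
    while v >= 0:
        if v == anc:
            return True
        v = tree.parent[v]
    return False
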
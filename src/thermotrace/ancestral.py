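"""Marginal ancestral-state posteriors, posterior sequence sampling, and
ancestral composition summaries.

For each internal node the up-down (inside-outside) algorithm yields the
marginal posterior distribution over A/C/G/T at every site, conditioned on
all tip data, under the branch-wise non-homogeneous model; rate categories
are marginalized with their site-specific posterior weight and the root
prior is pi(theta_root).  Ancestral sequences are then drawn site by site
from these marginals (100 draws per node by default), and the G+C fraction
of each draw summarizes the node's composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import STATE_ORDER, Alignment, RootedTree, SiteMask, write_alignment
from .inference import PruningEngine
from .substitution_model import GGParams

__all__ = [
    "AncestralPosterior",
    "AncestralSampleSet",
    "CompositionSummary",
    "node_posteriors",
    "sample_sequences",
    "composition",
]


@dataclass
class AncestralPosterior:
    """Per-node, per-site posterior state probabilities (state order ACGT)."""

    tree: RootedTree
    probs: dict[int, np.ndarray]      # node -> (sites, 4), rows sum to 1

    @property
    def n_sites(self) -> int:
        return next(iter(self.probs.values())).shape[0]

    def node(self, key: int | str) -> np.ndarray:
        if isinstance(key, str):
            key = self.tree.node_by_label(key)
        return self.probs[key]


@dataclass
class AncestralSampleSet:
    """Sampled ancestral sequences: node -> (n_samples, sites) state codes."""

    tree: RootedTree
    samples: dict[int, np.ndarray]
    seed: int

    @property
    def n_samples(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    def sequences(self, node: int | str) -> list[str]:
        if isinstance(node, str):
            node = self.tree.node_by_label(node)
        lut = np.array(list(STATE_ORDER))
        return ["".join(lut[row]) for row in self.samples[node]]

    def write_fasta(self, node: int | str, path: str | Path) -> None:
        if isinstance(node, str):
            node = self.tree.node_by_label(node)
        name = self.tree.labels[node] or f"node{node}"
        seqs = self.sequences(node)
        aln = Alignment(
            tuple(f"{name}_sample{i}" for i in range(len(seqs))), tuple(seqs)
        )
        write_alignment(aln, path)


@dataclass
class CompositionSummary:
    """Per-sample G+C fractions per node, with node means."""

    gc_samples: dict[int, np.ndarray]  # node -> (n_samples,)

    def mean(self, node: int) -> float:
        return float(self.gc_samples[node].mean())

    def to_frame(self, tree: RootedTree) -> pd.DataFrame:
        rows = []
        for v, gcs in self.gc_samples.items():
            name = tree.labels[v] or f"node{v}"
            for i, gc in enumerate(gcs):
                rows.append((name, v, i, float(gc)))
        return pd.DataFrame(rows, columns=["node", "node_id", "sample_index", "gc"])


def node_posteriors(aln: Alignment, tree: RootedTree, params: GGParams
                    ) -> AncestralPosterior:
    """Marginal posterior state probabilities for every internal node."""
    engine = PruningEngine(aln, tree, params.n_categories)
    return AncestralPosterior(tree, engine.state_posteriors(params))


def sample_sequences(post: AncestralPosterior, n: int = 100, seed: int = 0
                     ) -> AncestralSampleSet:
    """Draw ancestral sequences by independent per-site sampling from each
    node's marginal posterior; reproducible under ``seed``."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    samples: dict[int, np.ndarray] = {}
    for v, probs in post.probs.items():
        cum = np.cumsum(probs, axis=1)
        cum[:, -1] = 1.0
        u = rng.random((n, probs.shape[0]))
        samples[v] = (u[..., None] > cum[None, :, :]).sum(axis=2).astype(np.int8)
    return AncestralSampleSet(post.tree, samples, seed)


def composition(samples: AncestralSampleSet, mask: SiteMask | None = None
                ) -> CompositionSummary:
    """G+C fraction of every sampled ancestral sequence (over masked sites)."""
    gc: dict[int, np.ndarray] = {}
    for v, mat in samples.samples.items():
        sub = mat if mask is None else mat[:, mask.indices]
        if sub.shape[1] == 0:
            raise ValueError("empty site mask")
        is_gc = (sub == 1) | (sub == 2)   # C, G in ACGT order
        gc[v] = is_gc.mean(axis=1)
    return CompositionSummary(gc)
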
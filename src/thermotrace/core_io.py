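"""Core containers and file I/O for the ancestral-thermometry pipeline.

The pipeline works on four objects that are read from (and written back to)
plain-text files:

* :class:`Alignment` — a multiple sequence alignment of DNA (rRNA) sequences
  over the alphabet ``{A, C, G, T, -, N}`` (FASTA or relaxed PHYLIP).
* :class:`RootedTree` — a rooted, binary phylogeny with branch lengths in
  expected substitutions per site (Newick).
* an OGT table — optimal growth temperatures (degrees Celsius) per taxon
  (two-column TSV, header ``taxon\togt_celsius``), held as a pandas Series.
* :class:`SiteMask` — an ordered set of 0-based alignment column indices,
  typically the stem (base-paired) positions of the rRNA secondary
  structure (plain text, one integer per line, ``#`` comments allowed).

All site indices are 0-based, half-open, everywhere: in mask files, logs,
and TSV outputs.  Gaps (``-``) and ``N`` are treated downstream as missing
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

_LOG = logging.getLogger(__name__)

#: Fixed state order used by every numeric routine in the package.
STATE_ORDER = "ACGT"
_STATE_INDEX = {c: i for i, c in enumerate(STATE_ORDER)}
#: Integer code used for missing data (gap or N).
MISSING_CODE = 4
_VALID_CHARS = frozenset("ACGTN-")


class PairingError(ValueError):
    """Raised when alignment / tree / OGT-table label sets do not match."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """An immutable DNA multiple sequence alignment.

    Parameters
    ----------
    taxa
        Ordered, unique taxon labels.
    sequences
        One uppercase sequence per taxon over ``{A,C,G,T,-,N}``; all the
        same length.
    """

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if list(self.taxa).count(t) > 1})
            raise ValueError(f"duplicate taxon label(s): {dupes}")
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        n = len(self.sequences[0])
        for taxon, seq in zip(self.taxa, self.sequences):
            if len(seq) != n:
                raise ValueError(
                    f"ragged alignment: taxon {taxon!r} has length {len(seq)}, "
                    f"expected {n}"
                )
        if n < 1:
            raise ValueError("alignment must have at least one site")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def sites(self) -> int:
        return len(self.sequences[0])

    def sequence(self, taxon: str) -> str:
        try:
            return self.sequences[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def to_codes(self, taxa_order: Sequence[str] | None = None) -> np.ndarray:
        """Encode as an integer matrix (taxa x sites).

        A, C, G, T map to 0..3 (:data:`STATE_ORDER`); gap and N map to
        :data:`MISSING_CODE`.
        """
        order = list(taxa_order) if taxa_order is not None else list(self.taxa)
        mat = np.empty((len(order), self.sites), dtype=np.int8)
        for row, taxon in enumerate(order):
            seq = self.sequence(taxon)
            mat[row] = [_STATE_INDEX.get(c, MISSING_CODE) for c in seq]
        return mat

    def gc_content(self, mask: "SiteMask | None" = None) -> pd.Series:
        """Per-taxon G+C fraction over non-missing (masked) sites."""
        codes = self.to_codes()
        if mask is not None:
            codes = codes[:, mask.indices]
        present = codes != MISSING_CODE
        gc = (codes == _STATE_INDEX["G"]) | (codes == _STATE_INDEX["C"])
        denom = present.sum(axis=1)
        if np.any(denom == 0):
            bad = [t for t, d in zip(self.taxa, denom) if d == 0]
            raise ValueError(f"taxa with no scored sites: {bad}")
        return pd.Series(gc.sum(axis=1) / denom, index=list(self.taxa), name="gc")


def _normalize_sequence(label: str, raw: str) -> tuple[str, int]:
    seq = raw.upper().replace("U", "T")
    n_unknown = sum(1 for c in seq if c not in _VALID_CHARS)
    if n_unknown:
        seq = "".join(c if c in _VALID_CHARS else "N" for c in seq)
    return seq, n_unknown


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a DNA alignment from FASTA (default) or relaxed PHYLIP.

    Characters are uppercased, ``U`` is mapped to ``T`` and any character
    outside ``{A,C,G,T,-,N}`` is mapped to ``N`` (a warning reports the
    count).  Ragged rows and duplicate labels are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    elif fmt in {"phylip", "phylip-relaxed"}:
        records = list(AlignIO.read(str(path), "phylip-relaxed"))
    else:
        raise ValueError(f"unsupported alignment format: {format!r}")
    if not records:
        raise ValueError(f"no sequences found in {path}")
    taxa, seqs, unknown_total = [], [], 0
    for rec in records:
        seq, n_unknown = _normalize_sequence(rec.id, str(rec.seq))
        unknown_total += n_unknown
        taxa.append(rec.id)
        seqs.append(seq)
    if unknown_total:
        _LOG.warning(
            "%d unrecognized character(s) in %s mapped to N", unknown_total, path
        )
    return Alignment(tuple(taxa), tuple(seqs))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA (60-column wrapped)."""
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# SiteMask
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteMask:
    """An ordered set of 0-based alignment column indices."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("mask indices must be one-dimensional")
        if idx.size and idx.min() < 0:
            raise ValueError(f"negative site index: {idx.min()}")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("mask indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def validate_for(self, aln: Alignment) -> None:
        if len(self) == 0:
            raise ValueError("empty site mask")
        too_big = self.indices[self.indices >= aln.sites]
        if too_big.size:
            raise ValueError(
                f"mask index {int(too_big[0])} out of range for alignment "
                f"with {aln.sites} sites"
            )

    @classmethod
    def full(cls, n_sites: int) -> "SiteMask":
        return cls(np.arange(n_sites))

    def complement(self, n_sites: int) -> "SiteMask":
        keep = np.setdiff1d(np.arange(n_sites), self.indices)
        return SiteMask(keep)


def read_site_mask(path: str | Path) -> SiteMask:
    """Read a mask file: one 0-based integer per line, ``#`` comments."""
    indices = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            indices.append(int(line))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: not an integer: {line!r}") from None
    return SiteMask(np.asarray(indices, dtype=np.int64))


def write_site_mask(mask: SiteMask, path: str | Path) -> None:
    Path(path).write_text("".join(f"{int(i)}\n" for i in mask.indices))


def apply_mask(aln: Alignment, mask: SiteMask) -> Alignment:
    """Column-subset an alignment, keeping columns in mask order."""
    mask.validate_for(aln)
    idx = mask.indices
    new_seqs = tuple("".join(seq[i] for i in idx) for seq in aln.sequences)
    return Alignment(aln.taxa, new_seqs)


# ---------------------------------------------------------------------------
# RootedTree
# ---------------------------------------------------------------------------

@dataclass
class RootedTree:
    """A rooted binary phylogeny with stable post-order node IDs.

    Node IDs are assigned in post-order when the tree is parsed, so the
    root always has ID ``n_nodes - 1`` and IDs are reproducible across
    re-reads of the same file.  ``lengths[v]`` is the length of the branch
    *above* node ``v`` (NaN for the root).  Internal Newick labels (for
    example ``LUCA``) are preserved and usable as ancestor names.
    """

    parent: np.ndarray                 # (n_nodes,), -1 at root
    children: list[list[int]]          # child IDs per node, [] at leaves
    lengths: np.ndarray                # branch length above node, NaN at root
    labels: list[str | None]           # taxon names at leaves, optional elsewhere

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.parent.size
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        finite = self.lengths[np.isfinite(self.lengths)]
        if finite.size and finite.min() < 0:
            raise ValueError("negative branch length")
        for v in range(n):
            kids = self.children[v]
            if kids and len(kids) != 2:
                raise ValueError(
                    f"node {v} has {len(kids)} children; only binary rooted "
                    "trees are supported"
                )

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def postorder(self) -> np.ndarray:
        """Node IDs in post-order (children before parents)."""
        return np.arange(self.n_nodes)  # IDs are assigned post-order

    def preorder(self) -> np.ndarray:
        return np.arange(self.n_nodes)[::-1]

    def leaves(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.is_leaf(v)]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_labels(self) -> list[str]:
        return [self.labels[v] for v in self.leaves()]

    def node_by_label(self, label: str) -> int:
        for v, lab in enumerate(self.labels):
            if lab == label:
                return v
        raise KeyError(f"no node labelled {label!r}")

    def depths(self) -> np.ndarray:
        """Distance from the root to each node (root = 0)."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + (self.lengths[v] if np.isfinite(self.lengths[v]) else 0.0)
        return d

    def clade_leaves(self, v: int) -> list[int]:
        """Leaf IDs below (and including) node ``v``."""
        stack, out = [v], []
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.append(u)
            else:
                stack.extend(self.children[u])
        return sorted(out)

    def with_lengths(self, lengths: np.ndarray) -> "RootedTree":
        return RootedTree(
            self.parent.copy(), [list(c) for c in self.children],
            np.asarray(lengths, dtype=float).copy(), list(self.labels),
        )

    # -- Newick -------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
        return cls._from_dendropy(tree)

    @classmethod
    def _from_dendropy(cls, tree: dendropy.Tree) -> "RootedTree":
        seed = tree.seed_node
        if len(seed.child_nodes()) > 2:
            raise ValueError(
                "tree root is a polytomy (unrooted Newick); re-root the tree "
                "on a branch before use"
            )
        nodes = list(tree.postorder_node_iter())
        ids = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        lengths = np.full(n, np.nan)
        labels: list[str | None] = [None] * n
        for nd in nodes:
            v = ids[id(nd)]
            if nd.parent_node is not None:
                p = ids[id(nd.parent_node)]
                parent[v] = p
                children[p].append(v)
                lengths[v] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.taxon is not None:
                labels[v] = nd.taxon.label
            elif nd.label:
                labels[v] = nd.label
        # restore file order of children (postorder_node_iter preserves it,
        # but appends in visit order which is already file order)
        return cls(parent, children, lengths, labels)

    def to_newick(self, annotations: Mapping[int, str] | None = None) -> str:
        """Serialize as Newick.

        ``annotations`` maps node ID to an NHX-style comment body, emitted
        as ``[&&NHX:<body>]`` after the branch length.
        """

        def fmt(v: int) -> str:
            if self.is_leaf(v):
                core = self.labels[v] or f"n{v}"
            else:
                inner = ",".join(fmt(c) for c in self.children[v])
                core = f"({inner})" + (self.labels[v] or "")
            if self.parent[v] >= 0:
                core += f":{self.lengths[v]:.10g}"
            if annotations and v in annotations:
                core += f"[&&NHX:{annotations[v]}]"
            return core

        return fmt(self.root) + ";"


def read_tree(path: str | Path) -> RootedTree:
    """Read a rooted Newick tree with branch lengths.

    Node IDs are assigned deterministically in post-order.  A trifurcating
    root raises an error asking the user to root the tree first.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return RootedTree.from_newick(path.read_text())


def write_tree(tree: RootedTree, path: str | Path,
               annotations: Mapping[int, str] | None = None) -> None:
    Path(path).write_text(tree.to_newick(annotations) + "\n")


# ---------------------------------------------------------------------------
# OGT table
# ---------------------------------------------------------------------------

def read_ogt_table(path: str | Path) -> pd.Series:
    """Read a two-column TSV ``taxon\togt_celsius`` into a Series."""
    df = pd.read_csv(path, sep="\t")
    expected = ["taxon", "ogt_celsius"]
    if list(df.columns[:2]) != expected:
        raise ValueError(
            f"OGT table must have header 'taxon\\togt_celsius', got {list(df.columns)}"
        )
    if df["taxon"].duplicated().any():
        dupes = sorted(df.loc[df["taxon"].duplicated(), "taxon"])
        raise ValueError(f"duplicate taxa in OGT table: {dupes}")
    ogt = df.set_index("taxon")["ogt_celsius"].astype(float)
    if not np.isfinite(ogt.to_numpy()).all():
        bad = list(ogt.index[~np.isfinite(ogt.to_numpy())])
        raise ValueError(f"non-finite OGT value(s) for: {bad}")
    return ogt


def write_ogt_table(ogt: pd.Series, path: str | Path) -> None:
    df = ogt.rename("ogt_celsius").rename_axis("taxon").reset_index()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cross-file pairing
# ---------------------------------------------------------------------------

def check_pairing(aln: Alignment | None = None, tree: RootedTree | None = None,
                  ogt: pd.Series | None = None, *, require_ogt_cover: bool = False,
                  ) -> list[str]:
    """Validate that label sets of the provided inputs are consistent.

    Alignment taxa and tree leaves must match exactly (the symmetric
    difference is reported in the error).  OGT taxa may be a subset of the
    tree leaves (tips without a known growth temperature, e.g. Eukaryotes,
    stay in the tree); rows for unknown taxa are reported.

    Returns the list of tree leaves lacking an OGT (empty when ``ogt`` is
    None).
    """
    if aln is not None and tree is not None:
        a, t = set(aln.taxa), set(tree.leaf_labels())
        if a != t:
            raise PairingError(
                "alignment/tree label mismatch; only in alignment: "
                f"{sorted(a - t)}; only in tree: {sorted(t - a)}"
            )
    missing: list[str] = []
    if ogt is not None and tree is not None:
        t = set(tree.leaf_labels())
        extra = sorted(set(ogt.index) - t)
        if extra:
            raise PairingError(f"OGT table rows with no matching tree leaf: {extra}")
        missing = sorted(t - set(ogt.index))
        if missing:
            if require_ogt_cover:
                raise PairingError(f"tree leaves lacking an OGT: {missing}")
            _LOG.info("tree leaves lacking an OGT (kept in tree): %s", missing)
    return missing
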
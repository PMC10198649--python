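"""Synthetic data: two-block heterotachous alignments and mispartitioning.

The generating process is a two-block partition model with unlinked edge
lengths (P-UEL): two 8-taxon, 1000-site blocks are simulated under two
different GTR models on two trees sharing one topology, then concatenated.
Three edge-length regimes are provided:

``standard``
    every edge length drawn Exp(mean 0.06), resampled until > 0.005, so
    every edge expects more than 5 substitutions per 1000-site block;
``mild``
    block-1 tree has all edges 0.005 (exactly 5 expected substitutions
    per block per edge); block-2 tree mixes 0.005 and 0.001 with the long
    edges placed non-monophyletically (a long-branch-attraction shape);
``extreme``
    both trees mix 0.005 and 0.001 with non-monophyletic long edges.

Mispartitioning swaps the *fitted-block* labels of a random balanced set
of sites between the two blocks; the sites' true origins (which process
simulated them) are retained, so downstream scoring knows the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gtr import BASES, GTRModel
from .trees import Tree

__all__ = ["GENERATING_MODELS", "LabeledAlignment", "GeneratingCondition",
           "base_topology", "build_condition", "sample_gtr",
           "simulate_block", "concatenate_and_label", "mispartition",
           "simulate_replicate", "CONDITIONS"]

CONDITIONS = ("standard", "mild", "extreme")

#: The two fixed generating GTR models (block 1, block 2).  Rates are
#: (A<->C, A<->G, A<->T, C<->G, C<->T) with G<->T = 1; frequencies (A,C,G,T).
GENERATING_MODELS = (
    GTRModel(rates=(1.56, 3.20, 4.02, 1.32, 0.90),
             freqs=(0.28, 0.34, 0.19, 0.19)),
    GTRModel(rates=(1.17, 2.41, 1.79, 2.65, 2.99),
             freqs=(0.17, 0.30, 0.37, 0.16)),
)

_TIPS = tuple("abcdefgh")
# balanced topology ((a,b),(c,d)) | ((e,f),(g,h)): internal nodes u1..u4
# hang the four cherries; u1, u2 and v join at the central trifurcation,
# v carries u3 and u4.  13 edges total.
_EDGES = (
    ("a", "u1"), ("b", "u1"), ("c", "u2"), ("d", "u2"),
    ("e", "u3"), ("f", "u3"), ("g", "u4"), ("h", "u4"),
    ("u1", "z"), ("u2", "z"), ("v", "z"), ("u3", "v"), ("u4", "v"),
)
# long (0.005) edges of the two LBA trees: two non-sister tips plus the
# internal path between them; everything else 0.001
_LBA_LONG = {
    "D": {("a", "u1"), ("c", "u2"), ("u1", "z"), ("u2", "z")},
    "E": {("e", "u3"), ("g", "u4"), ("u3", "v"), ("u4", "v")},
}


def base_topology(lengths=None) -> Tree:
    """The fixed 8-taxon study topology with the given edge lengths.

    ``lengths`` maps (node, node) pairs to branch lengths, a scalar for
    all edges, or None for unit lengths.
    """
    if lengths is None:
        lengths = 1.0
    if np.isscalar(lengths):
        lengths = {e: float(lengths) for e in _EDGES}
    edges = [(u, v, lengths[(u, v)]) for u, v in _EDGES]
    return Tree.from_adjacency(_TIPS, edges)


def _lba_tree(which: str) -> Tree:
    longs = _LBA_LONG[which]
    return base_topology({e: (0.005 if e in longs else 0.001) for e in _EDGES})


def _standard_tree(rng: np.random.Generator) -> Tree:
    """Edge lengths iid Exp(mean 0.06), rejection-resampled to > 0.005."""
    lengths = {}
    for e in _EDGES:
        x = rng.exponential(0.06)
        while x <= 0.005:
            x = rng.exponential(0.06)
        lengths[e] = x
    return base_topology(lengths)


@dataclass
class GeneratingCondition:
    """One simulation arm: a pair of generating trees and GTR models."""

    name: str
    tree_pair: tuple[Tree, Tree]
    model_pair: tuple[GTRModel, GTRModel] = GENERATING_MODELS
    block_length: int = 1000

    def __post_init__(self):
        if not self.tree_pair[0].same_topology(self.tree_pair[1]):
            raise ValueError("generating trees must share one topology")


def build_condition(name: str, rng: np.random.Generator | None = None,
                    block_length: int = 1000) -> GeneratingCondition:
    """Construct a named study condition (standard / mild / extreme).

    The standard condition draws its two trees' edge lengths from the
    supplied ``rng`` once; the trees are then fixed for every replicate
    simulated under the condition.
    """
    if name == "standard":
        if rng is None:
            raise ValueError("the standard condition needs an rng "
                             "for its edge-length draws")
        trees = (_standard_tree(rng), _standard_tree(rng))
    elif name == "mild":
        trees = (base_topology(0.005), _lba_tree("D"))
    elif name == "extreme":
        trees = (_lba_tree("D"), _lba_tree("E"))
    else:
        raise ValueError(f"unknown condition {name!r}; "
                         f"expected one of {CONDITIONS}")
    return GeneratingCondition(name, trees, GENERATING_MODELS, block_length)


def sample_gtr(rng: np.random.Generator) -> GTRModel:
    """Draw a random GTR model the way the fixed generating pair was built.

    The five free exchangeabilities are uniform on [0.5, 5] (G<->T = 1);
    frequencies are four U(0,1) draws normalised to sum to 0.6 plus 0.1
    each, so every frequency lies in [0.1, 0.7] and they sum to 1.
    """
    rates = rng.uniform(0.5, 5.0, size=5)
    u = rng.uniform(0.0, 1.0, size=4)
    freqs = 0.1 + 0.6 * u / u.sum()
    return GTRModel(tuple(rates), tuple(freqs))


def simulate_block(tree: Tree, model: GTRModel, n_sites: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Simulate an (n_tips, n_sites) state matrix of iid sites.

    The root state is drawn from the stationary frequencies and each
    child's state from the transition matrix along its edge (preorder).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    pmats = model.transition_matrices(tree.lengths)
    cum = np.cumsum(pmats, axis=2)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    pi = np.cumsum(model.freqs)
    states[tree.root] = np.searchsorted(pi, rng.random(n_sites),
                                        side="right").astype(np.int8)
    for v in reversed(tree.postorder):  # preorder
        if v == tree.root:
            continue
        rows = cum[v][states[tree.parent[v]]]        # (n_sites, 4)
        u = rng.random(n_sites)
        states[v] = (u[:, None] >= rows).sum(axis=1).astype(np.int8)
    return states[: tree.n_tips].copy()


@dataclass
class LabeledAlignment:
    """A site matrix with per-site fitted-block and true-origin labels.

    ``fitted_block[i]`` is the block the fitting step will assign site i
    to (the partitioning scheme handed to the partition models);
    ``true_origin[i]`` records which generating process simulated it.
    Both are 1-based block indices.  At 0% mispartitioning they agree.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray          # (n_taxa, n_sites) int8 states
    fitted_block: np.ndarray    # (n_sites,) in {1, 2}
    true_origin: np.ndarray     # (n_sites,) in {1, 2}

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.fitted_block = np.asarray(self.fitted_block, dtype=np.int8)
        self.true_origin = np.asarray(self.true_origin, dtype=np.int8)
        n = self.matrix.shape[1]
        if self.fitted_block.shape != (n,) or self.true_origin.shape != (n,):
            raise ValueError("label vectors must match the site count")
        if len(self.taxa) != self.matrix.shape[0]:
            raise ValueError("taxa must match the matrix rows")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    def block(self, k: int) -> np.ndarray:
        """Columns assigned to fitted block k (1-based)."""
        return self.matrix[:, self.fitted_block == k]

    def sequences(self) -> dict[str, str]:
        lut = np.array(list(BASES))
        return {t: "".join(lut[self.matrix[i]])
                for i, t in enumerate(self.taxa)}

    # -- writers -------------------------------------------------------- #

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences().items():
                fh.write(f">{name}\n{seq}\n")

    def to_phylip(self, path) -> None:
        """Relaxed PHYLIP: names of any length, two-space separated."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa} {self.n_sites}\n")
            for name, seq in self.sequences().items():
                fh.write(f"{name}  {seq}\n")

    def labels_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("site\tfitted_block\ttrue_origin\n")
            for i in range(self.n_sites):
                fh.write(f"{i + 1}\t{self.fitted_block[i]}\t"
                         f"{self.true_origin[i]}\n")


def concatenate_and_label(block1: np.ndarray, block2: np.ndarray,
                          taxa) -> LabeledAlignment:
    """Concatenate two simulated blocks into a labelled alignment."""
    block1 = np.asarray(block1)
    block2 = np.asarray(block2)
    if block1.shape[0] != block2.shape[0]:
        raise ValueError("blocks must have the same taxa")
    n1, n2 = block1.shape[1], block2.shape[1]
    labels = np.concatenate([np.ones(n1, dtype=np.int8),
                             np.full(n2, 2, dtype=np.int8)])
    return LabeledAlignment(tuple(taxa), np.hstack([block1, block2]),
                            labels.copy(), labels.copy())


def mispartition(aln: LabeledAlignment, proportion: float,
                 rng: np.random.Generator) -> LabeledAlignment:
    """Swap the fitted-block labels of a random balanced subset of sites.

    A proportion p of each fitted block's sites (p * block_length must be
    an integer) is selected uniformly without replacement and exchanged
    between the blocks; the true origins are untouched and both fitted
    blocks keep their size.
    """
    if not 0 <= proportion <= 0.5:
        raise ValueError("proportion must be in [0, 0.5]")
    idx1 = np.flatnonzero(aln.fitted_block == 1)
    idx2 = np.flatnonzero(aln.fitted_block == 2)
    m = proportion * len(idx1)
    if abs(m - round(m)) > 1e-9 or len(idx1) != len(idx2):
        raise ValueError("proportion * block_length must be integral "
                         "and blocks balanced")
    m = int(round(m))
    new = aln.fitted_block.copy()
    if m:
        new[rng.choice(idx1, size=m, replace=False)] = 2
        new[rng.choice(idx2, size=m, replace=False)] = 1
    return replace(aln, fitted_block=new,
                   matrix=aln.matrix.copy(),
                   true_origin=aln.true_origin.copy())


def simulate_replicate(condition: GeneratingCondition, proportion: float,
                       rng: np.random.Generator) -> LabeledAlignment:
    """One replicate: simulate both blocks, concatenate, mispartition."""
    b1 = simulate_block(condition.tree_pair[0], condition.model_pair[0],
                        condition.block_length, rng)
    b2 = simulate_block(condition.tree_pair[1], condition.model_pair[1],
                        condition.block_length, rng)
    aln = concatenate_and_label(b1, b2, condition.tree_pair[0].taxa)
    return mispartition(aln, proportion, rng)
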
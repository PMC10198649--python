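"""Site-pattern likelihoods by Felsenstein pruning.

A site pattern assigns one of A/C/G/T to each tip; tips are taken in
alphabetical name order and a pattern is encoded as a base-4 integer with
A=0, C=1, G=2, T=3 and the first tip in the most significant digit, so
pattern 0 is all-A and pattern ``4^N - 1`` is all-T.

Pruning is vectorised over patterns and carries per-pattern scaling
factors in log space, so likelihoods of near-impossible patterns do not
underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gtr import BASES, GTRModel
from .trees import Tree

__all__ = ["enumerate_patterns", "pattern_log_likelihoods", "Pruner",
           "PatternDistribution", "true_pattern_distribution",
           "encode_patterns", "pattern_strings"]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def encode_patterns(patterns, n_taxa: int | None = None) -> np.ndarray:
    """Coerce patterns to an (S, N) integer state matrix.

    Accepts an integer matrix, a single pattern string, or a sequence of
    pattern strings over the alphabet ACGT (tip order = alphabetical).
    """
    if isinstance(patterns, str):
        patterns = [patterns]
    if isinstance(patterns, np.ndarray) and patterns.dtype != object \
            and patterns.dtype.kind in "iu":
        mat = np.asarray(patterns, dtype=np.int64)
    else:
        rows = []
        for p in patterns:
            if isinstance(p, str):
                try:
                    rows.append([_BASE_INDEX[c] for c in p])
                except KeyError as e:
                    raise ValueError(f"unknown base {e} in pattern {p!r}") from e
            else:
                rows.append(list(p))
        mat = np.asarray(rows, dtype=np.int64)
    if mat.ndim != 2:
        raise ValueError("patterns must form a 2-D matrix")
    if n_taxa is not None and mat.shape[1] != n_taxa:
        raise ValueError(f"patterns have {mat.shape[1]} states, "
                         f"expected {n_taxa}")
    if mat.size and (mat.min() < 0 or mat.max() > 3):
        raise ValueError("states must be in 0..3 (A,C,G,T)")
    return mat


def enumerate_patterns(n_taxa: int) -> np.ndarray:
    """All ``4^N`` site patterns as an (4^N, N) state matrix.

    Row ``h`` is the base-4 expansion of ``h`` (first tip = most
    significant digit); guarded to ``2 <= N <= 10``.
    """
    if not 2 <= n_taxa <= 10:
        raise ValueError("n_taxa must be between 2 and 10")
    h = np.arange(4 ** n_taxa, dtype=np.int64)
    shifts = 2 * np.arange(n_taxa - 1, -1, -1, dtype=np.int64)
    return (h[:, None] >> shifts[None, :]) & 3


def pattern_strings(states: np.ndarray) -> list[str]:
    """Render a state matrix back to ACGT strings (one per pattern)."""
    lut = np.array(list(BASES))
    return ["".join(row) for row in lut[np.asarray(states)]]


class Pruner:
    """Reusable pruning engine for one (topology, pattern set) pair.

    Optimisers evaluate the same patterns on the same topology many
    thousands of times with different edge lengths and models; this
    caches the traversal so each evaluation is pure array work.
    """

    def __init__(self, tree: Tree, patterns):
        self.tree = tree
        self.states = encode_patterns(patterns, tree.n_tips)
        self.n_patterns = self.states.shape[0]

    def log_likelihoods(self, pmats: np.ndarray, freqs: np.ndarray,
                        scale: bool = True) -> np.ndarray:
        """Pattern log-probabilities given per-node transition matrices.

        With ``scale=False`` the per-node rescaling is skipped and site
        likelihoods are floored at 1e-300: fine for <= 10 taxa inside an
        optimiser, where speed matters and patterns this improbable
        cannot influence the optimum.
        """
        tree, states = self.tree, self.states
        s = self.n_patterns
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(s) if scale else 0.0
        for v in tree.postorder:
            if v < tree.n_tips:
                continue
            m = np.ones((s, 4))
            for c in tree.children[v]:
                p = pmats[c]
                if c < tree.n_tips:
                    m *= p[:, states[:, c]].T
                else:
                    m *= partial.pop(c) @ p.T
            if scale:
                mx = m.max(axis=1)
                safe = np.where(mx > 0, mx, 1.0)
                m = m / safe[:, None]
                with np.errstate(divide="ignore"):
                    logscale += np.log(mx)
            partial[v] = m
        site = partial[tree.root] @ np.asarray(freqs)
        if not scale:
            return np.log(np.maximum(site, 1e-300))
        with np.errstate(divide="ignore"):
            return np.log(site) + logscale

    def for_model(self, model: GTRModel,
                  edge_lengths: np.ndarray | None = None,
                  scale: bool = True) -> np.ndarray:
        lengths = (self.tree.lengths if edge_lengths is None
                   else edge_lengths)
        return self.log_likelihoods(model.transition_matrices(lengths),
                                    model.freqs, scale=scale)


def pattern_log_likelihoods(tree: Tree, model: GTRModel,
                            patterns) -> np.ndarray:
    """Log-probability of each site pattern under ``(tree, model)``.

    The tree may be rooted anywhere; by time reversibility the result is
    independent of the rooting.
    """
    return Pruner(tree, patterns).for_model(model)


@dataclass
class PatternDistribution:
    """A probability distribution over all ``4^N`` site patterns."""

    n_taxa: int
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (4 ** self.n_taxa,):
            raise ValueError("probs must have length 4^N")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative pattern probability")
        if abs(self.probs.sum() - 1.0) > 1e-10:
            raise ValueError("pattern probabilities must sum to 1")

    def to_tsv(self, path) -> None:
        """Write a two-column (pattern, probability) table."""
        pats = pattern_strings(enumerate_patterns(self.n_taxa))
        with open(path, "w") as fh:
            fh.write("pattern\tprobability\n")
            for p, q in zip(pats, self.probs):
                fh.write(f"{p}\t{q:.17g}\n")


def true_pattern_distribution(tree: Tree, model: GTRModel) -> PatternDistribution:
    """Exact pattern distribution of a (tree, model) pair by pruning.

    Enumerates all ``4^N`` patterns (guarded to N <= 10) and evaluates
    each exactly; the probabilities sum to 1 up to pruning round-off.
    """
    logp = pattern_log_likelihoods(tree, model,
                                   enumerate_patterns(tree.n_tips))
    probs = np.exp(logp)
    probs /= probs.sum()
    return PatternDistribution(tree.n_tips, probs)
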
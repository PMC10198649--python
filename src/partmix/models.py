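"""Maximum-likelihood fitting of partition and edge-length mixture models.

Four model families are fitted to a two-block labelled alignment, all
special cases of a generalised mixture whose per-site likelihood is a
weighted sum of class likelihoods:

``P-UEL``
    two-block partition, unlinked edge lengths: each block gets its own
    tree (edge lengths) and GTR model; 42 free parameters for 8 taxa.
``P-LEL``
    two-block partition, linked edge lengths: one shared tree, per-block
    GTR models; because time and rate cannot be separated on a shared
    tree, the second block additionally carries a free relative-rate
    scalar (the "ninth" GTR parameter), giving 30 parameters.
``M-UGP``
    two-class GHOST mixture, unlinked GTR parameters: one topology, two
    sets of edge lengths and two GTRs plus one free class weight (43).
``M-LGP``
    two-class GHOST mixture, linked GTR parameters: as M-UGP but one
    shared GTR (35).

Usage follows the statsmodels pattern: build a model object from data,
call :meth:`fit`, inspect the returned results object::

    model = PartitionModel(aln, family="P-UEL", topology=tree)
    res = model.fit(seed=1)
    res.llf, res.aic, res.bic, res.summary()

Optimisation is bounded quasi-Newton (L-BFGS-B) on transformed
parameters (log edge lengths, log exchangeabilities, softmax
frequencies, logit mixture weight), with a configurable number of
restarts; the best restart wins.  Partition families with unlinked
blocks are fitted block by block (their likelihood separates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .gtr import GTRModel
from .likelihood import (PatternDistribution, Pruner,
                         pattern_log_likelihoods, true_pattern_distribution)
from .simulate import LabeledAlignment
from .trees import Tree

__all__ = ["FAMILIES", "count_free_parameters", "partition_bic_split",
           "lnL_partition", "lnL_mixture", "PartitionModel",
           "GhostMixtureModel", "FitResults", "fit_model"]

FAMILIES = ("P-LEL", "P-UEL", "M-UGP", "M-LGP")

# Optimisation bounds mirror the reference ML phylogenetics software:
# branch lengths in [1e-6, 10] expected substitutions, exchangeabilities
# in [0.01, 100] relative to G<->T, frequencies and mixture weights kept
# off 0/1 by bounded logits.  Under short-edge (boundary) conditions the
# floors matter: they keep fitted pattern distributions non-degenerate,
# as any bounded ML implementation does.
_LOG_BL = (np.log(1e-6), np.log(10.0))
_LOG_RATE = (np.log(1e-2), np.log(1e2))
_LOGIT_F = 9.0
_LOGIT_A = 9.0


def count_free_parameters(family: str, n_taxa: int = 8) -> int:
    """Free-parameter count q of a model family.

    Each GTR contributes 8 (5 exchangeabilities + 3 frequencies), each
    set of edge lengths 2N-3 (13 for 8 taxa), a mixture weight 1, and
    the P-LEL relative-rate scalar 1 (so its two GTRs count 8 + 9).
    """
    e = 2 * n_taxa - 3
    counts = {"P-LEL": 8 + 9 + e, "P-UEL": 8 + 8 + 2 * e,
              "M-UGP": 8 + 8 + 2 * e + 1, "M-LGP": 8 + 2 * e + 1}
    try:
        return counts[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}") from None


def partition_bic_split(family: str, n_taxa: int = 8) -> tuple[tuple[int, int], int]:
    """Per-block unique counts (q_1, q_2) and common count q_c.

    For the per-block BIC penalty: parameters unique to block k are
    penalised by ln(n_k), shared parameters by ln(n).  P-UEL shares
    nothing; P-LEL shares the 2N-3 edge lengths.
    """
    e = 2 * n_taxa - 3
    if family == "P-UEL":
        return (8 + e, 8 + e), 0
    if family == "P-LEL":
        return (8, 9), e
    raise ValueError(f"{family!r} is not a partition family")


# --------------------------------------------------------------------- #
# parameter transforms
# --------------------------------------------------------------------- #

def _softmax4(z3: np.ndarray) -> np.ndarray:
    z = np.concatenate([z3, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _freq_logits(freqs) -> np.ndarray:
    l = np.log(np.asarray(freqs, dtype=float))
    return np.clip(l[:3] - l[3], -_LOGIT_F, _LOGIT_F)


def _clip_log(x, lo, hi):
    return np.clip(np.log(np.asarray(x, dtype=float)), lo, hi)


def _compress(cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns and their counts for a column matrix."""
    if cols.shape[1] == 0:
        raise ValueError("empty block")
    pats, counts = np.unique(cols.T, axis=0, return_counts=True)
    return pats.astype(np.int64), counts.astype(float)


def _gtr(xr: np.ndarray, zf: np.ndarray) -> GTRModel:
    return GTRModel(tuple(np.exp(xr)), tuple(_softmax4(zf)))


# --------------------------------------------------------------------- #
# likelihood evaluation at given parameters (no fitting)
# --------------------------------------------------------------------- #

def _block_patterns(aln: LabeledAlignment):
    return _compress(aln.block(1)), _compress(aln.block(2))


def lnL_partition(aln: LabeledAlignment, trees: Sequence[Tree],
                  gtrs: Sequence[GTRModel], linked_edges: bool = False,
                  rate_scalar: float = 1.0) -> float:
    """Log-likelihood of a two-block partition model at given parameters.

    With ``linked_edges`` a single shared tree is used for both blocks
    and the second block's edge lengths are multiplied by
    ``rate_scalar``; otherwise ``trees`` holds one tree per block.
    """
    (p1, c1), (p2, c2) = _block_patterns(aln)
    if linked_edges:
        t1 = trees[0]
        t2 = t1.with_edge_lengths(np.clip(rate_scalar * t1.edge_lengths,
                                          0.0, None))
    else:
        t1, t2 = trees[0], trees[1]
    return float(c1 @ pattern_log_likelihoods(t1, gtrs[0], p1)
                 + c2 @ pattern_log_likelihoods(t2, gtrs[1], p2))


def lnL_mixture(aln: LabeledAlignment, trees: Sequence[Tree],
                gtrs: Sequence[GTRModel],
                weights: Sequence[float]) -> float:
    """Log-likelihood of a two-class edge-length mixture at given parameters.

    Per site, the class likelihoods are weight-averaged and logged; the
    per-site block labels are ignored (mixtures see the whole alignment).
    """
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-8 or np.any(w <= 0) or np.any(w >= 1):
        raise ValueError("weights must lie in (0,1) and sum to 1")
    pats, counts = _compress(aln.matrix)
    g = list(gtrs) if len(gtrs) == 2 else [gtrs[0], gtrs[0]]
    lp = np.stack([pattern_log_likelihoods(trees[k], g[k], pats)
                   for k in range(2)])
    lw = np.log(w)[:, None]
    m = (lw + lp).max(axis=0)
    tot = m + np.log(np.exp(lw + lp - m).sum(axis=0))
    return float(counts @ tot)


# --------------------------------------------------------------------- #
# results object
# --------------------------------------------------------------------- #

@dataclass
class FitResults:
    """Maximum-likelihood fit of one model family to one alignment.

    Carries the estimates (trees, GTRs, mixture weights, the P-LEL
    relative-rate scalar), the maximised log-likelihood ``llf``, the
    free-parameter count ``q`` and optimisation diagnostics.  AIC and
    the family-appropriate BIC (per-block for partition models) are
    derived properties.  Mixture classes are stored with the larger
    estimated weight first, so downstream matching is deterministic.
    """

    family: str
    trees: tuple[Tree, ...]
    gtrs: tuple[GTRModel, ...]
    weights: tuple[float, float] | None
    rate_scalar: float | None
    llf: float
    nobs: int
    converged: bool
    n_restarts_used: int
    model: object | None = None

    @property
    def q(self) -> int:
        return count_free_parameters(self.family, self.trees[0].n_tips)

    # statsmodels naming
    @property
    def k_params(self) -> int:
        return self.q

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.q

    @property
    def bic(self) -> float:
        """The study's BIC: conventional for mixtures, per-block for
        partition models (unique parameters penalised by their block
        size, shared ones by the total)."""
        from .selection import bic_mixture, bic_partition
        if self.family in ("M-UGP", "M-LGP"):
            return bic_mixture(self.llf, self.q, self.nobs)
        (q1, q2), qc = partition_bic_split(self.family, self.trees[0].n_tips)
        n1, n2 = self.block_sizes
        return bic_partition(self.llf, (q1, q2), (n1, n2), qc, self.nobs)

    @property
    def bic_conventional(self) -> float:
        from .selection import bic_mixture
        return bic_mixture(self.llf, self.q, self.nobs)

    @property
    def block_sizes(self) -> tuple[int, int]:
        if self.model is not None and hasattr(self.model, "aln"):
            fb = self.model.aln.fitted_block
            return int((fb == 1).sum()), int((fb == 2).sum())
        return (self.nobs // 2, self.nobs - self.nobs // 2)

    # -- fitted pattern distributions ----------------------------------- #

    def component_trees(self) -> tuple[Tree, ...]:
        """One tree per block/class (P-LEL block 2 = scaled shared tree)."""
        if self.family == "P-LEL":
            t = self.trees[0]
            return (t, t.with_edge_lengths(self.rate_scalar * t.edge_lengths))
        return self.trees

    def component_gtrs(self) -> tuple[GTRModel, GTRModel]:
        return self.gtrs if len(self.gtrs) == 2 else (self.gtrs[0], self.gtrs[0])

    def pattern_distributions(self) -> tuple[PatternDistribution, PatternDistribution]:
        """Exact per-component distributions over all 4^N site patterns."""
        return tuple(true_pattern_distribution(t, g)
                     for t, g in zip(self.component_trees(),
                                     self.component_gtrs()))

    def mixture_distribution(self) -> PatternDistribution:
        if self.weights is None:
            raise ValueError("not a mixture fit")
        d1, d2 = self.pattern_distributions()
        probs = self.weights[0] * d1.probs + self.weights[1] * d2.probs
        return PatternDistribution(d1.n_taxa, probs / probs.sum())

    # -- reporting ------------------------------------------------------ #

    def summary(self) -> str:
        lines = [f"{self.family} maximum-likelihood fit",
                 "=" * 40,
                 f"n sites:        {self.nobs}",
                 f"log-likelihood: {self.llf:.4f}",
                 f"free params q:  {self.q}",
                 f"AIC:            {self.aic:.4f}",
                 f"BIC:            {self.bic:.4f}",
                 f"converged:      {self.converged} "
                 f"({self.n_restarts_used} restarts)"]
        if self.weights is not None:
            lines.append(f"class weights:  ({self.weights[0]:.4f}, "
                         f"{self.weights[1]:.4f})")
        if self.rate_scalar is not None:
            lines.append(f"block-2 rate scalar: {self.rate_scalar:.4f}")
        for i, g in enumerate(self.gtrs, 1):
            r = ", ".join(f"{x:.3f}" for x in g.rates)
            f = ", ".join(f"{x:.3f}" for x in g.freqs)
            lines.append(f"GTR {i}: rates=({r}, 1)  freqs=({f})")
        for i, t in enumerate(self.trees, 1):
            lines.append(f"tree {i}: {t.newick()}")
        return "\n".join(lines)

    def to_report(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.summary() + "\n")


# --------------------------------------------------------------------- #
# optimisation machinery
# --------------------------------------------------------------------- #

_OPT_OPTIONS = dict(maxiter=600, maxfun=300000, ftol=1e-9, gtol=1e-6)


def _optimize(fun: Callable, x0s: list[np.ndarray], bounds) -> tuple:
    best = None
    for x0 in x0s:
        res = minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                       options=_OPT_OPTIONS)
        if best is None or res.fun < best.fun:
            best = res
    return best, len(x0s)


def _neutral_hom(e: int) -> np.ndarray:
    return np.concatenate([np.full(e, np.log(0.05)), np.zeros(5), np.zeros(3)])


def _random_hom(e: int, rng: np.random.Generator) -> np.ndarray:
    return np.concatenate([
        np.log(rng.uniform(0.001, 0.3, size=e)),
        np.log(rng.uniform(0.25, 4.0, size=5)),
        rng.normal(0.0, 0.5, size=3),
    ])


def _pack_gtr(g: GTRModel) -> np.ndarray:
    return np.concatenate([_clip_log(g.rates, *_LOG_RATE), _freq_logits(g.freqs)])


def _pack_tree(t: Tree) -> np.ndarray:
    return _clip_log(np.maximum(t.edge_lengths, 1e-8), *_LOG_BL)


def _hom_bounds(e: int):
    return ([_LOG_BL] * e + [_LOG_RATE] * 5 + [(-_LOGIT_F, _LOGIT_F)] * 3)


@dataclass
class _HomFit:
    tree: Tree
    gtr: GTRModel
    llf: float
    converged: bool


def _fit_homogeneous(topology: Tree, pats, counts, inits,
                     rng: np.random.Generator, restarts: int) -> _HomFit:
    e = topology.n_edges
    pruner = Pruner(topology, pats)
    base = topology.lengths.copy()
    enodes = topology.edge_nodes

    def negll(x):
        lengths = base.copy()
        lengths[enodes] = np.exp(x[:e])
        lp = pruner.for_model(_gtr(x[e:e + 5], x[e + 5:]), lengths,
                              scale=False)
        return -(counts @ lp)

    x0s = list(inits) + [_neutral_hom(e)]
    while len(x0s) < restarts:
        x0s.append(_random_hom(e, rng))
    best, _ = _optimize(negll, x0s[:max(restarts, len(inits))], _hom_bounds(e))
    x = best.x
    return _HomFit(topology.with_edge_lengths(np.exp(x[:e])),
                   _gtr(x[e:e + 5], x[e + 5:]), -float(best.fun),
                   bool(best.success))


# --------------------------------------------------------------------- #
# model classes
# --------------------------------------------------------------------- #

class _BaseModel:
    """Shared constructor and topology handling for the model classes."""

    family: str

    def __init__(self, aln: LabeledAlignment, topology: Tree | None = None,
                 topology_mode: str = "fixed"):
        if topology_mode not in ("fixed", "nni", "exhaustive"):
            raise ValueError("topology_mode must be fixed, nni or exhaustive")
        if topology_mode == "fixed" and topology is None:
            raise ValueError("fixed topology mode requires a topology")
        self.aln = aln
        self.topology = topology
        self.topology_mode = topology_mode

    # search modes delegate to fixed-topology fits over candidate trees
    def fit(self, restarts: int = 3, seed: int | None = None,
            init: dict | None = None,
            extra_inits: Sequence[dict] = ()) -> FitResults:
        """Fit by ML.  ``init`` seeds the first restart (e.g. the truth);
        ``extra_inits`` add further warm starts (e.g. a nested fit)."""
        rng = np.random.default_rng(seed)
        if self.topology_mode == "fixed":
            return self._fit_fixed(self.topology, restarts, rng, init,
                                   extra_inits)
        from .search import candidate_topologies
        best = None
        for topo in candidate_topologies(self, rng):
            res = self._fit_fixed(topo, max(2, restarts - 1), rng, None, ())
            if best is None or res.llf > best.llf:
                best = res
        return best

    def _fit_fixed(self, topology, restarts, rng, init, extra_inits):
        raise NotImplementedError


class PartitionModel(_BaseModel):
    """Two-block partition model (families ``P-UEL`` and ``P-LEL``)."""

    def __init__(self, aln, family: str = "P-UEL", topology: Tree | None = None,
                 topology_mode: str = "fixed"):
        if family not in ("P-UEL", "P-LEL"):
            raise ValueError("family must be P-UEL or P-LEL")
        super().__init__(aln, topology, topology_mode)
        self.family = family

    def _fit_fixed(self, topology, restarts, rng, init, extra_inits):
        (p1, c1), (p2, c2) = _block_patterns(self.aln)
        if self.family == "P-UEL":
            return self._fit_uel(topology, (p1, c1), (p2, c2), restarts,
                                 rng, init, extra_inits)
        return self._fit_lel(topology, (p1, c1), (p2, c2), restarts,
                             rng, init, extra_inits)

    def _fit_uel(self, topology, b1, b2, restarts, rng, init, extra_inits):
        fits = []
        for k, (pats, counts) in enumerate((b1, b2)):
            inits = []
            for d in ([init] if init else []) + list(extra_inits):
                if d is None:
                    continue
                tr = d["trees"][min(k, len(d["trees"]) - 1)]
                g = d["gtrs"][min(k, len(d["gtrs"]) - 1)]
                inits.append(np.concatenate([_pack_tree(tr), _pack_gtr(g)]))
            fits.append(_fit_homogeneous(topology, pats, counts, inits,
                                         rng, restarts))
        return FitResults(
            family="P-UEL", trees=(fits[0].tree, fits[1].tree),
            gtrs=(fits[0].gtr, fits[1].gtr), weights=None, rate_scalar=None,
            llf=fits[0].llf + fits[1].llf, nobs=self.aln.n_sites,
            converged=fits[0].converged and fits[1].converged,
            n_restarts_used=restarts, model=self)

    def _fit_lel(self, topology, b1, b2, restarts, rng, init, extra_inits):
        e = topology.n_edges
        (p1, c1), (p2, c2) = b1, b2
        sl_t = slice(0, e)
        sl_g1 = slice(e, e + 8)
        sl_g2 = slice(e + 8, e + 16)
        i_r = e + 16
        pr1, pr2 = Pruner(topology, p1), Pruner(topology, p2)
        base = topology.lengths.copy()
        enodes = topology.edge_nodes

        def negll(x):
            t = np.exp(x[sl_t])
            l1 = base.copy()
            l1[enodes] = t
            l2 = base.copy()
            l2[enodes] = np.clip(np.exp(x[i_r]) * t, 1e-10, 20.0)
            g1 = _gtr(x[sl_g1][:5], x[sl_g1][5:])
            g2 = _gtr(x[sl_g2][:5], x[sl_g2][5:])
            return -(c1 @ pr1.for_model(g1, l1, scale=False)
                     + c2 @ pr2.for_model(g2, l2, scale=False))

        def pack(d):
            trees = d["trees"]
            t1 = trees[0]
            if len(trees) > 1:
                scal = (trees[1].edge_lengths.sum()
                        / max(t1.edge_lengths.sum(), 1e-12))
            else:
                scal = d.get("rate_scalar", 1.0)
            return np.concatenate([_pack_tree(t1), _pack_gtr(d["gtrs"][0]),
                                   _pack_gtr(d["gtrs"][-1]),
                                   [np.clip(np.log(scal), *_LOG_RATE)]])

        x0s = [pack(d) for d in ([init] if init else []) + list(extra_inits)]
        x0s.append(np.concatenate([_neutral_hom(e)[:e], np.zeros(8),
                                   np.zeros(8), [0.0]]))
        while len(x0s) < restarts:
            x0s.append(np.concatenate([
                _random_hom(e, rng)[:e],
                np.log(rng.uniform(0.25, 4.0, 5)), rng.normal(0, 0.5, 3),
                np.log(rng.uniform(0.25, 4.0, 5)), rng.normal(0, 0.5, 3),
                [rng.normal(0, 0.5)]]))
        bounds = ([_LOG_BL] * e + [_LOG_RATE] * 5 + [(-_LOGIT_F, _LOGIT_F)] * 3
                  + [_LOG_RATE] * 5 + [(-_LOGIT_F, _LOGIT_F)] * 3
                  + [_LOG_RATE])
        best, used = _optimize(negll, x0s, bounds)
        x = best.x
        return FitResults(
            family="P-LEL",
            trees=(topology.with_edge_lengths(np.exp(x[sl_t])),),
            gtrs=(_gtr(x[sl_g1][:5], x[sl_g1][5:]),
                  _gtr(x[sl_g2][:5], x[sl_g2][5:])),
            weights=None, rate_scalar=float(np.exp(x[i_r])),
            llf=-float(best.fun), nobs=self.aln.n_sites,
            converged=bool(best.success), n_restarts_used=used, model=self)


class GhostMixtureModel(_BaseModel):
    """Two-class edge-length (GHOST) mixture on a single topology.

    ``linked_gtr=True`` gives the M-LGP family (one shared GTR),
    ``False`` the M-UGP family (per-class GTRs).
    """

    def __init__(self, aln, linked_gtr: bool = False,
                 topology: Tree | None = None, topology_mode: str = "fixed"):
        super().__init__(aln, topology, topology_mode)
        self.linked_gtr = linked_gtr
        self.family = "M-LGP" if linked_gtr else "M-UGP"

    def _fit_fixed(self, topology, restarts, rng, init, extra_inits):
        e = topology.n_edges
        pats, counts = _compress(self.aln.matrix)
        linked = self.linked_gtr
        n_g = 8 if linked else 16
        i_a = 2 * e + n_g

        pruner = Pruner(topology, pats)
        base = topology.lengths.copy()
        enodes = topology.edge_nodes

        def negll(x):
            l1 = base.copy()
            l1[enodes] = np.exp(x[:e])
            l2 = base.copy()
            l2[enodes] = np.exp(x[e:2 * e])
            g1 = _gtr(x[2 * e:2 * e + 5], x[2 * e + 5:2 * e + 8])
            g2 = g1 if linked else _gtr(x[2 * e + 8:2 * e + 13],
                                        x[2 * e + 13:2 * e + 16])
            lp1 = pruner.for_model(g1, l1, scale=False)
            lp2 = pruner.for_model(g2, l2, scale=False)
            a = x[i_a]
            la1 = -np.log1p(np.exp(-a))   # log sigmoid(a)
            la2 = -np.log1p(np.exp(a))    # log sigmoid(-a)
            m = np.maximum(la1 + lp1, la2 + lp2)
            tot = m + np.log(np.exp(la1 + lp1 - m) + np.exp(la2 + lp2 - m))
            return -(counts @ tot)

        def pack(d):
            trees = d["trees"]
            t2 = trees[1] if len(trees) > 1 else trees[0]
            parts = [_pack_tree(trees[0]), _pack_tree(t2),
                     _pack_gtr(d["gtrs"][0])]
            if not linked:
                parts.append(_pack_gtr(d["gtrs"][-1]))
            w = d.get("weights", (0.5, 0.5))
            parts.append([np.clip(logit(w[0]), -_LOGIT_A, _LOGIT_A)])
            return np.concatenate(parts)

        x0s = [pack(d) for d in ([init] if init else []) + list(extra_inits)]
        neutral = np.concatenate([np.full(e, np.log(0.03)),
                                  np.full(e, np.log(0.08)),
                                  np.zeros(n_g), [0.0]])
        x0s.append(neutral)
        while len(x0s) < restarts:
            x0s.append(np.concatenate([
                np.log(rng.uniform(0.001, 0.3, 2 * e)),
                np.log(rng.uniform(0.25, 4.0, 5)), rng.normal(0, 0.5, 3),
                *(() if linked else
                  (np.log(rng.uniform(0.25, 4.0, 5)), rng.normal(0, 0.5, 3))),
                [rng.normal(0, 1.0)]]))
        bounds = ([_LOG_BL] * (2 * e) + ([_LOG_RATE] * 5
                  + [(-_LOGIT_F, _LOGIT_F)] * 3) * (1 if linked else 2)
                  + [(-_LOGIT_A, _LOGIT_A)])
        best, used = _optimize(negll, x0s, bounds)
        x = best.x
        a1 = float(expit(x[i_a]))
        trees = (topology.with_edge_lengths(np.exp(x[:e])),
                 topology.with_edge_lengths(np.exp(x[e:2 * e])))
        if linked:
            gtrs = (_gtr(x[2 * e:2 * e + 5], x[2 * e + 5:2 * e + 8]),)
        else:
            gtrs = (_gtr(x[2 * e:2 * e + 5], x[2 * e + 5:2 * e + 8]),
                    _gtr(x[2 * e + 8:2 * e + 13], x[2 * e + 13:2 * e + 16]))
        weights = (a1, 1.0 - a1)
        if weights[0] < weights[1]:  # canonical order: larger weight first
            trees = trees[::-1]
            weights = weights[::-1]
            if not linked:
                gtrs = gtrs[::-1]
        return FitResults(
            family=self.family, trees=trees, gtrs=gtrs, weights=weights,
            rate_scalar=None, llf=-float(best.fun), nobs=self.aln.n_sites,
            converged=bool(best.success), n_restarts_used=used, model=self)


def fit_model(aln: LabeledAlignment, family: str, topology: Tree | None = None,
              topology_mode: str = "fixed", restarts: int = 3,
              seed: int | None = None, init: dict | None = None,
              extra_inits: Sequence[dict] = ()) -> FitResults:
    """Fit one of the four families to a labelled alignment.

    Thin functional front end over :class:`PartitionModel` and
    :class:`GhostMixtureModel`; see those classes for the details.
    """
    if family in ("P-UEL", "P-LEL"):
        model = PartitionModel(aln, family=family, topology=topology,
                               topology_mode=topology_mode)
    elif family in ("M-UGP", "M-LGP"):
        model = GhostMixtureModel(aln, linked_gtr=(family == "M-LGP"),
                                  topology=topology,
                                  topology_mode=topology_mode)
    else:
        raise ValueError(f"unknown family {family!r}")
    return model.fit(restarts=restarts, seed=seed, init=init,
                     extra_inits=extra_inits)
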
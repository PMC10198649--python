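"""Performance measures: branch scores, topology recovery, parameter errors.

The branch score (Kuhner--Felsenstein) between two trees on the same tip
set is the root of the sum, over the union of their bipartitions, of
squared edge-length differences, an absent bipartition contributing
length zero.  It is a metric on edge-weighted tree space.

Fitted models are scored against the generating pair with the matching
rules of the study design: a shared P-LEL tree is compared to both
generating trees and the two scores averaged; P-UEL blocks are matched
to their generating blocks; mixture classes are matched under whichever
class-to-tree assignment gives the smaller weight-averaged score (the
estimated class weights are the default weighting, a plain mean is
available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import FitResults
from .simulate import GeneratingCondition
from .trees import Tree

__all__ = ["branch_score", "branch_score_partition", "branch_score_mixture",
           "topology_correct", "parameter_errors", "EvaluationRecord",
           "evaluate_fit", "error_percentiles"]

#: percentiles used for the parameter-recovery sampling-distribution plots
PERCENTILES = (5, 25, 50, 75, 95)


def error_percentiles(values, percentiles=PERCENTILES) -> dict[int, float]:
    """Sampling-distribution percentiles of estimates or errors.

    The study design summarises each estimated parameter's sampling
    distribution by its median, (25th, 75th) and (5th, 95th)
    percentiles across replicates.
    """
    values = np.asarray(values, dtype=float)
    return {int(p): float(np.percentile(values, p)) for p in percentiles}


def branch_score(tree_a: Tree, tree_b: Tree) -> float:
    """Kuhner--Felsenstein branch score between two trees."""
    if set(tree_a.taxa) != set(tree_b.taxa):
        raise ValueError("trees must share one tip set")
    ba = tree_a.bipartitions()
    bb = tree_b.bipartitions()
    total = 0.0
    for split in ba.keys() | bb.keys():
        total += (ba.get(split, 0.0) - bb.get(split, 0.0)) ** 2
    return float(np.sqrt(total))


def branch_score_partition(fit: FitResults,
                           truth: GeneratingCondition) -> float:
    """Average branch score of a partition fit against the generating pair."""
    g1, g2 = truth.tree_pair
    if fit.family == "P-LEL":
        shared = fit.trees[0]
        return 0.5 * (branch_score(shared, g1) + branch_score(shared, g2))
    if fit.family == "P-UEL":
        return 0.5 * (branch_score(fit.trees[0], g1)
                      + branch_score(fit.trees[1], g2))
    raise ValueError("not a partition-family fit")


def _mixture_assignment(fit: FitResults, truth: GeneratingCondition,
                        weighting: str = "alpha") -> tuple[int, float]:
    g = truth.tree_pair
    if weighting == "alpha":
        w = np.asarray(fit.weights)
    elif weighting == "mean":
        w = np.array([0.5, 0.5])
    else:
        raise ValueError("weighting must be 'alpha' or 'mean'")
    straight = w[0] * branch_score(fit.trees[0], g[0]) \
        + w[1] * branch_score(fit.trees[1], g[1])
    crossed = w[0] * branch_score(fit.trees[0], g[1]) \
        + w[1] * branch_score(fit.trees[1], g[0])
    # ties break to the straight (1->1, 2->2) assignment
    return (0, straight) if straight <= crossed else (1, crossed)


def branch_score_mixture(fit: FitResults, truth: GeneratingCondition,
                         weighting: str = "alpha") -> float:
    """Weight-averaged branch score, minimised over class assignments."""
    if fit.family not in ("M-UGP", "M-LGP"):
        raise ValueError("not a mixture-family fit")
    return _mixture_assignment(fit, truth, weighting)[1]


def topology_correct(fitted: Tree, generating: Tree) -> bool:
    """True iff the unrooted Robinson--Foulds distance is zero."""
    return fitted.rf_distance(generating) == 0


@dataclass
class EvaluationRecord:
    """Per-replicate scores of one fit against the generating condition."""

    family: str
    topology_correct: tuple[bool, ...]
    branch_score: float
    freq_errors: np.ndarray   # (2, 4) signed, component x base
    rate_errors: np.ndarray   # (2, 6) signed, component x exchangeability


def parameter_errors(fit: FitResults,
                     truth: GeneratingCondition) -> tuple[np.ndarray, np.ndarray]:
    """Signed element-wise errors of frequencies (2x4) and rates (2x6).

    Partition blocks are matched to generating blocks by label; mixture
    classes by the assignment whose edge lengths match best (the
    branch-score-minimising allocation).  Rates are compared under the
    shared G<->T = 1 normalisation.
    """
    gm = truth.model_pair
    comp = fit.component_gtrs()
    if fit.family in ("M-UGP", "M-LGP"):
        if _mixture_assignment(fit, truth)[0] == 1:
            comp = comp[::-1]
    freq = np.stack([np.asarray(comp[j].freqs) - np.asarray(gm[j].freqs)
                     for j in range(2)])
    rate = np.stack([comp[j].rates6 - gm[j].rates6 for j in range(2)])
    return freq, rate


def evaluate_fit(fit: FitResults, truth: GeneratingCondition) -> EvaluationRecord:
    """Bundle topology flags, branch score and parameter errors for a fit."""
    gen = truth.tree_pair[0]
    topo = tuple(topology_correct(t, gen) for t in fit.trees)
    if fit.family in ("M-UGP", "M-LGP"):
        bs = branch_score_mixture(fit, truth)
    else:
        bs = branch_score_partition(fit, truth)
    freq, rate = parameter_errors(fit, truth)
    return EvaluationRecord(fit.family, topo, bs, freq, rate)
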
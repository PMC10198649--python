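"""Information criteria and the simulation estimator of rEKL.

AIC is ``-2 lnL + 2q``.  The quantity it estimates is the relative
expected Kullback--Leibler divergence (rEKL): minus twice the expected
predictive log-likelihood of the fitted model under the generating
process, averaged over estimation replicates.  Because the sites are iid
given the model, the expectation over future alignments collapses to a
sum over the ``4^N`` site patterns, which this module computes exactly
(no pattern sampling).  ``Bias(AIC) = rEKL - E(AIC)`` is then the
calibration error of AIC; zero means AIC is unbiased for rEKL.

For partition models the predictive weight of fitted block k mixes the
two true processes according to the block's actual composition: with a
mispartition proportion p, block k holds 1000(1-p) sites of its own
origin and 1000p of the other, so the true mass seen by block k is
``sum_j n_k^j p*_j(h)``.  (A ``mode="literal"`` option reproduces the
alternative accounting in which each fitted block is weighted by the
combined true mass of both blocks; it is proportion-independent and is
kept for audit only.)  For mixture models the truth is the equal-weight
mixture of the two generating processes over all n sites and the fitted
predictive distribution is the weight-averaged class distribution, so
mispartitioning does not enter.

BIC is conventional for mixtures, ``-2 lnL + q ln n``.  For partition
models each block's unique parameters are penalised by the log of that
block's size and shared parameters by ``ln n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .likelihood import PatternDistribution, true_pattern_distribution
from .models import FitResults, partition_bic_split
from .simulate import GeneratingCondition

__all__ = ["aic", "bic_mixture", "bic_partition", "true_pattern_distribution",
           "rekl_partition", "rekl_mixture", "bias_aic", "SelectionScores",
           "condition_distributions", "plug_in_rekl_bound"]


def aic(lnL: float, q: int) -> float:
    """Akaike information criterion, ``-2 lnL + 2q``."""
    if not np.isfinite(lnL):
        raise ValueError("lnL must be finite")
    return -2.0 * lnL + 2.0 * q


def bic_mixture(lnL: float, q: int, n: int) -> float:
    """Conventional BIC, ``-2 lnL + q ln(n)`` (n = total sites)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * lnL + q * np.log(n)


def bic_partition(lnL: float, q_k: Sequence[int], n_k: Sequence[int],
                  q_c: int, n: int) -> float:
    """Per-block BIC for partition models.

    ``-2 lnL + sum_k q_k ln(n_k) + q_c ln(n)`` where q_k are parameters
    unique to block k (penalised by the block size n_k) and q_c are
    common to all blocks.  With K=1 this is the conventional BIC.
    """
    q_k = np.asarray(q_k, dtype=float)
    n_k = np.asarray(n_k, dtype=float)
    if q_k.shape != n_k.shape:
        raise ValueError("q_k and n_k must align")
    if int(n_k.sum()) != n:
        raise ValueError("block sizes must sum to n")
    return float(-2.0 * lnL + (q_k * np.log(n_k)).sum() + q_c * np.log(n))


# --------------------------------------------------------------------- #
# rEKL estimators
# --------------------------------------------------------------------- #

def condition_distributions(condition: GeneratingCondition
                            ) -> tuple[PatternDistribution, PatternDistribution]:
    """Exact pattern distributions of the two generating processes."""
    return tuple(true_pattern_distribution(t, m)
                 for t, m in zip(condition.tree_pair, condition.model_pair))


def _composition(fit: FitResults) -> np.ndarray:
    """n_k^j: sites in fitted block k whose true origin is j (2x2)."""
    aln = fit.model.aln
    out = np.zeros((2, 2))
    for k in (1, 2):
        for j in (1, 2):
            out[k - 1, j - 1] = np.sum((aln.fitted_block == k)
                                       & (aln.true_origin == j))
    return out


def _log_clip(p: np.ndarray) -> np.ndarray:
    # fitted pattern probabilities can round to 0; floor far below any
    # probability reachable by an 8-taxon GTR model with bounded edges
    return np.log(np.maximum(p, 1e-300))


def rekl_partition(fits: Sequence[FitResults],
                   truth: GeneratingCondition | Sequence[PatternDistribution],
                   mode: str = "composition") -> tuple[float, np.ndarray]:
    """rEKL of a partition family from c replicate fits.

    Returns ``(rekl, per_replicate)`` where ``per_replicate[l] = -2
    sum_k sum_h w_k(h) ln p_hat_l^k(h)`` and ``rekl`` is its mean over
    replicates.  ``w_k(h) = sum_j n_k^j p*_j(h)`` under the default
    composition accounting (see module docstring); ``mode="literal"``
    uses ``w_k(h) = sum_j n_j p*_j(h)`` for every fitted block.
    """
    if not fits:
        raise ValueError("need at least one fit")
    if any(f.family not in ("P-UEL", "P-LEL") for f in fits):
        raise ValueError("rekl_partition expects partition-family fits")
    if len({f.family for f in fits}) != 1:
        raise ValueError("all fits must share one family")
    dists = (condition_distributions(truth)
             if isinstance(truth, GeneratingCondition) else tuple(truth))
    pstar = np.stack([d.probs for d in dists])        # (2, 4^N)
    per = np.empty(len(fits))
    for l, fit in enumerate(fits):
        nkj = _composition(fit)
        if mode == "literal":
            w = np.tile(nkj.sum(axis=0) @ pstar, (2, 1))
        elif mode == "composition":
            w = nkj @ pstar                            # (2, 4^N)
        else:
            raise ValueError("mode must be 'composition' or 'literal'")
        phat = fit.pattern_distributions()
        per[l] = -2.0 * sum(float(w[k] @ _log_clip(phat[k].probs))
                            for k in range(2))
    return float(per.mean()), per


def rekl_mixture(fits: Sequence[FitResults],
                 truth: GeneratingCondition | Sequence[PatternDistribution],
                 alpha_true: tuple[float, float] = (0.5, 0.5),
                 n: int | None = None) -> tuple[float, np.ndarray]:
    """rEKL of a mixture family from c replicate fits.

    ``per_replicate[l] = -2 sum_h n (a1 p*_1 + a2 p*_2)(h) ln(a1_hat
    p_hat_l^1 + a2_hat p_hat_l^2)(h)``; independent of mispartitioning
    because neither side uses the block labels.
    """
    if not fits:
        raise ValueError("need at least one fit")
    if any(f.family not in ("M-UGP", "M-LGP") for f in fits):
        raise ValueError("rekl_mixture expects mixture-family fits")
    if abs(sum(alpha_true) - 1.0) > 1e-9:
        raise ValueError("true weights must sum to 1")
    dists = (condition_distributions(truth)
             if isinstance(truth, GeneratingCondition) else tuple(truth))
    if n is None:
        n = fits[0].nobs
    w = n * (alpha_true[0] * dists[0].probs + alpha_true[1] * dists[1].probs)
    per = np.empty(len(fits))
    for l, fit in enumerate(fits):
        per[l] = -2.0 * float(w @ _log_clip(fit.mixture_distribution().probs))
    return float(per.mean()), per


def plug_in_rekl_bound(truth: GeneratingCondition,
                       n_k: tuple[int, int] | None = None) -> float:
    """The entropy lower bound: rEKL when the truth itself is plugged in.

    ``-2 sum_k n_k sum_h p*_k(h) ln p*_k(h)``; by Gibbs' inequality no
    fitted model can score below this at 0% mispartitioning.
    """
    dists = condition_distributions(truth)
    if n_k is None:
        n_k = (truth.block_length, truth.block_length)
    tot = 0.0
    for nk, d in zip(n_k, dists):
        p = d.probs[d.probs > 0]
        tot += -2.0 * nk * float(p @ np.log(p))
    return tot


def bias_aic(rekl, aic_values: Sequence[float]) -> tuple[float, float]:
    """``Bias(AIC) = rEKL - E(AIC)`` with its Monte-Carlo standard error.

    ``rekl`` may be the per-replicate vector (paired SE, the tighter and
    correct choice when rEKL and AIC come from the same replicates) or a
    scalar (SE then reflects only the AIC spread).
    """
    a = np.asarray(aic_values, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one AIC value")
    r = np.asarray(rekl, dtype=float)
    if r.ndim == 1:
        if r.shape != a.shape:
            raise ValueError("per-replicate rEKL must align with AIC values")
        d = r - a
    else:
        d = float(r) - a
    se = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else np.nan
    return float(d.mean()), se


@dataclass
class SelectionScores:
    """Aggregated criterion scores for one (condition, proportion, family)."""

    condition: str
    proportion: float
    family: str
    c: int
    mean_aic: float
    mean_bic: float
    rekl: float
    bias_aic: float
    mc_se: float

    def __post_init__(self):
        # invariant of the definition, recorded rather than recomputed
        if np.isfinite(self.rekl) and np.isfinite(self.mean_aic):
            assert abs(self.bias_aic - (self.rekl - self.mean_aic)) < 1e-6
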
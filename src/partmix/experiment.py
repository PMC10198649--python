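"""End-to-end orchestration of the simulation study.

One experiment runs, for each requested condition (standard / mild /
extreme) and each mispartition proportion, ``c`` replicate alignments;
fits the requested model families to every replicate; and aggregates
criterion scores (mean AIC, mean BIC, exact rEKL, Bias(AIC) with its
Monte-Carlo standard error) and performance measures (branch scores,
topology recovery, element-wise parameter errors).

Everything is reproducible from ``(config, seed)``: per-replicate random
streams are derived from the experiment seed with fixed spawn keys, so
results do not depend on iteration order.

The default scale is a desk-scale preset (c=20, proportions 0/0.25/0.5,
fixed generating topology); ``ExperimentConfig.full_scale()`` matches
the study design (c=100, eleven proportions).
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import evaluate_fit
from .models import FAMILIES, FitResults, fit_model
from .selection import (SelectionScores, bias_aic, condition_distributions,
                        rekl_mixture, rekl_partition)
from .simulate import (CONDITIONS, GeneratingCondition, build_condition,
                       simulate_replicate)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "bias_arm", "summarize_bias", "summarize_selection",
           "summarize_parameters"]

log = logging.getLogger("partmix.experiment")

_MIX = ("M-UGP", "M-LGP")
_PART = ("P-UEL", "P-LEL")


@dataclass(frozen=True)
class ExperimentConfig:
    """Scale and mode switches for one experiment run."""

    conditions: tuple[str, ...] = CONDITIONS
    proportions: tuple[float, ...] = (0.0, 0.25, 0.5)
    replicates: int = 20
    seed: int = 0
    topology_mode: str = "fixed"
    families: tuple[str, ...] = FAMILIES
    block_length: int = 1000
    restarts: int = 3
    rekl_mode: str = "composition"
    save_alignments: bool = False

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for p in self.proportions:
            if not 0 <= p <= 0.5:
                raise ValueError("proportions must lie in [0, 0.5]")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")
        for f in self.families:
            if f not in FAMILIES:
                raise ValueError(f"unknown family {f!r}")

    @classmethod
    def full_scale(cls, seed: int = 0, **kw) -> "ExperimentConfig":
        """The study design: 100 replicates x 11 proportions per condition."""
        return cls(proportions=tuple(np.round(np.arange(0, 0.501, 0.05), 2)),
                   replicates=100, seed=seed, **kw)


@dataclass
class ExperimentResult:
    """Results bundle: per-fit table, aggregated scores, evaluations."""

    config: ExperimentConfig
    conditions: dict[str, GeneratingCondition]
    fits: pd.DataFrame        # one row per (condition, proportion, rep, family)
    scores: pd.DataFrame      # one row per (condition, proportion, family)
    n_failures: int = 0

    def summarize_bias(self) -> pd.DataFrame:
        return summarize_bias(self)

    def summarize_selection(self) -> pd.DataFrame:
        return summarize_selection(self)

    def save(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        fmt = dict(sep="\t", index=False, float_format="%.6f")
        self.fits.to_csv(os.path.join(out_dir, "evaluation.tsv"), **fmt)
        self.scores.to_csv(os.path.join(out_dir, "scores.tsv"), **fmt)
        self.summarize_bias().to_csv(
            os.path.join(out_dir, "bias_table.tsv"), **fmt)
        self.summarize_selection().to_csv(
            os.path.join(out_dir, "selection_winners.tsv"), **fmt)
        with open(os.path.join(out_dir, "generating_trees.nwk"), "w") as fh:
            for name, cond in self.conditions.items():
                for i, t in enumerate(cond.tree_pair, 1):
                    fh.write(f"[{name} tree {i}] {t.newick()}\n")


def _truth_init(cond: GeneratingCondition) -> dict:
    return {"trees": cond.tree_pair, "gtrs": cond.model_pair,
            "weights": (0.5, 0.5)}


def _fit_replicate(aln, cond, config, fit_seed) -> dict[str, FitResults]:
    """Fit the requested families, warm-starting complex from nested fits."""
    topo = cond.tree_pair[0] if config.topology_mode == "fixed" else None
    truth = _truth_init(cond)
    fits: dict[str, FitResults] = {}
    order = [f for f in ("P-LEL", "P-UEL", "M-LGP", "M-UGP")
             if f in config.families]
    for i, fam in enumerate(order):
        extra = []
        if fam == "P-UEL" and "P-LEL" in fits:
            r = fits["P-LEL"]
            extra.append({"trees": r.component_trees(), "gtrs": r.gtrs})
        if fam == "M-UGP" and "M-LGP" in fits:
            r = fits["M-LGP"]
            extra.append({"trees": r.trees, "gtrs": r.component_gtrs(),
                          "weights": r.weights})
        fits[fam] = fit_model(
            aln, fam, topology=topo, topology_mode=config.topology_mode,
            restarts=config.restarts, seed=fit_seed + [i],
            init=truth, extra_inits=extra)
    return fits


def run_experiment(config: ExperimentConfig,
                   out_dir=None) -> ExperimentResult:
    """Run the full simulate -> fit -> score -> evaluate pipeline."""
    seed = config.seed
    conditions: dict[str, GeneratingCondition] = {}
    rows = []
    score_rows = []
    n_failures = 0
    for ci, cname in enumerate(config.conditions):
        cond = build_condition(cname, np.random.default_rng([seed, ci, 777]),
                               config.block_length)
        conditions[cname] = cond
        truth_dists = condition_distributions(cond)
        for pi, prop in enumerate(config.proportions):
            arm_fits: dict[str, list[FitResults]] = {f: [] for f in config.families}
            for rep in range(config.replicates):
                rng = np.random.default_rng([seed, ci, pi, rep])
                aln = simulate_replicate(cond, prop, rng)
                try:
                    fits = _fit_replicate(aln, cond, config,
                                          [seed, ci, pi, rep])
                except Exception:  # pragma: no cover - defensive
                    log.exception("replicate failed (%s p=%s rep=%d)",
                                  cname, prop, rep)
                    n_failures += 1
                    continue
                for fam, fit in fits.items():
                    arm_fits[fam].append(fit)
                    rec = evaluate_fit(fit, cond)
                    rows.append(dict(
                        condition=cname, proportion=prop, replicate=rep,
                        family=fam, llf=fit.llf, q=fit.q, aic=fit.aic,
                        bic=fit.bic, converged=fit.converged,
                        restarts=fit.n_restarts_used,
                        branch_score=rec.branch_score,
                        topology_correct=all(rec.topology_correct),
                        alpha1=(fit.weights[0] if fit.weights else np.nan),
                        rate_scalar=(fit.rate_scalar
                                     if fit.rate_scalar is not None
                                     else np.nan),
                        freq_err_rms=float(np.sqrt((rec.freq_errors**2).mean())),
                        rate_err_rms=float(np.sqrt((rec.rate_errors**2).mean())),
                        # the two parameters tracked in the recovery plots:
                        # pi_G and r_CG of block/class 1 (matched allocation)
                        piG_hat=float(cond.model_pair[0].freqs[2]
                                      + rec.freq_errors[0, 2]),
                        rCG_hat=float(cond.model_pair[0].rates6[3]
                                      + rec.rate_errors[0, 3]),
                    ))
                if config.save_alignments and out_dir:
                    d = os.path.join(out_dir, "alignments", cname)
                    os.makedirs(d, exist_ok=True)
                    stem = os.path.join(d, f"p{int(round(prop*100)):02d}_r{rep:03d}")
                    aln.to_fasta(stem + ".fasta")
                    aln.labels_to_tsv(stem + ".blocks.tsv")
            for fam, fam_fits in arm_fits.items():
                if not fam_fits:
                    continue
                if fam in _PART:
                    rekl, per = rekl_partition(fam_fits, truth_dists,
                                               mode=config.rekl_mode)
                else:
                    rekl, per = rekl_mixture(fam_fits, truth_dists)
                aics = np.array([f.aic for f in fam_fits])
                bias, se = bias_aic(per, aics)
                score_rows.append(dataclasses.asdict(SelectionScores(
                    condition=cname, proportion=prop, family=fam,
                    c=len(fam_fits), mean_aic=float(aics.mean()),
                    mean_bic=float(np.mean([f.bic for f in fam_fits])),
                    rekl=rekl, bias_aic=bias, mc_se=se)))
    result = ExperimentResult(config, conditions, pd.DataFrame(rows),
                              pd.DataFrame(score_rows), n_failures)
    if out_dir:
        result.save(out_dir)
    return result


def bias_arm(condition_name: str, family: str, replicates: int,
             seed: int = 0, proportion: float = 0.0, restarts: int = 2,
             block_length: int = 1000) -> SelectionScores:
    """One experiment arm for one family: simulate, fit, score.

    Runs ``replicates`` independent alignments of the named condition at
    the given mispartition proportion, fits the single family with the
    generating topology fixed, and returns the aggregated scores (mean
    AIC, mean per-family BIC, exact rEKL, Bias(AIC) with its paired
    Monte-Carlo standard error).  Replicate random streams are derived
    from ``seed`` with fixed keys, so the same seed always yields the
    same arm, and different families see the same alignments.
    """
    ci = CONDITIONS.index(condition_name)
    pi = int(round(proportion * 100))
    cond = build_condition(condition_name,
                           np.random.default_rng([seed, ci, 777]),
                           block_length)
    dists = condition_distributions(cond)
    truth = _truth_init(cond)
    fits = []
    for rep in range(replicates):
        rng = np.random.default_rng([seed, ci, pi, rep])
        aln = simulate_replicate(cond, proportion, rng)
        fits.append(fit_model(
            aln, family, topology=cond.tree_pair[0], restarts=restarts,
            seed=[seed, ci, pi, rep, FAMILIES.index(family)], init=truth))
    if family in _PART:
        rekl, per = rekl_partition(fits, dists)
    else:
        rekl, per = rekl_mixture(fits, dists)
    aics = np.array([f.aic for f in fits])
    bias, se = bias_aic(per, aics)
    return SelectionScores(
        condition=condition_name, proportion=proportion, family=family,
        c=replicates, mean_aic=float(aics.mean()),
        mean_bic=float(np.mean([f.bic for f in fits])), rekl=rekl,
        bias_aic=bias, mc_se=se)


def summarize_bias(result: ExperimentResult) -> pd.DataFrame:
    """Bias(AIC) table: partition families at the smallest and largest
    proportion, mixture families pooled across proportions (their bias
    does not depend on the block labels)."""
    scores = result.scores
    fits = result.fits
    rows = []
    for cname in result.config.conditions:
        s = scores[scores.condition == cname]
        for fam in result.config.families:
            sf = s[s.family == fam]
            if sf.empty:
                continue
            if fam in _PART:
                for p in (sf.proportion.min(), sf.proportion.max()):
                    r = sf[sf.proportion == p].iloc[0]
                    rows.append(dict(condition=cname,
                                     group=f"{p:.0%}", family=fam,
                                     bias_aic=r.bias_aic, mc_se=r.mc_se,
                                     c=int(r.c)))
            else:
                # pool the per-proportion means weighted by replicate count
                w = sf.c.to_numpy(float)
                bias = float((sf.bias_aic.to_numpy() * w).sum() / w.sum())
                se = float(np.sqrt((sf.mc_se.to_numpy() ** 2 * w**2).sum())
                           / w.sum())
                rows.append(dict(condition=cname, group="all", family=fam,
                                 bias_aic=bias, mc_se=se, c=int(w.sum())))
    return pd.DataFrame(rows)


def summarize_parameters(result: ExperimentResult) -> pd.DataFrame:
    """Percentile summaries of the tracked parameter estimates.

    For each (condition, proportion, family): the 5/25/50/75/95
    percentiles of the sampling distributions of pi_G and r_CG from
    block/class 1, the two parameters the recovery plots follow.
    """
    from .evaluate import PERCENTILES
    rows = []
    group = result.fits.groupby(["condition", "proportion", "family"])
    for (cname, prop, fam), g in group:
        row = dict(condition=cname, proportion=prop, family=fam)
        for col in ("piG_hat", "rCG_hat"):
            for p in PERCENTILES:
                row[f"{col}_p{p}"] = float(np.percentile(g[col], p))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_selection(result: ExperimentResult) -> pd.DataFrame:
    """Per (condition, proportion): the family each criterion prefers."""
    rows = []
    for (cname, prop), g in result.scores.groupby(["condition", "proportion"]):
        rows.append(dict(
            condition=cname, proportion=prop,
            aic_winner=g.loc[g.mean_aic.idxmin(), "family"],
            bic_winner=g.loc[g.mean_bic.idxmin(), "family"],
            rekl_winner=g.loc[g.rekl.idxmin(), "family"]))
    return pd.DataFrame(rows)
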
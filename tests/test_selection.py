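"""Information criteria and the exact rEKL estimators."""

from types import SimpleNamespace

import numpy as np
import pytest

import partmix as pm
from partmix.models import FitResults
from partmix.selection import plug_in_rekl_bound


def truth_as_fit(cond, family="P-UEL", weights=None):
    """Wrap the generating parameters in a FitResults (plug-in, no fitting)."""
    aln = pm.simulate_replicate(cond, 0.0, np.random.default_rng(0))
    model = SimpleNamespace(aln=aln)
    return FitResults(family=family, trees=cond.tree_pair,
                      gtrs=cond.model_pair,
                      weights=weights, rate_scalar=None, llf=0.0,
                      nobs=aln.n_sites, converged=True, n_restarts_used=0,
                      model=model)


@pytest.fixture(scope="module")
def small_cond():
    t1 = pm.read_newick("((A:0.10,B:0.18):0.06,C:0.12,D:0.22);")
    t2 = t1.with_edge_lengths(t1.edge_lengths * 1.7)
    return pm.GeneratingCondition("mild", (t1, t2), pm.GENERATING_MODELS,
                                  block_length=200)


class TestCriteria:
    def test_aic_values(self):
        assert pm.aic(-100.0, 5) == 210.0
        assert pm.aic(-100.0, 0) == 200.0
        with pytest.raises(ValueError):
            pm.aic(np.inf, 3)

    def test_bic_mixture_values(self):
        assert pm.bic_mixture(-100.0, 5, np.e ** 2) == \
            pytest.approx(210.0, abs=1e-10)
        assert pm.bic_mixture(-100.0, 5, 1) == 200.0
        assert pm.bic_mixture(0.0, 43, 2000) == pytest.approx(43 * np.log(2000))

    def test_bic_partition_reduces_to_conventional_for_one_block(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            lnl = -rng.uniform(100, 10_000)
            q = int(rng.integers(1, 60))
            n = int(rng.integers(10, 5000))
            assert pm.bic_partition(lnl, (q,), (n,), 0, n) == \
                pytest.approx(pm.bic_mixture(lnl, q, n), rel=1e-12)

    def test_bic_partition_penalty_structure(self):
        # P-UEL: all 42 parameters unique to their 1000-site block
        got = pm.bic_partition(0.0, (21, 21), (1000, 1000), 0, 2000)
        assert got == pytest.approx(42 * np.log(1000))
        # P-LEL: 13 shared edges penalised at the full 2000 sites
        got = pm.bic_partition(0.0, (8, 9), (1000, 1000), 13, 2000)
        assert got == pytest.approx(17 * np.log(1000) + 13 * np.log(2000))
        with pytest.raises(ValueError):
            pm.bic_partition(0.0, (21, 21), (900, 1000), 0, 2000)

    def test_results_bic_matches_direct_formula(self, toy_fits):
        _, _, fits = toy_fits
        r = fits["M-UGP"]
        assert r.bic == pytest.approx(pm.bic_mixture(r.llf, r.q, r.nobs))
        p = fits["P-UEL"]
        (q1, q2), qc = pm.partition_bic_split("P-UEL", n_taxa=4)
        assert p.bic == pytest.approx(
            pm.bic_partition(p.llf, (q1, q2), p.block_sizes, qc, p.nobs))


class TestREKL:
    def test_plug_in_truth_attains_entropy_bound(self, small_cond):
        fit = truth_as_fit(small_cond, "P-UEL")
        rekl, per = pm.rekl_partition([fit], small_cond)
        bound = plug_in_rekl_bound(small_cond)
        assert rekl == pytest.approx(bound, rel=1e-9)
        assert per.shape == (1,)

    def test_gibbs_inequality_for_misspecified_plug_ins(self, small_cond):
        bound = plug_in_rekl_bound(small_cond)
        rng = np.random.default_rng(17)
        for _ in range(5):
            wrong = pm.GeneratingCondition(
                "mild",
                tuple(t.with_edge_lengths(t.edge_lengths
                                          * rng.uniform(0.5, 2.0))
                      for t in small_cond.tree_pair),
                (pm.sample_gtr(rng), pm.sample_gtr(rng)),
                block_length=small_cond.block_length)
            fit = truth_as_fit(wrong, "P-UEL")
            rekl, _ = pm.rekl_partition([fit], small_cond)
            assert rekl >= bound - 1e-6

    def test_mixture_gibbs_inequality(self, small_cond):
        # the true equal-weight mixture plug-in scores no worse than
        # misspecified mixtures against the mixture truth
        truth_fit = truth_as_fit(small_cond, "M-UGP", weights=(0.5, 0.5))
        best, _ = pm.rekl_mixture([truth_fit], small_cond)
        rng = np.random.default_rng(23)
        for _ in range(5):
            w = float(rng.uniform(0.1, 0.9))
            wrong = pm.GeneratingCondition(
                "mild",
                tuple(t.with_edge_lengths(t.edge_lengths
                                          * rng.uniform(0.5, 2.0))
                      for t in small_cond.tree_pair),
                (pm.sample_gtr(rng), pm.sample_gtr(rng)),
                block_length=small_cond.block_length)
            fit = truth_as_fit(wrong, "M-UGP", weights=(w, 1 - w))
            rekl, _ = pm.rekl_mixture([fit], small_cond)
            assert rekl >= best - 1e-6

    def test_replicate_averaging(self, small_cond):
        fit = truth_as_fit(small_cond, "P-UEL")
        r1, _ = pm.rekl_partition([fit], small_cond)
        r2, per = pm.rekl_partition([fit, fit], small_cond)
        assert r1 == pytest.approx(r2, rel=1e-12)
        assert per[0] == pytest.approx(per[1])

    def test_literal_mode_is_proportion_independent(self, small_cond):
        # the literal weighting double-counts the true mass; it must not
        # react to the composition of the fitted blocks
        rng = np.random.default_rng(3)
        fits = []
        for p in (0.0, 0.25):
            aln = pm.simulate_replicate(small_cond, p, rng)
            model = SimpleNamespace(aln=aln)
            fits.append(FitResults(
                family="P-UEL", trees=small_cond.tree_pair,
                gtrs=small_cond.model_pair, weights=None, rate_scalar=None,
                llf=0.0, nobs=aln.n_sites, converged=True,
                n_restarts_used=0, model=model))
        r0, _ = pm.rekl_partition([fits[0]], small_cond, mode="literal")
        r1, _ = pm.rekl_partition([fits[1]], small_cond, mode="literal")
        assert r0 == pytest.approx(r1, rel=1e-12)
        # whereas the composition-aware default does react
        c0, _ = pm.rekl_partition([fits[0]], small_cond)
        c1, _ = pm.rekl_partition([fits[1]], small_cond)
        assert abs(c0 - c1) > 1e-6

    def test_mixture_rekl_ignores_mispartitioning(self, small_cond):
        rng = np.random.default_rng(4)
        aln = pm.simulate_replicate(small_cond, 0.0, rng)
        base = FitResults(family="M-LGP", trees=small_cond.tree_pair,
                          gtrs=(small_cond.model_pair[0],),
                          weights=(0.6, 0.4), rate_scalar=None, llf=0.0,
                          nobs=aln.n_sites, converged=True,
                          n_restarts_used=0,
                          model=SimpleNamespace(aln=aln))
        r0, _ = pm.rekl_mixture([base], small_cond)
        swapped = pm.mispartition(aln, 0.25, rng)
        base.model = SimpleNamespace(aln=swapped)
        r1, _ = pm.rekl_mixture([base], small_cond)
        assert r0 == pytest.approx(r1, rel=1e-12)

    def test_monte_carlo_cross_check_of_exact_distribution(self, small_cond):
        # simulated pattern frequencies converge on the exact pruning
        # distribution used by the rEKL estimators
        tree, model = small_cond.tree_pair[0], small_cond.model_pair[0]
        dist = pm.true_pattern_distribution(tree, model)
        n = 200_000
        mat = pm.simulate_block(tree, model, n, np.random.default_rng(6))
        idx = ((mat[0].astype(np.int64) * 4 + mat[1]) * 4
               + mat[2]) * 4 + mat[3]
        emp = np.bincount(idx, minlength=256) / n
        se = np.sqrt(dist.probs * (1 - dist.probs) / n)
        assert np.all(np.abs(emp - dist.probs) < 5 * np.maximum(se, 1e-5))


class TestBias:
    def test_bias_zero_when_aic_equals_rekl(self):
        b, se = pm.bias_aic(210.0, [210.0, 210.0, 210.0])
        assert b == 0.0 and se == 0.0

    def test_paired_bias_and_se(self):
        per = np.array([100.0, 110.0, 120.0])
        aics = np.array([90.0, 100.0, 110.0])
        b, se = pm.bias_aic(per, aics)
        assert b == pytest.approx(10.0)
        assert se == pytest.approx(0.0)

    def test_scalar_rekl_variant(self):
        b, se = pm.bias_aic(100.0, [90.0, 110.0])
        assert b == pytest.approx(0.0)
        assert se == pytest.approx(np.std([10.0, -10.0], ddof=1) / np.sqrt(2))
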
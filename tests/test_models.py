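"""Model fitting: parameter counts, likelihood evaluation, optimisation."""

import numpy as np
import pytest

import partmix as pm
from partmix.models import lnL_mixture, lnL_partition


class TestParameterCounts:
    @pytest.mark.parametrize("family,q", [("P-LEL", 30), ("P-UEL", 42),
                                          ("M-UGP", 43), ("M-LGP", 35)])
    def test_counts_for_8_taxa(self, family, q):
        assert pm.count_free_parameters(family) == q

    def test_counts_scale_with_edges(self):
        # 4 taxa: 5 edges per tree
        assert pm.count_free_parameters("P-UEL", n_taxa=4) == 8 + 8 + 10

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            pm.count_free_parameters("GTR+G")

    def test_partition_bic_split_consistency(self):
        for fam in ("P-UEL", "P-LEL"):
            (q1, q2), qc = pm.partition_bic_split(fam)
            assert q1 + q2 + qc == pm.count_free_parameters(fam)
        assert pm.partition_bic_split("P-UEL") == ((21, 21), 0)
        assert pm.partition_bic_split("P-LEL") == ((8, 9), 13)


class TestLikelihoodEvaluation:
    def test_puel_lnl_separates_over_blocks(self, toy_condition_alignment):
        cond, aln = toy_condition_alignment
        t1, t2 = cond.tree_pair
        g1, g2 = cond.model_pair
        full = lnL_partition(aln, (t1, t2), (g1, g2))
        b1 = pm.pattern_log_likelihoods(t1, g1, aln.block(1).T)
        b2 = pm.pattern_log_likelihoods(t2, g2, aln.block(2).T)
        assert full == pytest.approx(b1.sum() + b2.sum(), rel=1e-12)

    def test_plel_equals_puel_when_parameters_coincide(self,
                                                       toy_condition_alignment):
        cond, aln = toy_condition_alignment
        t = cond.tree_pair[0]
        g1, g2 = cond.model_pair
        linked = lnL_partition(aln, (t,), (g1, g2), linked_edges=True,
                               rate_scalar=1.0)
        unlinked = lnL_partition(aln, (t, t), (g1, g2))
        assert linked == pytest.approx(unlinked, rel=1e-12)

    def test_mixture_identical_classes_independent_of_weight(
            self, toy_condition_alignment):
        cond, aln = toy_condition_alignment
        t = cond.tree_pair[0]
        g = cond.model_pair[0]
        vals = [lnL_mixture(aln, (t, t), (g, g), (w, 1 - w))
                for w in (0.2, 0.5, 0.8)]
        assert np.ptp(vals) < 1e-9

    def test_mixture_degenerate_weight_approaches_homogeneous(
            self, toy_condition_alignment):
        cond, aln = toy_condition_alignment
        t1, t2 = cond.tree_pair
        g = cond.model_pair[0]
        hom = lnL_mixture(aln, (t1, t1), (g, g), (0.5, 0.5))
        near = lnL_mixture(aln, (t1, t2), (g, g), (1 - 1e-12, 1e-12))
        # class-2 contribution vanishes as its weight goes to 0
        assert near == pytest.approx(hom, abs=1e-6)

    def test_two_site_mixture_hand_computed(self):
        t1 = pm.read_newick("(A:0.05,B:0.05);")
        t2 = pm.read_newick("(A:0.4,B:0.4);")
        g = pm.GTRModel.jc()
        taxa = ("A", "B")
        # two sites: (A,C) and (G,G); rows are taxa, columns sites
        mat = np.array([[0, 2], [1, 2]], dtype=np.int8)
        aln = pm.LabeledAlignment(taxa, mat, np.array([1, 2]),
                                  np.array([1, 2]))
        a = (0.3, 0.7)
        got = lnL_mixture(aln, (t1, t2), (g, g), a)
        want = 0.0
        for pat in ("AC", "GG"):
            l1 = np.exp(pm.pattern_log_likelihoods(t1, g, [pat]))[0]
            l2 = np.exp(pm.pattern_log_likelihoods(t2, g, [pat]))[0]
            want += np.log(a[0] * l1 + a[1] * l2)
        assert got == pytest.approx(want, rel=1e-12)

    def test_invalid_weights_rejected(self, toy_condition_alignment):
        cond, aln = toy_condition_alignment
        t = cond.tree_pair[0]
        g = cond.model_pair[0]
        with pytest.raises(ValueError):
            lnL_mixture(aln, (t, t), (g, g), (0.7, 0.7))


class TestFitting:
    def test_nesting_inequalities(self, toy_fits):
        _, _, fits = toy_fits
        assert fits["M-UGP"].llf >= fits["M-LGP"].llf - 1e-6
        assert fits["P-UEL"].llf >= fits["P-LEL"].llf - 1e-6

    def test_fit_beats_generating_parameters(self, toy_fits):
        cond, aln, fits = toy_fits
        truth_part = lnL_partition(aln, cond.tree_pair, cond.model_pair)
        assert fits["P-UEL"].llf >= truth_part - 1e-6
        truth_mix = lnL_mixture(aln, cond.tree_pair,
                                cond.model_pair, (0.5, 0.5))
        assert fits["M-UGP"].llf >= truth_mix - 1e-6

    def test_q_and_information_criteria(self, toy_fits):
        _, _, fits = toy_fits
        for fam, res in fits.items():
            assert res.q == pm.count_free_parameters(fam, n_taxa=4)
            assert res.aic == pytest.approx(-2 * res.llf + 2 * res.q)

    def test_mixture_classes_canonically_ordered(self, toy_fits):
        _, _, fits = toy_fits
        for fam in ("M-UGP", "M-LGP"):
            w = fits[fam].weights
            assert w[0] >= w[1]
            assert w[0] + w[1] == pytest.approx(1.0)
            assert 0 < w[1] < 1

    def test_optimizer_determinism(self, toy_condition_alignment):
        cond, aln = toy_condition_alignment
        kw = dict(topology=cond.tree_pair[0], restarts=2, seed=11)
        a = pm.fit_model(aln, "P-LEL", **kw)
        b = pm.fit_model(aln, "P-LEL", **kw)
        assert a.llf == b.llf
        assert np.array_equal(a.trees[0].edge_lengths,
                              b.trees[0].edge_lengths)
        assert a.gtrs[0].rates == b.gtrs[0].rates
        assert a.rate_scalar == b.rate_scalar

    def test_exchangeable_blocks_give_similar_estimates(self):
        # both blocks simulated under the same process: the two P-UEL
        # block fits should agree within sampling error
        t = pm.read_newick("((A:0.10,B:0.18):0.06,C:0.12,D:0.22);")
        g = pm.GENERATING_MODELS[0]
        cond = pm.GeneratingCondition("mild", (t, t), (g, g),
                                      block_length=800)
        aln = pm.simulate_replicate(cond, 0.0, np.random.default_rng(21))
        res = pm.fit_model(aln, "P-UEL", topology=t, restarts=2, seed=5,
                           init={"trees": (t, t), "gtrs": (g, g)})
        f1 = np.asarray(res.gtrs[0].freqs)
        f2 = np.asarray(res.gtrs[1].freqs)
        assert np.abs(f1 - f2).max() < 0.08
        assert abs(res.trees[0].edge_lengths.sum()
                   - res.trees[1].edge_lengths.sum()) < 0.25

    def test_summary_report(self, toy_fits, tmp_path):
        _, _, fits = toy_fits
        text = fits["M-LGP"].summary()
        assert "M-LGP" in text and "log-likelihood" in text
        assert "class weights" in text
        fits["P-LEL"].to_report(tmp_path / "r.txt")
        assert "rate scalar" in (tmp_path / "r.txt").read_text()

    def test_fixed_mode_requires_topology(self, toy_condition_alignment):
        _, aln = toy_condition_alignment
        with pytest.raises(ValueError):
            pm.PartitionModel(aln, family="P-UEL")
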
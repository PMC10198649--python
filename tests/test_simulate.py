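"""The generating process: conditions, sequence simulation, mispartitioning."""

import numpy as np
import pytest
from scipy.stats import chisquare

import partmix as pm


class TestSampleGTR:
    def test_frequency_bounds_and_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = pm.sample_gtr(rng)
            f = np.asarray(m.freqs)
            assert np.all(f >= 0.1) and np.all(f <= 0.7)
            assert f.sum() == pytest.approx(1.0)
            assert np.all(np.asarray(m.rates) >= 0.5)
            assert np.all(np.asarray(m.rates) <= 5.0)

    def test_rate_mean_matches_uniform(self):
        rng = np.random.default_rng(1)
        rates = np.array([pm.sample_gtr(rng).rates for _ in range(10_000)])
        # mean of U(0.5, 5) is 2.75, sd = 4.5/sqrt(12)
        se = 4.5 / np.sqrt(12) / np.sqrt(10_000)
        assert np.all(np.abs(rates.mean(axis=0) - 2.75) < 3 * se)


class TestConditions:
    def test_mild_tree1_all_edges_give_5_expected_substitutions(self):
        cond = pm.build_condition("mild")
        expected = cond.tree_pair[0].edge_lengths * cond.block_length
        assert np.allclose(expected, 5.0)

    def test_mild_tree2_and_extreme_edge_length_sets(self):
        mild = pm.build_condition("mild")
        assert set(np.round(mild.tree_pair[1].edge_lengths, 6)) == {0.005, 0.001}
        ext = pm.build_condition("extreme")
        for t in ext.tree_pair:
            assert set(np.round(t.edge_lengths, 6)) == {0.005, 0.001}

    def test_long_edges_are_not_monophyletic(self):
        # the 0.005 tip edges of each LBA tree belong to different cherries
        for cond, k in [(pm.build_condition("mild"), 1),
                        (pm.build_condition("extreme"), 1)]:
            t = cond.tree_pair[k]
            all_taxa = set(t.taxa)
            long_tips = set()
            for s, l in t.bipartitions().items():
                if abs(l - 0.005) > 1e-12:
                    continue
                if len(s) == 1:
                    long_tips |= s
                elif len(s) == t.n_tips - 1:
                    long_tips |= all_taxa - s
            assert len(long_tips) == 2
            assert frozenset(long_tips) not in t.splits()

    def test_standard_condition_edges_exceed_5_substitutions(self):
        cond = pm.build_condition("standard", np.random.default_rng(5))
        for t in cond.tree_pair:
            assert np.all(t.edge_lengths * cond.block_length > 5.0)

    def test_trees_share_topology(self):
        for name in ("mild", "extreme"):
            cond = pm.build_condition(name)
            assert cond.tree_pair[0].same_topology(cond.tree_pair[1])

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            pm.build_condition("bogus")


class TestSimulateBlock:
    def test_zero_length_star_gives_constant_columns(self):
        star = pm.read_newick("(A:0.0,B:0.0,C:0.0,D:0.0);")
        mat = pm.simulate_block(star, pm.GENERATING_MODELS[0], 500,
                                np.random.default_rng(0))
        assert np.all(mat == mat[0])

    def test_tip_frequencies_match_stationary_distribution(self):
        cond = pm.build_condition("mild")
        model = pm.GENERATING_MODELS[0]
        n = 100_000
        mat = pm.simulate_block(cond.tree_pair[0], model, n,
                                np.random.default_rng(3))
        for row in mat:
            emp = np.bincount(row, minlength=4) / n
            for b in range(4):
                p = model.freqs[b]
                se = np.sqrt(p * (1 - p) / n)
                assert abs(emp[b] - p) < 4 * se

    def test_empirical_patterns_match_exact_distribution(self):
        # chi-square goodness of fit of simulated 4-taxon patterns
        # against the pruning-computed exact distribution
        tree = pm.read_newick("((A:0.15,B:0.31):0.12,C:0.22,D:0.08);")
        model = pm.GENERATING_MODELS[1]
        dist = pm.true_pattern_distribution(tree, model)
        n = 40_000
        mat = pm.simulate_block(tree, model, n, np.random.default_rng(9))
        idx = ((mat[0].astype(np.int64) * 4 + mat[1]) * 4 + mat[2]) * 4 + mat[3]
        obs = np.bincount(idx, minlength=256)
        keep = dist.probs * n >= 5
        obs_k = np.append(obs[keep], obs[~keep].sum())
        exp_k = np.append(dist.probs[keep], dist.probs[~keep].sum()) * n
        stat, p = chisquare(obs_k, exp_k)
        assert p > 0.01

    def test_invalid_site_count(self):
        with pytest.raises(ValueError):
            pm.simulate_block(pm.base_topology(0.01),
                              pm.GENERATING_MODELS[0], 0,
                              np.random.default_rng(0))


class TestConcatenateAndMispartition:
    def make(self, seed=0, block=50):
        cond = pm.build_condition("mild")
        rng = np.random.default_rng(seed)
        b1 = pm.simulate_block(cond.tree_pair[0], cond.model_pair[0], block, rng)
        b2 = pm.simulate_block(cond.tree_pair[1], cond.model_pair[1], block, rng)
        return pm.concatenate_and_label(b1, b2, cond.tree_pair[0].taxa)

    def test_concatenation_layout(self):
        cond = pm.build_condition("mild")
        aln = pm.simulate_replicate(cond, 0.0, np.random.default_rng(0))
        assert aln.n_sites == 2000 and aln.n_taxa == 8
        assert np.all(aln.fitted_block == aln.true_origin)
        assert np.all(aln.fitted_block[:1000] == 1)
        assert np.all(aln.fitted_block[1000:] == 2)

    def test_zero_proportion_is_identity(self):
        aln = self.make()
        out = pm.mispartition(aln, 0.0, np.random.default_rng(1))
        assert np.array_equal(out.fitted_block, aln.fitted_block)
        assert np.array_equal(out.matrix, aln.matrix)

    @pytest.mark.parametrize("prop", [0.1, 0.3, 0.5])
    def test_swap_counts_and_balance(self, prop):
        aln = self.make(block=100)
        out = pm.mispartition(aln, prop, np.random.default_rng(2))
        m = int(prop * 100)
        # balance preserved
        assert (out.fitted_block == 1).sum() == 100
        assert (out.fitted_block == 2).sum() == 100
        # exactly m sites moved each way; true origins untouched
        moved_1to2 = np.sum((aln.fitted_block == 1) & (out.fitted_block == 2))
        moved_2to1 = np.sum((aln.fitted_block == 2) & (out.fitted_block == 1))
        assert moved_1to2 == m and moved_2to1 == m
        assert np.array_equal(out.true_origin, aln.true_origin)
        # at 50%: half of fitted block 1 has true origin 2
        if prop == 0.5:
            fb1 = out.true_origin[out.fitted_block == 1]
            assert (fb1 == 2).sum() == 50

    def test_non_integral_swap_rejected(self):
        aln = self.make(block=50)
        with pytest.raises(ValueError):
            pm.mispartition(aln, 0.013, np.random.default_rng(0))

    def test_identical_seeds_reproduce_identical_replicates(self):
        cond = pm.build_condition("mild")
        a = pm.simulate_replicate(cond, 0.25, np.random.default_rng(123))
        b = pm.simulate_replicate(cond, 0.25, np.random.default_rng(123))
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.fitted_block, b.fitted_block)

    def test_full_design_enumerates_1100_alignments(self):
        config = pm.ExperimentConfig.full_scale()
        assert len(config.proportions) == 11
        assert len(config.proportions) * config.replicates == 1100


class TestWriters:
    def test_fasta_phylip_and_labels_round_trip(self, tmp_path):
        cond = pm.build_condition("mild")
        aln = pm.simulate_replicate(cond, 0.05, np.random.default_rng(4))
        fasta = tmp_path / "aln.fasta"
        labels = tmp_path / "aln.blocks.tsv"
        aln.to_fasta(fasta)
        aln.to_phylip(tmp_path / "aln.phy")
        aln.labels_to_tsv(labels)
        from partmix.io import read_alignment
        back = read_alignment(fasta, labels)
        assert np.array_equal(back.matrix, aln.matrix)
        assert np.array_equal(back.fitted_block, aln.fitted_block)
        assert np.array_equal(back.true_origin, aln.true_origin)
        first = (tmp_path / "aln.phy").read_text().splitlines()[0]
        assert first.split() == ["8", "2000"]
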
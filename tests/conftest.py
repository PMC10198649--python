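"""Shared fixtures: small trees, models and alignments built in memory."""

import numpy as np
import pytest

import partmix as pm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231101)


@pytest.fixture(scope="session")
def tree4():
    return pm.read_newick("((A:0.12,B:0.3):0.08,C:0.21,D:0.05);")


@pytest.fixture(scope="session")
def gtr_pair():
    return pm.GENERATING_MODELS


@pytest.fixture(scope="session")
def mild_condition():
    return pm.build_condition("mild")


@pytest.fixture(scope="session")
def extreme_condition():
    return pm.build_condition("extreme")


@pytest.fixture(scope="session")
def standard_condition():
    return pm.build_condition("standard", np.random.default_rng([0, 0, 777]))


@pytest.fixture(scope="session")
def mild_alignment(mild_condition):
    return pm.simulate_replicate(mild_condition, 0.0,
                                 np.random.default_rng(42))


def small_two_block(seed=7, n_tips=4, block=120):
    """A small 4-taxon two-block alignment for fast fitting tests."""
    t1 = pm.read_newick("((A:0.10,B:0.18):0.06,C:0.12,D:0.22);")
    t2 = t1.with_edge_lengths(t1.edge_lengths * 2.0)
    g1, g2 = pm.GENERATING_MODELS
    cond = pm.GeneratingCondition("mild", (t1, t2), (g1, g2),
                                  block_length=block)
    rng = np.random.default_rng(seed)
    return cond, pm.simulate_replicate(cond, 0.0, rng)


@pytest.fixture(scope="session")
def toy_condition_alignment():
    return small_two_block()


@pytest.fixture(scope="session")
def toy_fits(toy_condition_alignment):
    """All four families fitted to the small 4-taxon alignment."""
    cond, aln = toy_condition_alignment
    truth = {"trees": cond.tree_pair, "gtrs": cond.model_pair,
             "weights": (0.5, 0.5)}
    fits = {}
    for fam in pm.FAMILIES:
        extra = []
        if fam == "M-UGP" and "M-LGP" in fits:
            r = fits["M-LGP"]
            extra = [{"trees": r.trees, "gtrs": r.component_gtrs(),
                      "weights": r.weights}]
        fits[fam] = pm.fit_model(aln, fam, topology=cond.tree_pair[0],
                                 restarts=2, seed=3, init=truth,
                                 extra_inits=extra)
    return cond, aln, fits
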
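import pytest

from hicdelta import make_genome, synthetic


@pytest.fixture(scope="session")
def genome400():
    """10 Mb / 25 kb genome (400 bins) shared by simulation-based tests."""
    return make_genome(1, 10_000_000, 25_000, 200, seed=3)


@pytest.fixture(scope="session")
def truth400(genome400):
    return synthetic.default_truth(genome400, n_loops=20, seed=3)


@pytest.fixture(scope="session")
def hic400(genome400, truth400):
    """One simulated, balanced contact matrix at the default conditions."""
    cm = synthetic.simulate_hic(genome400, truth400, seed=11)
    cm.balance()
    return cm


@pytest.fixture(scope="session")
def oe400(hic400):
    return hic400.obs_over_exp(balanced=False)


@pytest.fixture(scope="session")
def ko_pair(genome400, truth400):
    """(truth_ko, matrix_wt, matrix_ko) with the default KO-like contrast."""
    t2 = synthetic.perturb_truth(truth400, delta_aa=-0.3, delta_bb=0.3,
                                 delta_ins=0.4, loop_drop=0.3, seed=7)
    cm1 = synthetic.simulate_hic(genome400, truth400, seed=21)
    cm2 = synthetic.simulate_hic(genome400, t2, seed=22)
    cm1.balance()
    cm2.balance()
    return t2, cm1, cm2
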
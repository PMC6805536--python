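import numpy as np
import pytest

import bayesnma as bn


@pytest.fixture(scope="session")
def toy_network():
    return bn.load_toy_diabetes()


@pytest.fixture(scope="session")
def single_trial_network():
    """One two-arm dichotomous trial with Woolf log-OR MLE 0.8109."""
    rows = [dict(study="S1", treatment="A", events=10, sample_size=100),
            dict(study="S1", treatment="B", events=20, sample_size=100)]
    return bn.prepare_network(rows, "dichotomous")


@pytest.fixture(scope="session")
def single_trial_fit(single_trial_network):
    """Fixed-effect logit fit of the single trial (shared across tests)."""
    model = bn.NMAModel(single_trial_network, link="logit", effects="fixed")
    return model.fit(n_adapt=500, n_burnin=1000, n_iter=8000, n_chains=2,
                     seed=123)


@pytest.fixture(scope="session")
def small_re_fit():
    """Random-effects fit of a small synthetic logit network."""
    cfg = bn.FixtureConfig(T=3, M=12, family="dichotomous", link="logit",
                           d=(0.0, 0.4, 0.8), sigma=0.2, n_per_arm=300,
                           baseline_mean=-1.0, baseline_sd=0.3, seed=5)
    nd, truth = bn.generate_synthetic_network(cfg)
    model = bn.NMAModel(nd, link="logit", effects="random")
    res = model.fit(n_adapt=1000, n_burnin=1500, n_iter=4000, n_chains=2,
                    seed=17)
    return nd, truth, res


def make_disconnected_network():
    rows = [dict(study="S1", treatment="A", events=5, sample_size=50),
            dict(study="S1", treatment="B", events=8, sample_size=50),
            dict(study="S2", treatment="C", events=3, sample_size=40),
            dict(study="S2", treatment="D", events=9, sample_size=40)]
    return bn.prepare_network(rows, "dichotomous")


def random_small_network(rng, T=5, M=6):
    """A random dichotomous network for property tests (may be disconnected)."""
    labels = [chr(ord("A") + t) for t in range(T)]
    rows = []
    for i in range(M):
        a = int(rng.integers(2, min(T, 3) + 1))
        trts = rng.choice(T, size=a, replace=False)
        for t in trts:
            rows.append(dict(study=f"S{i}", treatment=labels[t],
                             events=int(rng.integers(1, 20)),
                             sample_size=40))
    return bn.prepare_network(rows, "dichotomous")
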
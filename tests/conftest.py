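import numpy as np
import pytest

import otubench as ob


@pytest.fixture
def disjoint_pair():
    return ob.make_disjoint_pair(100, decay=0.99, seed=11)


@pytest.fixture
def sim_b_experiment():
    """A moderate Simulation B experiment with a strong effect."""
    template = ob.make_template(200, decay=0.99, seed=0)
    libs = ob.sample_library_sizes(20, 2000, log_sd=1.0, seed=1)
    perturbed = ob.pick_perturbed_otus(template, 0.10, seed=2)
    counts, design = ob.simulate_experiment_B(
        template, libs, 5.0, perturbed, n_per_class=10, seed=3
    )
    return counts, design


def nb_counts(rng, mu, phi, n_reps):
    """Direct NB sampler (gamma-Poisson), independent across OTUs."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if phi == 0:
        return rng.poisson(mu[:, None], size=(mu.size, n_reps))
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu)[:, None], size=(mu.size, n_reps))
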
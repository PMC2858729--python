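import numpy as np
import pytest

import raschpower as rp


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_dataset(rng):
    """A 60-patient, 5-item simulated dataset with a medium group effect."""
    bank = rp.make_item_difficulties(5)
    spec = rp.latent_spec_from_effect_size(0.5)
    traits, groups = rp.simulate_latent_traits(spec, 30, rng)
    return rp.simulate_responses(traits, groups, bank, rng), bank


def simulate_dataset(es, n_per_group, n_items, seed, epsilon=0.0):
    """Simulation-truth dataset + bank for a scenario cell, reproducibly."""
    rng = np.random.default_rng(seed)
    bank = rp.make_item_difficulties(n_items)
    if epsilon > 0:
        bank = rp.perturb_item_difficulties(bank, epsilon, rng)
    spec = rp.latent_spec_from_effect_size(es)
    traits, groups = rp.simulate_latent_traits(spec, n_per_group, rng)
    return rp.simulate_responses(traits, groups, bank, rng), bank
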
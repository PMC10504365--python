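import numpy as np
import pytest

from circbact.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """One shared error-free small simulation (3 linear + 3 circular loci)."""
    config = SimConfig(
        genome_length=20_000,
        n_linear_loci=3,
        n_circ_loci=3,
        n_samples=1,
        coverage_per_sample=40,
        substitution_error_rate=0.0,
        seed=7,
    )
    sim_genome, truth, reads = simulate(config)
    return config, sim_genome, truth, reads


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def random_bases(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
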
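import pytest

from mirisc_shift.synthetic_data import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """A compact full simulation with default noise levels."""
    return simulate_all(SimConfig(n_genes=60, rng_seed=1))


@pytest.fixture(scope="session")
def noise_free_sim():
    """Poisson counts, exact Ct decay, exact densitometry."""
    return simulate_all(
        SimConfig(n_genes=120, nb_dispersion=0.0, ct_noise_sd=0.0,
                  densitometry_noise_sd=0.0, rng_seed=2)
    )
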
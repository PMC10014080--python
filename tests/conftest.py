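import numpy as np
import pytest

import mutspectra as ms
from mutspectra.simulate import DECODE_SCALE_EFFECTS, effects_to_fractions


@pytest.fixture(scope="session")
def decode_effects():
    """Realistic per-class parental-age effects for synthetic data."""
    return DECODE_SCALE_EFFECTS


@pytest.fixture(scope="session")
def single_class_trios():
    """10,000 synthetic trios for one class with known parameters."""
    truth = ms.ParentalAgeEffect("x", 7.6, 1.35, 2.0, 0.4)
    scenario = ms.TrioScenario(
        n_trios=10_000, effects={"x": truth}, phased_fraction=0.4, seed=11
    )
    return truth, ms.simulate_trio_dataset(scenario)


@pytest.fixture(scope="session")
def constant_spectrum_variants(decode_effects):
    """50,000 variants from a single-epoch spectrum implied by the effects at
    generation time 30, observed in two populations."""
    fractions = effects_to_fractions(decode_effects, 30.0, 30.0)
    scenario = ms.SpectrumScenario(
        epochs=[ms.Epoch(0.0, 5000.0, fractions)],
        n_variants=50_000,
        populations={"POP1": 1.0, "POP2": 1.0},
        seed=7,
    )
    return ms.simulate_variant_dataset(scenario)


@pytest.fixture(scope="session")
def planted_signature_matrix():
    """96 x 45 matrix mixed from three known signatures plus Poisson noise."""
    rng = np.random.default_rng(42)
    signatures = rng.dirichlet(np.ones(96) * 0.3, size=3).T
    # sparse exposures: each column dominated by one signature, as in real
    # signature attributions
    exposures = rng.dirichlet(np.ones(3) * 0.3, size=45).T
    expected = signatures @ exposures
    observed = rng.poisson(expected * 20_000) / 20_000.0
    return signatures, exposures, observed
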
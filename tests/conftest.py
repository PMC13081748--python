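import math

import numpy as np
import pytest

import silacflux as sf


@pytest.fixture(scope="session")
def full_design():
    return sf.make_design(3, include_inhibitors=True)


@pytest.fixture(scope="session")
def small_design():
    return sf.make_design(3, include_inhibitors=False)


@pytest.fixture(scope="session")
def steady_state_truths():
    """Noise-free-friendly panel: one-day half-life, flux-balanced synthesis."""
    rng = np.random.default_rng(2024)
    k = math.log(2.0) / 24.0
    truths = []
    for i in range(30):
        a0 = float(10.0 ** rng.normal(6.0, 0.4))
        truths.append(sf.SimulationTruth(f"P{i:03d}", a0, k, a0 * k, n_peptides=3))
    return truths


@pytest.fixture(scope="session")
def noise_free_report(steady_state_truths, small_design):
    return sf.simulate_report(
        steady_state_truths,
        small_design,
        noise_cv=0.0,
        mcar_rate=0.0,
        mnar_threshold=0.0,
        qvalue_fail_rate=0.0,
        charge1_rate=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def noisy_run(full_design):
    """One realistic simulated experiment shared across tests."""
    truths = sf.make_truths(
        100, seed=7, n_autophagy_substrates=15, n_proteasome_substrates=10, n_contaminants=4
    )
    report = sf.simulate_report(truths, full_design, seed=7)
    return truths, report
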
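import dataclasses

import pytest

from prsopt import (
    DesignSpec,
    aggregate_replicates,
    example_truths,
    fit_quadratic_surface,
    generate_viability_table,
)


@pytest.fixture(scope="session")
def truths():
    return example_truths()


@pytest.fixture(scope="session")
def panel(truths):
    return truths["tumor"].panel


@pytest.fixture(scope="session")
def spec(panel):
    return DesignSpec(agents=panel)


@pytest.fixture(scope="session")
def noiseless_agg(truths):
    truth = dataclasses.replace(truths["tumor"], noise_sd=0.0, bio_rep_sd=0.0)
    return aggregate_replicates(generate_viability_table(truth))


@pytest.fixture(scope="session")
def noisy_agg(truths):
    truth = dataclasses.replace(truths["tumor"], noise_sd=3.0, bio_rep_sd=1.0, seed=7)
    return aggregate_replicates(generate_viability_table(truth))


@pytest.fixture(scope="session")
def tumor_fit(noisy_agg, spec):
    return fit_quadratic_surface(noisy_agg, spec)
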
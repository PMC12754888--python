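import dataclasses

import pytest

from vaxdce.choice_simulation import SimulationConfig, generate_population, simulate_choices
from vaxdce.defaults import study_attributes
from vaxdce.io_cli import build_design


@pytest.fixture(scope="session")
def attrs():
    return study_attributes()


@pytest.fixture(scope="session")
def design(attrs):
    """A small-candidate-pool blocked design with trap, shared across tests."""
    return build_design(attrs, seed=0, n_candidates=3000)


@pytest.fixture(scope="session")
def attentive_config():
    """Correctly specified simulation: no inattention, no hesitancy shift on
    the opt-out, so the conditional logit with an ASC is the true model."""
    return SimulationConfig(
        n_respondents=500, seed=0, p_inattentive=0.0, hesitant_optout_shift=0.0
    )


def simulate(design, attrs, config, **overrides):
    cfg = dataclasses.replace(config, **overrides) if overrides else config
    pop = generate_population(cfg, n_blocks=design.n_blocks)
    return simulate_choices(pop, design, attrs, cfg)


@pytest.fixture(scope="session")
def small_dataset(design, attrs, attentive_config):
    return simulate(design, attrs, attentive_config, n_respondents=400, seed=7)
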
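import pytest

from saltscreen import (
    GenerationScenario,
    generate_cohort,
    stc_from_observations,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scenario synthetic cohort (57 accessions, seed 1)."""
    scenario = GenerationScenario(seed=1)
    obs, courses, truth = generate_cohort(scenario)
    return scenario, obs, courses, truth


@pytest.fixture(scope="session")
def default_stc(default_cohort):
    _, obs, _, _ = default_cohort
    return stc_from_observations(obs)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Noise-off cohort: sigma_e = 0, cv = 0, unit sensitivities.

    Every tolerance-linked trait's STC then equals tau exactly.
    """
    scenario = GenerationScenario(
        seed=7, sigma_e=0.0, cv_replicate=0.0, sensitivity_range=(1.0, 1.0)
    )
    obs, courses, truth = generate_cohort(scenario)
    return scenario, obs, courses, truth
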
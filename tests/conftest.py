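import pytest

from chromanchor.integrate import run_integration
from chromanchor.simulate import SimulationParams, simulate_genome

# One clean and one noisy simulated study, shared across the suite.
# 3 chromosomes x 2 Mb, ~60 scaffolds, ~300 SbfI markers.
CLEAN = SimulationParams(seed=7, chimera_rate=0.05, marker_noise_rate=0.0)
NOISY = SimulationParams(seed=7, chimera_rate=0.05, marker_noise_rate=0.05)


@pytest.fixture(scope="session")
def truth_clean():
    return simulate_genome(CLEAN)


@pytest.fixture(scope="session")
def result_clean(truth_clean):
    return run_integration(
        truth_clean.genetic_map,
        truth_clean.layout,
        truth_clean.alignments,
        truth_clean.scaffold_sequences,
        truth_clean.features,
    )


@pytest.fixture(scope="session")
def truth_noisy():
    return simulate_genome(NOISY)


@pytest.fixture(scope="session")
def result_noisy(truth_noisy):
    return run_integration(
        truth_noisy.genetic_map,
        truth_noisy.layout,
        truth_noisy.alignments,
        truth_noisy.scaffold_sequences,
        truth_noisy.features,
    )
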
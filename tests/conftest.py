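import numpy as np
import pytest

from rosaslocus.synthetic import PlantedGeneSpec, SimulationConfig, generate_genome


@pytest.fixture(scope="session")
def standard_specs():
    """A mixed bag of planted genes covering the screening criteria."""
    return [
        PlantedGeneSpec("g_pistil", (8.0, 10.0), "present_relaxed_Y", "present",
                        0, 600, "+", expression_class="pistil_ovary_high"),
        PlantedGeneSpec("g_stamen", (8.0, 10.0), "present_strict", "present",
                        0, 450, "-", expression_class="stamen_only"),
        PlantedGeneSpec("g_acidic", (4.5, 6.5), "absent", "present",
                        0, 600, "+", expression_class="broad"),
        PlantedGeneSpec("g_nomotif2", (8.0, 10.0), "present_strict", "absent",
                        0, 399, "+", expression_class="pistil_ovary_high"),
        PlantedGeneSpec("g_silent", (8.0, 10.0), "present_strict", "present",
                        0, 600, "-", expression_class="not_expressed"),
    ]


@pytest.fixture(scope="session")
def small_bundle(standard_specs):
    return generate_genome(standard_specs,
                           SimulationConfig(seed=42, genome_length_nt=60_000))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
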
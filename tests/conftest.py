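import pytest

from skempi2.synthetic import (GeneratorConfig, PlantedCycleSpec,
                               PLANTABLE_LABELS, generate_table,
                               generate_toy_complex)


@pytest.fixture(scope="session")
def default_table():
    """Default-condition synthetic table with one planted cycle per class."""
    cfg = GeneratorConfig(
        planted_cycles=tuple(PlantedCycleSpec(l) for l in PLANTABLE_LABELS)
        + tuple(PlantedCycleSpec(l, background=True)
                for l in PLANTABLE_LABELS))
    entries, truth = generate_table(cfg)
    return entries, truth


@pytest.fixture(scope="session")
def toy_complex():
    """Default toy two-slab complex and its ground truth."""
    return generate_toy_complex()
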
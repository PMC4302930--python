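import pytest

from derepressome import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study at the canonical seed, shared across tests."""
    config = SimulationConfig(seed=0)
    annotation, truth, counts, design, tags = simulate_study(config)
    return {
        "config": config,
        "annotation": annotation,
        "truth": truth,
        "counts": counts,
        "design": design,
        "tags": tags,
    }


@pytest.fixture(scope="session")
def small_config():
    """A reduced study for cheap structural tests."""
    return SimulationConfig(
        n_genes=300,
        n_targets_up=8,
        n_targets_down=2,
        n_unmarked_de=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    annotation, truth, counts, design, tags = simulate_study(small_config)
    return {
        "config": small_config,
        "annotation": annotation,
        "truth": truth,
        "counts": counts,
        "design": design,
        "tags": tags,
    }
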
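import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

from circsponge import SimulationConfig, generate_genome, plant_circrnas, simulate_study


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A fast small study: 6 samples, 2,000 reads each, default circle mix."""
    defaults = dict(seed=seed, n_samples=6, raw_reads_per_sample=2_000)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """One fully-simulated small study shared across tests (read-only)."""
    out = tmp_path_factory.mktemp("study")
    cfg = small_config()
    res = simulate_study(cfg, out)
    res["config"] = cfg
    res["dir"] = out
    return res


@pytest.fixture(scope="session")
def planted_genome():
    """Genome + planted truths without reads (cheap, session-scoped)."""
    cfg = small_config(seed=2)
    genome = generate_genome(cfg)
    truths = plant_circrnas(genome, cfg)
    return cfg, genome, truths
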
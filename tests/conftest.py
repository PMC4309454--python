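import numpy as np
import pytest

from gbsmap import genome, simpop


@pytest.fixture(scope="session")
def bean_genome():
    return genome.build_genome(genome.bean_preset(), seed=1)


@pytest.fixture(scope="session")
def small_genome():
    return genome.build_genome(genome.small_preset(), seed=1)


@pytest.fixture(scope="session")
def small_panel(small_genome):
    return genome.build_marker_panel(small_genome, n_markers=60, seed=2)


@pytest.fixture(scope="session")
def small_population(small_genome, small_panel):
    return simpop.simulate_rils(small_genome, small_panel, n_lines=30,
                                generations=11, seed=3)


def flat_genome(length_mb=10.0, rate=2.0, name="chr1"):
    cfg = {"chromosomes": [{"name": name, "length_mb": length_mb,
                            "base_rate": rate, "pericentromere": None,
                            "peri_rate": 0.0, "hotspots": []}]}
    return genome.build_genome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
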
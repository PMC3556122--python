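import numpy as np
import pytest

from metastable import repeats, simulate as sim

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def sim_config():
    return sim.SimConfig(seed=11)


@pytest.fixture(scope="session")
def planted(sim_config):
    """Seeded synthetic genome with planted clade-structured LTR insertions."""
    rng = np.random.default_rng(sim_config.seed)
    consensus = sim.make_consensus(sim_config, rng)
    genome, rmout, truth = sim.plant_elements(sim_config, consensus, rng)
    return consensus, genome, rmout, truth


@pytest.fixture(scope="session")
def catalog(planted, sim_config):
    """Parsed, filtered, extracted and paired element catalog."""
    _, genome, rmout, _ = planted
    annotations = repeats.parse_repeatmasker_out(rmout)
    kept = repeats.filter_subtype(annotations, sim_config.subtype).kept
    elements = repeats.build_catalog(genome, kept, flank=400)
    return repeats.pair_ltrs(elements), annotations
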
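import pytest

from rgenseq import fixtures
from rgenseq.cutsite_caller import CallerParams, call_cut_sites
from rgenseq.synthetic_data import SimConfig, generate_genome, plant_sites, simulate_library


@pytest.fixture(scope="session")
def standard_scenario():
    """1-Mb genome, 12 sites (0-6 mismatches), ~200k reads, end repair on."""
    return fixtures.standard_scenario(seed=11)


@pytest.fixture(scope="session")
def standard_calls(standard_scenario):
    return call_cut_sites(
        standard_scenario.track, standard_scenario.genome, standard_scenario.guide,
        CallerParams(),
    )


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """100-kb genome, 4 low-mismatch sites, with the SAM written to disk."""
    guide = fixtures._random_guide(5)
    genome = {"chr_sim": generate_genome(100_000, 0.45, 5)}
    genome, sites = plant_sites(
        genome, guide,
        [(0, "+", 8.0), (1, "-", 16.0), (2, "+", 32.0), (3, "-", 64.0)],
        seed=5,
    )
    cfg = SimConfig(genome_length=100_000, genome_copies=500, seed=9,
                    background_break_rate=1e-4)
    sam = tmp_path_factory.mktemp("sam") / "small.sam"
    sim = simulate_library(genome, sites, cfg, sam_path=sam)
    return fixtures.Scenario(genome, guide, sites, cfg, sim)
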
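import numpy as np
import pytest

import pseudoattb as pab
from pseudoattb.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def canonical():
    """The synthetic stand-in canonical attB/attP set used throughout."""
    return pab.synthetic_canonical_att()


@pytest.fixture(scope="session")
def small_sim(canonical):
    """A small simulated experiment: host, sites, plasmid, transformants."""
    cfg = SimConfig(seed=101, genome_length=50_000, n_sites=10,
                    n_transformants=25)
    host, sites = pab.generate_host(cfg, canonical)
    plasmid, p_core0 = pab.make_plasmid(cfg, canonical)
    transformants = pab.simulate_transformants(host, sites, plasmid, p_core0,
                                               cfg, canonical)
    return {"config": cfg, "host": host, "sites": sites, "plasmid": plasmid,
            "plasmid_core0": p_core0, "transformants": transformants}


@pytest.fixture(scope="session")
def benchmark_sim(canonical):
    """The larger detection benchmark: 100 transformants over 10 sites."""
    cfg = SimConfig(seed=202, genome_length=50_000, n_sites=10,
                    n_transformants=100)
    host, sites = pab.generate_host(cfg, canonical)
    plasmid, p_core0 = pab.make_plasmid(cfg, canonical)
    transformants = pab.simulate_transformants(host, sites, plasmid, p_core0,
                                               cfg, canonical)
    return {"config": cfg, "host": host, "sites": sites, "plasmid": plasmid,
            "plasmid_core0": p_core0, "transformants": transformants}


@pytest.fixture(scope="session")
def benchmark_events(benchmark_sim):
    """All insertion events detected in the benchmark, in one indexing pass."""
    contigs = [t.genome for t in benchmark_sim["transformants"]]
    return pab.find_insertions(contigs, benchmark_sim["host"],
                               benchmark_sim["plasmid"].sequence)


@pytest.fixture(scope="session")
def observed_counts():
    """The published per-site event counts (multiplicities 4,4,2,2 + 15 singletons)."""
    return tuple(pab.datasets.nocardia_terpenica_sites()["events"])
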
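import numpy as np
import pytest
from hypothesis import settings

from propagule import coalsim as cs
from propagule import demography as dg

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_small():
    """Baseline scenario on a reduced one-chromosome genome (2 Mb)."""
    layout = dg.GenomeLayout.reduced(1, 2_000_000)
    return dg.build_baseline(layout=layout)


@pytest.fixture(scope="session")
def small_panel(baseline_small):
    """Simulated two-deme panel: 11 island + 4 mainland haplotypes, 2 Mb."""
    return cs.simulate_genome(baseline_small, 11, 4, seed=5)


@pytest.fixture(scope="session")
def const_layout():
    """One 2-Mb chromosome at map-scale recombination (outcrossing 1)."""
    return dg.GenomeLayout(
        (dg.Chromosome("1", 2_000_000, 7.1e-9, 3.6e-8),), outcrossing=1.0
    )


@pytest.fixture(scope="session")
def const_scenario(const_layout):
    """Constant Ne = 30 K in both demes (the island carrying capacity)."""
    return dg.build_baseline(layout=const_layout).replace(
        island=dg.NeTrajectory.constant(30_000),
        mainland=dg.NeTrajectory.constant(30_000),
    )


@pytest.fixture(scope="session")
def const_panel(const_scenario):
    """Neutral constant-Ne panel with well-mixed linkage (clean SFS)."""
    return cs.simulate_genome(const_scenario, 11, 2, seed=9)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
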
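import pytest

from fbscan import SimulationConfig, simulate, tiny_config
from fbscan.core import build_mps, rank_mps
from fbscan.fbs import call_fbs


@pytest.fixture(scope="session")
def tiny_ds():
    """Sub-second synthetic compendium for unit tests."""
    return simulate(tiny_config(seed=1))


@pytest.fixture(scope="session")
def default_ds():
    """The default-scale synthetic compendium (200 focal sites, 50 TFs,
    2 Mb) used for parameter-recovery checks."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_call(default_ds):
    """Full caller run on the default compendium at four percentiles."""
    mps = rank_mps(build_mps(default_ds.peaksets,
                             chrom_sizes=default_ds.chrom_sizes))
    return mps, call_fbs(mps, pcts=(85, 90, 95, 98))
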
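import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from akashikit.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A written 40-gene synthetic bundle with every side file."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(
        seed=11, n_genes=40, len_min=150, len_max=210, domain_gc3_shift=0.05
    )
    bundle = simulate(cfg, outdir)
    return cfg, bundle, outdir


@pytest.fixture(scope="session")
def memory_bundle():
    """A small in-memory bundle without file I/O."""
    cfg = SimulationConfig(seed=5, n_genes=25, len_min=120, len_max=150)
    return cfg, simulate(cfg)
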
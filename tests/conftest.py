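import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from magenes import synth_fixtures as sf


@pytest.fixture(scope="session")
def ancestors():
    return sf.make_ancestors(seed=7)


@pytest.fixture(scope="session")
def benchmark():
    """The fixed-seed curation benchmark: 40 planted genes, 40 decoys."""
    return sf.make_curation_benchmark(seed=42)


@pytest.fixture(scope="session")
def benchmark_readthrough(benchmark):
    return sf.run_curation_benchmark(benchmark, mode="readthrough")


@pytest.fixture(scope="session")
def benchmark_standard(benchmark):
    return sf.run_curation_benchmark(benchmark, mode="standard")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
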
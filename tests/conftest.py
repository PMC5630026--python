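import numpy as np
import pandas as pd
import pytest

from crevol import CountMatrix, SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_cres=60, n_genes=40, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture(scope="session")
def small_chip(small_bundle) -> CountMatrix:
    b = small_bundle
    return CountMatrix(b.chip_counts, b.metadata.loc[b.chip_counts.columns])


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_config):
    from crevol import write_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(small_config, out)
    return out
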
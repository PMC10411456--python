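from importlib import resources

import numpy as np
import pytest

from milkswap import (
    default_config,
    load_default_references,
    read_composition_table,
)
from milkswap.calibrate import TABLE_12_35_BASELINE, calibrate_to_baseline


def bundled_composition_path():
    return resources.files("milkswap.data").joinpath("composition_illustrative.csv")


@pytest.fixture(scope="session")
def table():
    with resources.as_file(bundled_composition_path()) as p:
        return read_composition_table(p)


@pytest.fixture(scope="session")
def refs():
    return load_default_references()


@pytest.fixture(scope="session")
def calibrated_config(table, refs):
    """Generator config calibrated to the published 12–35 m baseline rows."""
    return calibrate_to_baseline(
        TABLE_12_35_BASELINE, default_config(seed=2026), table, refs
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
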
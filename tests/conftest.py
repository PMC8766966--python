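from pathlib import Path

import pandas as pd
import pytest

from salitdm import GeneratorConfig, default_design

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def reference_metrics():
    """Validation metrics reported for the original salivary panel assay."""
    return pd.read_csv(DATA_DIR / "reference_validation_metrics.csv")


@pytest.fixture(scope="session")
def default_cfg(design):
    return GeneratorConfig.default(design, seed=7)
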
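from pathlib import Path

import pandas as pd
import pytest

import tempomod as tm

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def small_config() -> tm.SynthConfig:
    """Compact study: three planted modules of 30 features, default noise."""
    return tm.SynthConfig(
        n_genes=150,
        n_regions=150,
        planted_modules=[("early", 30, 2.0), ("late", 30, 2.0), ("CPN", 30, 2.0)],
        genome_length=600_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> tm.SyntheticStudy:
    return tm.generate_all(small_config)


@pytest.fixture(scope="session")
def condition_meta(small_study) -> pd.DataFrame:
    return small_study.dataset.expression.conditions
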
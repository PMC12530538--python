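import numpy as np
import pandas as pd
import pytest

import morphspec as ms

GRID = np.arange(300.0, 701.0)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: raw replicate dataset + metadata."""
    cfg = ms.default_study_config(seed=7)
    return ms.generate_dataset(cfg)


@pytest.fixture(scope="session")
def processed(study):
    ds, meta = study
    return ms.process_dataset(ds, meta), meta


@pytest.fixture(scope="session")
def lizard():
    return ms.builtin_visual_system("lizard")


@pytest.fixture(scope="session")
def d65():
    return ms.load_illuminant("d65")


def make_dataset(columns: dict, grid=None) -> ms.SpectralDataset:
    g = GRID if grid is None else np.asarray(grid, dtype=float)
    return ms.SpectralDataset(g, pd.DataFrame(columns))


@pytest.fixture()
def flat_illuminant():
    return ms.Illuminant("flat", GRID, np.ones_like(GRID), units="quanta")
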
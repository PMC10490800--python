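import warnings

import numpy as np
import pytest

from pellspec import synthetic
from pellspec.core import ReferenceTable, SpectraSet, WavelengthGrid, default_grid

warnings.filterwarnings("ignore", message=".*y residual is constant.*")


@pytest.fixture(scope="session")
def grid256() -> WavelengthGrid:
    return default_grid()


@pytest.fixture()
def small_set() -> SpectraSet:
    rng = np.random.default_rng(0)
    grid = WavelengthGrid(np.linspace(1000.0, 1090.0, 10))
    return SpectraSet(rng.uniform(0.2, 0.8, (6, 10)), grid, [f"A{i}" for i in range(6)])


@pytest.fixture(scope="session")
def nir_dataset(grid256):
    """Default-condition synthetic cohort: 144 samples on the 256-band grid."""
    cfg = synthetic.SimulationConfig()
    refs = synthetic.generate_reference_values(
        cfg.n_samples, cfg.moisture_range, cfg.other_fraction, seed=cfg.seed
    )
    spectra, truth = synthetic.generate_spectra(refs, grid256, cfg)
    return spectra, refs, truth, cfg
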
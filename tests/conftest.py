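import numpy as np
import pandas as pd
import pytest

from libspec import io_core, preprocess, synthgen


@pytest.fixture(scope="session")
def fixture_config():
    """The reduced separable survey design used across end-to-end tests."""
    return synthgen.acceptance_fixture_config(seed=1)


@pytest.fixture(scope="session")
def small_dataset(fixture_config):
    return synthgen.generate_dataset(fixture_config)


@pytest.fixture(scope="session")
def underground(small_dataset):
    return small_dataset.select_part("underground")


@pytest.fixture(scope="session")
def underground_normalized(underground):
    return preprocess.normalize_set(underground)


def make_set(intensities, origins=None, parts=None, wavelengths=None, tablets=None):
    """Hand-rolled SpectrumSet for unit tests."""
    intensities = np.asarray(intensities, dtype=float)
    n, v = intensities.shape
    if wavelengths is None:
        wavelengths = np.linspace(229.0, 878.0, v)
    origins = [1] * n if origins is None else list(origins)
    parts = ["underground"] * n if parts is None else list(parts)
    tablets = [f"T{i}" for i in range(n)] if tablets is None else list(tablets)
    meta = pd.DataFrame(
        {
            "origin": origins,
            "plant_id": [f"P{i}" for i in range(n)],
            "tablet_id": tablets,
            "part": parts,
            "position": [1] * n,
        }
    )
    return io_core.SpectrumSet(
        axis=io_core.WavelengthAxis(wavelengths), meta=meta, intensities=intensities
    )
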
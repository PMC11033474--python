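import numpy as np
import pandas as pd
import pytest

from ramanid import (SpectrumSet, SyntheticConfig, default_profiles,
                     generate_ramanome, preprocess_set)


def make_set(intensities, axis=None, species=None):
    """Small hand-built SpectrumSet with auto-generated labels."""
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    n, p = intensities.shape
    axis = np.arange(p, dtype=float) if axis is None else np.asarray(axis)
    species = species or ["A"] * n
    labels = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "species": species,
        "replicate": ["r1"] * n,
    })
    return SpectrumSet(axis, intensities, labels)


@pytest.fixture
def small_set():
    """3 cells x 5 wavenumbers, two species."""
    return make_set([[1, 2, 3, 2, 1],
                     [2, 4, 6, 4, 2],
                     [1, 1, 5, 1, 1]],
                    axis=[600, 700, 800, 900, 1000],
                    species=["A", "A", "B"])


def tiny_config(n_species=3, cells=8, seed=0, **kw):
    """Reduced generator config for fast classifier tests.

    Three well-separated species, one replicate, a coarse 4 cm^-1 grid.
    """
    profiles = default_profiles()
    picked = [profiles[i] for i in (0, 7, 8)][:n_species]
    defaults = dict(profiles=picked, n_replicates=1, cells_per_replicate=cells,
                    axis_step=4.0, seed=seed)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


@pytest.fixture
def tiny_ramanome():
    """3 separated species x 8 cells on a coarse axis, preprocessed."""
    return preprocess_set(generate_ramanome(tiny_config()))


@pytest.fixture(scope="session")
def bench_raw():
    """The default-condition benchmark Ramanome (9 species x 3 x 60)."""
    return generate_ramanome(SyntheticConfig(seed=20240408))


@pytest.fixture(scope="session")
def bench_set(bench_raw):
    return preprocess_set(bench_raw)
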
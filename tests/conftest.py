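import numpy as np
import pytest

from poriascreen.spectra import SpectraSet
from poriascreen.synth import (
    PeakTableConfig,
    SynthConfig,
    generate_peak_table,
    generate_spectra,
)


@pytest.fixture(scope="session")
def small_spectra() -> SpectraSet:
    """24 samples (2 parts x 4 regions, 3 replicates) on a short grid."""
    cfg = SynthConfig(
        n_per_part=12, n_regions=4, grid_start=10_000, grid_end=4_000,
        grid_step=40, seed=11,
    )
    return generate_spectra(cfg)


@pytest.fixture(scope="session")
def clean_spectra() -> SpectraSet:
    """Noise-free spectra: only part and region structure."""
    cfg = SynthConfig(
        n_per_part=12, n_regions=4, grid_step=40, noise_sd=0.0,
        baseline_drift_sd=0.0, scatter_sd=0.0, seed=7,
    )
    return generate_spectra(cfg)


@pytest.fixture(scope="session")
def default_peak_table():
    return generate_peak_table(PeakTableConfig(seed=5), 100)


def toy_set(absorbance, wavenumbers=None, **kw):
    """Minimal single-part SpectraSet around an absorbance matrix."""
    A = np.atleast_2d(np.asarray(absorbance, dtype=float))
    n, p = A.shape
    wn = np.arange(p, 0, -1, dtype=float) if wavenumbers is None else wavenumbers
    defaults = dict(
        part_label=np.array(["Poria"] * n, dtype=object),
        region_label=np.ones(n, dtype=int),
        sample_id=np.array([f"s{i}" for i in range(n)], dtype=object),
        replicate_id=np.ones(n, dtype=int),
    )
    defaults.update(kw)
    return SpectraSet(wavenumbers=wn, absorbance=A, **defaults)
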
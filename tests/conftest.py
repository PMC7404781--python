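import numpy as np
import pytest

from specocc.dataset import SampleMeta, SpectrumSet
from specocc.preprocess import snv
from specocc.synthetic import generate_study, preset_design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_set(intensities, wavenumbers=None, **meta_overrides):
    """Small SpectrumSet with default metadata."""
    intensities = np.atleast_2d(np.asarray(intensities, float))
    n, p = intensities.shape
    if wavenumbers is None:
        wavenumbers = np.arange(p, dtype=float)
    meta = [
        SampleMeta(sample_id=f"s{i}", **meta_overrides) for i in range(n)
    ]
    return SpectrumSet(wavenumbers, intensities, meta)


@pytest.fixture
def small_set(rng):
    return make_set(rng.standard_normal((10, 50)))


@pytest.fixture(scope="session")
def separable_study():
    """One realization of the default separable study (seed 1), SNV-treated."""
    design = preset_design("separable", seed=1)
    study = generate_study(design)
    return {name: snv(sset) for name, sset in study.items()} | {"design": design}
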
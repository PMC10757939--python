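import numpy as np
import pytest

from samhs import ExcitabilityField, NoiseModel, SubjectPhantom


@pytest.fixture
def default_phantom():
    return SubjectPhantom()


@pytest.fixture
def quiet_phantom():
    """Noise-free phantom: deterministic amplitudes, silent baseline."""
    return SubjectPhantom(
        noise=NoiseModel(amp_cv=0.0, baseline_rms=0.0),
        latency_sd=0.0,
    )


def make_phantom(center_offset=(0.0, 0.0, 0.0), amp_cv=0.3, baseline_rms=5.0, **kw):
    from samhs.phantom import FDI_MNI_MM

    return SubjectPhantom(
        field=ExcitabilityField(hotspot_center=FDI_MNI_MM + np.asarray(center_offset, float)),
        noise=NoiseModel(amp_cv=amp_cv, baseline_rms=baseline_rms),
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
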
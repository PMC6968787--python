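import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from cciqeeg.preprocess import extract_epochs
from cciqeeg.synth import RegimeParams, generate_recording, strain_presets

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ppks_recording():
    """One deterministic PPKS-preset recording shared across tests."""
    spec = dataclasses.replace(strain_presets()["PPKS"], seed=20240117)
    return generate_recording(spec)


@pytest.fixture(scope="session")
def ppks_epochs(ppks_recording):
    return extract_epochs(ppks_recording)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_regime(**kwargs) -> RegimeParams:
    """RegimeParams with uniform defaults, overridable per test."""
    base = dict(
        psd_exponent=1.0,
        band_gains={b: 1.0 for b in ("delta", "theta", "alpha", "beta")},
        shared_fraction={b: 0.5 for b in ("delta", "theta", "alpha", "beta")},
        am_depth=0.0,
        spike_rate=0.0,
        spike_amp=8.0,
        rms=50.0,
    )
    base.update(kwargs)
    return RegimeParams(**base)
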
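import warnings

import numpy as np
import pytest

import ebfkit as ek


@pytest.fixture(scope="session")
def default_coeffs():
    return ek.EBFCoefficients.default()


@pytest.fixture(scope="session")
def preset_names():
    return ek.available_presets()


@pytest.fixture(scope="session")
def noise_free_observations(preset_names):
    """Observation sets extracted from noise-free synthetic curve pairs over
    the full interface-depth schedules of all four beam classes."""
    obs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for name in preset_names:
            cfg = ek.SyntheticConfig(preset=name, noise_relative_sd=0.0)
            obs.extend(ek.synth_observation_set(cfg))
    return obs


@pytest.fixture(scope="session")
def interface_grid_observations(default_coeffs):
    """60 noise-free interface observations spanning the validated range."""
    em = np.linspace(0.2, 14.0, 60)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return [
            ek.BackscatterObservation(float(e), 0.0, float(ek.ebf_at_interface(e, default_coeffs)), True)
            for e in em
        ]
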
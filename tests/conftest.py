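import numpy as np
import pytest

from nirsaware import (
    EpochSet,
    GroundTruth,
    ParadigmSpec,
    State,
    default_montage,
    forward_to_intensity,
    simulate_concentrations,
)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def default_spec():
    return ParadigmSpec()


@pytest.fixture(scope="session")
def quiet_truth():
    """All noise sources off: the forward model is exactly invertible."""
    return GroundTruth(mayer_amp=0.0, cardiac_amp=0.0, drift_slope=0.0,
                       white_noise_sd=0.0, intensity_noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def quiet_run(default_spec, montage, quiet_truth):
    """Noise-free responsive run: concentrations and raw intensities."""
    conc = simulate_concentrations(default_spec, montage, quiet_truth)
    rec = forward_to_intensity(conc, montage, quiet_truth)
    return rec, conc


def make_synthetic_epochs(n_trials=40, n_channels=4, n_samples=20,
                          effect=0.0, seed=0, chromophore="HBO"):
    """Small Gaussian epoch set with an optional class-mean offset.

    Class labels alternate; with ``effect`` = 0 the two classes are
    exchangeable (a pure-noise null).
    """
    rng = np.random.default_rng(seed)
    labels = np.array(["IMAGERY", "NO_IMAGERY"] * (n_trials // 2))
    data = rng.normal(size=(n_trials, n_channels, n_samples))
    if effect:
        pattern = rng.normal(size=(n_channels, 1))
        bump = np.sin(np.linspace(0, np.pi, n_samples))
        data[labels == "IMAGERY"] += effect * pattern * bump
    return EpochSet(data=data, labels=labels, chromophore=chromophore,
                    sampling_rate=6.94)


@pytest.fixture
def synthetic_epochs():
    return make_synthetic_epochs


def random_spd(rng, d, scale=1.0):
    a = rng.normal(size=(d, d))
    m = a @ a.T + d * np.eye(d)
    return scale * m


@pytest.fixture
def spd_factory():
    return random_spd
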
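import numpy as np
import pytest

from hrident.excitation import (
    SpeedProfile,
    build_speed_profile,
    default_prbs_spec,
    generate_prbs_bits,
    select_balanced_window,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def prbs_spec():
    """The study excitation about a 2.0 m/s operating point."""
    return default_prbs_spec(mean_speed=2.0)


@pytest.fixture(scope="session")
def speed_profile_1hz(prbs_spec):
    """36-min formal-measurement speed profile at 1 Hz."""
    bits = generate_prbs_bits(prbs_spec, 36)
    return build_speed_profile(bits, prbs_spec, sample_period=1.0, duration=2160.0)


@pytest.fixture(scope="session")
def speed_profile_5s(speed_profile_1hz):
    """The same profile on the 0.2-Hz analysis grid."""
    v = speed_profile_1hz.speeds.reshape(-1, 5).mean(axis=1)
    return SpeedProfile(
        sample_times=speed_profile_1hz.sample_times[::5],
        speeds=v,
        mean_speed=speed_profile_1hz.mean_speed,
    )


@pytest.fixture(scope="session")
def balanced_window(speed_profile_5s):
    return select_balanced_window(speed_profile_5s, 360, 290.0)


@pytest.fixture(scope="session")
def prbs_input_deviation(speed_profile_5s, balanced_window):
    """Mean-removed input on the balanced evaluation window (±0.25 m/s)."""
    from hrident.preprocessing import extract_window, remove_mean_input

    return remove_mean_input(extract_window(speed_profile_5s, balanced_window))
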
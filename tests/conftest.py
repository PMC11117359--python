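import numpy as np
import pandas as pd
import pytest

from camtrapniche.simulate import SyntheticConfig, simulate_survey


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_survey():
    """A compact synthetic survey (10 cameras, one winter season)."""
    cfg = SyntheticConfig(n_cameras=10, n_days=90, seed=5)
    return simulate_survey(cfg)


@pytest.fixture()
def flat_calendar():
    """Equinox-like calendar: sunrise 06:00, sunset 18:00 in every month."""
    return pd.DataFrame(
        {"month": range(1, 13), "sunrise": [6.0] * 12, "sunset": [18.0] * 12}
    )
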
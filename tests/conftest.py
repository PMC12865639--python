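import numpy as np
import pytest

import surromet as sm


@pytest.fixture(scope="session")
def paperlike() -> sm.TrialSet:
    """18-trial synthetic set shaped like the published characteristics table."""
    return sm.paperlike_fixture(7)


@pytest.fixture(scope="session")
def synth15() -> tuple[sm.TrialSet, sm.SyntheticTruth]:
    """Default 15-trial synthetic set with its latent truth."""
    return sm.generate_trials(sm.SyntheticConfig(seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def log_hr_arrays(trials: sm.TrialSet, x_field: str = "hr_pfs2", y_field: str = "hr_os_initial"):
    """(x, y, w) arrays for trials reporting both endpoints, in trial_id order."""
    recs = sorted(
        (r for r in trials if getattr(r, x_field) is not None and getattr(r, y_field) is not None),
        key=lambda r: r.trial_id,
    )
    x = np.array([getattr(r, x_field).log_hr for r in recs])
    y = np.array([getattr(r, y_field).log_hr for r in recs])
    w = np.array([float(r.total_n) for r in recs])
    return x, y, w
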
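import numpy as np
import pytest

from rsfi.synthetic_data import SyntheticParams, make_panel


def sinusoid_panel(offsets, n_time=300, periods=1.0, harmonics=((1.0, 1.0),)):
    """Noise-free rows cos(k*theta - delta) sampled over whole periods."""
    offsets = np.asarray(offsets, dtype=float)
    theta = 2.0 * np.pi * periods * np.linspace(0, 1, n_time, endpoint=False)
    X = np.zeros((len(offsets), n_time))
    for mult, amp in harmonics:
        X += amp * np.cos(mult * theta[None, :] - mult * offsets[:, None])
    return X


@pytest.fixture(scope="session")
def small_panel():
    """8 ROIs, 6 subjects, 2 visits: quick but fully featured."""
    params = SyntheticParams(
        n_subjects=6, n_rois=8, n_time=150, signature_strength=0.5, seed=42
    )
    return params, make_panel(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
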
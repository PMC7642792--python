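import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mfscres as m

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

N = 64


@pytest.fixture(scope="session")
def stationary_pair():
    """Full-support random-field phantom + half-maps with a known FSC profile.

    The target curve is a logistic falloff crossing 0.5 at shell 16 and the
    t = 0.143 level near shell 20.5.
    """
    ks = np.arange(1, N // 2 + 1)
    phi = 1.0 / (1.0 + np.exp((ks - 16) / 2.5))
    phantom = m.make_phantom(N, "shell-limited", seed=11, k1=N // 2)
    u, v = m.make_half_pair(phantom, m.ssnr_from_fsc(phi), seed=12)
    return u, v, phi


@pytest.fixture(scope="session")
def generous_sphere():
    return m.make_mask(N, "sphere", diameter=0.7 * N)


@pytest.fixture(scope="session")
def noise_pair_with_blob_mask():
    """Half-maps with no shared structure (solvent background only) and the
    tight binary support mask of the blob phantom they were grown around."""
    phantom = m.make_phantom(N, "blob-ensemble", seed=21)
    u, v = m.make_half_pair(
        phantom, np.zeros(N // 2), seed=22, background=1.0
    )
    mask = m.make_mask(N, "blob-support", phantom=phantom)
    return u, v, mask
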
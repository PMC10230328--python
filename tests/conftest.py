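import numpy as np
import pytest

from elastohydro.assembly import Assembly, Attachment, Filament, Structure
from elastohydro.assembly import build_spherical_body


@pytest.fixture
def rng():
    return np.random.default_rng(20230021)


@pytest.fixture
def free_filament():
    """Small free filament (N=5, n=2) with a non-trivial random state."""
    fil = Filament(N=5, n=2)
    asm = Assembly([Structure(attachments=[Attachment(fil)])])
    state = np.random.default_rng(7).normal(size=asm.state_size) * 0.3
    return fil, asm, state


@pytest.fixture
def body_with_filament():
    """Spherical body with one clamped filament, random mild state."""
    body = build_spherical_body(0.3, 12)
    fil = Filament(N=4, n=1)
    st = Structure(body=body, attachments=[Attachment(fil, offset=[0, 0, 0.3])])
    asm = Assembly([st])
    state = np.random.default_rng(11).normal(size=asm.state_size) * 0.25
    return fil, asm, state


def semicircle_state(assembly, N):
    """Generators r_i = (theta_i/2) y_hat: unit-length semicircular arc."""
    state = np.zeros(assembly.state_size)
    theta = np.arange(N) * np.pi / (N - 1)
    for i in range(N):
        r = 0.5 * theta[i] * np.array([0.0, 1.0, 0.0])
        if i == 0:
            state[3:6] = r
        else:
            state[6 + 3 * (i - 1) : 9 + 3 * (i - 1)] = r
    return state
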
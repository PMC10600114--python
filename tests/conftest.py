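"""Shared fixtures and the independent adaptive-ODE reference simulator.

The reference implementation below integrates the same piecewise-constant
Bloch-McConnell model with scipy's adaptive RK45 at tight tolerances and is
deliberately independent of the package's matrix-exponential propagation
path (it shares only the matrix assembly, which is itself unit-tested
against closed forms and equilibrium identities).
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cestgen import (
    Pool,
    TissueSystem,
    build_generator,
    two_pool,
    water_only,
)
from cestgen.sequences import pulse_envelope


def integrate_reference(system, protocol, rtol=1e-10, atol=1e-12):
    """End-to-end adaptive-step reference trajectory for a protocol."""

    def run(a, b, m, dt):
        if dt <= 0:
            return m
        sol = solve_ivp(lambda t, y: a @ y + b, (0.0, dt), m,
                        rtol=rtol, atol=atol, method="RK45")
        return sol.y[:, -1]

    m = system.equilibrium()
    signals = []
    for el in protocol.elements:
        a0, b0 = build_generator(system, 0.0, el.offset_ppm, protocol.b0_t)
        m = run(a0, b0, m, el.trec_s)
        env = pulse_envelope(el.pulse.shape, el.pulse.n_segments)
        seg_dt = el.pulse.tp_s / el.pulse.n_segments
        for pulse_idx in range(el.n_p):
            if pulse_idx > 0:
                m = run(a0, b0, m, el.gap_s)
            for amp in env:
                a1, b1 = build_generator(
                    system, el.pulse.b1_ut * amp, el.offset_ppm, protocol.b0_t
                )
                m = run(a1, b1, m, seg_dt)
        fa = np.deg2rad(el.fa_deg)
        signals.append(np.sin(fa) * abs(m[2]))
        m[0] = 0.0
        m[1] = 0.0
        m[2] *= np.cos(fa)
    return np.asarray(signals)


def random_system(rng, n_solutes=None, semisolid=False):
    """A random physically plausible tissue system."""
    if n_solutes is None:
        n_solutes = int(rng.integers(0, 3))
    water = Pool("water", rng.uniform(1.3, 3.4), rng.uniform(0.04, 1.2))
    solutes = tuple(
        Pool(
            f"s{i}",
            rng.uniform(1.3, 3.4),
            rng.uniform(1e-3, 0.04),
            rng.uniform(2e-4, 0.05),
            rng.uniform(5, 1500),
            rng.uniform(-3.5, 4.3),
        )
        for i in range(n_solutes)
    )
    ss = None
    if semisolid:
        ss = Pool("mt", rng.uniform(0.8, 1.6), rng.uniform(4e-5, 1e-4),
                  rng.uniform(0.02, 0.2), rng.uniform(10, 60), -2.4,
                  "super-lorentzian")
    return TissueSystem(water, solutes, ss)


@pytest.fixture(scope="session")
def amine_system():
    """The worked two-pool amine example system."""
    return two_pool(2.5, 0.8, 2.5, 0.04, 0.003, 500.0, 3.0, name="solute")


@pytest.fixture(scope="session")
def water_system():
    return water_only(2.5, 0.8)
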
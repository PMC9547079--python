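import numpy as np
import pytest

import qubode as qb


@pytest.fixture(scope="session")
def scheme615() -> qb.FixedPointScheme:
    return qb.FixedPointScheme(6, 15)


@pytest.fixture(scope="session")
def morse_params() -> qb.MorseParameters:
    return qb.MorseParameters()


@pytest.fixture(scope="session")
def morse_system(morse_params):
    return qb.make_system(morse_params)


@pytest.fixture(scope="session")
def harmonic_system():
    """Unit harmonic oscillator dr/dt = p, dp/dt = -r (mu = k = omega = 1)."""
    return qb.ODESystemSpec(
        n=2,
        rhs=lambda x, y: np.array([y[1], -y[0]]),
        jac=lambda x, y: np.array([[0.0, 1.0], [-1.0, 0.0]]),
        labels=["r", "p"],
        name="harmonic",
    )


@pytest.fixture(scope="session")
def harmonic_reference():
    """Closed form for the unit oscillator started at (r0, p0)."""

    def ref(times, r0=1.0, p0=0.0):
        amp = np.hypot(r0, p0)
        phi = np.arctan2(-p0, r0)
        return np.column_stack(
            [amp * np.cos(times + phi), -amp * np.sin(times + phi)]
        )

    return ref


def euler_cell_qubo(scheme, force=0.0146, dx=0.4, y0=0.0):
    """Single-unknown one-step cell: dy/dx = const, the simplest QUBO."""
    seg = qb.LinearSegment(x=[0.0], const=[[force]], lin=[[[0.0]]])
    qp = qb.build_qp(seg, dx, [y0])
    return qp, qb.qp_to_qubo(qp, scheme)
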
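"""Classical vibration of a Morse diatomic (H2 defaults) in atomic units.

The bond obeys Hamilton's equations

    dr/dt = p / mu,        dp/dt = F(r) = -dV/dr,

with the Morse potential V(r) = De * (1 - exp(-a (r - re)))^2.  Total energy
E = p^2/(2 mu) + V(r) below the dissociation energy De gives bound (periodic)
vibration; above it the bond breaks and r grows without bound after the inner
bounce.

The default parameters model H2: De = 0.17449 Hartree, a = 1.02764 1/Bohr,
re = 1.40201 Bohr, mu = 918.076 electron masses (half the proton mass).  With
these, the harmonic period at the well bottom is ~313.6 a.u., so a 400 a.u.
window covers about 1.25 ground-state vibrational periods; starting from a
compressed bond at r0 = 0.90 Bohr puts the energy near half of De, and
r0 = 0.70 Bohr lies above the dissociation threshold.

For bound energies the trajectory has a closed form.  Writing eps = E/De,
omega0 = a*sqrt(2 De/mu) and omega_b = omega0*sqrt(1 - eps),

    r(t) = re + (1/a) * ln[ (1 - sqrt(eps) cos(omega_b t + phi)) / (1 - eps) ]
    p(t) = mu * omega_b * sqrt(eps) * sin(omega_b t + phi)
           / ( a * (1 - sqrt(eps) cos(omega_b t + phi)) )

with the phase phi fixed by (r0, p0); substitution shows E is conserved
identically.  Unbound energies use adaptive high-accuracy integration
(rtol = 1e-12) instead; the two routes agree to ~1e-8 where both apply,
which the test suite verifies.

All computation is in Hartree atomic units; :func:`convert_units` translates
at the boundaries (1 a.u. of time ~ 24.19 attoseconds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .propagator import ODESystemSpec

__all__ = [
    "MorseParameters",
    "PhaseState",
    "morse_potential",
    "morse_force",
    "morse_force_derivative",
    "hamilton_rhs",
    "hamilton_jacobian",
    "make_system",
    "total_energy",
    "reference_trajectory",
    "vibrational_period",
    "momentum_scale",
    "convert_units",
    "AU_TIME_FS",
    "HARTREE_EV",
    "BOHR_ANGSTROM",
]

AU_TIME_FS = 2.4188843265e-2       # one atomic time unit in femtoseconds
HARTREE_EV = 27.211386245988
BOHR_ANGSTROM = 0.529177210903


@dataclass(frozen=True)
class MorseParameters:
    """Morse well: dissociation energy, range, equilibrium length, mass.

    Units: Hartree, 1/Bohr, Bohr, electron masses.
    """

    d_e: float = 0.17449
    a: float = 1.02764
    r_e: float = 1.40201
    mu: float = 918.076

    def __post_init__(self) -> None:
        for name in ("d_e", "a", "r_e", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PhaseState:
    """One phase-space point of the bond: (r [Bohr], p [a.u.], t [a.u.])."""

    r: float
    p: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"bond length must be positive, got {self.r}")


def _check_r(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond length must be positive")
    return r


def morse_potential(r, params: MorseParameters):
    """V(r) = De (1 - exp(-a (r - re)))^2, zero at the minimum."""
    r = _check_r(r)
    u = np.exp(-params.a * (r - params.r_e))
    out = params.d_e * (1.0 - u) ** 2
    return float(out) if out.ndim == 0 else out


def morse_force(r, params: MorseParameters):
    """F(r) = -dV/dr = -2 a De (1 - exp(-a(r-re))) exp(-a(r-re))."""
    r = _check_r(r)
    u = np.exp(-params.a * (r - params.r_e))
    out = -2.0 * params.a * params.d_e * (1.0 - u) * u
    return float(out) if out.ndim == 0 else out


def morse_force_derivative(r, params: MorseParameters):
    """dF/dr = 2 a^2 De exp(-a(r-re)) (1 - 2 exp(-a(r-re)))."""
    r = _check_r(r)
    u = np.exp(-params.a * (r - params.r_e))
    out = 2.0 * params.a**2 * params.d_e * u * (1.0 - 2.0 * u)
    return float(out) if out.ndim == 0 else out


def hamilton_rhs(state: PhaseState, params: MorseParameters) -> tuple[float, float]:
    """(dr/dt, dp/dt) = (p/mu, F(r))."""
    return state.p / params.mu, morse_force(state.r, params)


def hamilton_jacobian(state: PhaseState, params: MorseParameters) -> np.ndarray:
    """Jacobian of the flow: [[0, 1/mu], [F'(r), 0]]."""
    return np.array(
        [
            [0.0, 1.0 / params.mu],
            [morse_force_derivative(state.r, params), 0.0],
        ]
    )


def total_energy(r: float, p: float, params: MorseParameters) -> float:
    """E = p^2/(2 mu) + V(r) in Hartree."""
    return p * p / (2.0 * params.mu) + morse_potential(r, params)


def make_system(params: MorseParameters | None = None) -> ODESystemSpec:
    """The (r, p) Hamiltonian system packaged for the propagator."""
    params = params or MorseParameters()

    def rhs(x, y):
        return np.array([y[1] / params.mu, morse_force(y[0], params)])

    def jac(x, y):
        return np.array(
            [
                [0.0, 1.0 / params.mu],
                [morse_force_derivative(y[0], params), 0.0],
            ]
        )

    return ODESystemSpec(
        n=2, rhs=rhs, jac=jac, labels=["r_bohr", "p_au"], name="morse-h2"
    )


def vibrational_period(params: MorseParameters | None = None) -> float:
    """Small-amplitude (harmonic) period at the well bottom, in a.u.

    omega0 = a sqrt(2 De / mu), period = 2 pi / omega0.
    """
    params = params or MorseParameters()
    omega0 = params.a * np.sqrt(2.0 * params.d_e / params.mu)
    return float(2.0 * np.pi / omega0)


def momentum_scale(params: MorseParameters | None = None) -> float:
    """mu * omega0: momentum amplitude per unit coordinate amplitude.

    The default momentum rescale factor for coupled-mode propagation, chosen
    so equal phase-space amplitudes contribute equal residual magnitudes.
    """
    params = params or MorseParameters()
    return float(params.mu * params.a * np.sqrt(2.0 * params.d_e / params.mu))


def _bound_closed_form(
    params: MorseParameters, r0: float, p0: float, times: np.ndarray
) -> np.ndarray:
    e = total_energy(r0, p0, params)
    eps = e / params.d_e
    out = np.empty((times.shape[0], 2))
    if eps < 1e-14:
        out[:, 0] = r0
        out[:, 1] = 0.0
        return out
    sq = np.sqrt(eps)
    omega0 = params.a * np.sqrt(2.0 * params.d_e / params.mu)
    omega_b = omega0 * np.sqrt(1.0 - eps)
    u0 = np.exp(-params.a * (r0 - params.r_e))
    cos_phi = np.clip((1.0 - (1.0 - eps) / u0) / sq, -1.0, 1.0)
    sin_phi = np.sqrt(max(0.0, 1.0 - cos_phi**2))
    if p0 < 0:
        sin_phi = -sin_phi
    phi = np.arctan2(sin_phi, cos_phi)
    theta = omega_b * times + phi
    denom = 1.0 - sq * np.cos(theta)
    out[:, 0] = params.r_e + np.log(denom / (1.0 - eps)) / params.a
    out[:, 1] = params.mu * omega_b * sq * np.sin(theta) / (params.a * denom)
    return out


def _integrated(
    params: MorseParameters, r0: float, p0: float, times: np.ndarray
) -> np.ndarray:
    def rhs(t, y):
        return [y[1] / params.mu, morse_force(y[0], params)]

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        [r0, p0],
        t_eval=times,
        method="DOP853",
        rtol=1e-12,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    return sol.y.T


def reference_trajectory(
    params: MorseParameters,
    r0: float,
    p0: float,
    times: np.ndarray,
    force_integrator: bool = False,
) -> np.ndarray:
    """Reference (r, p) at the given times, shape (len(times), 2).

    Bound energies (E < De) use the closed-form solution; unbound energies
    (or ``force_integrator=True``) use DOP853 with rtol = atol = 1e-12.
    The first row equals (r0, p0) exactly.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    times = np.asarray(times, dtype=float)
    e = total_energy(r0, p0, params)
    if not force_integrator and e < params.d_e * (1.0 - 1e-12):
        out = _bound_closed_form(params, r0, p0, times)
    else:
        out = _integrated(params, r0, p0, times)
    out[0] = (r0, p0)
    return out


_TIME_UNITS = {"au": 1.0, "fs": AU_TIME_FS, "as": AU_TIME_FS * 1e3}
_ENERGY_UNITS = {"hartree": 1.0, "ev": HARTREE_EV}
_LENGTH_UNITS = {"bohr": 1.0, "angstrom": BOHR_ANGSTROM}


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between a.u. time/fs/as, Hartree/eV, and Bohr/Angstrom."""
    f, t = from_unit.lower(), to_unit.lower()
    for table in (_TIME_UNITS, _ENERGY_UNITS, _LENGTH_UNITS):
        if f in table and t in table:
            return value * table[t] / table[f]
    raise ValueError(f"unsupported unit conversion {from_unit!r} -> {to_unit!r}")
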
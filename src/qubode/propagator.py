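"""Trajectory propagation by chunked least-squares solves.

The time grid is walked in runs of ``M`` steps.  At the start of each run the
right-hand side is linearized (first-order Taylor at the run's initial state),
the run's residual functional is assembled with :func:`qubode.qubo.build_qp`,
minimized by the configured backend, and the run's final point seeds the next
run.  In the ``M = 1`` limit the right-hand sides are fully known from the
previous step, every equation decouples, and the continuous minimizer is
exactly one forward-Euler step — the anchor oracle for everything downstream.

Two dispatch modes mirror the two hardware strategies: ``coupled`` solves all
``N`` equations of a run at once (N*M*K bits per QUBO), ``sequential`` solves
one equation at a time against the previous state (Jacobi update, K*M bits
per QUBO, constant qubit budget regardless of system size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .encoding import FixedPointScheme
from .qubo import (
    LinearSegment,
    QPProblem,
    build_qp,
    decode_solution,
    qp_to_qubo,
)
from .solvers import (
    AnnealSchedule,
    solve_exhaustive,
    solve_qp_continuous,
    solve_sa,
    solve_sa_greedy,
    solve_with_restarts,
)

__all__ = [
    "ODESystemSpec",
    "TimeGrid",
    "PropagationConfig",
    "Trajectory",
    "SaturationError",
    "linearize",
    "propagate",
    "apply_scaling",
]

logger = logging.getLogger(__name__)

SOLVER_CHOICES = ("qp", "exhaustive", "sa", "sa+greedy")


class SaturationError(RuntimeError):
    """A state component left the representable fixed-point range.

    Aborting (rather than clamping) makes encoding saturation loud: a
    dissociating bond run long enough will eventually overflow the range and
    any clamped continuation would be silently wrong.
    """

    def __init__(self, step: int, state: np.ndarray, message: str):
        super().__init__(message)
        self.step = step
        self.state = state


@dataclass
class ODESystemSpec:
    """A first-order ODE system dy/dx = f(x, y).

    ``rhs(x, y) -> (N,)`` is required; ``jac(x, y) -> (N, N)`` is optional
    (central finite differences are used when absent).  ``scales`` are
    per-variable factors applied by :func:`apply_scaling`; ``weights`` are
    per-equation penalty factors passed to the residual functional.
    """

    n: int
    rhs: Callable[[float, np.ndarray], np.ndarray]
    jac: Callable[[float, np.ndarray], np.ndarray] | None = None
    labels: list[str] | None = None
    weights: np.ndarray | None = None
    scales: np.ndarray | None = None
    name: str = "ode-system"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.labels is None:
            self.labels = [f"y{k + 1}" for k in range(self.n)]
        if len(self.labels) != self.n:
            raise ValueError("labels length must equal n")


@dataclass(frozen=True)
class TimeGrid:
    """Equidistant grid: points x_i = start + i * dx for i = 0 .. n_steps."""

    start: float
    dx: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError(f"dx must be positive, got {self.dx}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")

    @classmethod
    def from_total_time(cls, total: float, n_steps: int, start: float = 0.0) -> "TimeGrid":
        """Grid of ``n_steps`` propagation steps covering ``total`` time."""
        return cls(start=start, dx=total / n_steps, n_steps=n_steps)

    @property
    def times(self) -> np.ndarray:
        return self.start + self.dx * np.arange(self.n_steps + 1)


@dataclass
class PropagationConfig:
    """How each run of the propagation is solved.

    solver: "qp" (continuous reference), "exhaustive" (global binary
    optimum), "sa" (annealing), or "sa+greedy" (annealing + greedy descent).
    ``attempts`` restarts stochastic solvers per run, keeping the best energy.
    ``mode`` is "sequential" (one equation per solve) or "coupled" (all at
    once); ``gauss_seidel`` lets sequential solves see the freshly updated
    components of the current run instead of the run-start state.
    """

    solver: str = "qp"
    mode: str = "sequential"
    m_per_run: int = 1
    scheme: FixedPointScheme = field(default_factory=lambda: FixedPointScheme(6, 15))
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    attempts: int = 1
    accept_threshold: float | None = None
    seed: int = 0
    gauss_seidel: bool = False

    def __post_init__(self) -> None:
        if self.solver not in SOLVER_CHOICES:
            raise ValueError(f"solver must be one of {SOLVER_CHOICES}")
        if self.mode not in ("sequential", "coupled"):
            raise ValueError("mode must be 'sequential' or 'coupled'")
        if self.m_per_run < 1:
            raise ValueError("m_per_run must be >= 1")
        if self.attempts < 1:
            raise ValueError("attempts must be >= 1")

    def to_dict(self) -> dict:
        return {
            "solver": self.solver,
            "mode": self.mode,
            "m_per_run": self.m_per_run,
            "k_int": self.scheme.k_int,
            "k_frac": self.scheme.k_frac,
            "reads": self.schedule.reads,
            "sweeps": self.schedule.sweeps,
            "attempts": self.attempts,
            "accept_threshold": self.accept_threshold,
            "seed": self.seed,
            "gauss_seidel": self.gauss_seidel,
        }


@dataclass
class Trajectory:
    """Propagated solution plus per-run solver diagnostics."""

    times: np.ndarray
    values: np.ndarray  # (n_points, N)
    labels: list[str]
    reports: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    def component(self, k: int) -> np.ndarray:
        return self.values[:, k]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times})
        for k, lab in enumerate(self.labels):
            df[lab] = self.values[:, k]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def report_dict(self) -> dict:
        return {"config": self.config, "steps": self.reports}


def linearize(
    system: ODESystemSpec, x0: float, y0: np.ndarray, fd_step: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """First-order Taylor coefficients of f at (x0, y0).

    Returns ``(f0, J)`` with ``f(x, y) ~ f0 + J @ (y - y0)``, so the
    segment-constant coefficient is ``f0 - J @ y0``.  Without a supplied
    Jacobian, central finite differences with step ``fd_step`` per component.
    """
    y0 = np.asarray(y0, dtype=float)
    try:
        f0 = np.asarray(system.rhs(x0, y0), dtype=float)
    except Exception as exc:
        raise RuntimeError(
            f"right-hand side evaluation failed at x={x0}, y={y0}: {exc}"
        ) from exc
    if f0.shape != (system.n,):
        raise ValueError(
            f"rhs returned shape {f0.shape}, expected ({system.n},)"
        )
    if system.jac is not None:
        jac = np.asarray(system.jac(x0, y0), dtype=float)
        if jac.shape != (system.n, system.n):
            raise ValueError(
                f"jac returned shape {jac.shape}, expected ({system.n}, {system.n})"
            )
    else:
        jac = np.empty((system.n, system.n))
        for k in range(system.n):
            yp = y0.copy()
            ym = y0.copy()
            yp[k] += fd_step
            ym[k] -= fd_step
            jac[:, k] = (
                np.asarray(system.rhs(x0, yp), dtype=float)
                - np.asarray(system.rhs(x0, ym), dtype=float)
            ) / (2.0 * fd_step)
    return f0, jac


def _check_range(
    state: np.ndarray, scheme: FixedPointScheme, step: int, decoded: bool = False
) -> None:
    """Abort when a state (nearly) saturates the representable interval.

    A decoded solver solution can never lie *outside* the range — a true
    minimizer beyond it is pinned to the boundary instead — so for decoded
    states anything within one resolution step of either end is treated as
    saturated.
    """
    lo, hi = scheme.min_value, scheme.max_value
    if decoded:
        lo, hi = lo + scheme.resolution, hi - scheme.resolution
    if np.any(state < lo) or np.any(state > hi):
        raise SaturationError(
            step,
            state,
            f"state {state} left the representable range [{lo}, {hi}] "
            f"at step {step}: encoding saturated",
        )


def _derived_seed(master: int, run: int, eq: int) -> int:
    return (master + 1_000_003 * run + 7_919 * (eq + 1)) % (2**31)


def _solve_cell(
    qp: QPProblem, config: PropagationConfig, cell_seed: int
) -> tuple[np.ndarray, dict]:
    """Minimize one run's functional with the configured backend."""
    if config.solver == "qp":
        y = solve_qp_continuous(qp)
        return y, {
            "solver": "qp",
            "epsilon": qp.energy(y),
            "attempts": 1,
        }
    qubo = qp_to_qubo(qp, config.scheme)
    if config.solver == "exhaustive":
        rep = solve_exhaustive(qubo)
    else:
        inner = solve_sa if config.solver == "sa" else solve_sa_greedy
        base = config.schedule

        def run_inner(qb, seed):
            return inner(qb, replace(base, seed=seed))

        rep = solve_with_restarts(
            run_inner,
            qubo,
            max_attempts=config.attempts,
            accept_threshold=config.accept_threshold,
            seed=cell_seed,
        )
    y = decode_solution(rep.best_bits, qubo)
    return y, {
        "solver": config.solver,
        "epsilon": rep.best_energy + qubo.constant_offset,
        "attempts": rep.attempts_used,
        "attempt_energies": [
            float(e + qubo.constant_offset) for e in rep.attempt_energies
        ],
        "seed": cell_seed,
    }


def propagate(
    system: ODESystemSpec,
    grid: TimeGrid,
    y_init: np.ndarray,
    config: PropagationConfig,
) -> Trajectory:
    """Walk the grid in runs of ``m_per_run`` steps (see module docstring).

    The first trajectory point equals ``y_init`` exactly.  For binary-solver
    backends every state component is checked against the representable range
    each run; leaving it raises :class:`SaturationError` with the step index.
    """
    y0 = np.asarray(y_init, dtype=float)
    if y0.shape != (system.n,):
        raise ValueError(f"y_init has shape {y0.shape}, expected ({system.n},)")
    binary = config.solver != "qp"
    if binary:
        _check_range(y0, config.scheme, 0)

    n_pts = grid.n_steps + 1
    values = np.empty((n_pts, system.n))
    values[0] = y0
    reports: list[dict] = []
    state = y0.copy()
    x = grid.start
    step = 0
    run = 0
    while step < grid.n_steps:
        m = min(config.m_per_run, grid.n_steps - step)
        xs = x + grid.dx * np.arange(m)
        if config.mode == "coupled":
            f0, jac = linearize(system, x, state)
            seg = LinearSegment.from_taylor(xs, f0, jac, state)
            qp = build_qp(seg, grid.dx, state, weights=system.weights)
            y_flat, info = _solve_cell(qp, config, _derived_seed(config.seed, run, 0))
            pts = y_flat.reshape(m, system.n)
        else:
            pts = np.empty((m, system.n))
            work = state.copy()
            infos = []
            for eq in range(system.n):
                f0, jac = linearize(system, x, work)
                # 1-equation cell: other variables frozen at `work`
                const = f0[eq] - jac[eq, eq] * work[eq]
                seg = LinearSegment(
                    x=xs,
                    const=np.full((m, 1), const),
                    lin=np.full((m, 1, 1), jac[eq, eq]),
                )
                w_eq = None if system.weights is None else np.asarray(
                    system.weights, dtype=float
                )[eq:eq + 1]
                qp = build_qp(seg, grid.dx, state[eq:eq + 1], weights=w_eq)
                y_eq, info = _solve_cell(
                    qp, config, _derived_seed(config.seed, run, eq)
                )
                pts[:, eq] = y_eq
                infos.append(info)
                if config.gauss_seidel:
                    work[eq] = y_eq[-1]
            info = {
                "solver": config.solver,
                "epsilon": float(sum(i["epsilon"] for i in infos)),
                "attempts": max(i["attempts"] for i in infos),
                "per_equation": infos,
            }
        if binary:
            for dm in range(m):
                _check_range(pts[dm], config.scheme, step + dm + 1, decoded=True)
        values[step + 1:step + 1 + m] = pts
        state = pts[-1].copy()
        info.update({"run": run, "first_step": step + 1, "m": m})
        reports.append(info)
        logger.info(
            "run %d (steps %d..%d): solver=%s epsilon=%.3e attempts=%d",
            run, step + 1, step + m, config.solver, info["epsilon"],
            info["attempts"],
        )
        x += m * grid.dx
        step += m
        run += 1
    return Trajectory(
        times=grid.times,
        values=values,
        labels=list(system.labels or []),
        reports=reports,
        config=config.to_dict(),
    )


def apply_scaling(
    system: ODESystemSpec, scale_factors: np.ndarray
) -> ODESystemSpec:
    """Rescale variables: y_n = s_n * y~_n, f~_n(x, y~) = f_n(x, s*y~)/s_n.

    Useful when variable ranges differ strongly (e.g. bond length of order 1
    Bohr against momentum of order mu*omega): equalizing the ranges equalizes
    the residual contributions in the functional.  Propagating the scaled
    system from ``y0 / s`` and multiplying back by ``s`` reproduces the
    unscaled continuous-backend trajectory.
    """
    s = np.asarray(scale_factors, dtype=float)
    if s.shape != (system.n,):
        raise ValueError(f"expected {system.n} scale factors, got shape {s.shape}")
    if np.any(s <= 0):
        raise ValueError("scale factors must be positive")

    inner_rhs = system.rhs
    inner_jac = system.jac

    def rhs(x, yt):
        return np.asarray(inner_rhs(x, s * np.asarray(yt)), dtype=float) / s

    jac = None
    if inner_jac is not None:
        def jac(x, yt):  # J~_nk = J_nk * s_k / s_n
            j = np.asarray(inner_jac(x, s * np.asarray(yt)), dtype=float)
            return j * s[None, :] / s[:, None]

    return ODESystemSpec(
        n=system.n,
        rhs=rhs,
        jac=jac,
        labels=[f"{lab}_scaled" for lab in (system.labels or [])],
        weights=system.weights,
        scales=s,
        name=f"{system.name}-scaled",
    )
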
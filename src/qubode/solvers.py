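"""Minimizers for the continuous (QP) and binary (QUBO) functionals.

Four routes with different guarantees:

* :func:`solve_qp_continuous` — exact stationary point of the continuous
  quadratic form; the reference any binary solver is judged against.
* :func:`solve_exhaustive` — global optimum over all bit states by
  enumeration; the ground-truth oracle, practical up to ~24 bits.
* :func:`solve_sa` — single-bit-flip Metropolis simulated annealing with
  geometric cooling; a classical stand-in for a heuristic/hardware annealer.
* :func:`greedy_descent` — steepest single-bit-flip descent to a 1-flip local
  minimum; the classical post-processing step of the hybrid strategy
  (anneal for a coarse guess near the global basin, then descend greedily).

:func:`solve_with_restarts` wraps any stochastic solver, re-running it with
derived seeds and keeping the best-energy state, mirroring the
restart-and-select-best strategy.  All binary solvers report raw bit energies
``q^T Q q`` (the problem's ``constant_offset`` is excluded and constant per
instance, so best-of selection is unaffected).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from numba import njit

from .qubo import QPProblem, QUBOProblem, qubo_energy
from .encoding import bits_to_string

__all__ = [
    "AnnealSchedule",
    "SolverReport",
    "QuboSampler",
    "solve_qp_continuous",
    "solve_exhaustive",
    "solve_sa",
    "greedy_descent",
    "solve_sa_greedy",
    "solve_with_restarts",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass
class AnnealSchedule:
    """Configuration of one simulated-annealing solve.

    ``reads`` restarts of the Metropolis chain from fresh random states,
    ``sweeps`` full passes over the bits per read, temperatures interpolated
    geometrically from ``t_initial`` down to ``t_initial * t_final_ratio``.
    When ``t_initial`` is None it is set per instance to the largest
    single-flip |dE| of a random probe state, so the hottest sweeps can cross
    any barrier while the coldest only accept descents.

    The deep default cooling ratio reflects the fixed-point encoding: bit
    weights span a 2**(K_I + K_D) dynamic range, so single-flip energy scales
    span its square (~1e9 for the (6, 15) scheme) and the chain must reach
    temperatures far below the high-bit scale before the low bits freeze into
    anything meaningful.
    """

    reads: int = 10
    sweeps: int = 100
    t_initial: float | None = None
    t_final_ratio: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads < 1 or self.sweeps < 1:
            raise ValueError("reads and sweeps must be >= 1")
        if self.t_initial is not None and self.t_initial <= 0:
            raise ValueError("t_initial must be positive")
        if not 0 < self.t_final_ratio <= 1:
            raise ValueError("t_final_ratio must be in (0, 1]")


@dataclass
class SolverReport:
    """Outcome of one binary solve (possibly spanning several attempts)."""

    best_bits: np.ndarray
    best_energy: float
    attempt_energies: list[float] = field(default_factory=list)
    attempts_used: int = 1
    reads_used: int = 0
    seed: int | None = None
    notes: str = ""

    def to_json_dict(self) -> dict:
        return {
            "best_bits": bits_to_string(self.best_bits),
            "best_energy": self.best_energy,
            "attempt_energies": list(map(float, self.attempt_energies)),
            "attempts_used": self.attempts_used,
            "reads_used": self.reads_used,
            "seed": self.seed,
            "notes": self.notes,
        }


class QuboSampler(Protocol):
    """Adapter contract for external annealing backends.

    A sampler receives the upper-triangular coordinate entries of Q and a read
    budget and returns sampled bit states with their energies.  The in-repo
    solvers satisfy it; a hardware SDK could be plugged in behind the same
    surface without touching the propagation code.
    """

    def sample(
        self, entries: list[tuple[int, int, float]], n_bits: int, num_reads: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (states of shape (num_reads, n_bits), energies)."""
        ...


# --------------------------------------------------------------------------
# continuous reference

def solve_qp_continuous(qp: QPProblem) -> np.ndarray:
    """Solve the continuous quadratic program exactly.

    The least-squares construction makes ``H + H^T`` positive semidefinite
    (definite once the initial point is eliminated on propagation problems),
    so the stationary point ``(H + H^T) y = -d`` is the global minimizer.
    Singular systems fall back to the least-norm solution with a warning.
    """
    a = qp.h + qp.h.T
    try:
        y = np.linalg.solve(a, -qp.d)
    except np.linalg.LinAlgError:
        warnings.warn("singular QP system; returning least-norm solution")
        logger.warning("singular QP system; returning least-norm solution")
        y = np.linalg.lstsq(a, -qp.d, rcond=None)[0]
    return y


# --------------------------------------------------------------------------
# exhaustive oracle

def _bit_table(n_bits: int) -> np.ndarray:
    """Bit patterns of integers 0..2**n_bits-1, pattern[p] = (m >> p) & 1.

    Position 0 of the pattern (the MSB of the fixed-point encoding) maps to
    the least-significant bit of the enumeration integer: ties in energy are
    therefore broken toward the lowest pattern value sum_p bits[p] * 2**p,
    since enumeration visits patterns in that order and argmin keeps the
    first.
    """
    ints = np.arange(1 << n_bits, dtype=np.int64)
    return ((ints[:, None] >> np.arange(n_bits)[None, :]) & 1).astype(np.float64)


def solve_exhaustive(qubo: QUBOProblem, max_bits: int = 24) -> SolverReport:
    """Global minimum over all 2**n_bits states by split-half enumeration.

    The bits are split into a low and a high half; enumerating each half's
    internal energy once and the cross term as a matrix product covers all
    2**n_bits states at ~O(2**n_bits) cost.  Deterministic; ties broken
    toward the lowest bit-pattern value (see :func:`_bit_table`).
    """
    nb = qubo.n_bits
    if nb > max_bits:
        raise ValueError(
            f"exhaustive enumeration refused: {nb} bits > max_bits={max_bits}"
        )
    q = qubo.q
    kl = (nb + 1) // 2
    kh = nb - kl
    a = _bit_table(kl)                      # low positions 0 .. kl-1
    e_a = ((a @ q[:kl, :kl]) * a).sum(axis=1)
    if kh == 0:
        energies = e_a
    else:
        b = _bit_table(kh)                  # high positions kl .. nb-1
        e_b = ((b @ q[kl:, kl:]) * b).sum(axis=1)
        cross = q[:kl, kl:] + q[kl:, :kl].T
        energies = e_a[:, None] + e_b[None, :] + (a @ cross) @ b.T
        # ravel 'F' iterates the low half fastest: flat index == pattern value
        energies = energies.ravel(order="F")
    best_m = int(np.argmin(energies))
    best_e = float(energies[best_m])
    bits = ((best_m >> np.arange(nb)) & 1).astype(np.uint8)
    return SolverReport(
        best_bits=bits,
        best_energy=best_e,
        attempt_energies=[best_e],
        attempts_used=1,
        reads_used=1 << nb,
        seed=None,
        notes="exhaustive enumeration",
    )


# --------------------------------------------------------------------------
# simulated annealing

@njit(cache=True)
def _sa_kernel(w, diag, q, betas, order, unif, best_q):  # pragma: no cover
    """One Metropolis chain: sequential single-bit flips, geometric cooling.

    ``w`` is Q + Q^T with zero diagonal, ``diag`` the diagonal of Q; the
    energy change of flipping bit k is (1 - 2 q_k)(diag_k + w_k . q).
    Returns the best energy seen; best state written into ``best_q``.
    """
    nb = q.shape[0]
    # current energy
    e = 0.0
    for i in range(nb):
        if q[i] > 0.5:
            e += diag[i]
            for j in range(i + 1, nb):
                if q[j] > 0.5:
                    e += w[i, j]
    best_e = e
    for i in range(nb):
        best_q[i] = q[i]
    n_sweeps = betas.shape[0]
    for s in range(n_sweeps):
        beta = betas[s]
        for t in range(nb):
            k = order[s, t]
            de = diag[k]
            for j in range(nb):
                de += w[k, j] * q[j]
            de *= 1.0 - 2.0 * q[k]
            if de <= 0.0 or unif[s, t] < np.exp(-de * beta):
                q[k] = 1.0 - q[k]
                e += de
                if e < best_e:
                    best_e = e
                    for i in range(nb):
                        best_q[i] = q[i]
    return best_e


def _auto_t_initial(w: np.ndarray, diag: np.ndarray, rng) -> float:
    probe = rng.integers(0, 2, size=diag.shape[0]).astype(float)
    de = (1.0 - 2.0 * probe) * (diag + w @ probe)
    t0 = float(np.max(np.abs(de)))
    return t0 if t0 > 0 else 1.0


def _sa_reads(
    qubo: QUBOProblem, schedule: AnnealSchedule
) -> list[tuple[float, np.ndarray]]:
    """Run all annealing reads; return each read's best (energy, bits)."""
    nb = qubo.n_bits
    w = qubo.q + qubo.q.T
    diag = np.diag(qubo.q).copy()
    np.fill_diagonal(w, 0.0)
    rng = np.random.default_rng(schedule.seed)
    t0 = schedule.t_initial or _auto_t_initial(w, diag, rng)
    t1 = t0 * schedule.t_final_ratio
    betas = 1.0 / np.geomspace(t0, t1, schedule.sweeps)
    out = []
    for _ in range(schedule.reads):
        q = rng.integers(0, 2, size=nb).astype(np.float64)
        order = np.empty((schedule.sweeps, nb), dtype=np.int64)
        for s in range(schedule.sweeps):
            order[s] = rng.permutation(nb)
        unif = rng.random((schedule.sweeps, nb))
        bq = np.empty(nb)
        e = _sa_kernel(w, diag, q, betas, order, unif, bq)
        out.append((float(e), (bq > 0.5).astype(np.uint8)))
    return out


def solve_sa(qubo: QUBOProblem, schedule: AnnealSchedule) -> SolverReport:
    """Simulated annealing over the QUBO bits, reproducible given the seed."""
    reads = _sa_reads(qubo, schedule)
    best_e, best_bits = min(reads, key=lambda t: t[0])
    return SolverReport(
        best_bits=best_bits,
        best_energy=best_e,
        attempt_energies=[best_e],
        attempts_used=1,
        reads_used=schedule.reads,
        seed=schedule.seed,
        notes="simulated annealing",
    )


# --------------------------------------------------------------------------
# greedy post-processing

def greedy_descent(qubo: QUBOProblem, start: np.ndarray) -> SolverReport:
    """Steepest single-bit-flip descent to a 1-flip local minimum.

    At each step flips the bit with the most negative energy change (ties
    broken toward the lowest bit index); stops when no flip decreases the
    energy, so the energy is non-increasing along the path.
    """
    q = np.asarray(start, dtype=float).copy().ravel()
    if q.shape[0] != qubo.n_bits:
        raise ValueError(f"start has {q.shape[0]} bits, expected {qubo.n_bits}")
    w = qubo.q + qubo.q.T
    diag = np.diag(qubo.q).copy()
    np.fill_diagonal(w, 0.0)
    e = qubo_energy(qubo, q)
    while True:
        de = (1.0 - 2.0 * q) * (diag + w @ q)
        k = int(np.argmin(de))
        if de[k] >= 0.0:
            break
        q[k] = 1.0 - q[k]
        e += float(de[k])
    return SolverReport(
        best_bits=q.astype(np.uint8),
        best_energy=float(e),
        attempt_energies=[float(e)],
        attempts_used=1,
        reads_used=0,
        seed=None,
        notes="greedy descent",
    )


def solve_sa_greedy(qubo: QUBOProblem, schedule: AnnealSchedule) -> SolverReport:
    """Hybrid: every annealing read's solution seeds a greedy descent.

    The annealer is good at landing near the global basin but not at settling
    to its exact bottom; greedy descent does the opposite.  Each read's best
    state is therefore polished independently and the lowest polished energy
    wins — never worse than plain annealing with the same schedule.
    """
    reads = _sa_reads(qubo, schedule)
    best: SolverReport | None = None
    sa_best = min(e for e, _ in reads)
    for _, bits in reads:
        gd = greedy_descent(qubo, bits)
        if best is None or gd.best_energy < best.best_energy:
            best = gd
    assert best is not None
    best.reads_used = schedule.reads
    best.seed = schedule.seed
    best.notes = "sa + greedy descent"
    best.attempt_energies = [sa_best, best.best_energy]
    return best


# --------------------------------------------------------------------------
# restarts

def solve_with_restarts(
    inner: Callable[[QUBOProblem, int], SolverReport],
    qubo: QUBOProblem,
    max_attempts: int,
    accept_threshold: float | None = None,
    seed: int = 0,
) -> SolverReport:
    """Run ``inner(qubo, derived_seed)`` up to ``max_attempts`` times.

    Attempt ``r`` uses seed ``(seed XOR r) mod 2**31`` so restart streams are
    reproducible and prefixes coincide across different attempt budgets (the
    best of 10 attempts can only improve on the best of 1).  By default all
    attempts run and the best-energy state is kept; an ``accept_threshold``
    enables early stopping once the energy is good enough.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    best: SolverReport | None = None
    energies: list[float] = []
    used = 0
    reads = 0
    for attempt in range(max_attempts):
        derived = (seed ^ attempt) % _SEED_MOD
        rep = inner(qubo, derived)
        used += 1
        reads += rep.reads_used
        energies.append(rep.best_energy)
        if best is None or rep.best_energy < best.best_energy:
            best = rep
        if accept_threshold is not None and best.best_energy <= accept_threshold:
            break
    assert best is not None
    return SolverReport(
        best_bits=best.best_bits,
        best_energy=best.best_energy,
        attempt_energies=energies,
        attempts_used=used,
        reads_used=reads,
        seed=seed,
        notes=f"best of {used} attempts ({best.notes})",
    )
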
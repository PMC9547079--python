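"""Least-squares compilation of a linearized ODE segment to QP and QUBO form.

For a first-order system dy_n/dx = f_n(x, y) on an equidistant grid, the
solution over a segment of ``M`` steps is cast as the minimizer of the total
squared residual of the first-order finite difference,

    eps(y) = sum_{i=1..M} sum_n w_n * ( (y_{n,i+1} - y_{n,i})/dx - f_{n,i} )^2,

with f linear in y inside the segment (f_n = f_{n,0} + sum_k f_{n,k} y_k).
Expanding the squares gives a quadratic form eps = y^T H y + y^T d + const
over the unknown grid values (:class:`QPProblem`).  The known initial point of
the segment is eliminated by substitution, folding its contributions into the
linear term and the constant, so the functional stays exactly quadratic in the
remaining unknowns and its minimum stays zero-achievable when the difference
equations are exactly satisfiable.

Substituting the signed fixed-point encoding of each unknown turns the QP into
a QUBO over the bits: each H element becomes a K x K block whose entries are
products of bit weights, and the linear term folds onto the diagonal because
q^2 = q for binary q (:func:`qp_to_qubo`).  The dropped constants are tracked
in ``constant_offset`` so that QP and QUBO energies are directly comparable —
that equivalence is the module's central contract and is what the test suite
leans on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .encoding import FixedPointScheme, decode

__all__ = [
    "LinearSegment",
    "QPProblem",
    "QUBOProblem",
    "build_qp",
    "qp_to_qubo",
    "qubo_energy",
    "decode_solution",
    "export_qubo",
    "import_qubo",
]


@dataclass(frozen=True)
class LinearSegment:
    """Linear(ized) right-hand sides over one segment of the grid.

    ``const[i, n]`` is the constant coefficient f_{n,0} and ``lin[i, n, k]``
    the coefficient of y_k in f_n, both at grid point ``i`` (0-based within
    the segment, ``i = 0 .. M-1``); ``x`` holds the abscissae of those points.
    """

    x: np.ndarray          # (M,)
    const: np.ndarray      # (M, N)
    lin: np.ndarray        # (M, N, N)

    def __post_init__(self) -> None:
        x, c, a = map(np.asarray, (self.x, self.const, self.lin))
        object.__setattr__(self, "x", np.atleast_1d(x).astype(float))
        object.__setattr__(self, "const", np.atleast_2d(c).astype(float))
        object.__setattr__(self, "lin", a.astype(float))
        m, n = self.const.shape
        if self.x.shape != (m,):
            raise ValueError(f"x has shape {self.x.shape}, expected ({m},)")
        if self.lin.shape != (m, n, n):
            raise ValueError(
                f"lin has shape {self.lin.shape}, expected ({m}, {n}, {n})"
            )

    @property
    def n_steps(self) -> int:
        return self.const.shape[0]

    @property
    def n_equations(self) -> int:
        return self.const.shape[1]

    @classmethod
    def from_taylor(
        cls,
        x: np.ndarray,
        f0: np.ndarray,
        jac: np.ndarray,
        y0: np.ndarray,
    ) -> "LinearSegment":
        """Segment from a first-order Taylor expansion at the segment start.

        f(x, y) ~ f(x0, y0) + J (y - y0), replicated over the segment points.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        f0 = np.asarray(f0, dtype=float)
        jac = np.asarray(jac, dtype=float)
        y0 = np.asarray(y0, dtype=float)
        m = x.shape[0]
        const_row = f0 - jac @ y0
        return cls(
            x=x,
            const=np.tile(const_row, (m, 1)),
            lin=np.tile(jac, (m, 1, 1)),
        )


@dataclass
class QPProblem:
    """Quadratic functional eps(y) = y^T H y + y^T d + constant_offset.

    ``labels[r]`` identifies unknown ``r`` as ``(equation index, grid index)``
    where the grid index counts from 1 (the first *unknown* point after the
    segment's known initial point).
    """

    h: np.ndarray
    d: np.ndarray
    constant_offset: float
    labels: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.h = np.atleast_2d(np.asarray(self.h, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        n = self.h.shape[0]
        if self.h.shape != (n, n):
            raise ValueError(f"H must be square, got {self.h.shape}")
        if self.d.shape != (n,):
            raise ValueError(f"d has shape {self.d.shape}, expected ({n},)")
        if not self.labels:
            self.labels = [(0, i + 1) for i in range(n)]

    @property
    def n_unknowns(self) -> int:
        return self.h.shape[0]

    def energy(self, y: np.ndarray, include_offset: bool = True) -> float:
        y = np.asarray(y, dtype=float)
        val = float(y @ self.h @ y + y @ self.d)
        return val + self.constant_offset if include_offset else val


@dataclass
class QUBOProblem:
    """Binary functional eps(q) = q^T Q q (+ constant_offset).

    ``q`` is stored upper-triangular; ``index_map[b]`` identifies flat bit
    ``b`` as ``(equation index, grid index, bit position j)``, in the same
    MSB-first order as :mod:`qubode.encoding`.
    """

    q: np.ndarray
    constant_offset: float
    scheme: FixedPointScheme
    index_map: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        nb = self.q.shape[0]
        if self.q.shape != (nb, nb):
            raise ValueError(f"Q must be square, got {self.q.shape}")
        if len(self.index_map) != nb:
            raise ValueError("index map length must equal Q dimension")

    @property
    def n_bits(self) -> int:
        return self.q.shape[0]

    @property
    def n_unknowns(self) -> int:
        return self.n_bits // self.scheme.total_bits


def build_qp(
    segment: LinearSegment,
    dx: float,
    initial_values: np.ndarray,
    weights: np.ndarray | None = None,
) -> QPProblem:
    """Assemble the least-squares QP for one segment.

    Parameters
    ----------
    segment : LinearSegment
        Linear coefficients of f at the ``M`` points where residuals are
        formed (the segment start and the ``M - 1`` interior points).
    dx : float
        Grid step.
    initial_values : array (N,)
        Known solution at the segment's first point; eliminated by
        substitution so the unknowns are the ``M`` following points.
    weights : array (N,), optional
        Per-equation penalty factors multiplying each squared residual
        (default all ones).  Useful when the natural scales of the variables
        differ strongly.
    """
    if dx <= 0:
        raise ValueError(f"dx must be positive, got {dx}")
    m, n = segment.n_steps, segment.n_equations
    y0 = np.asarray(initial_values, dtype=float)
    if y0.shape != (n,):
        raise ValueError(f"initial_values has shape {y0.shape}, expected ({n},)")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights has shape {w.shape}, expected ({n},)")

    # Full quadratic form over all (M+1)*N grid values, point-major order.
    n_tot = (m + 1) * n
    big_h = np.zeros((n_tot, n_tot))
    big_d = np.zeros(n_tot)
    offset = 0.0

    def idx(i: int, eq: int) -> int:
        return i * n + eq

    for i in range(m):
        for eq in range(n):
            # residual_g . y + b, with g the gradient of the residual
            g = np.zeros(n_tot)
            g[idx(i + 1, eq)] += 1.0 / dx
            g[idx(i, eq)] -= 1.0 / dx
            g[idx(i, 0):idx(i, 0) + n] -= segment.lin[i, eq, :]
            b = -segment.const[i, eq]
            big_h += w[eq] * np.outer(g, g)
            big_d += 2.0 * w[eq] * b * g
            offset += w[eq] * b * b

    # Eliminate the known first point: y = [a; z] with a = y0.
    haa = big_h[:n, :n]
    haz = big_h[:n, n:]
    hza = big_h[n:, :n]
    hzz = big_h[n:, n:]
    d_z = big_d[n:] + hza @ y0 + haz.T @ y0
    off_z = offset + float(y0 @ haa @ y0 + big_d[:n] @ y0)

    labels = [(eq, i) for i in range(1, m + 1) for eq in range(n)]
    return QPProblem(h=hzz, d=d_z, constant_offset=off_z, labels=labels)


def qp_to_qubo(qp: QPProblem, scheme: FixedPointScheme) -> QUBOProblem:
    """Convert a QP over continuous unknowns to a QUBO over their bits.

    Each element ``H[u, v]`` becomes a ``K x K`` block with entries
    ``2**(-(j+j')) * H[u, v]``; the diagonal bit ``(u, j)`` additionally
    absorbs the linear term and the encoding offset:

        Q_diag = 2**(-2j) H_uu + 2**(-j) d_u - sum_k 2**(K_I-1-j) (H_uk + H_ku)

    The constant dropped by the binary substitution,
    ``2**(2(K_I-1)) * sum(H) - 2**(K_I-1) * sum(d)``, is accumulated into
    ``constant_offset`` together with the incoming QP offset, so QUBO and QP
    energies agree exactly on decoded states.
    """
    k = scheme.total_bits
    wts = scheme.weights  # 2**(-j), MSB first
    n = qp.n_unknowns
    c = scheme.offset  # 2**(K_I - 1)

    full = np.kron(qp.h, np.outer(wts, wts))
    # Fold into upper-triangular storage (diagonal handled below).
    tri = np.triu(full, 1) + np.tril(full, -1).T

    row_sums = qp.h.sum(axis=1) + qp.h.sum(axis=0)  # sum_k (H_uk + H_ku)
    diag = (
        np.repeat(np.diag(qp.h), k) * np.tile(wts, n) ** 2
        + np.repeat(qp.d, k) * np.tile(wts, n)
        - c * np.repeat(row_sums, k) * np.tile(wts, n)
    )
    np.fill_diagonal(tri, diag)

    offset = float(c * c * qp.h.sum() - c * qp.d.sum()) + qp.constant_offset
    index_map = [
        (eq, grid, int(j))
        for (eq, grid) in qp.labels
        for j in scheme.bit_positions
    ]
    return QUBOProblem(q=tri, constant_offset=offset, scheme=scheme, index_map=index_map)


def qubo_energy(
    qubo: QUBOProblem, bits: np.ndarray, include_offset: bool = False
) -> float:
    """Evaluate eps(q) = q^T Q q, optionally adding the constant offset."""
    b = np.asarray(bits, dtype=float).ravel()
    if b.shape != (qubo.n_bits,):
        raise ValueError(f"expected {qubo.n_bits} bits, got shape {b.shape}")
    val = float(b @ qubo.q @ b)
    return val + qubo.constant_offset if include_offset else val


def decode_solution(bits: np.ndarray, qubo: QUBOProblem) -> np.ndarray:
    """Decode concatenated bit vectors back to the continuous unknowns."""
    b = np.asarray(bits).ravel()
    if b.shape != (qubo.n_bits,):
        raise ValueError(f"expected {qubo.n_bits} bits, got shape {b.shape}")
    k = qubo.scheme.total_bits
    return np.array(
        [decode(b[u * k:(u + 1) * k], qubo.scheme) for u in range(qubo.n_unknowns)]
    )


def export_qubo(qubo: QUBOProblem, coo_path, map_path=None) -> None:
    """Write Q as a plain-text coordinate list plus a JSON bit-index map.

    Header comment lines record the scheme and the constant offset; data lines
    are ``row col coefficient`` for the non-zero upper-triangular entries.
    """
    lines = [
        f"# qubode QUBO coordinate list, upper-triangular",
        f"# n_bits {qubo.n_bits}",
        f"# scheme k_int {qubo.scheme.k_int} k_frac {qubo.scheme.k_frac}",
        f"# constant_offset {float(qubo.constant_offset)!r}",
        f"# bit order per variable: most-significant (j = -K_I+1) first",
    ]
    rows, cols = np.nonzero(qubo.q)
    for r, cc in zip(rows, cols):
        lines.append(f"{r} {cc} {float(qubo.q[r, cc])!r}")
    with open(coo_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if map_path is not None:
        meta = {
            "k_int": qubo.scheme.k_int,
            "k_frac": qubo.scheme.k_frac,
            "constant_offset": qubo.constant_offset,
            "index_map": [list(t) for t in qubo.index_map],
        }
        with open(map_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def import_qubo(coo_path, map_path=None) -> QUBOProblem:
    """Read back a QUBO written by :func:`export_qubo` (exact round trip)."""
    n_bits = None
    k_int = k_frac = None
    offset = 0.0
    entries = []
    with open(coo_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                toks = line[1:].split()
                if toks[:1] == ["n_bits"]:
                    n_bits = int(toks[1])
                elif toks[:1] == ["scheme"]:
                    k_int, k_frac = int(toks[2]), int(toks[4])
                elif toks[:1] == ["constant_offset"]:
                    offset = float(toks[1])
                continue
            r, cc, v = line.split()
            entries.append((int(r), int(cc), float(v)))
    if n_bits is None or k_int is None:
        raise ValueError(f"{coo_path}: missing header lines")
    q = np.zeros((n_bits, n_bits))
    for r, cc, v in entries:
        q[r, cc] = v
    scheme = FixedPointScheme(k_int, k_frac)
    if map_path is not None:
        with open(map_path) as fh:
            meta = json.load(fh)
        index_map = [tuple(t) for t in meta["index_map"]]
    else:
        k = scheme.total_bits
        index_map = [
            (0, u + 1, int(j))
            for u in range(n_bits // k)
            for j in scheme.bit_positions
        ]
    return QUBOProblem(q=q, constant_offset=offset, scheme=scheme, index_map=index_map)
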
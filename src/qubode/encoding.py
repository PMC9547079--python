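"""Signed fixed-point binary encoding of continuous variables.

A real value is represented with ``K = K_I + K_D`` bits as

    y = -2**(K_I - 1) + sum_{j = -K_I+1}^{K_D} 2**(-j) * q_j,   q_j in {0, 1},

i.e. an unsigned weighted bit sum shifted by a constant offset so that the
representable interval is roughly symmetric about zero.  ``K_I`` bits carry the
integer part (including the sign offset), ``K_D`` bits the fractional part.
The scheme covers ``[-2**(K_I-1), 2**(K_I-1) - 2**(-K_D)]`` on a uniform grid
of spacing ``2**(-K_D)``, so nearest rounding incurs an error of at most
``2**(-K_D-1)``.

This representation is deliberately *fixed*-point: the decoded value is linear
in the bits, which keeps any quadratic functional of the continuous variables
quadratic in the bits — the property a QUBO compilation relies on.  A
floating-point layout (mantissa times 2**exponent) would be polynomial of
higher degree in the bits and is out of scope.

Bit order everywhere in this package is most-significant first: position 0
holds the ``j = -K_I+1`` bit (weight ``2**(K_I-1)``), position ``K-1`` holds
the ``j = K_D`` bit (weight ``2**(-K_D)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FixedPointScheme",
    "EncodingRangeError",
    "decode",
    "encode",
    "representable_range",
    "variables_per_budget",
    "bits_to_string",
    "bits_from_string",
]


class EncodingRangeError(ValueError):
    """Raised when a value cannot be represented by the scheme.

    Out-of-range values are a hard error, never clamped: a silently clamped
    coordinate or momentum would corrupt a trajectory invisibly.
    """


@dataclass(frozen=True)
class FixedPointScheme:
    """Bit budget of one encoded variable.

    Parameters
    ----------
    k_int : int
        Number of integer bits ``K_I`` (>= 1; the leading bit doubles as the
        sign offset).
    k_frac : int
        Number of fractional bits ``K_D`` (>= 0).
    """

    k_int: int
    k_frac: int

    def __post_init__(self) -> None:
        if self.k_int < 1:
            raise ValueError(f"k_int must be >= 1, got {self.k_int}")
        if self.k_frac < 0:
            raise ValueError(f"k_frac must be >= 0, got {self.k_frac}")

    @property
    def total_bits(self) -> int:
        """K = K_I + K_D, bits (qubits) per encoded variable."""
        return self.k_int + self.k_frac

    @property
    def offset(self) -> float:
        """The constant shift 2**(K_I - 1) subtracted from the bit sum."""
        return 2.0 ** (self.k_int - 1)

    @property
    def bit_positions(self) -> np.ndarray:
        """Exponent index j for each bit, MSB first: -K_I+1 ... K_D."""
        return np.arange(-self.k_int + 1, self.k_frac + 1)

    @property
    def weights(self) -> np.ndarray:
        """Bit weights 2**(-j), MSB first: 2**(K_I-1) ... 2**(-K_D)."""
        return 2.0 ** (-self.bit_positions.astype(float))

    @property
    def resolution(self) -> float:
        """Grid spacing of representable values, 2**(-K_D)."""
        return 2.0 ** (-self.k_frac)

    @property
    def max_rounding_error(self) -> float:
        """Half the grid spacing, 2**(-K_D-1)."""
        return 2.0 ** (-self.k_frac - 1)

    @property
    def min_value(self) -> float:
        return -self.offset

    @property
    def max_value(self) -> float:
        """Largest exactly representable value, 2**(K_I-1) - 2**(-K_D)."""
        return self.offset - self.resolution


def representable_range(scheme: FixedPointScheme) -> tuple[float, float, float]:
    """Return ``(min, max, max_rounding_error)`` of the scheme.

    ``min`` and ``max`` are the smallest/largest exactly representable values;
    nearest rounding of any value in between errs by at most the third entry.
    """
    return scheme.min_value, scheme.max_value, scheme.max_rounding_error


def decode(bits: np.ndarray, scheme: FixedPointScheme) -> float:
    """Decode a bit vector (MSB first) into its continuous value."""
    bits = np.asarray(bits)
    if bits.shape != (scheme.total_bits,):
        raise ValueError(
            f"expected {scheme.total_bits} bits, got shape {bits.shape}"
        )
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("bits must be 0 or 1")
    return float(-scheme.offset + scheme.weights @ bits.astype(float))


def encode(value: float, scheme: FixedPointScheme) -> np.ndarray:
    """Encode a value as the nearest representable bit vector (MSB first).

    Rounds to nearest with ties toward +inf, which attains the half-step error
    bound ``2**(-K_D-1)``.  Values farther than half a step outside the
    representable interval raise :class:`EncodingRangeError`.
    """
    value = float(value)
    if not np.isfinite(value):
        raise EncodingRangeError(f"cannot encode non-finite value {value!r}")
    scaled = (value + scheme.offset) * 2.0**scheme.k_frac
    level = int(np.floor(scaled + 0.5))  # ties toward +inf
    if level < 0 or level > 2**scheme.total_bits - 1:
        lo, hi, _ = representable_range(scheme)
        raise EncodingRangeError(
            f"value {value} outside representable range [{lo}, {hi}] "
            f"of scheme (K_I={scheme.k_int}, K_D={scheme.k_frac})"
        )
    k = scheme.total_bits
    return np.array([(level >> (k - 1 - pos)) & 1 for pos in range(k)], dtype=np.uint8)


def variables_per_budget(scheme: FixedPointScheme, logical_qubits: int) -> int:
    """How many encoded variables fit into a fully-connected qubit budget.

    Each continuous unknown consumes ``K_I + K_D`` fully connected logical
    qubits, so an annealer exposing ``logical_qubits`` of them can carry this
    many simultaneous one-step equations.
    """
    if logical_qubits < 0:
        raise ValueError("logical_qubits must be non-negative")
    return logical_qubits // scheme.total_bits


def bits_to_string(bits: np.ndarray) -> str:
    """Serialize a bit vector as a 0/1 string, most-significant bit first."""
    return "".join(str(int(b)) for b in np.asarray(bits).ravel())


def bits_from_string(s: str) -> np.ndarray:
    if set(s) - {"0", "1"}:
        raise ValueError(f"invalid bit string {s!r}")
    return np.array([int(c) for c in s], dtype=np.uint8)
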
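"""Signed fixed-point (Q-format) arithmetic emulation.

This module emulates the datapath word of a multiplierless digital neuron:
a two's-complement fixed-point number with ``int_bits`` integer bits
(including the sign) and ``frac_bits`` fraction bits.  The default Q8.8
word (16 bits, ulp ``2**-8``) is the one the hardware design uses for
every variable and constant.

Two semantics are deliberately hardware-like rather than numerically nice:

* conversion from a real number **truncates toward -inf** (the behaviour of
  an arithmetic right shift), it does not round;
* overflow **saturates** at the format limits instead of wrapping, and
  saturation events can be counted by passing a :class:`SatCounter`.

Scalar values are wrapped in the immutable :class:`QValue`; simulators that
need speed operate on raw int64 mantissa arrays through the ``*_array``
helpers, which implement the same semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "QFormat",
    "QValue",
    "Q8_8",
    "SatCounter",
    "quantize",
    "q_add",
    "q_sub",
    "q_neg",
    "q_shift",
    "quantize_array",
    "saturate_array",
    "shift_array",
    "ShiftAddConstant",
]


@dataclass(frozen=True)
class QFormat:
    """A signed fixed-point format: ``int_bits`` integer (incl. sign) + ``frac_bits`` fraction bits."""

    int_bits: int = 8
    frac_bits: int = 8

    def __post_init__(self) -> None:
        if self.int_bits < 1:
            raise ValueError("int_bits must be >= 1 (sign bit)")
        if self.frac_bits < 0:
            raise ValueError("frac_bits must be >= 0")
        if self.total_bits > 64:
            raise ValueError("formats wider than 64 bits are not supported")

    @property
    def total_bits(self) -> int:
        return self.int_bits + self.frac_bits

    @property
    def scale(self) -> int:
        """Mantissa units per 1.0, i.e. ``2**frac_bits``."""
        return 1 << self.frac_bits

    @property
    def raw_min(self) -> int:
        return -(1 << (self.total_bits - 1))

    @property
    def raw_max(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def min_value(self) -> float:
        return self.raw_min / self.scale

    @property
    def max_value(self) -> float:
        return self.raw_max / self.scale

    @property
    def ulp(self) -> float:
        return 1.0 / self.scale

    def __str__(self) -> str:  # e.g. "Q8.8"
        return f"Q{self.int_bits}.{self.frac_bits}"


#: The 16-bit word used throughout the hardware emulation.
Q8_8 = QFormat(8, 8)


class SatCounter:
    """Counts saturation events in a fixed-point computation."""

    def __init__(self) -> None:
        self.count = 0

    def add(self, n: int) -> None:
        self.count += int(n)


@dataclass(frozen=True)
class QValue:
    """A fixed-point number: ``value = raw * 2**-frac_bits``."""

    raw: int
    fmt: QFormat = Q8_8

    def __post_init__(self) -> None:
        if not (self.fmt.raw_min <= self.raw <= self.fmt.raw_max):
            raise ValueError(
                f"raw mantissa {self.raw} outside {self.fmt} range "
                f"[{self.fmt.raw_min}, {self.fmt.raw_max}]"
            )

    @property
    def value(self) -> float:
        return self.raw / self.fmt.scale

    def __float__(self) -> float:
        return self.value

    def __repr__(self) -> str:
        return f"QValue({self.value!r} [{self.raw} {self.fmt}])"


def _sat_raw(raw: int, fmt: QFormat, counter: SatCounter | None = None) -> int:
    if raw > fmt.raw_max:
        if counter is not None:
            counter.add(1)
        return fmt.raw_max
    if raw < fmt.raw_min:
        if counter is not None:
            counter.add(1)
        return fmt.raw_min
    return raw


def quantize(x: float, fmt: QFormat = Q8_8, counter: SatCounter | None = None) -> QValue:
    """Convert a real number to the nearest-below representable value.

    Truncates ``x * 2**frac_bits`` toward -inf and saturates to the format
    range.  Raises :class:`ValueError` for non-finite input.
    """
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"cannot quantize non-finite value {x!r}")
    raw = math.floor(x * fmt.scale)
    return QValue(_sat_raw(raw, fmt, counter), fmt)


def _check_fmt(a: QValue, b: QValue) -> QFormat:
    if a.fmt != b.fmt:
        raise ValueError(f"format mismatch: {a.fmt} vs {b.fmt}")
    return a.fmt


def q_add(a: QValue, b: QValue, counter: SatCounter | None = None) -> QValue:
    """Exact mantissa addition, saturated to the common format."""
    fmt = _check_fmt(a, b)
    return QValue(_sat_raw(a.raw + b.raw, fmt, counter), fmt)


def q_sub(a: QValue, b: QValue, counter: SatCounter | None = None) -> QValue:
    fmt = _check_fmt(a, b)
    return QValue(_sat_raw(a.raw - b.raw, fmt, counter), fmt)


def q_neg(a: QValue, counter: SatCounter | None = None) -> QValue:
    return QValue(_sat_raw(-a.raw, a.fmt, counter), a.fmt)


def q_shift(a: QValue, k: int, counter: SatCounter | None = None) -> QValue:
    """Arithmetic shift by ``k`` bits (``k > 0`` left, ``k < 0`` right).

    Right shifts truncate toward -inf (Python's ``>>`` on negative ints);
    left shifts saturate on overflow.
    """
    if abs(k) > a.fmt.total_bits:
        raise ValueError(f"|k| must be <= total width {a.fmt.total_bits}")
    if k >= 0:
        raw = a.raw << k
    else:
        raw = a.raw >> (-k)
    return QValue(_sat_raw(raw, a.fmt, counter), a.fmt)


# ---------------------------------------------------------------------------
# Array (raw-mantissa) helpers for the bit-accurate simulators.
# ---------------------------------------------------------------------------

def saturate_array(raw: np.ndarray, fmt: QFormat, counter: SatCounter | None = None) -> np.ndarray:
    """Clip an int64 mantissa array to the format range, counting saturations."""
    if counter is not None:
        counter.add(int(np.count_nonzero((raw > fmt.raw_max) | (raw < fmt.raw_min))))
    return np.clip(raw, fmt.raw_min, fmt.raw_max)


def quantize_array(x: np.ndarray, fmt: QFormat = Q8_8, counter: SatCounter | None = None) -> np.ndarray:
    """Vectorized :func:`quantize`: returns int64 raw mantissas."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot quantize non-finite values")
    raw = np.floor(x * fmt.scale).astype(np.int64)
    return saturate_array(raw, fmt, counter)


def shift_array(raw: np.ndarray, k: int, fmt: QFormat, counter: SatCounter | None = None) -> np.ndarray:
    """Arithmetic shift of int64 mantissas (floor semantics for right shifts)."""
    raw = np.asarray(raw, dtype=np.int64)
    if k >= 0:
        return saturate_array(raw << k, fmt, counter)
    return raw >> (-k)  # numpy >> on int64 is arithmetic: truncates toward -inf


# ---------------------------------------------------------------------------
# Shift-add decomposition of fractional constants.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftAddConstant:
    """A constant realized as a signed sum of powers of two, applied by shifts.

    ``terms`` is a tuple of ``(sign, k)`` pairs meaning ``sign * 2**-k``; a
    multiplication by the constant becomes ``sum(sign * (x >> k))`` in the
    fixed-point datapath.  Decomposition error is kept below half a Q8.8 ulp
    so the constant multiplies of the neuron update (a, b/T, 1/T, 1/3) do
    not dominate the word-length error.
    """

    terms: tuple[tuple[int, int], ...]

    @property
    def value(self) -> float:
        return sum(s * 2.0 ** -k for s, k in self.terms)

    @classmethod
    def decompose(cls, c: float, tol: float = 2.0 ** -9, max_terms: int = 10) -> "ShiftAddConstant":
        """Greedy signed power-of-two recoding of ``c`` to within ``tol``."""
        if not math.isfinite(c):
            raise ValueError("constant must be finite")
        terms: list[tuple[int, int]] = []
        r = float(c)
        while abs(r) >= tol and len(terms) < max_terms:
            k = int(round(-math.log2(abs(r))))
            # round() of the exponent picks the closest power of two
            s = 1 if r > 0 else -1
            terms.append((s, k))
            r -= s * 2.0 ** -k
        return cls(tuple(terms))

    def apply_float(self, x):
        """Multiply by the decomposed constant using exact power-of-two scalings."""
        out = 0.0
        for s, k in self.terms:
            out = out + s * (x * 2.0 ** -k)
        return out

    def apply_raw(self, raw: np.ndarray, fmt: QFormat, counter: SatCounter | None = None) -> np.ndarray:
        """Fixed-point multiply: signed sum of arithmetic right shifts of ``raw``."""
        raw = np.asarray(raw, dtype=np.int64)
        out = np.zeros_like(raw)
        for s, k in self.terms:
            out = out + s * shift_array(raw, -k, fmt, counter)
        return saturate_array(out, fmt, counter)

    def __str__(self) -> str:
        return " ".join(f"{'+' if s > 0 else '-'}2^-{k}" for s, k in self.terms) or "0"
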
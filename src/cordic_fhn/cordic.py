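"""Linear-mode CORDIC multiplication and the two-stage CORDIC cube.

A product ``x*y`` is computed with shifts, adds and sign tests only: the
multiplier ``y`` is greedily recoded as a signed sum of powers of two
``sum(mu_i * 2**-i)`` over a schedule of shift indices, and the same signed
shifts of ``x`` are accumulated into the product ``z``.  At every step the
quantity ``z + x*y`` is conserved (up to backend quantization), so the
final result is ``x*(y - r)`` with a residual ``|r| <= 2**-i_max``.

The cubic nonlinearity of the FitzHugh-Nagumo neuron is replaced by two
chained CORDIC multiplies, ``(V*V)*V``; with the default 16-step schedule
(shift indices -7..+8) each stage contributes at most ``|x| * 2**-8`` of
error over the membrane range ``[-2, 2]``.

Backends:

* **real** — binary floating point; scaling by ``2.0**-i`` is exact, so it
  reproduces the shift-add arithmetic without word-length effects;
* **fixed** — Q-format mantissa arithmetic (see :mod:`cordic_fhn.qformat`)
  with truncation toward -inf after every shift, matching the 16-bit
  datapath.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .qformat import Q8_8, QFormat, QValue, SatCounter, quantize_array, saturate_array

__all__ = [
    "CordicSchedule",
    "DEFAULT_SCHEDULE",
    "symmetric_schedule",
    "cordic_multiply",
    "cordic_cube",
    "cube_error_sweep",
]


@dataclass(frozen=True)
class CordicSchedule:
    """The iteration window of the linear-mode multiplier.

    Step ``i`` applies a shift of magnitude ``2**-i``; the window runs from
    the coarsest index ``i_min`` (negative = left shifts) to the finest
    ``i_max``.  The default -7..+8 window is 16 iterations and converges for
    any multiplier with ``|y| <= 2**8 - 2**-8``.
    """

    i_min: int = -7
    i_max: int = 8

    def __post_init__(self) -> None:
        if self.i_min >= self.i_max:
            raise ValueError("i_min must be < i_max")

    @property
    def n(self) -> int:
        return self.i_max - self.i_min + 1

    @property
    def indices(self) -> range:
        return range(self.i_min, self.i_max + 1)

    @property
    def convergence_bound(self) -> float:
        """Largest ``|y|`` the signed recoding can drive to the residual bound."""
        return 2.0 ** (-self.i_min + 1) - 2.0 ** -self.i_max

    @property
    def residual_bound(self) -> float:
        return 2.0 ** -self.i_max


DEFAULT_SCHEDULE = CordicSchedule()


def symmetric_schedule(n: int) -> CordicSchedule:
    """The ``n``-iteration window centred like the default one.

    ``i_min = -(n/2 - 1)``, ``i_max = +n/2`` — at ``n = 16`` this is the
    default -7..+8 window, and each +2 iterations adds one finer shift
    (halving the worst-case residual) and one coarser shift.
    """
    if n < 4 or n % 2:
        raise ValueError("iteration count must be an even integer >= 4")
    return CordicSchedule(-(n // 2 - 1), n // 2)


def _check_domain(y, sched: CordicSchedule) -> None:
    bound = sched.convergence_bound
    ymax = float(np.max(np.abs(y))) if np.ndim(y) else abs(float(y))
    if ymax > bound:
        raise ValueError(
            f"multiplier magnitude {ymax} outside the convergence domain "
            f"|y| <= {bound} of schedule {sched.i_min}..{sched.i_max}"
        )


def _multiply_real(x, y, sched: CordicSchedule):
    """Float backend: vectorized over numpy arrays; shifts are exact scalings."""
    x = np.asarray(x, dtype=float)
    y = np.array(y, dtype=float, copy=True)
    _check_domain(y, sched)
    z = np.zeros(np.broadcast(x, y).shape)
    y = np.broadcast_to(y, z.shape).copy()
    for i in sched.indices:
        d = 2.0 ** -i
        mu = np.sign(y)
        y -= mu * d
        z += mu * (x * d)
    return z if z.shape else float(z)


def _multiply_fixed_raw(
    x_raw: np.ndarray,
    y_raw: np.ndarray,
    fmt: QFormat,
    sched: CordicSchedule,
    counter: SatCounter | None = None,
) -> np.ndarray:
    """Fixed backend on int64 mantissas: every step shift+add+sign test.

    Right shifts of ``x`` truncate toward -inf (the word-length error
    source); the ``y``/``z`` accumulators carry guard bits (wide integers),
    because the plain-sign direction rule takes the coarse steps even for
    small multipliers and the transient partial sums exceed the output
    word.  Only the final product is saturated to the format.
    """
    x_raw = np.asarray(x_raw, dtype=np.int64)
    y = np.array(np.broadcast_to(y_raw, np.broadcast(x_raw, y_raw).shape), dtype=np.int64)
    _check_domain(y / fmt.scale, sched)
    z = np.zeros_like(y)
    for i in sched.indices:
        d_raw = fmt.scale >> i if i >= 0 else fmt.scale << (-i)
        if d_raw == 0:
            break  # shift finer than the word's ulp: contributes nothing
        mu = np.sign(y)
        y = y - mu * d_raw
        xd = x_raw >> i if i >= 0 else x_raw << (-i)  # arithmetic, truncates toward -inf
        z = z + mu * xd
    return saturate_array(z, fmt, counter)


def cordic_multiply(x, y, sched: CordicSchedule = DEFAULT_SCHEDULE):
    """Shift-add product ``z = x*(y - r)``, ``|r| <= 2**-i_max``.

    Accepts floats/arrays (real backend) or a pair of :class:`QValue` with a
    common format (fixed backend, returns a :class:`QValue`).
    """
    if isinstance(x, QValue) or isinstance(y, QValue):
        if not (isinstance(x, QValue) and isinstance(y, QValue)):
            raise TypeError("fixed backend needs both operands as QValue")
        if x.fmt != y.fmt:
            raise ValueError(f"format mismatch: {x.fmt} vs {y.fmt}")
        raw = _multiply_fixed_raw(np.int64(x.raw), np.int64(y.raw), x.fmt, sched)
        return QValue(int(raw), x.fmt)
    return _multiply_real(x, y, sched)


def cordic_cube(V, sched: CordicSchedule = DEFAULT_SCHEDULE):
    """Two-stage CORDIC approximation of ``V**3``: stage 1 = V*V, stage 2 = (V*V)*V.

    Each stage runs the full schedule, so the default cube costs 32
    iterations in total.
    """
    if isinstance(V, QValue):
        sq = cordic_multiply(V, V, sched)
        return cordic_multiply(sq, V, sched)
    sq = _multiply_real(V, V, sched)
    return _multiply_real(sq, V, sched)


def cube_fixed_raw(
    v_raw: np.ndarray,
    fmt: QFormat = Q8_8,
    sched: CordicSchedule = DEFAULT_SCHEDULE,
    counter: SatCounter | None = None,
) -> np.ndarray:
    """Vectorized fixed-backend cube on raw mantissas (simulator building block)."""
    sq = _multiply_fixed_raw(v_raw, v_raw, fmt, sched, counter)
    return _multiply_fixed_raw(sq, v_raw, fmt, sched, counter)


def cube_error_sweep(
    iteration_counts: Sequence[int],
    grid_step: float = 1.0 / 400.0,
    v_range: tuple[float, float] = (-2.0, 2.0),
    backend: str = "real",
    fmt: QFormat = Q8_8,
    norm: float = 8.0,
) -> pd.DataFrame:
    """Cube approximation error versus iteration count.

    For each even count ``n`` the symmetric ``n``-step window is used for
    both stages and ``|cube(V) - V**3|`` is averaged over a uniform grid on
    ``v_range``.  Returns a frame with columns ``n_iter, mae, max_err,
    nrmse`` where ``nrmse = rmse / norm`` (the normalization constant is
    configurable; the hardware literature normalizes the cube's error by 8).

    The default grid step is deliberately not a power of two: on a
    2**-8-aligned lattice the float-backend recoding terminates exactly and
    the sweep degenerates to zero for fine schedules.
    """
    lo, hi = v_range
    if not hi > lo:
        raise ValueError("empty evaluation grid")
    V = np.arange(lo, hi + grid_step / 2, grid_step)
    if V.size == 0:
        raise ValueError("empty evaluation grid")
    exact = V ** 3
    rows = []
    for n in iteration_counts:
        sched = symmetric_schedule(int(n))
        if backend == "real":
            approx = cordic_cube(V, sched)
        elif backend == "fixed":
            approx = cube_fixed_raw(quantize_array(V, fmt), fmt, sched) / fmt.scale
        else:
            raise ValueError(f"unknown backend {backend!r}")
        err = approx - exact
        rows.append(
            {
                "n_iter": int(n),
                "mae": float(np.mean(np.abs(err))),
                "max_err": float(np.max(np.abs(err))),
                "nrmse": float(np.sqrt(np.mean(err ** 2)) / norm),
            }
        )
    return pd.DataFrame(rows).sort_values("n_iter", ascending=False).reset_index(drop=True)
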
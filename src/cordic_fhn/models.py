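"""The FitzHugh-Nagumo neuron and its multiplierless CORDIC variant.

Original model (dimensionless)::

    dV/dt = V - V^3/3 - W + I(t)
    dW/dt = (a - b*W + V) / T

with membrane potential ``V``, recovery variable ``W`` and drive ``I``
(constant or sinusoidal).  The CORDIC variant replaces ``V^3`` by the
two-stage shift-add cube of :mod:`cordic_fhn.cordic`; everything else is
unchanged.

Defaults are ``a = 0.7``, ``b = 0.8``, ``T = 12.5``: the classical
parameterisation, and the one consistent with the published equilibrium
table (its Jacobian entry ``D = -b/T = -0.064`` pins ``b = 0.8``).  The
swapped assignment that appears in parts of the hardware literature is
available by constructing :class:`FHNParams` explicitly.

Simulators
----------
* :func:`simulate_continuous` — adaptive RK45 (dense output), the
  reference for dynamical analysis;
* :func:`simulate_discrete` — forward Euler with ``dt = 2**-5`` (the power
  of two makes the step multiply a 5-bit right shift), in a ``real``
  (float) or ``fixed`` (bit-accurate Q8.8) backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels
from .cordic import DEFAULT_SCHEDULE, CordicSchedule, cordic_cube  # noqa: F401
from .qformat import Q8_8, QFormat, ShiftAddConstant, quantize

__all__ = [
    "FHNParams",
    "DriveSpec",
    "Trajectory",
    "fhn_rhs",
    "cordic_fhn_rhs",
    "simulate_continuous",
    "simulate_discrete",
    "detect_spikes",
]


@dataclass(frozen=True)
class FHNParams:
    """Model constants: recovery offset ``a``, gain ``b``, time constant ``T``, Euler step ``dt``."""

    a: float = 0.7
    b: float = 0.8
    T: float = 12.5
    dt: float = 2.0 ** -5

    def __post_init__(self) -> None:
        if self.T <= 0 or self.dt <= 0:
            raise ValueError("T and dt must be positive")


@dataclass(frozen=True)
class DriveSpec:
    """Input current: ``I_in`` (constant) or ``I_in * sin(2*pi*f*t)`` (sinusoid)."""

    kind: str = "constant"
    I_in: float = 0.5
    f: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid"):
            raise ValueError(f"unknown drive kind {self.kind!r}")

    @classmethod
    def constant(cls, I_in: float) -> "DriveSpec":
        return cls("constant", I_in, 0.0)

    @classmethod
    def sinusoid(cls, I_in: float, f: float) -> "DriveSpec":
        return cls("sinusoid", I_in, f)

    @property
    def is_sin(self) -> bool:
        return self.kind == "sinusoid"

    def current(self, t):
        if self.is_sin:
            return self.I_in * np.sin(2.0 * np.pi * self.f * t)
        return self.I_in if np.ndim(t) == 0 else np.full(np.shape(t), self.I_in)


@dataclass
class Trajectory:
    """A time-indexed (V, W) series with full provenance in ``meta``."""

    t: np.ndarray
    V: np.ndarray
    W: np.ndarray
    meta: dict = field(default_factory=dict)
    V_raw: np.ndarray | None = None
    W_raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.V) == len(self.W)):
            raise ValueError("t, V, W must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t, "V": self.V, "W": self.W}
        if self.V_raw is not None:
            cols["V_raw"] = self.V_raw
            cols["W_raw"] = self.W_raw
        return pd.DataFrame(cols)


def _validate_model(model: str) -> bool:
    if model not in ("fhn", "cordic"):
        raise ValueError(f"model must be 'fhn' or 'cordic', got {model!r}")
    return model == "cordic"


def fhn_rhs(V, W, params: FHNParams, I):
    """Right-hand side of the original model; vectorized."""
    dV = V - (V * V * V) / 3.0 - W + I
    dW = (params.a - params.b * W + V) / params.T
    return dV, dW


def cordic_fhn_rhs(V, W, params: FHNParams, I, sched: CordicSchedule = DEFAULT_SCHEDULE):
    """Right-hand side with the cubic replaced by the two-stage CORDIC cube."""
    if np.ndim(V) == 0:
        nl = _kernels.cube_cordic(float(V), sched.i_min, sched.i_max)
    else:
        nl = cordic_cube(np.asarray(V, dtype=float), sched)
    dV = V - nl / 3.0 - W + I
    dW = (params.a - params.b * W + V) / params.T
    return dV, dW


def make_rhs(model: str, params: FHNParams, sched: CordicSchedule = DEFAULT_SCHEDULE) -> Callable:
    """A ``f(V, W, I) -> (dV, dW)`` closure for the chosen model."""
    if _validate_model(model):
        return lambda V, W, I: cordic_fhn_rhs(V, W, params, I, sched)
    return lambda V, W, I: fhn_rhs(V, W, params, I)


def simulate_continuous(
    model: str,
    params: FHNParams = FHNParams(),
    drive: DriveSpec = DriveSpec(),
    t_span: float = 1000.0,
    init: tuple[float, float] = (0.0, 0.0),
    rtol: float | None = None,
    atol: float | None = None,
    t_step: float = 0.05,
    sched: CordicSchedule = DEFAULT_SCHEDULE,
) -> Trajectory:
    """Adaptive RK45 solution sampled on a uniform output grid.

    Default tolerances are tight (1e-8/1e-10) for the smooth original
    model.  The CORDIC model's right-hand side is a staircase, so an
    embedded pair's error estimate near a step is O(h * jump) and tight
    tolerances stall the controller; its defaults are 1e-4/1e-7, which
    resolves the trajectory to well below the staircase amplitude.
    """
    use_cordic = _validate_model(model)
    if t_span < 0:
        raise ValueError("t_span must be >= 0")
    if t_span == 0.0:
        t = np.array([0.0])
        return Trajectory(
            t, np.array([init[0]]), np.array([init[1]]),
            meta=_meta(model, "continuous", params, drive, sched),
        )
    if rtol is None:
        rtol = 1e-4 if use_cordic else 1e-8
    if atol is None:
        atol = 1e-7 if use_cordic else 1e-10
    i_min, i_max = sched.i_min, sched.i_max
    a, b, T = params.a, params.b, params.T
    I_in, f, is_sin = drive.I_in, drive.f, drive.is_sin

    def rhs(t, y):
        V, W = y
        I = I_in * math.sin(2.0 * math.pi * f * t) if is_sin else I_in
        if use_cordic:
            nl = _kernels.cube_cordic(V, i_min, i_max)
        else:
            nl = V * V * V
        return (V - nl / 3.0 - W + I, (a - b * W + V) / T)

    t_eval = np.arange(0.0, t_span + t_step / 2, t_step)
    sol = solve_ivp(rhs, (0.0, t_span), list(init), method="RK45",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"solver failed: {sol.message}")
    meta = _meta(model, "continuous", params, drive, sched, rtol=rtol, atol=atol)
    return Trajectory(sol.t, sol.y[0], sol.y[1], meta=meta)


# shift-add recodings of the fixed-datapath constants (reported in meta)
_INV3 = ShiftAddConstant.decompose(1.0 / 3.0)


def _fixed_constants(params: FHNParams):
    b_c = ShiftAddConstant.decompose(params.b)
    invT_c = ShiftAddConstant.decompose(1.0 / params.T)
    return _INV3, b_c, invT_c


def simulate_discrete(
    model: str,
    params: FHNParams = FHNParams(),
    drive: DriveSpec = DriveSpec(),
    n_steps: int = 32000,
    backend: str = "real",
    init: tuple[float, float] = (0.0, 0.0),
    sched: CordicSchedule = DEFAULT_SCHEDULE,
    fmt: QFormat = Q8_8,
    guard_bits: int = 8,
) -> Trajectory:
    """Forward-Euler simulation in the real or bit-accurate fixed backend.

    In the fixed backend every datapath signal is a truncated Q8.8 word
    and constant multiplies are shift-add recodings; the two state
    registers carry ``guard_bits`` extra fraction bits because the
    ``dt = 2**-5`` right shift makes typical per-step increments smaller
    than one word ulp (a plain word accumulator deadbands at a spurious
    rest state).  The recorded V, W samples are the truncated word values.
    """
    use_cordic = _validate_model(model)
    if backend not in ("real", "fixed"):
        raise ValueError(f"backend must be 'real' or 'fixed', got {backend!r}")
    dt = params.dt
    t = np.arange(n_steps + 1) * dt
    if backend == "real":
        V, W = _kernels.euler_traj(
            use_cordic, params.a, params.b, params.T, dt,
            sched.i_min, sched.i_max,
            drive.I_in, drive.f, drive.is_sin, n_steps,
            float(init[0]), float(init[1]),
        )
        return Trajectory(t, V, W, meta=_meta(model, "euler-real", params, drive, sched))
    # fixed backend: dt must be a power of two so the step multiply is a shift
    dt_shift = -math.log2(dt)
    if abs(dt_shift - round(dt_shift)) > 1e-12 or dt_shift < 0:
        raise ValueError("fixed backend requires dt = 2**-k")
    inv3_c, b_c, invT_c = _fixed_constants(params)
    a_raw = quantize(params.a, fmt).raw
    V0_raw = quantize(init[0], fmt).raw
    W0_raw = quantize(init[1], fmt).raw

    def _terms(c: ShiftAddConstant):
        s = np.array([t_[0] for t_ in c.terms], dtype=np.int64)
        k = np.array([t_[1] for t_ in c.terms], dtype=np.int64)
        return s, k

    inv3_s, inv3_k = _terms(inv3_c)
    b_s, b_k = _terms(b_c)
    invT_s, invT_k = _terms(invT_c)
    V_raw, W_raw, n_sat = _kernels.fixed_euler_traj(
        use_cordic, np.int64(a_raw), np.int64(fmt.scale),
        np.int64(fmt.raw_min), np.int64(fmt.raw_max),
        inv3_s, inv3_k, b_s, b_k, invT_s, invT_k,
        int(round(dt_shift)), int(guard_bits), sched.i_min, sched.i_max,
        drive.I_in, drive.f, drive.is_sin, dt, n_steps,
        np.int64(V0_raw), np.int64(W0_raw),
    )
    meta = _meta(model, "euler-fixed", params, drive, sched)
    meta["format"] = str(fmt)
    meta["guard_bits"] = int(guard_bits)
    meta["saturations"] = int(n_sat)
    meta["constants"] = {
        "1/3": str(inv3_c),
        "b": str(b_c),
        "1/T": str(invT_c),
        "dt": f"->> {int(round(dt_shift))}",
    }
    return Trajectory(t, V_raw / fmt.scale, W_raw / fmt.scale, meta=meta,
                      V_raw=V_raw, W_raw=W_raw)


def detect_spikes(t: np.ndarray, V: np.ndarray, threshold: float = 1.0,
                  refractory: float = 5.0) -> np.ndarray:
    """Spike times: upward crossings of ``threshold`` with a refractory gap."""
    t = np.asarray(t)
    V = np.asarray(V)
    idx = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold)) + 1
    times = []
    last = -np.inf
    for i in idx:
        if t[i] - last >= refractory:
            times.append(t[i])
            last = t[i]
    return np.asarray(times)


def _meta(model, backend, params, drive, sched, **extra) -> dict:
    m = {
        "model": model,
        "backend": backend,
        "params": {"a": params.a, "b": params.b, "T": params.T, "dt": params.dt},
        "drive": {"kind": drive.kind, "I_in": drive.I_in, "f": drive.f},
        "schedule": {"i_min": sched.i_min, "i_max": sched.i_max},
    }
    m.update(extra)
    return m
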
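"""Equilibria, Jacobians, stability classes and Hopf scans.

At constant drive the equilibria are the nullcline intersections.  For the
original model this is one real root of a cubic in V (the cubic is
strictly monotone for b < 1, so the root is unique); for the CORDIC model
the staircase nonlinearity is bracketed on a fine grid and bisected.

Stability follows the trace/determinant rules of the 2x2 Jacobian
``J = [[A, B], [C, D]]``:

* ``det < 0`` — saddle;
* ``det > 0, tr < 0`` — stable (node if ``tr^2 >= 4 det`` else spiral);
* ``det > 0, tr > 0`` — unstable node/spiral likewise;
* ``tr == 0, det > 0`` — center/degenerate.

For the original model the Jacobian is analytic: ``A = 1 - V^2``,
``B = -1``, ``C = 1/T``, ``D = -b/T``.  The CORDIC staircase has no
classical derivative, so its Jacobian uses central finite differences with
a step wider than the staircase tread (default ``h = 2**-6``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _kernels
from .cordic import DEFAULT_SCHEDULE, CordicSchedule
from .models import DriveSpec, FHNParams, make_rhs, simulate_discrete

__all__ = [
    "EquilibriumReport",
    "find_equilibria",
    "jacobian_at",
    "classify_equilibrium",
    "hopf_scan",
]


@dataclass(frozen=True)
class EquilibriumReport:
    """A fixed point with its Jacobian, trace/determinant and stability class."""

    V_star: float
    W_star: float
    A: float
    B: float
    C: float
    D: float
    klass: str

    @property
    def trace(self) -> float:
        return self.A + self.D

    @property
    def det(self) -> float:
        return self.A * self.D - self.B * self.C

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(np.array([[self.A, self.B], [self.C, self.D]]))

    @property
    def stable(self) -> bool:
        return self.klass.startswith("stable")


def classify_equilibrium(A: float, B: float, C: float, D: float) -> str:
    """Stability class from the trace/determinant sign rules."""
    tr = A + D
    det = A * D - B * C
    if det < 0:
        return "saddle"
    if det == 0 or tr == 0:
        return "center/degenerate"
    kind = "node" if tr * tr - 4.0 * det >= 0 else "spiral"
    return f"{'stable' if tr < 0 else 'unstable'} {kind}"


def jacobian_at(
    model: str,
    params: FHNParams,
    point: tuple[float, float],
    sched: CordicSchedule = DEFAULT_SCHEDULE,
    h: float = 2.0 ** -6,
) -> tuple[float, float, float, float]:
    """Jacobian entries (A, B, C, D) at a phase-plane point.

    Original model: analytic.  CORDIC model: central differences with step
    ``h`` on the V-equation (the W-equation is linear in both models).
    """
    V, _W = point
    B = -1.0
    C = 1.0 / params.T
    D = -params.b / params.T
    if model == "fhn":
        A = 1.0 - V * V
    else:
        gp = V + h - _kernels.cube_cordic(V + h, sched.i_min, sched.i_max) / 3.0
        gm = V - h - _kernels.cube_cordic(V - h, sched.i_min, sched.i_max) / 3.0
        A = (gp - gm) / (2.0 * h)
    return A, B, C, D


def find_equilibria(
    model: str,
    params: FHNParams = FHNParams(),
    I: float = 0.5,
    sched: CordicSchedule = DEFAULT_SCHEDULE,
    grid_step: float = 2.0 ** -8,
    v_range: tuple[float, float] = (-3.0, 3.0),
) -> list[EquilibriumReport]:
    """All constant-drive fixed points, classified.

    Solves ``V - nl(V)/3 - (a + V)/b + I = 0`` (the V-nullcline meeting the
    W-nullcline ``W = (a + V)/b``): closed-form cubic roots plus polishing
    for the original model, sign-change bracketing + bisection on a
    ``grid_step`` lattice for the staircase model.
    """
    a, b = params.a, params.b
    roots: list[float] = []
    if model == "fhn":
        # -V^3/3 + (1 - 1/b) V + (I - a/b) = 0
        rr = np.roots([-1.0 / 3.0, 0.0, 1.0 - 1.0 / b, I - a / b])
        roots = sorted(float(r.real) for r in rr if abs(r.imag) < 1e-9)
    else:
        def g(V: float) -> float:
            nl = _kernels.cube_cordic(V, sched.i_min, sched.i_max)
            return V - nl / 3.0 - (a + V) / b + I

        grid = np.arange(v_range[0], v_range[1] + grid_step / 2, grid_step)
        vals = np.array([g(v) for v in grid])
        sign = np.sign(vals)
        for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-12))
        roots.extend(float(grid[i]) for i in np.flatnonzero(vals == 0.0))
        roots = sorted(roots)
    reports = []
    for V in roots:
        W = (a + V) / b
        A, B, C, D = jacobian_at(model, params, (V, W), sched)
        reports.append(EquilibriumReport(V, W, A, B, C, D, classify_equilibrium(A, B, C, D)))
    return reports


def hopf_scan(
    model: str,
    params: FHNParams = FHNParams(),
    I_values=np.linspace(0.0, 2.0, 41),
    transient: float = 300.0,
    horizon: float = 600.0,
    sched: CordicSchedule = DEFAULT_SCHEDULE,
) -> pd.DataFrame:
    """Equilibrium branch and post-transient orbit extrema along a drive sweep.

    For each constant drive value the fixed point is solved and a discrete
    trajectory from (0, 0) supplies the orbit's V min/max after the
    transient; where the orbit extrema detach from the equilibrium a limit
    cycle surrounds it.  The returned frame flags the rows where the
    stability class changes.
    """
    I_values = np.asarray(I_values, dtype=float)
    if I_values.size == 0:
        raise ValueError("empty drive sweep")
    if np.any(np.diff(I_values) <= 0):
        raise ValueError("I_range must be strictly increasing")
    dt = params.dt
    n_steps = int(round(horizon / dt))
    k0 = int(round(transient / dt))
    rows = []
    for I in I_values:
        eq = find_equilibria(model, params, I, sched)[0]
        traj = simulate_discrete(model, params, DriveSpec.constant(I), n_steps, sched=sched)
        V_post = traj.V[k0:]
        rows.append(
            {
                "I": I,
                "V_star": eq.V_star,
                "W_star": eq.W_star,
                "klass": eq.klass,
                "stable": eq.stable,
                "V_min": float(V_post.min()),
                "V_max": float(V_post.max()),
            }
        )
    df = pd.DataFrame(rows)
    df["stability_change"] = df["stable"].ne(df["stable"].shift(fill_value=df["stable"].iloc[0]))
    return df
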
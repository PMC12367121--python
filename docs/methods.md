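# Methods

This note records the model, the arithmetic emulation, the numerical
choices and the limits of what the validation suite shows.  Nothing here
states a result that the tests or `scripts/acceptance.py` do not compute.

## Models

The original neuron is the two-variable FitzHugh–Nagumo system

    dV/dt = V − V³/3 − W + I(t)
    dW/dt = (a − b·W + V)/T

with dimensionless `V` (membrane potential), `W` (recovery), and drive
`I(t)` either constant or `I_in·sin(2πf·t)`.  Time is the model's
dimensionless time; the hardware literature labels it in ms and `f` in
Hz, and we carry those labels through metadata without rescaling.

Parameter defaults are `a = 0.7`, `b = 0.8`, `T = 12.5`.  Part of the
hardware literature prints the swapped assignment `a = 0.8, b = 0.7`, but
the same sources print the Jacobian entry `D = −b/T = −0.064`, which
forces `b = 0.8`; with our assignment the published equilibrium table is
reproduced to all four printed decimals (the swapped variant remains
available through `FHNParams`).

The CORDIC neuron replaces `V³` with a two-stage linear-mode CORDIC cube.
Each stage recodes the multiplier greedily over shift indices
`i = i_min … i_max` with step direction `μᵢ = sign(yᵢ)` (a step is skipped
only when the residual is exactly zero).  Any direction rule that
preserves the conservation invariant `zᵢ + x·yᵢ = const` and the residual
bound `|r| ≤ 2^−i_max` is equivalent at the level of the contract; this
one makes `|y|` strictly decrease whenever a step fires, and the tests
freeze it.

## Iteration schedules

The default window is `i_min = −7`, `i_max = +8` (16 iterations per
stage, 32 per cube).  For error-versus-iteration sweeps the window is
varied **symmetrically**: an `n`-step schedule uses
`i_min = −(n/2 − 1), i_max = +n/2`.  Each +2 iterations then adds one
finer and one coarser shift, so the worst-case cube error
`8·2^−(n/2)` — and, empirically, the grid-mean error — halves per +2
iterations, which is exactly the published error-table pattern (the
printed "MAE" column coincides with the worst-case bound, our grid mean
sits below it; the sweep checks the printed values as upper bounds).
Truncating only the fine end instead would quarter the error per +2
iterations and break that pattern.

The sweep grid default is a uniform step of 1/400 over `[−2, 2]`.  The
step is deliberately **not** a power of two: every multiple of `2⁻⁸` in
`[−2, 2]` is exactly recodable by the default window, so on a
`2⁻⁸`-aligned lattice the float-backend cube is error-free for `n ≥ 16`
and the sweep degenerates to zero.  The published nRMSE column implies
normalization by 8 rather than the cube's range 16; we normalize by a
configurable constant (default 8) and treat MAE as the authoritative
column.

## Fixed-point emulation

The datapath word is Q8.8 (16 bits: 8 integer including sign, 8
fraction; ulp `2⁻⁸`).  Conversion truncates toward −∞ (arithmetic-shift
semantics; the hardware's rounding behaviour is unstated, truncation is
assumed), and overflow saturates rather than wraps, with saturation
events counted and reported in trajectory metadata.

Fractional constants (`1/3`, `b`, `1/T`) are realized as greedy signed
power-of-two recodings with decomposition error below `2⁻⁹` (half an
ulp); the chosen shift sets are reported in the trajectory metadata.
`dt = 2⁻⁵` makes the Euler-step multiply a 5-bit right shift.

Inside the CORDIC iteration the `y`/`z` accumulators carry guard bits
(wide integers): the plain-sign direction rule takes the coarse steps
even for small multipliers and the transient partial sums exceed the
output word; only the final product is saturated.  Truncation applies to
the shifted copies of `x`, which is the word-length error source.

The **state registers of the fixed-point integrator carry `guard_bits`
extra fraction bits (default 8)**.  With the step realized as `>> 5`,
typical per-step increments — especially of `W`, whose right-hand side is
of order 0.1 — are below one word ulp; a pure word-width accumulator
truncates them to zero and the neuron deadbands at a spurious rest state
(measured: it freezes and never spikes).  All datapath signals the
accumulators feed (the CORDIC unit, the constant multiplies, the recorded
samples) remain truncated Q8.8 words, so exported trajectories are
exactly representable in the format.

Word-length effects shift the tonic period slightly, so fixed-vs-float
trajectory error is dominated by accumulated spike-phase drift: measured
MAE ≈ 0.09 over 100 time units and ≈ 0.94 over 1000, with identical
spike counts.  The regression test freezes these measured values; a
single-evaluation error bound does not describe a trajectory over many
periods.

## Continuous solver

`simulate_continuous` uses RK45.  For the smooth original model the
tolerances are rtol 1e−8 / atol 1e−10.  The CORDIC right-hand side is a
staircase with jumps of order 1e−2; an embedded pair's error estimate
across a jump is O(h·jump), so tight tolerances drive the step size
toward 1e−7 and stall.  CORDIC-model runs therefore default to rtol 1e−4
/ atol 1e−7, which resolves the trajectory well below the staircase
amplitude.  Waveform-fidelity comparisons use 100-time-unit spans on a
0.05 output grid; over much longer spans the metric is dominated by
accumulated phase drift between the two models rather than by the
pointwise cube error.

## Dynamical analysis

Equilibria solve the nullcline intersection
`V − nl(V)/3 − (a+V)/b + I = 0`.  For the original model the cubic is
strictly monotone when `b < 1`, so the single real root comes from the
cubic's companion roots; the CORDIC staircase is bracketed on a `2⁻⁸`
grid and bisected.  The original Jacobian is analytic
(`A = 1 − V², B = −1, C = 1/T, D = −b/T`); the staircase has no classical
derivative, so the CORDIC model uses central differences with
`h = 2⁻⁶` — wider than a staircase tread, so the difference quotient
samples the mean slope.

Stability follows the trace/determinant sign rules, cross-checked against
eigenvalues on random matrices.  Two discrepancies in the published
equilibrium table are resolved by the mathematics: the `I = 0.5` row is
labelled stable although its own printed entries give trace
`0.3522 − 0.064 > 0` (the sign rules, and the observed tonic spiking at
that drive, say unstable spiral), and the `D = +0.064` entry at `I = 2`
is a sign typo (`D = −b/T` identically).  The Hopf condition
`trace = 0` gives `V*² = 1 − b/T` and hence drive values 0.3312 and
1.4188 in closed form; the prose range "0.5 to 1.5" in the hardware
literature is a rounded visual reading of a figure, and the scan asserts
the computed window.

## Chaos diagnostics

Bifurcation diagrams record strict post-transient local maxima of `V(t)`
(minimum separation 1 time unit) along a drive sweep from a zero initial
state, with forward Euler at `dt = 2⁻⁵`; sweeps use transient 500 and
horizon 1500 time units (the acceptance-scale settings — large enough
for 10 slow-drive cycles, small enough to keep the suite fast).

The maximum Lyapunov exponent uses a two-trajectory (Benettin-style)
renormalization scheme rather than tangent-vector propagation, because
the staircase has no Jacobian: separation `d0`, renormalized every 1 time
unit, transient 500, horizon 5000.  `d0 = 2⁻⁶` by default: an
infinitesimal separation leaves both copies of the CORDIC model on one
staircase tread, where the approximate cube's local slope is zero and the
V-equation looks uniformly expanding — the estimator then reports
spurious positive exponents in every regime.  A separation spanning
several treads samples the mean slope; with it the two models agree in
regime sign at all showcased drive settings, and the smooth model's
exponent is insensitive to `d0` across `2⁻⁸ … 2⁻⁴`.  The estimator is
validated against the logistic map at `r = 4` (closed form `ln 2`).

Period-doubling structure: at drive frequency 0.13 the amplitude sweep
shows the classic 1 → 2 → 4 → chaos → 4 → 2 → 1 cascade for both models.
At the slow frequency 0.01 the smooth model's windows carry one or two
peak branches at these settings, while the CORDIC model's staircase
splits the subthreshold branch and its sweep contains both exactly-2 and
exactly-4 branch windows; the acceptance check therefore reads the 2/4
pattern off the emulated model.

## Network comparison

Two populations of 1000 neurons share a seeded topology: each neuron
receives exactly 100 presynaptic inputs sampled uniformly without
replacement (no self-connections), 80 % of neurons are excitatory.  The
synapse model is not specified by the hardware literature; the minimal
current-based choice consistent with an E/I split is used — a presynaptic
spike injects a rectangular current pulse into its targets
(`w_exc = +0.05`, `w_inh = −0.25`, width 1 ms), values exposed in config
and stamped into every output.  Spikes are upward crossings of
`V_th = 1.0` with a 5 ms refractory period (no spike detector is defined
by the source literature either).  Initial states are drawn uniformly
over the tonic orbit's range to desynchronize the population — identical
neurons from identical states would fire in lockstep — and are shared by
both model runs, so the raster discrepancy measures the arithmetic
approximation alone.  Drive 0.5, duration 1200 ms, last 1000 ms analysed.

Raster discrepancy: per neuron, spikes of the two runs are matched
greedily by nearest time within a 20 ms window, one-to-one; the reported
numbers are the mean |Δt| over matched pairs and the matched fraction
(unmatched spikes count against it).  This is a stochastic,
order-of-magnitude comparison: the measured mean at the default seed is a
few ms, consistent with the published "about 5 ms", and it grows
monotonically as CORDIC iterations are reduced.

## What the synthetic conditions do and do not show

All inputs are parameter sets; there is no external data.  The validation
shows that the shift-add approximation preserves the original model's
equilibria, stability classes, waveforms, chaos regimes and collective
spiking statistics *under the stated parameter ranges* (`|V| ≤ 2`,
`|y| ≤ 2` per CORDIC stage, the studied drive grid).  It does not
calibrate the neuron to biophysical units, does not cover drives outside
the convergence domain of the schedule, and does not emulate RTL timing,
pipelining or synthesis-level behaviour of any specific hardware.
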
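"""Compiled inner loops (numba) for the simulators.

These kernels repeat, in scalar form, exactly the arithmetic of the numpy
reference paths in :mod:`cordic_fhn.cordic` and :mod:`cordic_fhn.qformat`:
the float kernels use the same operation ordering (so results agree
bitwise), and the integer kernels use the same truncating shifts.  The
test suite cross-checks kernel output against the reference paths.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def cube_cordic(v, i_min, i_max):
    """Two-stage shift-add cube of a float (exact power-of-two scalings)."""
    # stage 1: v * v
    y = v
    z = 0.0
    for i in range(i_min, i_max + 1):
        d = 2.0 ** -i
        if y > 0.0:
            y -= d
            z += v * d
        elif y < 0.0:
            y += d
            z -= v * d
    sq = z
    # stage 2: (v*v) * v
    y = v
    z = 0.0
    for i in range(i_min, i_max + 1):
        d = 2.0 ** -i
        if y > 0.0:
            y -= d
            z += sq * d
        elif y < 0.0:
            y += d
            z -= sq * d
    return z


@njit(cache=True)
def _drive(t, I_amp, f, is_sin):
    if is_sin:
        return I_amp * math.sin(TWO_PI * f * t)
    return I_amp


@njit(cache=True)
def euler_traj(use_cordic, a, b, T, dt, i_min, i_max,
               I_amp, f, is_sin, n_steps, V0, W0):
    """Forward-Euler trajectory (real backend); returns (V, W) of length n_steps+1."""
    V_out = np.empty(n_steps + 1)
    W_out = np.empty(n_steps + 1)
    V = V0
    W = W0
    V_out[0] = V
    W_out[0] = W
    for k in range(n_steps):
        I = _drive(k * dt, I_amp, f, is_sin)
        if use_cordic:
            nl = cube_cordic(V, i_min, i_max)
        else:
            nl = V * V * V
        dV = V - nl / 3.0 - W + I
        dW = (a - b * W + V) / T
        V = V + dt * dV
        W = W + dt * dW
        V_out[k + 1] = V
        W_out[k + 1] = W
    return V_out, W_out


@njit(cache=True)
def benettin_mle(use_cordic, a, b, T, dt, i_min, i_max,
                 I_amp, f, is_sin, d0, renorm_steps,
                 n_transient, n_steps, V0, W0):
    """Two-trajectory (Benettin-style) largest Lyapunov exponent.

    Evolves a reference and a perturbed copy (initial separation ``d0``
    along V), renormalizes the separation every ``renorm_steps`` Euler
    steps, and averages ``ln(d/d0)`` over the horizon.

    Returns ``(lambda, n_renorm, status)`` with status 0 = ok,
    1 = separation overflow/collapse before renormalization.
    """
    V = V0
    W = W0
    for k in range(n_transient):
        I = _drive(k * dt, I_amp, f, is_sin)
        if use_cordic:
            nl = cube_cordic(V, i_min, i_max)
        else:
            nl = V * V * V
        dV = V - nl / 3.0 - W + I
        dW = (a - b * W + V) / T
        V = V + dt * dV
        W = W + dt * dW
    Vp = V + d0
    Wp = W
    acc = 0.0
    n_renorm = 0
    t0 = n_transient * dt
    k = 0
    while k < n_steps:
        for j in range(renorm_steps):
            t = t0 + (k + j) * dt
            I = _drive(t, I_amp, f, is_sin)
            if use_cordic:
                nl = cube_cordic(V, i_min, i_max)
                nlp = cube_cordic(Vp, i_min, i_max)
            else:
                nl = V * V * V
                nlp = Vp * Vp * Vp
            dV = V - nl / 3.0 - W + I
            dW = (a - b * W + V) / T
            dVp = Vp - nlp / 3.0 - Wp + I
            dWp = (a - b * Wp + Vp) / T
            V = V + dt * dV
            W = W + dt * dW
            Vp = Vp + dt * dVp
            Wp = Wp + dt * dWp
        k += renorm_steps
        dist = math.sqrt((Vp - V) ** 2 + (Wp - W) ** 2)
        if not math.isfinite(dist) or dist <= 0.0:
            return 0.0, n_renorm, 1
        acc += math.log(dist / d0)
        n_renorm += 1
        s = d0 / dist
        Vp = V + (Vp - V) * s
        Wp = W + (Wp - W) * s
    if n_renorm == 0:
        return 0.0, 0, 1
    lam = acc / (n_renorm * renorm_steps * dt)
    return lam, n_renorm, 0


@njit(cache=True)
def _apply_terms(raw, signs, ks):
    """Signed sum of arithmetic shifts: multiply a mantissa by a recoded constant."""
    out = np.int64(0)
    for j in range(signs.shape[0]):
        k = ks[j]
        if k >= 0:
            out += signs[j] * (raw >> k)
        else:
            out += signs[j] * (raw << (-k))
    return out


@njit(cache=True)
def _cube_fixed(v_raw, scale, i_min, i_max):
    """Two-stage fixed-point cube on a raw mantissa with guard-bit accumulators."""
    # stage 1
    y = v_raw
    z = np.int64(0)
    for i in range(i_min, i_max + 1):
        d = scale >> i if i >= 0 else scale << (-i)
        if d == 0:
            break
        xd = v_raw >> i if i >= 0 else v_raw << (-i)
        if y > 0:
            y -= d
            z += xd
        elif y < 0:
            y += d
            z -= xd
    sq = z
    # stage 2
    y = v_raw
    z = np.int64(0)
    for i in range(i_min, i_max + 1):
        d = scale >> i if i >= 0 else scale << (-i)
        if d == 0:
            break
        xd = sq >> i if i >= 0 else sq << (-i)
        if y > 0:
            y -= d
            z += xd
        elif y < 0:
            y += d
            z -= xd
    return z


@njit(cache=True)
def fixed_euler_traj(use_cordic, a_raw, scale, raw_min, raw_max,
                     inv3_signs, inv3_ks, b_signs, b_ks, invT_signs, invT_ks,
                     dt_shift, guard_bits, i_min, i_max,
                     I_amp, f, is_sin, dt, n_steps, V0_raw, W0_raw):
    """Forward-Euler in Q-format mantissa arithmetic (shift-add constants).

    Every datapath signal (CORDIC inputs, constant multiplies, the
    recorded samples) is a truncated Q-format word; the constant
    multiplies 1/3, b and 1/T are signed shift sums.  The two state
    registers alone carry ``guard_bits`` extra fraction bits: with the
    step realized as a ``dt_shift``-bit right shift, per-step increments
    are routinely smaller than one word ulp and a word-width accumulator
    would deadband at a spurious rest state.  Returns the raw (word)
    mantissa series plus the saturation-event count.
    """
    V_raw = np.empty(n_steps + 1, dtype=np.int64)
    W_raw = np.empty(n_steps + 1, dtype=np.int64)
    acc_min = raw_min << guard_bits
    acc_max = raw_max << guard_bits
    V_acc = V0_raw << guard_bits
    W_acc = W0_raw << guard_bits
    V_raw[0] = V0_raw
    W_raw[0] = W0_raw
    n_sat = 0
    for k in range(n_steps):
        V = V_acc >> guard_bits  # truncated word view, feeds the datapath
        W = W_acc >> guard_bits
        I = _drive(k * dt, I_amp, f, is_sin)
        I_q = np.int64(math.floor(I * scale))
        if use_cordic:
            cube = _cube_fixed(V, scale, i_min, i_max)
        else:
            # idealized cubic, still word-limited: truncate V^3 to the grid
            cube = np.int64(math.floor((V / scale) ** 3 * scale))
        if cube > raw_max or cube < raw_min:
            n_sat += 1
            cube = raw_max if cube > raw_max else raw_min
        nl = _apply_terms(cube, inv3_signs, inv3_ks)
        dv = V - nl - W + I_q
        w_inc = _apply_terms(a_raw - _apply_terms(W, b_signs, b_ks) + V,
                             invT_signs, invT_ks)
        V_acc += (dv << guard_bits) >> dt_shift
        W_acc += (w_inc << guard_bits) >> dt_shift
        if V_acc > acc_max or V_acc < acc_min:
            n_sat += 1
            V_acc = acc_max if V_acc > acc_max else acc_min
        if W_acc > acc_max or W_acc < acc_min:
            n_sat += 1
            W_acc = acc_max if W_acc > acc_max else acc_min
        V_raw[k + 1] = V_acc >> guard_bits
        W_raw[k + 1] = W_acc >> guard_bits
    return V_raw, W_raw, n_sat


@njit(cache=True)
def network_sim(use_cordic, a, b, T, dt, i_min, i_max, I_amp, n_steps,
                out_indptr, out_targets, weights,
                v_th, refr_steps, pulse_steps,
                V0, W0, record, max_spikes):
    """Euler co-integration of a pulse-coupled FHN population (real backend).

    ``out_indptr``/``out_targets`` is the CSR list of postsynaptic targets
    per neuron; a presynaptic spike adds ``weights[j]`` to each target's
    input current for ``pulse_steps`` steps.  Spikes are upward threshold
    crossings with a refractory period.

    Returns (spike_neurons, spike_steps, n_spikes, V_hist, W_hist); the
    histories have shape (n_steps+1, n) when ``record`` else (1, 1).
    """
    n = V0.shape[0]
    V = V0.copy()
    W = W0.copy()
    I_syn = np.zeros(n)
    # ring of pending pulse expirations; size P+1 so an injection scheduled
    # P+1 subtractions ahead never aliases the slot being cleared this step
    n_slots = pulse_steps + 1
    expire = np.zeros((n_slots, n))
    last_spike = np.full(n, -10 ** 9, dtype=np.int64)
    spike_neurons = np.empty(max_spikes, dtype=np.int64)
    spike_steps = np.empty(max_spikes, dtype=np.int64)
    step_spikers = np.empty(n, dtype=np.int64)
    n_spikes = 0
    if record:
        V_hist = np.empty((n_steps + 1, n))
        W_hist = np.empty((n_steps + 1, n))
        V_hist[0] = V
        W_hist[0] = W
    else:
        V_hist = np.empty((1, 1))
        W_hist = np.empty((1, 1))
    for k in range(n_steps):
        slot = k % n_slots
        for i in range(n):
            I_syn[i] -= expire[slot, i]
            expire[slot, i] = 0.0
        n_step_spikes = 0
        for i in range(n):
            Vi = V[i]
            Wi = W[i]
            if use_cordic:
                nl = cube_cordic(Vi, i_min, i_max)
            else:
                nl = Vi * Vi * Vi
            I = I_amp + I_syn[i]
            dV = Vi - nl / 3.0 - Wi + I
            dW = (a - b * Wi + Vi) / T
            V_new = Vi + dt * dV
            W[i] = Wi + dt * dW
            if Vi < v_th and V_new >= v_th and (k + 1 - last_spike[i]) >= refr_steps:
                last_spike[i] = k + 1
                step_spikers[n_step_spikes] = i
                n_step_spikes += 1
                if n_spikes < max_spikes:
                    spike_neurons[n_spikes] = i
                    spike_steps[n_spikes] = k + 1
                    n_spikes += 1
            V[i] = V_new
        # inject after the whole step so a spike affects targets from k+1 on,
        # active for pulse_steps steps
        slot_off = (k + 1 + pulse_steps) % n_slots
        for s in range(n_step_spikes):
            i = step_spikers[s]
            w = weights[i]
            for p in range(out_indptr[i], out_indptr[i + 1]):
                tgt = out_targets[p]
                I_syn[tgt] += w
                expire[slot_off, tgt] += w
        if record:
            V_hist[k + 1] = V
            W_hist[k + 1] = W
    return spike_neurons[:n_spikes], spike_steps[:n_spikes], n_spikes, V_hist, W_hist
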
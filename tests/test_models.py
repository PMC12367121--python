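"""Neuron right-hand sides and the continuous / Euler / fixed-point simulators."""

import numpy as np
import pytest

from cordic_fhn.cordic import DEFAULT_SCHEDULE, cordic_cube
from cordic_fhn.models import (
    DriveSpec,
    FHNParams,
    Trajectory,
    cordic_fhn_rhs,
    detect_spikes,
    fhn_rhs,
    simulate_continuous,
    simulate_discrete,
)

PARAMS = FHNParams()


class TestRhs:
    def test_vanishes_at_published_equilibrium(self):
        dV, dW = fhn_rhs(-0.8048, -0.1311, PARAMS, 0.5)
        assert abs(dV) < 1e-3 and abs(dW) < 1e-3

    def test_origin_no_drive(self):
        assert fhn_rhs(0.0, 0.0, PARAMS, 0.0) == (0.0, 0.7 / 12.5)

    def test_drive_only_term(self):
        dV, _ = fhn_rhs(0.0, 0.0, PARAMS, 1.0)
        assert dV == 1.0

    def test_cordic_rhs_differs_by_cube_error_over_three(self, rng):
        for V in rng.uniform(-2, 2, size=50):
            dV_o, dW_o = fhn_rhs(V, 0.1, PARAMS, 0.5)
            dV_c, dW_c = cordic_fhn_rhs(V, 0.1, PARAMS, 0.5)
            e = cordic_cube(float(V)) - V ** 3
            assert dV_c - dV_o == pytest.approx(-e / 3.0, abs=1e-12)
            assert dW_c == dW_o

    def test_cordic_rhs_near_two_thirds_at_unit_v(self):
        dV, _ = cordic_fhn_rhs(1.0, 0.0, PARAMS, 0.0)
        assert abs(dV - 2.0 / 3.0) <= 0.0104

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            simulate_discrete("hodgkin", n_steps=1)


class TestContinuous:
    def test_zero_span_returns_init(self):
        traj = simulate_continuous("fhn", t_span=0.0, init=(0.3, -0.1))
        assert len(traj) == 1
        assert (traj.V[0], traj.W[0]) == (0.3, -0.1)

    def test_stable_equilibrium_is_invariant(self):
        # start at the I=2 stable node: the orbit must stay put
        traj = simulate_continuous(
            "fhn", drive=DriveSpec.constant(2.0), t_span=200.0, init=(1.3341, 2.5426)
        )
        assert np.max(np.abs(traj.V - 1.3341)) < 1e-3
        assert np.max(np.abs(traj.W - 2.5426)) < 1e-3

    def test_tonic_firing_at_half_milliamp(self):
        traj = simulate_continuous("fhn", drive=DriveSpec.constant(0.5), t_span=1000.0)
        assert len(detect_spikes(traj.t, traj.V)) >= 3

    def test_cordic_trace_follows_original(self):
        a = simulate_continuous("fhn", drive=DriveSpec.constant(0.5), t_span=100.0)
        b = simulate_continuous("cordic", drive=DriveSpec.constant(0.5), t_span=100.0)
        assert np.mean(np.abs(a.V - b.V)) < 0.01


class TestDiscrete:
    def test_single_euler_step_by_hand(self):
        traj = simulate_discrete("fhn", drive=DriveSpec.constant(1.0), n_steps=1)
        assert traj.V[1] == 0.03125
        assert traj.W[1] == pytest.approx(2.0 ** -5 * 0.7 / 12.5)

    def test_first_order_convergence(self):
        # halving dt halves the global error against the continuous solution
        ref = simulate_continuous("fhn", drive=DriveSpec.constant(0.5), t_span=50.0, t_step=0.05)
        errs = []
        for dt in (2.0 ** -5, 2.0 ** -6):
            p = FHNParams(dt=dt)
            tr = simulate_discrete("fhn", p, DriveSpec.constant(0.5), n_steps=int(50.0 / dt))
            errs.append(np.max(np.abs(np.interp(ref.t, tr.t, tr.V) - ref.V)))
        assert errs[1] == pytest.approx(errs[0] / 2, rel=0.25)

    def test_fixed_backend_is_q8_8_representable(self):
        tr = simulate_discrete("cordic", drive=DriveSpec.constant(0.5),
                               n_steps=8000, backend="fixed")
        np.testing.assert_array_equal(tr.V * 256, np.round(tr.V * 256))
        assert tr.meta["format"] == "Q8.8"

    def test_fixed_backend_stays_in_membrane_range(self):
        tr = simulate_discrete("cordic", drive=DriveSpec.constant(0.5),
                               n_steps=16000, backend="fixed")
        assert tr.V.min() >= -2.1 and tr.V.max() <= 2.1
        assert tr.W.min() >= -0.6 and tr.W.max() <= 1.6
        assert tr.meta["saturations"] == 0

    def test_fixed_backend_regression_against_real(self):
        """Word-length effects shift the tonic phase; the measured drift is
        frozen as a regression value (spike count must still agree)."""
        real = simulate_discrete("cordic", drive=DriveSpec.constant(0.5), n_steps=32000)
        fixed = simulate_discrete("cordic", drive=DriveSpec.constant(0.5),
                                  n_steps=32000, backend="fixed")
        mae = np.mean(np.abs(real.V - fixed.V))
        assert mae == pytest.approx(0.935, abs=0.1)
        n_real = len(detect_spikes(real.t, real.V))
        n_fixed = len(detect_spikes(fixed.t, fixed.V))
        assert n_real == n_fixed == 26

    def test_fixed_kernel_matches_pure_python_word_replay(self):
        """Replay the fixed datapath with plain Python ints (independent of
        numba) and demand bit-identical mantissas."""
        from cordic_fhn.qformat import Q8_8, ShiftAddConstant, quantize

        n_steps, g, dshift = 400, 8, 5
        tr = simulate_discrete("cordic", drive=DriveSpec.constant(0.5),
                               n_steps=n_steps, backend="fixed")
        inv3 = ShiftAddConstant.decompose(1.0 / 3.0).terms
        b_t = ShiftAddConstant.decompose(0.8).terms
        invT = ShiftAddConstant.decompose(0.08).terms

        def shr(x, k):  # arithmetic shift, k>=0 right
            return x >> k if k >= 0 else x << (-k)

        def mulc(x, terms):
            return sum(s * shr(x, k) for s, k in terms)

        def cube(v):
            out = v
            for _stage in range(2):
                y, z, x = v, 0, out
                for i in range(-7, 9):
                    d = shr(256, i)
                    if d == 0:
                        break
                    if y > 0:
                        y -= d
                        z += shr(x, i)
                    elif y < 0:
                        y += d
                        z -= shr(x, i)
                out = z
            return z

        a_raw = quantize(0.7).raw
        I_q = quantize(0.5).raw
        V_acc = W_acc = 0
        for k in range(n_steps):
            V, W = V_acc >> g, W_acc >> g
            c = min(max(cube(V), Q8_8.raw_min), Q8_8.raw_max)
            dv = V - mulc(c, inv3) - W + I_q
            w_inc = mulc(a_raw - mulc(W, b_t) + V, invT)
            V_acc += (dv << g) >> dshift
            W_acc += (w_inc << g) >> dshift
            assert tr.V_raw[k + 1] == V_acc >> g
            assert tr.W_raw[k + 1] == W_acc >> g

    def test_non_power_of_two_dt_rejected_in_fixed(self):
        with pytest.raises(ValueError, match="2\\*\\*-k"):
            simulate_discrete("fhn", FHNParams(dt=0.01), n_steps=1, backend="fixed")


class TestTrajectory:
    def test_length_and_monotonicity_validated(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0]), np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.0]), np.zeros(2), np.zeros(2))

    def test_frame_includes_raw_mantissas_when_fixed(self):
        tr = simulate_discrete("fhn", n_steps=4, backend="fixed")
        assert list(tr.to_frame().columns) == ["t", "V", "W", "V_raw", "W_raw"]


def test_spike_detector_refractory():
    t = np.arange(0.0, 20.0, 0.5)
    V = np.where((t % 4) < 1.0, 1.5, 0.0)  # crossings every 4 time units
    times = detect_spikes(t, V, threshold=1.0, refractory=5.0)
    assert len(times) >= 2
    assert np.all(np.diff(times) >= 5.0)
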
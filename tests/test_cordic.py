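"""Shift-add multiplier contract: residual bound, conservation, cube error."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cordic_fhn import _kernels
from cordic_fhn.cordic import (
    DEFAULT_SCHEDULE,
    CordicSchedule,
    cordic_cube,
    cordic_multiply,
    cube_error_sweep,
    cube_fixed_raw,
    symmetric_schedule,
)
from cordic_fhn.qformat import Q8_8, QValue, quantize, quantize_array


class TestSchedule:
    def test_default_window(self):
        assert (DEFAULT_SCHEDULE.i_min, DEFAULT_SCHEDULE.i_max) == (-7, 8)
        assert DEFAULT_SCHEDULE.n == 16

    @pytest.mark.parametrize("n, lo, hi", [(16, -7, 8), (14, -6, 7), (18, -8, 9), (10, -4, 5)])
    def test_symmetric_windows(self, n, lo, hi):
        s = symmetric_schedule(n)
        assert (s.i_min, s.i_max, s.n) == (lo, hi, n)

    def test_rejects_odd_or_tiny(self):
        with pytest.raises(ValueError):
            symmetric_schedule(15)
        with pytest.raises(ValueError):
            CordicSchedule(3, 3)


class TestMultiply:
    def test_zero_and_unit(self):
        assert cordic_multiply(1.7, 0.0) == 0.0
        assert cordic_multiply(1.0, 1.0) == 1.0  # recoding terminates exactly

    def test_signed_example_within_residual_bound(self):
        z = cordic_multiply(-1.5, 1.25)
        assert abs(z - (-1.875)) <= 1.5 * 2.0 ** -8

    def test_domain_error_names_bound(self):
        with pytest.raises(ValueError, match="convergence"):
            cordic_multiply(1.0, 300.0)

    @given(
        st.floats(min_value=-2.0, max_value=2.0),
        st.floats(min_value=-2.0, max_value=2.0),
    )
    def test_residual_bound_random(self, x, y):
        z = cordic_multiply(x, y)
        assert abs(z - x * y) <= abs(x) * 2.0 ** -8 + 1e-12

    def test_residual_bound_bulk(self, rng):
        # dense random sample of the membrane range
        x = rng.uniform(-2, 2, size=100_000)
        y = rng.uniform(-2, 2, size=100_000)
        z = cordic_multiply(x, y)
        assert np.all(np.abs(z - x * y) <= np.abs(x) * 2.0 ** -8 + 1e-12)

    def test_exact_on_q8_8_lattice_slice(self):
        # every multiple of 2^-8 in [-2,2] is exactly recodable by the
        # default window, so the float backend is exact there
        y = np.arange(-512, 513, dtype=float) / 256.0
        x = np.full_like(y, -1.5)
        np.testing.assert_allclose(cordic_multiply(x, y), x * y, atol=1e-12)

    def test_conservation_invariant(self, rng):
        # z_i + x*y_i is constant along the iteration in the real backend
        sched = DEFAULT_SCHEDULE
        for _ in range(200):
            x = rng.uniform(-2, 2)
            y0 = rng.uniform(-2, 2)
            y, z = y0, 0.0
            for i in sched.indices:
                d = 2.0 ** -i
                mu = np.sign(y)
                y -= mu * d
                z += mu * (x * d)
                assert z + x * y == pytest.approx(x * y0, abs=1e-12)

    def test_fixed_backend_matches_qvalue_api(self):
        a, b = quantize(1.5), quantize(-1.25)
        z = cordic_multiply(a, b)
        assert isinstance(z, QValue)
        assert z.value == pytest.approx(-1.875, abs=1.5 * 2 ** -8 + 16 * Q8_8.ulp)

    def test_fixed_backend_format_mismatch(self):
        from cordic_fhn.qformat import QFormat

        with pytest.raises(ValueError, match="mismatch"):
            cordic_multiply(quantize(1.0), quantize(1.0, QFormat(4, 4)))
        with pytest.raises(TypeError):
            cordic_multiply(quantize(1.0), 1.0)


class TestCube:
    def test_zero(self):
        assert cordic_cube(0.0) == 0.0

    def test_worst_case_at_two(self):
        assert abs(cordic_cube(2.0) - 8.0) <= 0.032

    def test_odd_symmetry(self, rng):
        V = rng.uniform(0, 2, size=2000)
        np.testing.assert_array_equal(cordic_cube(-V), -cordic_cube(V))

    def test_scalar_kernel_matches_vector_path(self, rng):
        V = rng.uniform(-2, 2, size=500)
        vec = cordic_cube(V)
        scal = [_kernels.cube_cordic(v, -7, 8) for v in V]
        np.testing.assert_array_equal(vec, scal)

    def test_fixed_cube_kernel_matches_numpy_fixed_path(self, rng):
        V = rng.uniform(-2, 2, size=300)
        raw = quantize_array(V)
        ref = cube_fixed_raw(raw, Q8_8, DEFAULT_SCHEDULE)
        ker = [
            _kernels._cube_fixed(np.int64(r), np.int64(256), -7, 8) for r in raw
        ]
        np.testing.assert_array_equal(ref, np.clip(ker, Q8_8.raw_min, Q8_8.raw_max))


class TestErrorSweep:
    @pytest.fixture(scope="class")
    @staticmethod
    def sweep():
        return cube_error_sweep([10, 12, 14, 16, 18, 20]).set_index("n_iter")

    def test_published_upper_bounds(self, sweep):
        # worst-case error equals the printed table exactly; the grid mean is below it
        for n, bound in [(10, 0.2480), (12, 0.1245), (14, 0.0624), (16, 0.0312), (18, 0.0156), (20, 0.0078)]:
            assert sweep.loc[n, "mae"] <= bound
            assert sweep.loc[n, "max_err"] == pytest.approx(8.0 * 2.0 ** -(n // 2), rel=1e-2)

    def test_mae_halves_per_two_iterations(self, sweep):
        mae = sweep["mae"].sort_index()
        ratios = mae.to_numpy()[:-1] / mae.to_numpy()[1:]
        assert np.all((ratios > 1.7) & (ratios < 2.3))

    def test_mae_monotone_non_increasing(self, sweep):
        mae = sweep["mae"].sort_index().to_numpy()
        assert np.all(np.diff(mae) <= 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            cube_error_sweep([16], v_range=(1.0, 1.0))

    def test_fixed_backend_sweep_runs(self):
        df = cube_error_sweep([16], backend="fixed", grid_step=1.0 / 64.0)
        assert df.loc[0, "mae"] < 0.2
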
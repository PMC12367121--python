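"""Comparison statistics and hardware cost functions.

Trace agreement between the original and CORDIC neurons is summarised by
MAE, RMSE, range-normalized RMSE and Pearson correlation; Lyapunov-curve
agreement by a range-normalized RMSE in percent.  The hardware quality
scores combine approximation error with the design's maximum clock
frequency (CF1 = MAE / f_max) and additionally its power draw
(CF2 = MAE * P / f_max).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "compare_traces", "nrmse_mle", "cost_functions"]


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    rmse: float
    nrmse: float
    corr: float
    n: int
    normalization: tuple[float, float]  # (V_max, V_min) of the reference

    @property
    def nrmse_percent(self) -> float:
        return 100.0 * self.nrmse

    @property
    def corr_percent(self) -> float:
        return 100.0 * self.corr

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "nrmse": self.nrmse,
            "corr": self.corr,
            "n": self.n,
            "V_max": self.normalization[0],
            "V_min": self.normalization[1],
        }


def compare_traces(reference, test) -> MetricsReport:
    """MAE / RMSE / nRMSE / Pearson correlation between two aligned series.

    nRMSE is normalized by the reference's range; correlation is Pearson on
    the raw aligned samples.  Raises on length mismatch or zero variance.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ValueError(f"series must be 1-D and equally long, got {ref.shape} vs {tst.shape}")
    if ref.size == 0:
        raise ValueError("empty series")
    diff = tst - ref
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    vmax, vmin = float(ref.max()), float(ref.min())
    rng = vmax - vmin
    nrmse = rmse / rng if rng > 0 else (0.0 if rmse == 0 else np.inf)
    s_ref, s_tst = float(np.std(ref)), float(np.std(tst))
    if s_ref == 0.0 or s_tst == 0.0:
        raise ValueError("correlation undefined: a series has zero variance")
    cov = float(np.mean((ref - ref.mean()) * (tst - tst.mean())))
    corr = cov / (s_ref * s_tst)
    return MetricsReport(mae, rmse, nrmse, corr, ref.size, (vmax, vmin))


def nrmse_mle(mle_ref, mle_test) -> float:
    """RMSE between two Lyapunov-exponent curves, normalized by the
    reference curve's range, in percent."""
    ref = np.asarray(mle_ref, dtype=float)
    tst = np.asarray(mle_test, dtype=float)
    if ref.shape != tst.shape:
        raise ValueError("curves must share the parameter grid")
    rng = float(ref.max() - ref.min())
    rmse = float(np.sqrt(np.mean((tst - ref) ** 2)))
    if rng == 0.0:
        if rmse == 0.0:
            return 0.0
        raise ValueError("degenerate reference range: nRMSE undefined")
    return 100.0 * rmse / rng


def cost_functions(mae: float, freq_hz: float, power_w: float | None = None):
    """Hardware cost scores: ``CF1 = MAE / f`` and ``CF2 = MAE * P / f``.

    ``freq_hz`` in Hz, ``power_w`` in watts.  CF2 is ``None`` when power is
    not given (not all published designs report it).
    """
    if mae < 0:
        raise ValueError("mae must be non-negative")
    if freq_hz <= 0:
        raise ValueError("freq_hz must be positive")
    cf1 = mae / freq_hz
    if power_w is None:
        return cf1, None
    if power_w <= 0:
        raise ValueError("power_w must be positive")
    return cf1, mae * power_w / freq_hz
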
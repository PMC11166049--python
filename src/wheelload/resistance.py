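"""Instantaneous rolling resistance and method comparison.

Converts a relative front-wheel load trace (measured, predicted, or the
static drag-test value) into a rolling-resistance force trace via

    F_IR(t) = cf * FN_f(t) + cr * (FN_tot - FN_f(t)),

and compares model-based and drag-test-based estimates against the gold
standard (rolling resistance from the directly measured front load).

Signed comparison errors here are estimate - reference; note the load
model's fit metrics use the opposite orientation (observed - predicted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import RollingCoefficients

__all__ = [
    "RollingResistanceTrace",
    "MethodComparison",
    "instantaneous_rolling_resistance",
    "constant_trace",
    "compare_methods",
]


@dataclass
class RollingResistanceTrace:
    """Rolling-resistance force over time from one estimation route."""

    t: np.ndarray
    f_ir: np.ndarray
    source: str  # gold | model | drag

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_ir = np.asarray(self.f_ir, dtype=float)
        if self.t.shape != self.f_ir.shape:
            raise ValueError("t and f_ir must have the same length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def mean(self) -> float:
        return float(np.mean(self.f_ir))


@dataclass
class MethodComparison:
    """Per-trial errors of both estimates vs the gold standard.

    ME/MAE/RMSE are expressed in percent of the trial-mean gold-standard
    rolling resistance (the same reference for both methods); the gold
    mean and its SD are reported in newtons.
    """

    gold_mean_N: float
    gold_sd_N: float
    model_me_pct: float
    model_mae_pct: float
    model_rmse_pct: float
    drag_me_pct: float
    drag_mae_pct: float
    drag_rmse_pct: float

    def summary(self) -> str:
        return (
            "Rolling-resistance comparison (percent of mean gold F_IR)\n"
            f"gold standard   {self.gold_mean_N:6.2f} ({self.gold_sd_N:.2f}) N\n"
            f"                 ME     MAE    RMSE\n"
            f"model-based    {self.model_me_pct:6.2f} {self.model_mae_pct:6.2f}"
            f" {self.model_rmse_pct:6.2f}\n"
            f"drag-based     {self.drag_me_pct:6.2f} {self.drag_mae_pct:6.2f}"
            f" {self.drag_rmse_pct:6.2f}"
        )

    def as_dict(self) -> dict:
        return {
            "gold_mean_N": self.gold_mean_N,
            "gold_sd_N": self.gold_sd_N,
            "model": {"me": self.model_me_pct, "mae": self.model_mae_pct,
                      "rmse": self.model_rmse_pct},
            "drag": {"me": self.drag_me_pct, "mae": self.drag_mae_pct,
                     "rmse": self.drag_rmse_pct},
        }


def instantaneous_rolling_resistance(rel_front, fn_total: float,
                                     coeffs: RollingCoefficients,
                                     t=None,
                                     source: str = "model") -> RollingResistanceTrace:
    """Rolling resistance from a relative front-load trace (percent)."""
    rel_front = np.asarray(rel_front, dtype=float)
    if fn_total <= 0:
        raise ValueError("fn_total must be positive")
    if np.any((rel_front < 0) | (rel_front > 100)):
        raise ValueError("rel_front must lie within [0, 100] percent")
    fn_front = rel_front / 100.0 * fn_total
    f_ir = coeffs.cf * fn_front + coeffs.cr * (fn_total - fn_front)
    if t is None:
        t = np.arange(len(rel_front), dtype=float)
    return RollingResistanceTrace(t=np.asarray(t, dtype=float), f_ir=f_ir,
                                  source=source)


def constant_trace(f_ir: float, t, source: str = "drag") -> RollingResistanceTrace:
    """A constant-valued trace (the drag-test estimate) on a given grid."""
    t = np.asarray(t, dtype=float)
    return RollingResistanceTrace(t=t, f_ir=np.full(t.shape, float(f_ir)),
                                  source=source)


def _error_stats(estimate: np.ndarray, gold: np.ndarray, gold_mean: float):
    err = estimate - gold
    scale = 100.0 / gold_mean
    return (
        float(np.mean(err) * scale),
        float(np.mean(np.abs(err)) * scale),
        float(np.sqrt(np.mean(err**2)) * scale),
    )


def compare_methods(gold: RollingResistanceTrace,
                    model: RollingResistanceTrace,
                    drag: RollingResistanceTrace) -> MethodComparison:
    """Errors of the model-based and drag-based estimates vs the gold trace.

    The model trace must share the gold trace's grid (a model windowed over
    k samples starts k-1 samples late; crop the gold trace accordingly
    before calling). The drag trace must be constant; it is broadcast onto
    the gold grid.
    """
    if len(model) != len(gold) or not np.allclose(model.t, gold.t, atol=1e-9):
        raise ValueError("gold and model traces are not on the same grid")
    if np.ptp(drag.f_ir) > 1e-9:
        raise ValueError("drag-based trace must be constant")
    gold_mean = gold.mean
    drag_full = np.full(len(gold), drag.f_ir[0] if len(drag) else np.nan)
    m_me, m_mae, m_rmse = _error_stats(model.f_ir, gold.f_ir, gold_mean)
    d_me, d_mae, d_rmse = _error_stats(drag_full, gold.f_ir, gold_mean)
    return MethodComparison(
        gold_mean_N=gold_mean,
        gold_sd_N=float(np.std(gold.f_ir)),
        model_me_pct=m_me, model_mae_pct=m_mae, model_rmse_pct=m_rmse,
        drag_me_pct=d_me, drag_mae_pct=d_mae, drag_rmse_pct=d_rmse,
    )
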
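"""Rolling-resistance coefficient calibration from drag tests.

A drag test pulls the occupied, stationary-posture wheelchair at constant
speed while tow force and front-wheel normal force are measured. Over a
series of conditions with different load distributions, the rolling
resistance obeys

    F_drag = cf * FN_f + cr * FN_r,        FN_tot = FN_f + FN_r,

so with FN_r eliminated each condition contributes one linear equation in
the two unknown coefficients (cf for the small front casters, cr for the
large rear wheels):

    F_drag = cr * FN_tot + (cf - cr) * FN_f.

:class:`DragTestCalibration` solves the resulting system by ordinary least
squares — exact with two conditions, an overdetermined fit with more.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DragTestRecord",
    "RollingCoefficients",
    "DragTestCalibration",
    "summarize_drag_condition",
    "solve_coefficients",
    "drag_based_rolling_resistance",
]


@dataclass(frozen=True)
class DragTestRecord:
    """Mean forces of one drag-test condition (trailing analysis window)."""

    condition_id: str
    f_drag_mean: float
    fn_front_mean: float
    fn_total: float

    def __post_init__(self) -> None:
        if not 0 < self.fn_front_mean < self.fn_total:
            raise ValueError(
                f"{self.condition_id}: fn_front_mean must lie in (0, fn_total)"
            )
        if self.f_drag_mean <= 0:
            raise ValueError(f"{self.condition_id}: drag force must be positive")


@dataclass
class RollingCoefficients:
    """Fitted (cf, cr) pair with fit diagnostics.

    ``warnings`` flags physically unexpected solutions (negative values, or
    cf <= cr — front casters normally roll worse than the large rear
    wheels); the fit never fails on them.
    """

    cf: float
    cr: float
    n_conditions: int = 0
    residual_rms_N: float = 0.0
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cf) and np.isfinite(self.cr)):
            raise ValueError("coefficients must be finite")

    def summary(self) -> str:
        lines = [
            "Rolling-resistance calibration",
            "------------------------------",
            f"cf (front)      {self.cf: .6f}",
            f"cr (rear)       {self.cr: .6f}",
            f"conditions      {self.n_conditions}",
            f"residual RMS    {self.residual_rms_N: .4f} N",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "cf": self.cf,
                    "cr": self.cr,
                    "n_conditions": self.n_conditions,
                    "residual_rms_N": self.residual_rms_N,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "RollingCoefficients":
        with open(path) as fh:
            d = json.load(fh)
        return cls(cf=d["cf"], cr=d["cr"],
                   n_conditions=d.get("n_conditions", 0),
                   residual_rms_N=d.get("residual_rms_N", 0.0))


def summarize_drag_condition(drag_force, fn_front, fn_total: float,
                             window_s: float = 10.0,
                             rate_hz: float = 100.0,
                             condition_id: str = "") -> DragTestRecord:
    """Average the trailing ``window_s`` seconds of one drag-test recording."""
    drag_force = np.asarray(drag_force, dtype=float)
    fn_front = np.asarray(fn_front, dtype=float)
    n_window = int(round(window_s * rate_hz))
    if len(drag_force) < n_window or len(fn_front) < n_window:
        raise ValueError(
            f"recording shorter than the {window_s}-s analysis window"
        )
    return DragTestRecord(
        condition_id=condition_id or "condition",
        f_drag_mean=float(np.mean(drag_force[-n_window:])),
        fn_front_mean=float(np.mean(fn_front[-n_window:])),
        fn_total=float(fn_total),
    )


class DragTestCalibration:
    """Least-squares model for (cf, cr) over a set of drag-test records."""

    def __init__(self, records: list[DragTestRecord]):
        if len(records) < 2:
            raise ValueError("need at least 2 drag-test conditions")
        fronts = np.array([r.fn_front_mean for r in records])
        if np.ptp(fronts) < 1e-12 * max(1.0, fronts.max()):
            ids = ", ".join(r.condition_id for r in records)
            raise ValueError(
                "rank-deficient design: all conditions have the same front "
                f"load ({ids}); vary posture or ballast"
            )
        self.records = list(records)

    def fit(self) -> RollingCoefficients:
        fn_f = np.array([r.fn_front_mean for r in self.records])
        fn_tot = np.array([r.fn_total for r in self.records])
        drag = np.array([r.f_drag_mean for r in self.records])
        # columns: front load (coefficient cf), rear load (coefficient cr)
        design = np.column_stack([fn_f, fn_tot - fn_f])
        coef, *_ = np.linalg.lstsq(design, drag, rcond=None)
        cf, cr = float(coef[0]), float(coef[1])
        resid = drag - design @ coef
        notes = []
        if cf < 0 or cr < 0:
            notes.append("negative coefficient: check drag-test data")
        elif cf <= cr:
            notes.append(
                "cf <= cr: front casters fitted with lower rolling "
                "resistance than rear wheels, which is physically unexpected"
            )
        for note in notes:
            warnings.warn(note, stacklevel=2)
        return RollingCoefficients(
            cf=cf,
            cr=cr,
            n_conditions=len(self.records),
            residual_rms_N=float(np.sqrt(np.mean(resid**2))),
            warnings=notes,
        )


def solve_coefficients(records: list[DragTestRecord]) -> RollingCoefficients:
    """Convenience wrapper: ``DragTestCalibration(records).fit()``."""
    return DragTestCalibration(records).fit()


def drag_based_rolling_resistance(coeffs: RollingCoefficients,
                                  fn_front_static: float,
                                  fn_total: float) -> float:
    """Constant rolling resistance from the static (upright) load split."""
    if not 0 <= fn_front_static <= fn_total:
        raise ValueError("fn_front_static must lie in [0, fn_total]")
    return coeffs.cf * fn_front_static + coeffs.cr * (fn_total - fn_front_static)
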
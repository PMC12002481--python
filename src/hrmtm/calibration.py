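"""Validation statistics and least-squares refitting of the empirical formula.

Two facilities live here:

* :func:`validate` -- the predicted-vs-measured error report used to judge
  the formula on held-out amplicons (per-row absolute differences, their
  mean and maximum).

* :func:`fit_coefficients` -- a reconstruction of the coefficient-derivation
  step.  The published constants (0.27, the /3 divisor, the (150+2n)/n
  length term) were stated without a derivation; since the formula is linear
  in those constants once the thermodynamic ratio is moved to the left-hand
  side, ordinary least squares is the natural reconstruction:

      y_i = Tm_i - 1000*dH_i/dS_i + 273.15 = -c*GC%_i - a/n_i - b

  with free parameters among c (optionally per GC branch), a and b; any
  parameter held fixed keeps its default value.  Outputs of the fit are
  reported, never asserted against the published constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .nn_thermo import ThermoResult
from .tm_model import TmCoefficients, TmPrediction, select_branch


class CalibrationError(ValueError):
    """Raised for unusable validation or training input."""


@dataclass(frozen=True)
class ValidationReport:
    """Per-record |predicted - measured| differences with mean and max (degC)."""

    rows: pd.DataFrame  # columns: id, predicted, measured, difference
    mean_abs_diff: float
    max_abs_diff: float

    def to_frame(self, *, decimals: int | None = 2) -> pd.DataFrame:
        """Table-style report with a footer mean row; rounded for display."""
        frame = self.rows.copy()
        footer = pd.DataFrame(
            [{"id": "mean", "predicted": np.nan, "measured": np.nan,
              "difference": self.mean_abs_diff}]
        )
        frame = pd.concat([frame, footer], ignore_index=True)
        if decimals is not None:
            for col in ("predicted", "measured", "difference"):
                frame[col] = frame[col].round(decimals)
        return frame


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted coefficients, residuals and in-sample rmse of the reconstruction."""

    coefficients: Mapping[str, float]  # fitted values, keyed c / c_mid / c_low / a / b
    fixed: Mapping[str, float]  # parameters held at their defaults
    residuals: np.ndarray  # measured - fitted Tm per training row, degC
    rmse: float  # degC
    notes: str = ""


def _as_pairs(predictions: Iterable[TmPrediction] | Mapping[str, float]) -> list[tuple[str, float]]:
    if isinstance(predictions, Mapping):
        return list(predictions.items())
    return [(p.sequence_id, p.tm_celsius) for p in predictions]


def validate(
    predictions: Iterable[TmPrediction] | Mapping[str, float],
    measured: Mapping[str, float],
) -> ValidationReport:
    """Compare predictions with measured Tm values, id by id.

    ``predictions`` may be TmPrediction objects (keyed by ``sequence_id``) or
    a plain id -> degC mapping.  Every prediction id must be present in
    ``measured``; differences are reported as absolute values.
    """
    pairs = _as_pairs(predictions)
    if not pairs:
        raise CalibrationError("no predictions to validate")
    missing = [pid for pid, _ in pairs if pid not in measured]
    if missing:
        raise CalibrationError(f"no measured Tm for id(s): {', '.join(missing)}")
    rows = pd.DataFrame(
        [
            {
                "id": pid,
                "predicted": tm,
                "measured": measured[pid],
                "difference": abs(tm - measured[pid]),
            }
            for pid, tm in pairs
        ],
        columns=["id", "predicted", "measured", "difference"],
    )
    return ValidationReport(
        rows=rows,
        mean_abs_diff=float(rows["difference"].mean()),
        max_abs_diff=float(rows["difference"].max()),
    )


def fit_coefficients(
    training: Sequence[tuple[ThermoResult, float]],
    free: Sequence[str] = ("c", "a", "b"),
    *,
    per_branch_c: bool = False,
    coefficients: TmCoefficients | None = None,
    extrapolate: bool = False,
) -> CalibrationResult:
    """Least-squares refit of the empirical correction on (thermo, measured Tm) rows.

    Parameters
    ----------
    training
        Pairs of :class:`ThermoResult` and the measured Tm in degC.
    free
        Which of ``c`` (GC coefficient), ``a`` (length numerator constant) and
        ``b`` (length slope / additive offset) to estimate; the rest stay at
        their values in ``coefficients``.
    per_branch_c
        Estimate separate GC coefficients for the mid- and low-GC branches.
        On the low branch the default "coefficient" is 1/gc_divisor_low.

    Notes
    -----
    The length term (a + b*n)/n = a/n + b makes b both the length slope and
    the asymptotic additive constant; they are the same parameter here.
    """
    defaults = coefficients or TmCoefficients()
    free = tuple(free)
    unknown = [f for f in free if f not in ("c", "a", "b")]
    if unknown:
        raise CalibrationError(f"unknown free parameter(s): {', '.join(unknown)}")
    if not training:
        raise CalibrationError("no training rows")

    branches = [select_branch(t.gc_percent, defaults, extrapolate=extrapolate) for t, _ in training]
    gc = np.array([t.gc_percent for t, _ in training])
    n = np.array([float(t.n) for t, _ in training])
    ratio = np.array([1000.0 * t.dH_total / t.dS_total for t, _ in training])
    tm = np.array([m for _, m in training])
    # Left-hand side: what the empirical correction must explain.
    y = tm - ratio + defaults.kelvin_offset

    mid = np.array([b == "mid_gc" for b in branches])
    c_default = np.where(mid, defaults.gc_coeff_mid, 1.0 / defaults.gc_divisor_low)

    columns: list[np.ndarray] = []
    names: list[str] = []
    if "c" in free:
        if per_branch_c:
            if mid.any():
                columns.append(np.where(mid, -gc, 0.0))
                names.append("c_mid")
            if (~mid).any():
                columns.append(np.where(~mid, -gc, 0.0))
                names.append("c_low")
        else:
            columns.append(-gc)
            names.append("c")
    else:
        y = y + c_default * gc
    if "a" in free:
        columns.append(-1.0 / n)
        names.append("a")
    else:
        y = y + defaults.length_const / n
    if "b" in free:
        columns.append(-np.ones_like(n))
        names.append("b")
    else:
        y = y + defaults.length_slope

    if len(training) < len(names):
        raise CalibrationError(
            f"{len(training)} training rows cannot identify {len(names)} free parameters"
        )
    design = np.column_stack(columns)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CalibrationError(
            "rank-deficient design: the training rows do not separate the free "
            "parameters (e.g. all GC% identical with c free)"
        )
    estimate, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ estimate  # identical to measured - fitted Tm
    rmse = float(np.sqrt(np.mean(residuals**2)))

    fitted = dict(zip(names, (float(v) for v in estimate)))
    fixed = {}
    if "c" not in free:
        fixed["c_mid"] = defaults.gc_coeff_mid
        fixed["c_low"] = 1.0 / defaults.gc_divisor_low
    if "a" not in free:
        fixed["a"] = defaults.length_const
    if "b" not in free:
        fixed["b"] = defaults.length_slope
    return CalibrationResult(
        coefficients=fitted,
        fixed=fixed,
        residuals=residuals,
        rmse=rmse,
        notes=(
            "ordinary least squares on y = Tm - 1000*dH/dS + 273.15 = -c*GC% - a/n - b; "
            "reconstruction of an unstated derivation, not an assertion about it"
        ),
    )


def evaluate_rmse(
    training: Sequence[tuple[ThermoResult, float]],
    coefficients: TmCoefficients | None = None,
    *,
    extrapolate: bool = False,
) -> float:
    """In-sample rmse (degC) of a fixed coefficient set on (thermo, measured) rows."""
    from .tm_model import predict_tm

    errors = [
        predict_tm(t, coefficients, extrapolate=extrapolate).tm_celsius - m
        for t, m in training
    ]
    return float(np.sqrt(np.mean(np.square(errors))))
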
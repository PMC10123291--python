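"""Five-parameter logistic (5PL) immunoassay calibration and normalization.

Multiplex bead assays report a fluorescence response per well; standard
wells at known concentrations define, per analyte, a sigmoid standard curve

    y = D + (A - D) / (1 + (x / C)**B)**g

with lower/upper asymptotes A and D, inflection-scale C (pg/mL), slope B
and asymmetry g > 0 (g = 1 recovers the symmetric 4PL). Sample responses
are inverted through the fitted curve, doubled for the 1:2 assay dilution,
background-subtracted against medium-only wells, and expressed per animal
as n-fold of the pooled untreated control wells.

Responses outside the open asymptote interval cannot be inverted and are
censored (flagged, never extrapolated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "FivePLParams",
    "CalibrationError",
    "forward_5pl",
    "inverse_5pl",
    "fit_5pl",
    "FivePLCalibrator",
    "concentration_from_response",
    "correct_sample",
    "fold_change",
    "process_plate",
]

OK = "ok"
CENSORED_LOW = "censored_low"
CENSORED_HIGH = "censored_high"
ZERO_CONTROL = "zero_control_mean"


class CalibrationError(RuntimeError):
    """Raised when a standard curve cannot be fitted for an analyte."""


@dataclass(frozen=True)
class FivePLParams:
    """Fitted 5PL parameters plus fit diagnostics."""

    A: float  # lower asymptote (response units)
    D: float  # upper asymptote (response units)
    C: float  # inflection-scale concentration (pg/mL)
    B: float  # slope
    g: float  # asymmetry (>0; 1 = 4PL)
    sse: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.g <= 0:
            raise ValueError("g must be > 0")
        if self.A == self.D:
            raise ValueError("A and D must differ")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.A, self.D, self.C, self.B, self.g)


def forward_5pl(x, A: float, D: float, C: float, B: float, g: float):
    """Evaluate the 5PL response at concentration ``x`` (vectorized)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        u = np.where(x > 0, (x / C) ** B, 0.0 if B > 0 else np.inf)
        y = D + (A - D) / (1.0 + u) ** g
    return y if y.ndim else float(y)


def inverse_5pl(y, A: float, D: float, C: float, B: float, g: float):
    """Closed-form inverse of :func:`forward_5pl` on the open response interval."""
    y = np.asarray(y, dtype=float)
    x = C * (((A - D) / (y - D)) ** (1.0 / g) - 1.0) ** (1.0 / B)
    return x if x.ndim else float(x)


def _fit_residuals(theta, x, y, weights):
    A, D, logC, B, logg = theta
    pred = forward_5pl(x, A, D, np.exp(logC), B, np.exp(logg))
    return (pred - y) * weights


def fit_5pl(
    concentrations: Sequence[float],
    responses: Sequence[float],
    weighting: str = "none",
    analyte: str | None = None,
) -> FivePLParams:
    """Least-squares 5PL fit of a standard series.

    Multi-start (log-spaced C starts bracketing the concentration range,
    both slope signs) nonlinear least squares; unweighted by default,
    ``weighting="inv_y2"`` for 1/y**2 relative weighting. Deterministic for
    a given data set and configuration.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be matching 1-D arrays")
    if np.unique(x[x > 0]).size < 4:
        raise CalibrationError(
            f"analyte {analyte!r}: need >=4 distinct positive standard concentrations"
        )
    if np.ptp(y) == 0:
        raise CalibrationError(f"analyte {analyte!r}: degenerate (constant) responses")
    if weighting == "none":
        w = np.ones_like(y)
    elif weighting == "inv_y2":
        w = 1.0 / np.maximum(np.abs(y), 1e-12)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    order = np.argsort(x)
    increasing = y[order][-1] >= y[order][0]
    a0 = float(y.min()) if increasing else float(y.max())
    d0 = float(y.max()) if increasing else float(y.min())
    span = max(abs(d0 - a0), 1e-6)
    xpos = x[x > 0]
    c_starts = np.exp(np.linspace(np.log(xpos.min()), np.log(xpos.max()), 3))
    b0 = 1.0 if increasing else -1.0
    ylo, yhi = float(y.min()), float(y.max())
    lower = np.array([ylo - 10 * span, ylo - 10 * span,
                      np.log(xpos.min()) - 7.0, -20.0, np.log(0.02)])
    upper = np.array([yhi + 10 * span, yhi + 10 * span,
                      np.log(xpos.max()) + 7.0, 20.0, np.log(50.0)])

    best = None
    scale = max(abs(a0), abs(d0), 1.0)
    for c0 in c_starts:
        theta0 = np.array([a0, d0, np.log(c0), b0, 0.0])
        try:
            res = least_squares(
                _fit_residuals,
                theta0,
                args=(x, y, w),
                bounds=(lower, upper),
                xtol=1e-13,
                ftol=1e-13,
                gtol=1e-13,
                max_nfev=600,
            )
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < (1e-10 * scale) ** 2:
            break  # already at an essentially exact fit
    if best is None:
        raise CalibrationError(f"analyte {analyte!r}: all fit starts failed")
    if not best.success:  # evaluation budget hit: polish from the best point
        best = least_squares(
            _fit_residuals, best.x, args=(x, y, w), bounds=(lower, upper),
            xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=3000,
        )
    A, D, logC, B, logg = best.x
    sse = float(2.0 * best.cost)
    converged = bool(best.success) and np.isfinite(sse)
    if not converged:
        raise CalibrationError(f"analyte {analyte!r}: 5PL fit did not converge")
    return FivePLParams(A=float(A), D=float(D), C=float(np.exp(logC)),
                        B=float(B), g=float(np.exp(logg)), sse=sse, converged=True)


class FivePLCalibrator(BaseEstimator):
    """Standard-curve calibrator with a scikit-learn style interface.

    ``fit(concentrations, responses)`` estimates the five parameters;
    ``response(x)`` evaluates the forward curve and ``concentration(y)``
    inverts it, returning censoring flags for responses outside the fitted
    asymptote interval.

    Parameters
    ----------
    weighting : {"none", "inv_y2"}, default "none"
        Residual weighting of the least-squares fit.
    """

    def __init__(self, weighting: str = "none"):
        self.weighting = weighting

    def fit(self, concentrations, responses, analyte: str | None = None):
        self.params_ = fit_5pl(concentrations, responses,
                               weighting=self.weighting, analyte=analyte)
        self.sse_ = self.params_.sse
        self.converged_ = self.params_.converged
        return self

    def response(self, concentrations):
        return forward_5pl(concentrations, *self.params_.as_tuple())

    def concentration(self, responses):
        return concentration_from_response(self.params_, responses)


def concentration_from_response(params: FivePLParams, responses):
    """Invert responses to concentrations with range censoring.

    Returns ``(concentrations, flags)``; out-of-range responses yield NaN
    with ``censored_low`` / ``censored_high`` flags, never an extrapolated
    value. ``censored_low`` marks responses at or beyond the asymptote on
    the low-concentration side.
    """
    y = np.atleast_1d(np.asarray(responses, dtype=float))
    A, D, C, B, g = params.as_tuple()
    lo, hi = min(A, D), max(A, D)
    inside = (y > lo) & (y < hi)
    conc = np.full(y.shape, np.nan)
    flags = np.full(y.shape, OK, dtype=object)
    if inside.any():
        conc[inside] = inverse_5pl(y[inside], A, D, C, B, g)
    # x -> 0 gives response A when B > 0 (and D when B < 0)
    low_end = A if B > 0 else D
    below = ~inside & ((y <= lo) if low_end == lo else (y >= hi))
    flags[below] = CENSORED_LOW
    flags[~inside & ~below] = CENSORED_HIGH
    if np.isscalar(responses) or np.asarray(responses).ndim == 0:
        return float(conc[0]), str(flags[0])
    return conc, flags


def correct_sample(concentration, dilution_factor: float = 2.0, background_mean: float = 0.0):
    """Dilution-correct and background-subtract an interpolated concentration.

    corrected = concentration * dilution_factor - background_mean, floored
    at 0 (concentrations are physical quantities).
    """
    if background_mean < 0:
        raise ValueError("background_mean must be >= 0")
    c = np.asarray(concentration, dtype=float)
    out = np.maximum(c * dilution_factor - background_mean, 0.0)
    return float(out) if out.ndim == 0 else out


def fold_change(values, control_values):
    """n-fold of each treatment value over the mean of pooled control wells.

    Returns ``(n_folds, reason)``; a zero control mean yields NaN with the
    ``zero_control_mean`` reason code (no pseudo-count is invented).
    """
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size == 0:
        raise ValueError("no control wells")
    ctrl_mean = float(np.nanmean(control_values))
    v = np.asarray(values, dtype=float)
    if ctrl_mean == 0:
        out = np.full(v.shape, np.nan)
        reason = ZERO_CONTROL
    else:
        out = v / ctrl_mean
        reason = OK
    if out.ndim == 0:
        return float(out), reason
    return out, reason


def process_plate(
    standards: pd.DataFrame,
    samples: pd.DataFrame,
    dilution_factor: float = 2.0,
    weighting: str = "none",
) -> tuple[pd.DataFrame, dict[str, FivePLParams]]:
    """Run the full calibration chain on a multiplex plate.

    ``standards``: columns [analyte, concentration, response].
    ``samples``: columns [well, role, analyte, response, animal, genotype,
    treatment, dilution] with roles treatment/control/background.

    Per analyte: fit the 5PL, invert every non-standard well, double by the
    dilution factor, subtract the mean background-well concentration
    (floored at 0), then express each treatment/control well per animal as
    n-fold of that animal's pooled control-well mean.

    Returns the tidy record table and the per-analyte fitted parameters.
    """
    required = {"well", "role", "analyte", "response", "animal", "genotype", "treatment"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    records = []
    calibrations: dict[str, FivePLParams] = {}
    for analyte, std in standards.groupby("analyte", sort=False):
        params = fit_5pl(std["concentration"], std["response"],
                         weighting=weighting, analyte=str(analyte))
        calibrations[str(analyte)] = params
        wells = samples[samples["analyte"] == analyte].copy()
        if wells.empty:
            continue
        conc, flags = concentration_from_response(params, wells["response"].to_numpy())
        wells["concentration"] = conc
        wells["flag"] = flags
        bg = wells[wells["role"] == "background"]["concentration"]
        bg_mean = float(np.nanmean(bg)) if len(bg) else 0.0
        if "dilution" in wells.columns:
            dil = wells["dilution"].astype(float).to_numpy()
        else:
            dil = np.full(len(wells), float(dilution_factor))
        is_sample = (wells["role"] != "background").to_numpy()
        wells["corrected"] = np.nan
        wells.loc[is_sample, "corrected"] = np.maximum(
            wells.loc[is_sample, "concentration"].to_numpy() * dil[is_sample] - bg_mean,
            0.0,
        )
        wells["background_mean"] = bg_mean
        records.append(wells)
    if not records:
        raise CalibrationError("no analytes in standards table")
    table = pd.concat(records, ignore_index=True)

    table["n_fold"] = np.nan
    table["n_fold_reason"] = pd.NA
    for (analyte, animal), grp in table[table["role"] != "background"].groupby(
        ["analyte", "animal"], sort=False
    ):
        ctrl = grp[grp["role"] == "control"]["corrected"].to_numpy()
        if ctrl.size == 0:
            raise ValueError(f"animal {animal!r} has no control wells for {analyte!r}")
        treat_idx = grp.index[grp["role"] == "treatment"]
        nf, reason = fold_change(table.loc[treat_idx, "corrected"].to_numpy(), ctrl)
        table.loc[treat_idx, "n_fold"] = nf
        table.loc[treat_idx, "n_fold_reason"] = reason
    return table, calibrations
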
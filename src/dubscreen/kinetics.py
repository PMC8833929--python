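"""One-phase exponential decay fitting for chase experiments.

The model is Y(t) = (Y0 - plateau) * exp(-k t) + plateau with k >= 0 and
half-life t1/2 = ln(2)/k. For fluorescent-reporter chases the plateau is
held at zero by default (the reporter decays to background); a free plateau
is available for densitometry series with residual background. Fits are
unweighted least squares; minutes-labeled series are converted to hours at
construction so every reported rate is per hour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigurationError, ParameterError, SampleSizeError

__all__ = [
    "DecaySeries",
    "DecayFit",
    "fit_one_phase_decay",
    "half_life",
    "compare_chase_conditions",
]


@dataclass
class DecaySeries:
    """A labeled intensity-versus-time chase series.

    ``unit`` may be ``"hours"`` or ``"minutes"``; minutes are converted to
    hours on construction. Times must be nonnegative and strictly
    increasing.
    """

    condition: str
    times: np.ndarray
    intensities: np.ndarray
    source: str = "imaging"
    unit: str = "hours"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.unit == "minutes":
            self.times = self.times / 60.0
            self.unit = "hours"
        elif self.unit != "hours":
            raise ConfigurationError(f"unknown time unit {self.unit!r}")
        if self.times.size != self.intensities.size:
            raise ConfigurationError("times and intensities differ in length")
        if self.times.size and (np.any(self.times < 0) or np.any(np.diff(self.times) <= 0)):
            raise ConfigurationError("times must be nonnegative and strictly increasing")
        if self.source not in ("imaging", "densitometry"):
            raise ConfigurationError(f"unknown source {self.source!r}")


@dataclass
class DecayFit:
    condition: str
    y0: float
    plateau: float
    k: float  # per hour
    half_life: float  # hours; inf when k == 0
    rss: float
    converged: bool
    plateau_mode: str

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.y0 - self.plateau) * np.exp(-self.k * t) + self.plateau


def _initial_guess(t: np.ndarray, y: np.ndarray, plateau: float) -> tuple[float, float]:
    """Y0 from the first sample; k from a log-linear regression on
    plateau-subtracted values (nonpositive values excluded)."""
    y0 = float(y[0])
    shifted = y - plateau
    ok = shifted > 0
    if ok.sum() >= 2:
        slope = np.polyfit(t[ok], np.log(shifted[ok]), 1)[0]
        k0 = max(-float(slope), 0.0)
    else:
        k0 = 0.0
    return y0, k0


def fit_one_phase_decay(series: DecaySeries,
                        plateau_mode: str = "fixed_zero") -> DecayFit:
    """Least-squares fit of the one-phase decay to a chase series.

    ``plateau_mode`` is ``"fixed_zero"`` (two free parameters Y0, k) or
    ``"free"`` (three). A non-decreasing series yields k = 0 with a warning
    rather than an error; the half-life is then reported as infinity.
    """
    if plateau_mode not in ("fixed_zero", "free"):
        raise ParameterError(f"unknown plateau_mode {plateau_mode!r}")
    t, y = series.times, series.intensities
    min_pts = 2 if plateau_mode == "fixed_zero" else 3
    if t.size < min_pts:
        raise SampleSizeError(
            f"{plateau_mode} fit needs at least {min_pts} points, got {t.size}"
        )

    plateau0 = 0.0 if plateau_mode == "fixed_zero" else float(np.min(y))
    y00, k0 = _initial_guess(t, y, plateau0)

    if y[-1] >= y[0]:
        warnings.warn(
            f"series {series.condition!r} is non-decreasing; reporting k = 0",
            stacklevel=2,
        )
        plateau = plateau0 if plateau_mode == "free" else 0.0
        resid = y - float(np.mean(y))
        return DecayFit(series.condition, float(np.mean(y)), plateau, 0.0,
                        math.inf, float(np.sum(resid**2)), True, plateau_mode)

    if plateau_mode == "fixed_zero":
        def resid(p):
            return p[0] * np.exp(-p[1] * t) - y

        x0 = [max(y00, 1e-12), max(k0, 1e-6)]
        lb, ub = [0.0, 0.0], [np.inf, np.inf]
    else:
        def resid(p):
            return (p[0] - p[2]) * np.exp(-p[1] * t) + p[2] - y

        x0 = [max(y00, 1e-12), max(k0, 1e-6), plateau0]
        lb, ub = [0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]

    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12,
                        gtol=1e-12, max_nfev=500 * len(x0))
    y0 = float(sol.x[0])
    k = float(sol.x[1])
    plateau = float(sol.x[2]) if plateau_mode == "free" else 0.0
    hl = math.inf if k <= 0 else math.log(2) / k
    return DecayFit(series.condition, y0, plateau, k, hl,
                    float(np.sum(sol.fun**2)), bool(sol.success), plateau_mode)


def half_life(k: float) -> float:
    """Half-life ln(2)/k in hours for a decay rate k (per hour)."""
    if k <= 0:
        raise ParameterError("half-life requires k > 0")
    return math.log(2) / k


def compare_chase_conditions(fits: list[DecayFit], control_condition: str,
                             reference_time_h: float | None = None) -> pd.DataFrame:
    """Tabulate k, half-life, and remaining fraction per condition, with
    ratios against the designated control.

    ``reference_time_h`` defaults to the control's half-life, so the control
    row's remaining fraction is 0.5 when its plateau is zero.
    """
    if len(fits) < 2:
        raise SampleSizeError("need at least 2 fitted conditions to compare")
    by_cond = {f.condition: f for f in fits}
    if control_condition not in by_cond:
        raise ParameterError(f"control condition {control_condition!r} not among fits")
    ctrl = by_cond[control_condition]
    if reference_time_h is None:
        reference_time_h = ctrl.half_life if math.isfinite(ctrl.half_life) else 0.0

    rows = []
    for f in fits:
        remaining = float(f.predict(reference_time_h) / f.y0) if f.y0 > 0 else np.nan
        rows.append(
            {
                "condition": f.condition,
                "k_per_h": f.k,
                "half_life_h": f.half_life,
                "remaining_fraction": remaining,
                "k_ratio_vs_control": f.k / ctrl.k if ctrl.k > 0 else np.nan,
                "half_life_ratio_vs_control": (
                    f.half_life / ctrl.half_life
                    if math.isfinite(f.half_life) and math.isfinite(ctrl.half_life)
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
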
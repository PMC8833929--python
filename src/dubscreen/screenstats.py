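"""Hit calling for the overexpression screen.

A construct is a hit when it passes all three criteria against the
empty-vector control measured in the same run:

1. its final-time-point per-cell reporter intensities are significantly
   higher than control, with the significance cutoff chosen as the knee
   point of all constructs' p-values on a logarithmic waterfall curve
   (applied as ``p < cutoff``);
2. its median intensity at the final time point is strictly more than
   1.2-fold the control median;
3. its mean-intensity increase over the last 24 h exceeds the control's.

The t-test entering criterion 1 is the classical pooled-variance Student
form (Welch available behind a flag); Wilcoxon rank-sum p-values with
Bonferroni correction are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CoverageError,
    DegenerateControlError,
    KneePointError,
    ParameterError,
    SampleSizeError,
)
from .imquant import WellTimeSeries

__all__ = [
    "TestResults",
    "ConstructStats",
    "ScreenResult",
    "two_sample_tests",
    "knee_point_cutoff",
    "median_fold",
    "last24_increment",
    "call_hits",
    "screen_measurements",
]


class TestResults(NamedTuple):
    p_ttest: float
    p_wilcoxon: float
    p_bonferroni: float


def two_sample_tests(treated, control, m_tests: int = 1,
                     exact_max_n: int = 25, welch: bool = False) -> TestResults:
    """Two-sided t-test and Wilcoxon rank-sum p-values, plus Bonferroni.

    The Wilcoxon p is exact (full enumeration) when both samples have at
    most ``exact_max_n`` observations and no ties are present, otherwise the
    tie-corrected normal approximation is used. The Bonferroni value is
    ``min(1, m_tests * p_wilcoxon)``.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 2 or control.size < 2:
        raise SampleSizeError("both samples need at least 2 observations")
    if m_tests < 1:
        raise ParameterError("m_tests must be >= 1")

    if np.ptp(treated) == 0 and np.ptp(control) == 0:
        p_t = 1.0 if treated[0] == control[0] else 0.0
    else:
        p_t = float(stats.ttest_ind(treated, control, equal_var=not welch).pvalue)

    pooled = np.concatenate([treated, control])
    has_ties = np.unique(pooled).size < pooled.size
    if max(treated.size, control.size) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    p_w = float(
        stats.mannwhitneyu(
            treated, control, alternative="two-sided", method=method,
            use_continuity=False,
        ).pvalue
    )
    return TestResults(p_t, p_w, min(1.0, m_tests * p_w))


def knee_point_cutoff(pvalues: Sequence[float], tol: float = 1e-9) -> float:
    """P-value at the knee of the logarithmic waterfall curve.

    Sorts ``-log10(p)`` in decreasing order against rank, min-max normalizes
    both axes to [0, 1], and returns the p-value at the point of maximum
    perpendicular distance from the chord joining the first and last points.
    Ties in distance resolve to the smaller p (more conservative cutoff).
    The cutoff is meant to be applied as ``p < cutoff``.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size < 3:
        raise SampleSizeError("knee point needs at least 3 p-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    y = -np.log10(p)  # decreasing
    if np.ptp(y) == 0:
        raise KneePointError(
            "all p-values equal; no knee exists — use a fixed cutoff"
        )
    x = np.linspace(0.0, 1.0, p.size)
    yn = (y - y[-1]) / (y[0] - y[-1])
    # chord joins (0, 1) and (1, 0); |x + y - 1| / sqrt(2) is the distance
    d = np.abs(x + yn - 1.0) / math.sqrt(2.0)
    if np.all(d < tol):
        raise KneePointError(
            "waterfall is collinear in log space; no knee — use a fixed cutoff"
        )
    return float(p[int(np.argmax(d))])  # argmax takes the first (smaller p) on ties


def median_fold(treated, control) -> float:
    """Ratio of treated to control median intensity."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    med_c = float(np.median(control))
    if med_c <= 0:
        raise DegenerateControlError("control median must be > 0")
    return float(np.median(treated)) / med_c


def last24_increment(series: WellTimeSeries, window_h: float = 24.0,
                     stat: str = "mean") -> float:
    """Summary-intensity change over the final ``window_h`` hours.

    Uses the per-time-point summary mean (median behind ``stat``); the value
    at ``t_end - window_h`` is linearly interpolated when no sample lies
    exactly there.
    """
    summ = series.summary
    t = summ["time_h"].to_numpy(float)
    v = summ[stat].to_numpy(float)
    if t.size < 2 or t[-1] - t[0] < window_h:
        raise CoverageError(
            f"series covers {t[-1] - t[0] if t.size else 0:g} h; "
            f"needs >= {window_h:g} h ending at the final time point"
        )
    t0 = t[-1] - window_h
    return float(v[-1] - np.interp(t0, t, v))


@dataclass
class ConstructStats:
    construct_id: str
    n_cells_final: int
    p_ttest: float
    p_wilcoxon: float
    p_bonferroni: float
    median_fold: float
    increment_last24: float
    control_increment_last24: float
    passed_significance: bool
    passed_fold: bool
    passed_increment: bool

    @property
    def is_hit(self) -> bool:
        return self.passed_significance and self.passed_fold and self.passed_increment


@dataclass
class ScreenResult:
    constructs: list[ConstructStats]
    cutoff: float
    cutoff_method: str
    control_id: str
    control_increment: float

    @property
    def hits(self) -> list[str]:
        return [c.construct_id for c in self.constructs if c.is_hit]

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for c in self.constructs:
            row = asdict(c)
            row["is_hit"] = c.is_hit
            rows.append(row)
        return pd.DataFrame(rows)


def call_hits(series: Mapping[str, WellTimeSeries], control_id: str,
              fold_threshold: float = 1.2,
              cutoff: "str | float" = "knee",
              m_tests: int | None = None,
              welch: bool = False) -> ScreenResult:
    """Apply the three-criterion hit-calling procedure to a screen.

    ``series`` maps construct ids (including the control) to their pooled
    time series; per-cell vectors at the final shared time point feed the
    two-sample tests and the fold criterion. ``cutoff`` is ``"knee"`` for the
    waterfall knee on the uncorrected t-test p-values, or a fixed numeric
    p-value.
    """
    if control_id not in series:
        raise ParameterError(f"control construct {control_id!r} missing from series")
    treated_ids = [cid for cid in series if cid != control_id]
    if cutoff == "knee" and len(treated_ids) < 3:
        raise SampleSizeError("knee mode requires at least 3 treated constructs")

    control = series[control_id]
    t_final = float(control.times[-1])
    control_vec = control.values[t_final]
    control_incr = last24_increment(control)
    m = m_tests if m_tests is not None else len(treated_ids)

    stats_rows: list[ConstructStats] = []
    pvals: list[float] = []
    for cid in treated_ids:
        s = series[cid]
        if float(s.times[-1]) != t_final or t_final not in s.values:
            raise CoverageError(
                f"construct {cid!r} lacks the final {t_final:g} h time point"
            )
        vec = s.values[t_final]
        tests = two_sample_tests(vec, control_vec, m_tests=m, welch=welch)
        fold = median_fold(vec, control_vec)
        incr = last24_increment(s)
        stats_rows.append(
            ConstructStats(
                construct_id=cid,
                n_cells_final=int(vec.size),
                p_ttest=tests.p_ttest,
                p_wilcoxon=tests.p_wilcoxon,
                p_bonferroni=tests.p_bonferroni,
                median_fold=fold,
                increment_last24=incr,
                control_increment_last24=control_incr,
                passed_significance=False,  # set once the cutoff is known
                passed_fold=fold > fold_threshold,
                passed_increment=incr > control_incr,
            )
        )
        pvals.append(tests.p_ttest)

    if cutoff == "knee":
        chosen = knee_point_cutoff(pvals)
        method = "knee"
    else:
        chosen = float(cutoff)
        if not 0 < chosen <= 1:
            raise ParameterError("fixed cutoff must lie in (0, 1]")
        method = "fixed"
    for row in stats_rows:
        row.passed_significance = row.p_ttest < chosen

    return ScreenResult(stats_rows, chosen, method, control_id, control_incr)


def screen_measurements(measurements: pd.DataFrame, control_id: str = "EV",
                        value_column: str = "mean_reporter",
                        **kwargs) -> ScreenResult:
    """Convenience wrapper: build per-construct series from a per-cell
    measurement table and call hits."""
    from .imquant import build_timeseries

    series = build_timeseries(measurements, value_column=value_column)
    return call_hits(series, control_id=control_id, **kwargs)
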
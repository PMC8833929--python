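"""Cohort- and bench-level statistics.

Expression ranking of a gene within a gene set (median FPKM across samples),
quartile stratification, Kaplan-Meier product-limit curves and the two-group
Mantel-Cox (log-rank) test computed from the formula (observed vs expected
events over risk sets with hypergeometric variance), paired growth-curve
comparison, delta-delta-Ct relative expression, and densitometry fold
ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateSplitError,
    IntegrityError,
    PairingError,
    ParameterError,
    SampleSizeError,
)

__all__ = [
    "LogRankResult",
    "rank_gene",
    "quartile_groups",
    "logrank",
    "km_curve",
    "growth_comparison",
    "ddct",
    "densitometry_fold",
]


def rank_gene(fpkm: pd.DataFrame, gene: str,
              gene_set: "list[str] | None" = None,
              stat: str = "median") -> tuple[int, float]:
    """Rank of ``gene`` within ``gene_set`` by per-gene summary expression.

    Rank 1 is the highest expression; ties share the smaller rank.
    Percentile is ``100 * (1 - (rank - 1) / |set|)``. ``stat`` is
    ``"median"`` (robust to FPKM outliers) or ``"mean"``.
    """
    genes = list(gene_set) if gene_set is not None else list(fpkm.index)
    if gene not in genes:
        raise ParameterError(f"gene {gene!r} not in the gene set")
    missing = [g for g in genes if g not in fpkm.index]
    if missing:
        raise ParameterError(f"genes absent from the matrix: {missing[:5]}")
    sub = fpkm.loc[genes]
    summary = sub.median(axis=1) if stat == "median" else sub.mean(axis=1)
    ranks = stats.rankdata(-summary.to_numpy(float), method="min")
    rank = int(ranks[genes.index(gene)])
    percentile = 100.0 * (1.0 - (rank - 1) / len(genes))
    return rank, percentile


def quartile_groups(expression: "pd.Series | pd.DataFrame", gene: str | None = None
                    ) -> pd.Series:
    """Partition samples into bottom / middle / top expression quartiles.

    Boundaries are the 25th and 75th percentiles (linear interpolation);
    boundary ties are assigned to the lower group (bottom includes values
    equal to Q25; top is strictly above Q75).
    """
    if isinstance(expression, pd.DataFrame):
        if gene is None:
            raise ParameterError("gene is required with a matrix input")
        if gene not in expression.index:
            raise ParameterError(f"gene {gene!r} not in the matrix")
        expression = expression.loc[gene]
    x = expression.to_numpy(float)
    if x.size < 4:
        raise SampleSizeError("quartile groups need at least 4 samples")
    if np.ptp(x) == 0:
        raise DegenerateSplitError("constant expression; quartiles undefined")
    q25, q75 = np.quantile(x, [0.25, 0.75])
    labels = np.where(x <= q25, "bottom", np.where(x > q75, "top", "middle"))
    return pd.Series(labels, index=expression.index, name="quartile_group")


@dataclass
class LogRankResult:
    chi_square: float
    p: float
    observed: dict[str, float]
    expected: dict[str, float]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"observed": self.observed, "expected": self.expected}
        ).rename_axis("group")


def logrank(times, events, groups) -> LogRankResult:
    """Two-group Mantel-Cox log-rank test.

    At each distinct event time, expected events per group are proportional
    to the groups' at-risk counts, with the hypergeometric variance; the
    statistic (O1 - E1)^2 / Var is referred to chi-square with 1 df.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if np.any(t < 0):
        raise ParameterError("survival times must be >= 0")
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ParameterError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if e.sum() < 1:
        raise SampleSizeError("log-rank needs at least one event")
    is_g1 = g == labels[0]
    if is_g1.all() or not is_g1.any():
        raise ParameterError("one group is empty")

    o1 = 0.0
    e1 = 0.0
    var = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & is_g1).sum()
        d = int(((t == et) & (e == 1)).sum())
        d1 = int(((t == et) & (e == 1) & is_g1).sum())
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        chi2 = 0.0
    else:
        chi2 = (o1 - e1) ** 2 / var
    p = float(stats.chi2.sf(chi2, 1)) if var > 0 else 1.0
    total_events = float(e.sum())
    observed = {labels[0]: o1, labels[1]: total_events - o1}
    expected = {labels[0]: e1, labels[1]: total_events - e1}
    return LogRankResult(float(chi2), p, observed, expected)


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step table with columns ``time, n_at_risk, n_events,
    survival``, starting from S(0) = 1. Right-censored samples leave the
    risk set without dropping the curve.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size < 1:
        raise SampleSizeError("need at least one sample")
    if np.any(t < 0):
        raise ParameterError("survival times must be >= 0")
    rows = [{"time": 0.0, "n_at_risk": int(t.size), "n_events": 0, "survival": 1.0}]
    s = 1.0
    for et in np.unique(t[e == 1]):
        n = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n
        rows.append({"time": float(et), "n_at_risk": n, "n_events": d, "survival": s})
    return pd.DataFrame(rows)


def growth_comparison(curves: pd.DataFrame, day_threshold: float = 4.0
                      ) -> dict:
    """Paired two-sided t-test on live-cell counts after a threshold day.

    ``curves`` has columns ``condition, replicate, day, count`` with exactly
    two conditions and matched replicates; per-replicate counts on days
    strictly greater than ``day_threshold`` are pooled into matched pairs.
    A zero-variance nonzero difference is reported as p = 0 with a warning.
    """
    required = {"condition", "replicate", "day", "count"}
    if not required.issubset(curves.columns):
        raise IntegrityError(f"curves must have columns {sorted(required)}")
    conditions = sorted(curves["condition"].unique().tolist())
    if len(conditions) != 2:
        raise PairingError(f"need exactly 2 conditions, got {len(conditions)}")
    late = curves[curves["day"] > day_threshold]
    wide = late.pivot_table(index=["replicate", "day"], columns="condition",
                            values="count", aggfunc="first")
    if wide.isna().any().any() or len(wide) < 2:
        raise PairingError(
            "replicate/day pairs do not match across conditions "
            "(need >= 2 matched pairs after the threshold day)"
        )
    a = wide[conditions[0]].to_numpy(float)
    b = wide[conditions[1]].to_numpy(float)
    diff = a - b
    if np.allclose(diff, 0):
        return {"t": 0.0, "p": 1.0, "n_pairs": len(diff),
                "mean_difference": 0.0, "conditions": conditions}
    if np.ptp(diff) == 0:
        warnings.warn(
            "constant nonzero paired difference; t statistic is degenerate",
            stacklevel=2,
        )
        return {"t": np.inf if diff[0] > 0 else -np.inf, "p": 0.0,
                "n_pairs": len(diff), "mean_difference": float(diff.mean()),
                "conditions": conditions}
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "n_pairs": len(diff), "mean_difference": float(diff.mean()),
            "conditions": conditions}


def ddct(ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control
         ) -> float:
    """Relative expression by the delta-delta-Ct method.

    Replicate Ct values are averaged before differencing; the result is
    ``2 ** -ddct`` with ``ddct = (Ct_target - Ct_ref)_treated -
    (Ct_target - Ct_ref)_control``.
    """
    vals = [np.mean(np.asarray(v, dtype=float)) for v in
            (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)]
    if not all(np.isfinite(v) for v in vals):
        raise ParameterError("all Ct values must be finite")
    delta_delta = (vals[0] - vals[1]) - (vals[2] - vals[3])
    return float(2.0 ** (-delta_delta))


def densitometry_fold(target_band: float, loading_band: float,
                      target_ref: float, loading_ref: float) -> float:
    """Loading-normalized band-intensity fold versus a reference lane."""
    if loading_band <= 0 or loading_ref <= 0:
        raise ParameterError("loading-control bands must be > 0")
    return (target_band / loading_band) / (target_ref / loading_ref)
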
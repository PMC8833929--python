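"""Cohort statistics against hand computations and lifelines cross-checks."""

import numpy as np
import pandas as pd
import pytest

from dubscreen import cohort, simdata
from dubscreen.errors import (
    DegenerateSplitError,
    PairingError,
    ParameterError,
    SampleSizeError,
)


# ---------------------------------------------------------------------------
# expression ranking
# ---------------------------------------------------------------------------

def _fpkm(values_by_gene):
    return pd.DataFrame(values_by_gene).T


def test_highest_median_ranks_first():
    fpkm = _fpkm({"a": [10, 12], "b": [5, 6], "c": [1, 2]})
    rank, pct = cohort.rank_gene(fpkm, "a")
    assert (rank, pct) == (1, 100.0)


def test_simulated_focal_gene_lands_in_top_five_percent():
    cfg = simdata.CohortSimConfig(target_gene_rank=9, seed=0)
    fpkm, _, _ = simdata.simulate_cohort(cfg)
    rank, pct = cohort.rank_gene(fpkm, "focal")
    assert rank == 9
    assert pct >= 95.0


def test_tied_genes_share_smaller_rank():
    fpkm = _fpkm({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
    for g in "abc":
        assert cohort.rank_gene(fpkm, g)[0] == 1


def test_missing_gene_rejected():
    fpkm = _fpkm({"a": [1, 2]})
    with pytest.raises(ParameterError):
        cohort.rank_gene(fpkm, "zzz")


def test_rank_invariant_to_sample_order_and_common_rescaling():
    rng = np.random.default_rng(0)
    fpkm = pd.DataFrame(rng.lognormal(2, 1, (20, 30)),
                        index=[f"g{i}" for i in range(20)])
    base = cohort.rank_gene(fpkm, "g7")
    shuffled = fpkm.sample(frac=1.0, axis=1, random_state=1)
    assert cohort.rank_gene(shuffled, "g7") == base
    assert cohort.rank_gene(3.0 * fpkm, "g7") == base


# ---------------------------------------------------------------------------
# quartile groups
# ---------------------------------------------------------------------------

def test_eight_distinct_samples_split_two_and_two():
    expr = pd.Series(np.arange(1.0, 9.0), index=[f"s{i}" for i in range(8)])
    groups = cohort.quartile_groups(expr)
    counts = groups.value_counts()
    assert counts["top"] == 2 and counts["bottom"] == 2


def test_cohort_of_811_splits_203_per_extreme_quartile():
    rng = np.random.default_rng(0)
    expr = pd.Series(rng.lognormal(2, 1, 811))
    groups = cohort.quartile_groups(expr)
    counts = groups.value_counts()
    assert counts["top"] == 203 and counts["bottom"] == 203


def test_top_minimum_at_least_bottom_maximum():
    rng = np.random.default_rng(1)
    expr = pd.Series(rng.normal(0, 1, 101))
    groups = cohort.quartile_groups(expr)
    assert expr[groups == "top"].min() >= expr[groups == "bottom"].max()


def test_constant_expression_rejected():
    with pytest.raises(DegenerateSplitError):
        cohort.quartile_groups(pd.Series([3.0] * 10))


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_duplicated_groups_give_zero_chi_square():
    times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    events = [1, 1, 0, 1, 1, 0]
    groups = ["A"] * 3 + ["B"] * 3
    res = cohort.logrank(times, events, groups)
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_four_sample_risk_table_hand_computation():
    # A events at 1, 3; B events at 2, 4.
    # Risk sets: t=1 (2A,2B) E_A=.5 V=.25 | t=2 (1A,2B) E_A=1/3 V=2/9
    # t=3 (1A,1B) E_A=.5 V=.25 | t=4 (1B only) no variance contribution.
    # O_A=2, E_A=4/3, Var=13/18 -> chi2 = (2/3)^2 / (13/18) = 8/13
    res = cohort.logrank([1, 3, 2, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
    assert res.chi_square == pytest.approx(8 / 13, rel=1e-12)
    assert res.observed["A"] == 2
    assert res.expected["A"] == pytest.approx(4 / 3, rel=1e-12)
    total_o = sum(res.observed.values())
    total_e = sum(res.expected.values())
    assert total_o == pytest.approx(total_e)


def test_logrank_matches_lifelines():
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(2)
    t = rng.exponential(10, 80)
    e = (rng.random(80) < 0.8).astype(int)
    g = np.where(rng.random(80) < 0.5, "A", "B")
    ours = cohort.logrank(t, e, g)
    ref = logrank_test(t[g == "A"], t[g == "B"], e[g == "A"], e[g == "B"])
    assert ours.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
    assert ours.p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_consistent_with_permutation_null():
    rng = np.random.default_rng(3)
    t = rng.exponential(5, 30)
    e = np.ones(30, dtype=int)
    g = np.array(["A"] * 15 + ["B"] * 15)
    observed = cohort.logrank(t, e, g).chi_square
    perm = np.empty(1000)
    for i in range(1000):
        perm[i] = cohort.logrank(t, e, rng.permutation(g)).chi_square
    p_perm = float(np.mean(perm >= observed))
    from scipy import stats

    p_chi2 = float(stats.chi2.sf(observed, 1))
    assert p_perm == pytest.approx(p_chi2, abs=3 * np.sqrt(p_chi2 * (1 - p_chi2) / 1000) + 0.01)


def test_empty_group_rejected():
    with pytest.raises(ParameterError):
        cohort.logrank([1, 2], [1, 1], ["A", "A"])


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_no_events_keeps_curve_flat():
    km = cohort.km_curve([1.0, 2.0, 3.0], [0, 0, 0])
    assert np.all(km.survival == 1.0)


def test_all_events_step_down_by_product_limit():
    km = cohort.km_curve([1.0, 2.0, 3.0], [1, 1, 1])
    assert km.survival.tolist() == pytest.approx([1.0, 2 / 3, 1 / 3, 0.0])


def test_trailing_censored_sample_does_not_drop_curve():
    km_all = cohort.km_curve([1.0, 2.0, 3.0], [1, 1, 0])
    assert km_all.survival.iloc[-1] == pytest.approx(1 / 3)


def test_km_matches_lifelines():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(4)
    t = rng.exponential(10, 50)
    e = (rng.random(50) < 0.7).astype(int)
    ours = cohort.km_curve(t, e)
    ref = KaplanMeierFitter().fit(t, e)
    for _, row in ours.iterrows():
        assert row.survival == pytest.approx(
            float(ref.predict(row.time)), rel=1e-9, abs=1e-12
        )


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def _growth(rng, advantage=1.0, n_reps=4, noise=0.05, days=range(1, 9)):
    rows = []
    for rep in range(n_reps):
        for day in days:
            base = 1e4 * 2 ** (day / 2)
            rows.append({"condition": "vector", "replicate": rep, "day": day,
                         "count": base * rng.lognormal(0, noise)})
            rows.append({"condition": "otub1", "replicate": rep, "day": day,
                         "count": advantage * base * rng.lognormal(0, noise)})
    return pd.DataFrame(rows)


def test_identical_growth_curves_not_significant():
    df = _growth(np.random.default_rng(0), advantage=1.0, noise=0.0)
    res = cohort.growth_comparison(df, day_threshold=4)
    assert res["p"] == 1.0


def test_constant_positive_difference_is_degenerate():
    rows = []
    for rep in range(3):
        for day in (5, 6):
            rows.append({"condition": "a", "replicate": rep, "day": day, "count": 110.0})
            rows.append({"condition": "b", "replicate": rep, "day": day, "count": 100.0})
    with pytest.warns(UserWarning, match="degenerate"):
        res = cohort.growth_comparison(pd.DataFrame(rows), day_threshold=4)
    assert res["p"] == 0.0


def test_planted_growth_advantage_detected_in_most_seeds():
    detected = 0
    for seed in range(100):
        df = _growth(np.random.default_rng(seed), advantage=1.3)
        res = cohort.growth_comparison(df, day_threshold=4)
        detected += res["p"] < 0.05
    assert detected >= 90


def test_unmatched_replicates_rejected():
    df = _growth(np.random.default_rng(0))
    with pytest.raises(PairingError):
        cohort.growth_comparison(df[~((df.condition == "otub1") & (df.replicate == 0))],
                                 day_threshold=4)


# ---------------------------------------------------------------------------
# bench-level folds
# ---------------------------------------------------------------------------

def test_ddct_values():
    assert cohort.ddct(20, 20, 20, 20) == pytest.approx(1.0)
    assert cohort.ddct(25, 20, 24, 20) == pytest.approx(0.5)
    assert cohort.ddct(23, 20, 24, 20) == pytest.approx(2.0)
    # replicates average before differencing
    assert cohort.ddct([24.9, 25.1], [20.0, 20.0], 24, 20) == pytest.approx(0.5)


def test_ddct_requires_finite_ct():
    with pytest.raises(ParameterError):
        cohort.ddct(np.nan, 20, 24, 20)


def test_densitometry_fold_arithmetic_and_invariance():
    assert cohort.densitometry_fold(100, 100, 100, 100) == pytest.approx(1.0)
    assert cohort.densitometry_fold(150, 100, 100, 100) == pytest.approx(1.5)
    assert cohort.densitometry_fold(300, 200, 200, 200) == pytest.approx(
        cohort.densitometry_fold(150, 100, 100, 100)
    )
    with pytest.raises(ParameterError):
        cohort.densitometry_fold(1, 0, 1, 1)


def test_quartile_groups_need_four_samples():
    with pytest.raises(SampleSizeError):
        cohort.quartile_groups(pd.Series([1.0, 2.0, 3.0]))
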
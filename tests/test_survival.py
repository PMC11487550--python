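"""Survival machinery against hand-derived values, lifelines and a
permutation reference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import build_cohort
from imos.survival import (
    SkipSignal,
    bh_fdr,
    gene_survival_screen,
    km_estimate,
    logrank_test,
    pearson_test,
    split_by_gene_expression,
)


# ---------------------------------------------------------------- KM

def test_km_worked_fixture(km_worked_fixture):
    times, events = km_worked_fixture
    curve = km_estimate(times, events)
    assert curve.survival_at(1.0) == pytest.approx(3 / 4)
    assert curve.survival_at(3.0) == pytest.approx(3 / 8)
    assert list(curve.event_times) == [1.0, 3.0]
    assert list(curve.at_risk) == [4, 2]


def test_km_no_censoring_equals_empirical():
    curve = km_estimate([1.0, 3.0], [1, 1])
    assert curve.survival_at(1.0) == pytest.approx(0.5)
    assert curve.survival_at(3.0) == pytest.approx(0.0)


def test_km_all_censored_stays_at_one():
    curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
    assert curve.event_times.size == 0
    assert curve.survival_at(99.0) == 1.0


def test_km_random_no_censoring_matches_empirical(rng):
    for _ in range(20):
        n = int(rng.integers(3, 40))
        times = rng.exponential(10.0, n) + 0.01
        curve = km_estimate(times, np.ones(n, dtype=int))
        for t in rng.choice(times, size=5):
            emp = np.mean(times > t)
            assert curve.survival_at(t) == pytest.approx(emp, abs=1e-12)


def test_km_matches_lifelines_with_censoring(rng):
    lifelines = pytest.importorskip("lifelines")
    times = rng.exponential(10.0, 60) + 0.01
    events = rng.integers(0, 2, 60)
    if events.sum() == 0:
        events[0] = 1
    kmf = lifelines.KaplanMeierFitter().fit(times, events)
    curve = km_estimate(times, events)
    for t in np.unique(times[events == 1]):
        ref = float(kmf.predict(t))
        assert curve.survival_at(t) == pytest.approx(ref, abs=1e-9)


# ---------------------------------------------------------------- log-rank

def test_logrank_identical_multisets_null():
    times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    events = [1, 0, 1, 1, 0, 1]
    groups = ["A"] * 3 + ["B"] * 3
    res = logrank_test(times, events, groups)
    assert res.chi2 == 0.0 and res.p == 1.0
    assert res.direction == "none"


def test_logrank_observed_expected_conservation_and_symmetry(rng):
    times = rng.exponential(5.0, 30) + 0.01
    events = rng.integers(0, 2, 30)
    events[0] = 1
    groups = np.where(rng.random(30) < 0.5, "high", "low")
    if len(set(groups)) < 2:
        groups[0], groups[1] = "high", "low"
    res = logrank_test(times, events, groups, high_label="high")
    assert sum(res.observed.values()) == pytest.approx(sum(res.expected.values()), abs=1e-9)
    swapped = logrank_test(times, events, groups, high_label="low")
    assert swapped.chi2 == pytest.approx(res.chi2)
    assert swapped.p == pytest.approx(res.p)
    # designating the other group as "high" flips the sign of O - E
    oe = res.observed["high"] - res.expected["high"]
    oe_sw = swapped.observed["low"] - swapped.expected["low"]
    assert oe == pytest.approx(-oe_sw)


def test_logrank_direction_on_separated_groups():
    # group A dies early, group B late: A observed > expected
    times = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
    events = [1, 1, 1, 1, 1, 1]
    groups = ["A", "A", "A", "B", "B", "B"]
    res = logrank_test(times, events, groups, high_label="A")
    assert res.observed["A"] > res.expected["A"]
    assert res.direction == "high_worse"


def test_logrank_zero_events_flagged():
    res = logrank_test([1.0, 2.0], [0, 0], ["A", "B"])
    assert res.p == 1.0 and res.chi2 == 0.0 and res.direction == "none"


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank
    for _ in range(10):
        n = 40
        times = rng.exponential(5.0, n) + 0.01
        events = rng.integers(0, 2, n)
        events[:2] = 1
        groups = np.array(["high"] * (n // 2) + ["low"] * (n - n // 2))
        mine = logrank_test(times, events, groups, high_label="high")
        ref = ll_logrank(
            times[groups == "high"], times[groups == "low"],
            events[groups == "high"], events[groups == "low"],
        )
        assert mine.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_matches_permutation_reference(rng):
    """Analytic chi-square p agrees with a 10^4-draw label-permutation
    reference on a fixed 10-sample two-group dataset."""
    times = np.array([2.0, 3.0, 5.0, 7.0, 8.0, 9.0, 12.0, 15.0, 16.0, 20.0])
    events = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1])
    groups = np.array(["high"] * 5 + ["low"] * 5)
    obs = logrank_test(times, events, groups, high_label="high")
    n_perm = 10_000
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        chi = logrank_test(times, events, perm, high_label="high").chi2
        exceed += chi >= obs.chi2 - 1e-12
    p_perm = exceed / n_perm
    mc_sd = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    # chi-square approximation at n=10 is coarse; allow 4 MC sds + 0.03
    assert abs(obs.p - p_perm) < 4 * mc_sd + 0.03


# ---------------------------------------------------------------- splits & screen

def test_split_examples():
    cohort = build_cohort(
        [5.0, 6.0, 7.0, 8.0], [1, 1, 1, 0],
        {"g1": [1.0, 2.0, 3.0, 4.0], "flat": [2.0, 2.0, 2.0, 2.0]},
    )
    split = split_by_gene_expression(cohort, "g1", q=0.5)
    assert sum(v == "high" for v in split.values()) == 2
    assert split["s4"] == "high" and split["s1"] == "low"
    with pytest.raises(SkipSignal, match="constant"):
        split_by_gene_expression(cohort, "flat")
    tiny = build_cohort([5.0, 6.0, 7.0], [1, 1, 1], {"g1": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="fewer than 4"):
        split_by_gene_expression(tiny, "g1")


def test_screen_skips_absent_gene_and_recovers_planted(rng):
    from imos.simulate import SimulationTruth, generate_cohort

    genes = [f"G{i:03d}" for i in range(20)]
    truth = SimulationTruth(
        seed=5, gene_ids=genes, signature_loadings={},
        planted_beneficial={}, planted_harmful={"G000": float(np.log(2))},
        cnv_concordant={}, meth_anticorrelated={}, mutated_prognostic={},
        specific_genes={},
    )
    cohort, _ = generate_cohort(400, truth, seed=5)
    results, skipped = gene_survival_screen(cohort, ["G000", "missing"])
    assert "missing" in skipped
    hit = {r.gene_id: r for r in results}["G000"]
    assert hit.p < 0.05 and hit.direction == "high_worse"


# ---------------------------------------------------------------- BH-FDR

def brute_force_bh(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        q[idx] = running
    return q


def test_bh_worked_example():
    assert np.allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])


def test_bh_equal_inputs_and_empty():
    assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    assert bh_fdr([]).size == 0
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_matches_brute_force_and_never_decreases(pvals):
    p = np.asarray(pvals)
    q = bh_fdr(p)
    assert np.allclose(q, brute_force_bh(p), atol=1e-12)
    assert (q >= p - 1e-12).all()


def test_bh_permutation_equivariance(rng):
    p = rng.random(50)
    q = bh_fdr(p)
    perm = rng.permutation(50)
    assert np.allclose(bh_fdr(p[perm]), q[perm])


# ---------------------------------------------------------------- Pearson

def test_pearson_exact_line_and_hand_value():
    r, p = pearson_test([1, 2, 3, 4], [3, 5, 7, 9])
    assert r == pytest.approx(1.0)
    # x=(1..5), y=(2,1,4,3,5): cov terms give r = 8 / sqrt(10*10) = 0.8
    r, p = pearson_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert r == pytest.approx(0.8)
    t = 0.8 * np.sqrt(3 / (1 - 0.64))
    from scipy.stats import t as tdist
    assert p == pytest.approx(2 * tdist.sf(t, df=3), rel=1e-9)


def test_pearson_constant_returns_none_and_pairwise_complete():
    assert pearson_test([1, 2, 3], [5, 5, 5]) is None
    r, _ = pearson_test([1, 2, np.nan, 3, 4], [2, 4, 7.0, 6, 8])
    assert r == pytest.approx(1.0)
    with pytest.raises(ValueError, match=">=3"):
        pearson_test([1, 2], [3, 4])
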
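"""KDIGO detection/staging/recovery, metabolic patterns, posteriors, Cox contrasts."""

import numpy as np
import pandas as pd
import pytest

from akiphen.outcomes import (CreatinineTrajectory, MetabolicSeries,
                              MetabolicThresholds, assess_recovery,
                              classify_metabolic_state,
                              compute_metabolic_thresholds, cox_compare,
                              detect_aki, metabolic_summary, posterior_by_cluster,
                              severity_mortality_curve, stage_kdigo)


def traj(times, values, **kw):
    return CreatinineTrajectory(patient_id="t", times=np.array(times, float),
                                values=np.array(values, float), **kw)


# ---------------------------------------------------------------------------
# hand-scored trajectory fixtures: (trajectory, expect_aki, expect_stage,
#                                   expect_recovered)
# ---------------------------------------------------------------------------
def _fixtures():
    cases = []
    # 1 constant -> no AKI
    cases.append((traj([0, 1, 2, 3], [80, 80, 80, 80]), False, None, None))
    # 2 small noise below both criteria
    cases.append((traj([0, 1, 2, 3], [80, 84, 78, 82]), False, None, None))
    # 3 ratio criterion: 130/80 = 1.625 >= 1.5 at day 3, stage 1
    cases.append((traj([0, 1, 3], [80, 82, 130]), True, "1", False))
    # 4 absolute-only: 110 >= 80 + 26.4 within 48 h, ratio 1.375 < 1.5
    cases.append((traj([0, 1], [80, 110]), True, "1", False))
    # 5 stage 2: peak/baseline 2.2
    cases.append((traj([0, 2, 4], [70, 154, 150]), True, "2", False))
    # 6 stage 3 by ratio 3.5
    cases.append((traj([0, 2], [70, 245]), True, "3-noRRT", False))
    # 7 stage 3 by absolute peak >= 353.6 though ratio 2.5 < 3
    cases.append((traj([0, 2], [150, 375]), True, "3-noRRT", False))
    # 8 RRT dominates a ratio-1.6 episode
    cases.append((traj([0, 2], [80, 128], rrt=True, rrt_start=2.5), True, "3-RRT",
                  False))
    # 9 slow creep: 7-day rolling window resets, never 1.5x within a window
    cases.append((traj([0, 6, 13, 20, 27], [80, 100, 125, 156, 195]), False, None,
                  None))
    # 10 same creep compressed into 6 days: 120/80 = 1.5 at day 6 inside window
    cases.append((traj([0, 2, 4, 6], [80, 95, 108, 120]), True, "1", False))
    # 11 absolute rise slower than 48 h window -> not triggered; ratio at day 4
    cases.append((traj([0, 2, 4], [100, 124, 150]), True, "1", False))
    # 12 recovery: peak 2.2x then below 1.5x baseline at day 6
    cases.append((traj([0, 2, 4, 6], [70, 154, 120, 100]), True, "2", True))
    # 13 plateau at 1.6x baseline -> never recovered
    cases.append((traj([0, 2, 4, 6, 8], [80, 176, 130, 128, 128]), True, "2", False))
    # 14 dips to exactly 1.5x -> still not recovered (strictly below required)
    cases.append((traj([0, 2, 4], [80, 176, 120]), True, "2", False))
    # 15 recovered value but RRT ongoing -> not recovered
    cases.append((traj([0, 2, 4, 6], [80, 250, 140, 100], rrt=True, rrt_start=2.2),
                  True, "3-RRT", False))
    # 16 RRT stopped before the low value -> recovered
    cases.append((traj([0, 2, 4, 8], [80, 250, 140, 100], rrt=True, rrt_start=2.2,
                       rrt_end=5.0), True, "3-RRT", True))
    # 17 decreasing trajectory -> no AKI
    cases.append((traj([0, 1, 2, 3], [120, 110, 100, 90]), False, None, None))
    # 18 drop then rebound to baseline: 90/60 = 1.5 vs rolling min -> AKI
    cases.append((traj([0, 1, 2], [90, 60, 90]), True, "1", False))
    # 19 late episode after a quiet week, recovery censored at last sample
    cases.append((traj([0, 7, 9, 10], [80, 82, 130, 125]), True, "1", False))
    # 20 two-point absolute rise at high baseline (ratio 1.2 < 1.5)
    cases.append((traj([0, 1], [140, 170]), True, "1", False))
    return cases


def test_hand_scored_trajectory_fixtures():
    score = 0
    for i, (t, want_aki, want_stage, want_rec) in enumerate(_fixtures(), 1):
        kd = stage_kdigo(t)
        ok = kd.aki == want_aki
        if want_aki:
            ok = ok and kd.stage == want_stage
            rec, _ = assess_recovery(t, kd)
            ok = ok and rec == want_rec
        assert ok, f"fixture {i}: got {kd}"
        score += ok
    assert score == 20


def test_detection_onset_and_criterion():
    aki, onset, crit = detect_aki(traj([0, 1, 3], [80, 82, 130]))
    assert aki and onset == 3 and crit == "ratio"
    aki, onset, crit = detect_aki(traj([0, 1], [80, 110]))
    assert aki and onset == 1 and crit == "absolute"


def test_rrt_without_creatinine_aki_warns_and_stages():
    with pytest.warns(UserWarning):
        kd = stage_kdigo(traj([0, 1], [80, 80], rrt=True, rrt_start=0.5))
    assert kd.stage == "3-RRT" and kd.aki


def test_staging_monotone_under_upscaling():
    rng = np.random.default_rng(0)
    order = {None: 0, "1": 1, "2": 2, "3-noRRT": 3}
    for _ in range(50):
        base = rng.uniform(50, 120)
        t = np.arange(8.0)
        v = np.concatenate([[base], base * rng.uniform(0.9, 1.8, 7)])
        prev = -1
        for scale in (1.0, 1.3, 1.8, 2.5):
            scaled = v.copy()
            scaled[1:] *= scale
            kd = stage_kdigo(CreatinineTrajectory("m", t, scaled))
            stage = order[kd.stage if kd.aki else None]
            assert stage >= prev
            prev = stage


def test_trajectory_validation():
    with pytest.raises(ValueError):
        traj([0, 1, 1], [80, 80, 80])
    with pytest.raises(ValueError):
        traj([0, 1], [80, -5])


# ---------------------------------------------------------------------------
# metabolic patterns
# ---------------------------------------------------------------------------

def oracle_profile(lac, glu, thr):
    """Exhaustive rule table written independently of the implementation."""
    if lac >= thr.lactate_median and glu >= thr.glucose_q75:
        return "stress_response"
    if lac >= thr.lactate_median:
        return "impaired_metabolism"
    if glu >= thr.glucose_q75:
        return "isolated_hyperglycaemia"
    if glu < thr.glucose_q25:
        return "isolated_hypoglycaemia"
    return "baseline"


def test_thresholds_quantiles():
    thr = compute_metabolic_thresholds([1, 2, 3], np.arange(1.0, 9.0))
    assert thr.lactate_median == 2
    assert thr.glucose_q25 == pytest.approx(2.75)
    assert thr.glucose_q50 == pytest.approx(4.5)
    assert thr.glucose_q75 == pytest.approx(6.25)
    degenerate = compute_metabolic_thresholds([1, 2], [5.0] * 6)
    assert degenerate.glucose_q25 == degenerate.glucose_q75 == 5.0
    with pytest.raises(ValueError):
        compute_metabolic_thresholds([1.0], [1, 2, 3, 4])


def test_classifier_matches_rule_table_oracle():
    thr = MetabolicThresholds(lactate_median=1.5, glucose_q25=5.0, glucose_q50=7.0,
                              glucose_q75=10.0)
    rng = np.random.default_rng(0)
    lac = rng.uniform(0.1, 4.0, 10_000)
    glu = rng.uniform(1.0, 20.0, 10_000)
    for l, g in zip(lac, glu):
        assert classify_metabolic_state(l, g, thr) == oracle_profile(l, g, thr)
    # boundary conventions: above = >=, below = <
    assert classify_metabolic_state(1.5, 10.0, thr) == "stress_response"
    assert classify_metabolic_state(1.5, 9.99, thr) == "impaired_metabolism"
    assert classify_metabolic_state(1.49, 4.99, thr) == "isolated_hypoglycaemia"
    assert classify_metabolic_state(1.49, 5.0, thr) == "baseline"
    assert classify_metabolic_state(1.49, 8.0, thr) == "baseline"  # q50-q75 gap


THR = MetabolicThresholds(lactate_median=1.5, glucose_q25=5.0, glucose_q50=7.0,
                          glucose_q75=10.0)


def test_single_measurement_occupies_whole_stay():
    s = MetabolicSeries("p", [1.0], [2.0], [12.0])
    out = metabolic_summary(s, THR, 0.0, 10.0)
    assert out.relative_time["stress_response"] == pytest.approx(1.0)
    assert out.dominant == "stress_response"


def test_two_measurements_split_at_midpoint():
    s = MetabolicSeries("p", [0.0, 5.0], [2.0, 1.0], [12.0, 6.0])
    out = metabolic_summary(s, THR, 0.0, 10.0)
    assert out.relative_time["stress_response"] == pytest.approx(0.5)
    assert out.relative_time["baseline"] == pytest.approx(0.5)


def test_irregular_occupancy_matches_hand_integration():
    # profiles: stress(0->1.5), baseline(1.5->2), hypo(2->6), impaired(6->7),
    # hyper(7->10); LOS 10
    s = MetabolicSeries("p", [0.0, 1.5, 2.0, 6.0, 7.0],
                        lactate=[2.0, 1.0, 1.0, 2.0, 1.0],
                        glucose=[12.0, 6.0, 4.0, 6.0, 11.0])
    out = metabolic_summary(s, THR, 0.0, 10.0)
    want = {"stress_response": 0.15, "baseline": 0.05,
            "isolated_hypoglycaemia": 0.4, "impaired_metabolism": 0.1,
            "isolated_hyperglycaemia": 0.3}
    for k, v in want.items():
        assert out.relative_time[k] == pytest.approx(v, abs=1e-12)
    assert out.dominant == "isolated_hypoglycaemia"


def test_relative_times_sum_to_one_randomized():
    rng = np.random.default_rng(1)
    for _ in range(1000):
        m = rng.integers(1, 12)
        t = np.sort(rng.uniform(0, 9, m))
        t += np.arange(m) * 1e-6  # strict ordering
        s = MetabolicSeries("p", t, rng.uniform(0.2, 4, m), rng.uniform(1, 20, m))
        out = metabolic_summary(s, THR, 0.0, 10.0)
        assert sum(out.relative_time.values()) == pytest.approx(1.0, abs=1e-9)


def test_empty_series_raises():
    with pytest.raises(ValueError):
        metabolic_summary(MetabolicSeries("p", [], [], []), THR, 0.0, 1.0)


# ---------------------------------------------------------------------------
# posteriors
# ---------------------------------------------------------------------------

def test_posterior_reduces_to_conditional_frequency():
    labels = np.array(["A"] * 10 + ["B"] * 10)
    outcome = np.array([1] * 8 + [0] * 2 + [1] * 3 + [0] * 7)
    rep = posterior_by_cluster(labels, outcome, n_boot=50, seed=0)
    assert rep.posterior.loc["A", 1] == pytest.approx(0.8)
    assert rep.posterior.loc["B", 1] == pytest.approx(0.3)
    # rows normalize over outcome levels
    np.testing.assert_allclose(rep.posterior.sum(axis=1), 1.0)


def test_posterior_identical_rates_give_large_pairwise_p():
    # both clusters of 200 share the same death rate; the bootstrapped difference
    # straddles zero so the two-sided percentile p stays large
    rng = np.random.default_rng(2)
    hits = 0
    for rep_i in range(50):
        labels = np.repeat(["A", "B"], 200)
        per_cluster = np.concatenate([np.ones(60, int), np.zeros(140, int)])
        outcome = np.concatenate([rng.permutation(per_cluster),
                                  rng.permutation(per_cluster)])
        rep = posterior_by_cluster(labels, outcome, n_boot=200, seed=rep_i)
        hits += rep.pairwise_p[("A", "B", 1)] > 0.5
    assert hits >= 48  # >= 95% of 50 meta-replicates


def test_posterior_needs_two_clusters():
    with pytest.raises(ValueError):
        posterior_by_cluster(np.array(["A"] * 5), np.array([0, 1, 0, 1, 0]),
                             n_boot=10)


# ---------------------------------------------------------------------------
# Cox comparison
# ---------------------------------------------------------------------------

def test_cox_three_subject_hand_oracle():
    # times 1,2,3 all events, groups A,B,A: score equation solved by hand gives
    # beta = 0.5*ln(2), HR = sqrt(2)
    res = cox_compare([1.0, 2.0, 3.0], [1, 1, 1], ["A", "B", "A"], reference="A")
    assert res.hazard_ratio["B"] == pytest.approx(np.sqrt(2.0), abs=1e-6)


def test_cox_null_two_identical_groups():
    rng = np.random.default_rng(3)
    t = rng.exponential(5.0, 400)
    res = cox_compare(t, np.ones(400, int), np.repeat(["A", "B"], 200))
    assert 0.8 < res.hazard_ratio["B"] < 1.25
    assert res.ci_low["B"] < 1.0 < res.ci_high["B"]


def test_cox_errors_and_flags():
    with pytest.raises(ValueError):
        cox_compare([1, 2], [0, 0], ["A", "B"])
    with pytest.raises(ValueError):
        cox_compare([1, -1], [1, 1], ["A", "B"])


# ---------------------------------------------------------------------------
# severity-mortality curves
# ---------------------------------------------------------------------------

def test_severity_curve_threshold_recovery():
    rng = np.random.default_rng(4)
    ratio = rng.uniform(1.0, 4.0, 400)
    death = (ratio > 2.0).astype(int)
    out = severity_mortality_curve(np.zeros(400, int), ratio, death,
                                   grid=np.linspace(1, 4, 61))
    curve = out[0]
    cross = curve["grid"][np.argmin(np.abs(curve["prob"] - 0.5))]
    assert abs(cross - 2.0) <= 0.1
    assert curve["lrt_p"] < 1e-6


def test_severity_curve_suppresses_degenerate_clusters():
    rng = np.random.default_rng(5)
    cluster = np.array([0] * 5 + [1] * 50)
    ratio = rng.uniform(1, 3, 55)
    death = np.concatenate([[0, 1, 0, 1, 0], np.ones(50, int)])
    with pytest.warns(UserWarning):
        out = severity_mortality_curve(cluster, ratio, death)
    assert out == {}
    with pytest.raises(ValueError):
        severity_mortality_curve([0] * 20, np.full(20, 0.5), [0, 1] * 10)
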
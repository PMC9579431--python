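"""Renal and metabolic outcome scoring, and between-cluster outcome comparison.

AKI is detected from serum-creatinine trajectories with the creatinine-based KDIGO
rules: a >= 1.5-fold rise over the lowest value in the preceding 7 days, or an absolute
rise of more than 26.4 umol/L over the lowest value in the preceding 48 h.  Severity is
staged from the peak-to-baseline ratio (1.5 / 2.0 / 3.0 cuts, or peak >= 353.6 umol/L
for stage 3), with stage 3 split by the need for renal replacement therapy (RRT).
Recovery is the first post-onset time with creatinine below 1.5 x baseline and no
ongoing RRT.

Paired lactate/glucose measurements are classified into five metabolic profiles against
cohort-level quantile thresholds, and each patient's ICU stay is summarised by the
relative time spent in each profile (step-function occupancy).

Cluster-level outcome contrasts use Naive-Bayes posteriors (which, with a single
categorical predictor, reduce to smoothed conditional frequencies) with patient-level
bootstrap confidence intervals and p-values, and Cox proportional-hazards models for
time-to-event outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RATIO_THRESHOLD = 1.5          # KDIGO fold-rise criterion
ABSOLUTE_THRESHOLD = 26.4      # umol/L rise criterion
RATIO_WINDOW_DAYS = 7.0
ABSOLUTE_WINDOW_DAYS = 2.0
STAGE3_ABSOLUTE_PEAK = 353.6   # umol/L

METABOLIC_PROFILES = (
    "baseline",
    "impaired_metabolism",
    "isolated_hyperglycaemia",
    "isolated_hypoglycaemia",
    "stress_response",
)


@dataclass
class CreatinineTrajectory:
    """Timestamped serum creatinine for one patient (times in days from hospital admission)."""

    patient_id: object
    times: np.ndarray
    values: np.ndarray           # umol/L
    rrt: bool = False
    rrt_start: float | None = None
    rrt_end: float | None = None  # None while RRT ongoing
    icu_admission: float = 0.0
    icu_discharge: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values) or len(self.times) == 0:
            raise ValueError("times and values must be equal-length and nonempty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("creatinine must be positive")

    @property
    def baseline(self) -> float:
        """First serum creatinine recorded following hospital admission."""
        return float(self.values[0])


@dataclass
class MetabolicSeries:
    """Paired lactate/glucose measurements (mmol/L) during the ICU stay."""

    patient_id: object
    times: np.ndarray
    lactate: np.ndarray
    glucose: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.lactate = np.asarray(self.lactate, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if not (len(self.times) == len(self.lactate) == len(self.glucose)):
            raise ValueError("times, lactate and glucose must be equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times) and np.any(self.lactate <= 0):
            raise ValueError("lactate must be positive")


@dataclass
class KdigoResult:
    aki: bool
    onset: float | None = None
    stage: str | None = None      # "1", "2", "3-noRRT", "3-RRT"
    criterion: str | None = None  # "ratio", "absolute"


# ---------------------------------------------------------------------------
# AKI detection / staging / recovery
# ---------------------------------------------------------------------------

def detect_aki(traj: CreatinineTrajectory):
    """First time the KDIGO creatinine criteria fire; ``(aki, onset, criterion)``.

    The reference for each criterion is the rolling minimum over a half-open window
    (t - w, t] ending at the candidate measurement.
    """
    t, v = traj.times, traj.values
    for i in range(len(t)):
        in_ratio = (t > t[i] - RATIO_WINDOW_DAYS) & (t <= t[i])
        ref_ratio = v[in_ratio].min()
        if v[i] >= RATIO_THRESHOLD * ref_ratio and v[i] > ref_ratio:
            return True, float(t[i]), "ratio"
        in_abs = (t > t[i] - ABSOLUTE_WINDOW_DAYS) & (t <= t[i])
        ref_abs = v[in_abs].min()
        if v[i] >= ref_abs + ABSOLUTE_THRESHOLD:
            return True, float(t[i]), "absolute"
    return False, None, None


def stage_kdigo(traj: CreatinineTrajectory, rrt: bool | None = None) -> KdigoResult:
    """Maximum KDIGO stage over the stay; RRT dominates as stage 3-RRT."""
    if rrt is None:
        rrt = traj.rrt
    aki, onset, criterion = detect_aki(traj)
    if not aki:
        if rrt:
            warnings.warn(
                f"patient {traj.patient_id}: RRT without creatinine-criteria AKI; "
                "staged 3-RRT",
                stacklevel=2,
            )
            return KdigoResult(aki=True, onset=traj.rrt_start, stage="3-RRT", criterion=None)
        return KdigoResult(aki=False)
    ratio = traj.values.max() / traj.baseline
    if rrt:
        stage = "3-RRT"
    elif ratio >= 3.0 or traj.values.max() >= STAGE3_ABSOLUTE_PEAK:
        stage = "3-noRRT"
    elif ratio >= 2.0:
        stage = "2"
    else:
        stage = "1"  # ratio in [1.5, 2.0) or absolute criterion only
    return KdigoResult(aki=True, onset=onset, stage=stage, criterion=criterion)


def assess_recovery(traj: CreatinineTrajectory, kdigo: KdigoResult):
    """``(recovered, time)``: first post-onset measurement below 1.5 x baseline with no
    ongoing RRT; censored at the last measurement otherwise."""
    if not kdigo.aki:
        raise ValueError("recovery is defined only after an AKI episode")
    onset = kdigo.onset if kdigo.onset is not None else traj.times[0]
    threshold = RATIO_THRESHOLD * traj.baseline
    for t, v in zip(traj.times, traj.values):
        if t <= onset:
            continue
        if v >= threshold:
            continue
        if traj.rrt and traj.rrt_start is not None and traj.rrt_start <= t:
            if traj.rrt_end is None or t < traj.rrt_end:
                continue  # still on RRT
        return True, float(t)
    return False, float(traj.times[-1])


# ---------------------------------------------------------------------------
# Metabolic patterns
# ---------------------------------------------------------------------------

@dataclass
class MetabolicThresholds:
    lactate_median: float
    glucose_q25: float
    glucose_q50: float
    glucose_q75: float

    def __post_init__(self):
        if not (self.glucose_q25 <= self.glucose_q50 <= self.glucose_q75):
            raise ValueError("glucose quantiles must be ordered")


def compute_metabolic_thresholds(lactate_all, glucose_all) -> MetabolicThresholds:
    """Cohort-level thresholds over the pooled ICU measurements (linear-interpolation
    quantiles)."""
    lac = np.asarray(lactate_all, dtype=float)
    glu = np.asarray(glucose_all, dtype=float)
    if len(glu) < 4 or len(lac) < 2:
        raise ValueError("need >= 4 glucose and >= 2 lactate measurements cohort-wide")
    q25, q50, q75 = np.quantile(glu, [0.25, 0.50, 0.75])
    return MetabolicThresholds(
        lactate_median=float(np.median(lac)),
        glucose_q25=float(q25), glucose_q50=float(q50), glucose_q75=float(q75),
    )


def classify_metabolic_state(lactate: float, glucose: float,
                             thr: MetabolicThresholds) -> str:
    """Five-way lactate/glucose profile; 'above' means >=, 'below' means <.

    With lactate below the median, glucose splits at q25 (isolated hypoglycaemia
    below, baseline in [q25, q75), isolated hyperglycaemia at or above q75); with
    lactate at or above the median, glucose splits at q75 (impaired metabolism below,
    stress response at or above).
    """
    high_lactate = lactate >= thr.lactate_median
    if high_lactate:
        return "stress_response" if glucose >= thr.glucose_q75 else "impaired_metabolism"
    if glucose < thr.glucose_q25:
        return "isolated_hypoglycaemia"
    if glucose >= thr.glucose_q75:
        return "isolated_hyperglycaemia"
    return "baseline"


@dataclass
class MetabolicSummary:
    patient_id: object
    relative_time: dict          # profile -> fraction of ICU stay
    dominant: str


def metabolic_summary(series: MetabolicSeries, thr: MetabolicThresholds,
                      icu_admission: float, icu_discharge: float) -> MetabolicSummary:
    """Step-function occupancy of the five profiles over the ICU stay.

    Each measurement's profile holds from its timestamp to the next measurement; the
    last holds until ICU discharge, and the interval before the first measurement is
    assigned to the first profile.  Relative times sum to 1.
    """
    if len(series.times) == 0:
        raise ValueError("empty metabolic series")
    los = icu_discharge - icu_admission
    if los <= 0:
        raise ValueError("non-positive ICU length of stay")
    inside = (series.times >= icu_admission) & (series.times <= icu_discharge)
    t = series.times[inside]
    if len(t) == 0:
        raise ValueError("no measurements inside the ICU interval")
    profiles = [
        classify_metabolic_state(l, g, thr)
        for l, g in zip(series.lactate[inside], series.glucose[inside])
    ]
    bounds = np.concatenate([[icu_admission], t[1:], [icu_discharge]])
    occupancy = dict.fromkeys(METABOLIC_PROFILES, 0.0)
    for k, prof in enumerate(profiles):
        start = bounds[k] if k > 0 else icu_admission
        end = bounds[k + 1] if k + 1 < len(bounds) else icu_discharge
        occupancy[prof] += end - start
    # first profile also covers [icu_admission, t[0]) by the assignment rule above;
    # bounds construction already folds that interval into segment 0.
    rel = {p: occupancy[p] / los for p in METABOLIC_PROFILES}
    dominant = max(METABOLIC_PROFILES, key=lambda p: rel[p])  # ties -> earliest listed
    return MetabolicSummary(patient_id=series.patient_id, relative_time=rel,
                            dominant=dominant)


# ---------------------------------------------------------------------------
# Naive-Bayes posteriors with bootstrap inference
# ---------------------------------------------------------------------------

@dataclass
class PosteriorReport:
    posterior: pd.DataFrame          # clusters x outcome levels
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    pairwise_p: dict                 # (cluster_a, cluster_b, level) -> p
    n_boot: int
    dropped_replicates: int = 0


def _conditional_freq(labels, outcome, clusters, levels, alpha: float) -> pd.DataFrame:
    table = pd.DataFrame(0.0, index=clusters, columns=levels)
    for c in clusters:
        mask = labels == c
        n = mask.sum()
        for lv in levels:
            k = np.sum(outcome[mask] == lv)
            table.loc[c, lv] = (k + alpha) / (n + alpha * len(levels))
    return table


def posterior_by_cluster(labels, outcome, n_boot: int = 2000, seed: int = 0,
                         alpha: float = 0.0) -> PosteriorReport:
    """P(outcome level | cluster) with percentile-bootstrap CIs and pairwise p-values.

    With cluster as the single categorical predictor the Naive-Bayes posterior equals
    the (Laplace-smoothed) conditional frequency.  Bootstrap resamples patients; a
    resample missing a cluster is redrawn (max 10 retries, then dropped).
    """
    labels = np.asarray(labels)
    outcome = np.asarray(outcome)
    clusters = sorted(pd.unique(labels).tolist())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    levels = sorted(pd.unique(outcome).tolist())
    point = _conditional_freq(labels, outcome, clusters, levels, alpha)

    rng = np.random.default_rng(seed)
    n = len(labels)
    boots = []
    dropped = 0
    for _ in range(n_boot):
        for _retry in range(10):
            idx = rng.integers(0, n, n)
            if set(clusters) <= set(labels[idx]):
                boots.append(_conditional_freq(labels[idx], outcome[idx],
                                               clusters, levels, alpha).to_numpy())
                break
        else:
            dropped += 1
    arr = np.array(boots)  # (B, n_clusters, n_levels)
    lo = pd.DataFrame(np.percentile(arr, 2.5, axis=0), index=clusters, columns=levels)
    hi = pd.DataFrame(np.percentile(arr, 97.5, axis=0), index=clusters, columns=levels)

    pairwise = {}
    for ia, a in enumerate(clusters):
        for b in clusters[ia + 1:]:
            for il, lv in enumerate(levels):
                diff = arr[:, clusters.index(a), il] - arr[:, clusters.index(b), il]
                p = 2 * min(np.mean(diff <= 0), np.mean(diff >= 0))
                pairwise[(a, b, lv)] = min(1.0, float(p))
    return PosteriorReport(posterior=point, ci_low=lo, ci_high=hi,
                           pairwise_p=pairwise, n_boot=n_boot,
                           dropped_replicates=dropped)


# ---------------------------------------------------------------------------
# Cox proportional-hazards comparison
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    hazard_ratio: dict   # cluster -> HR vs reference
    ci_low: dict
    ci_high: dict
    p_value: dict
    reference: object
    flags: list = field(default_factory=list)


def cox_compare(time, event, cluster, reference=None) -> CoxResult:
    """Proportional-hazards contrast of clusters against a reference level.

    Delegates the partial-likelihood fit to lifelines; event times here are continuous
    so tie handling is immaterial.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceWarning

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cluster = np.asarray(cluster)
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    if event.sum() == 0:
        raise ValueError("no events observed")
    levels = sorted(pd.unique(cluster).tolist())
    if len(levels) < 2:
        raise ValueError("need >= 2 clusters")
    if reference is None:
        reference = levels[0]

    flags = []
    df = pd.DataFrame({"time": time, "event": event})
    contrast_cols = []
    for lv in levels:
        if lv == reference:
            continue
        col = f"cluster_{lv}"
        df[col] = (cluster == lv).astype(float)
        contrast_cols.append((lv, col))
        if event[cluster == lv].sum() == 0:
            flags.append(f"cluster {lv}: all censored (monotone likelihood risk)")

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-10})
    summ = cph.summary
    hr, lo, hi, p = {}, {}, {}, {}
    for lv, col in contrast_cols:
        hr[lv] = float(np.exp(summ.loc[col, "coef"]))
        lo[lv] = float(np.exp(summ.loc[col, "coef lower 95%"]))
        hi[lv] = float(np.exp(summ.loc[col, "coef upper 95%"]))
        p[lv] = float(summ.loc[col, "p"])
    return CoxResult(hazard_ratio=hr, ci_low=lo, ci_high=hi, p_value=p,
                     reference=reference, flags=flags)


# ---------------------------------------------------------------------------
# Severity-mortality association per cluster
# ---------------------------------------------------------------------------

def severity_mortality_curve(cluster, severity_ratio, death, grid=None,
                             min_cluster_size: int = 10):
    """Per-cluster logistic fit of hospital death on a restricted-cubic-spline basis of
    the peak/baseline creatinine ratio.

    Returns ``{cluster: dict(grid, prob, ci_low, ci_high, lrt_p)}``; clusters with
    fewer than ``min_cluster_size`` patients or a single death class are suppressed
    with a warning.  Complete separation (a ratio cut perfectly predicting death)
    is handled by refitting under a small ridge penalty.
    """
    from scipy import stats

    from .risk_model import pirls
    from .splines import default_knots, rcs_basis

    cluster = np.asarray(cluster)
    ratio = np.asarray(severity_ratio, dtype=float)
    death = np.asarray(death, dtype=int)
    if np.any(ratio < 1):
        raise ValueError("peak/baseline ratio must be >= 1")
    if grid is None:
        grid = np.linspace(ratio.min(), ratio.max(), 50)
    out = {}
    for c in sorted(pd.unique(cluster).tolist()):
        mask = cluster == c
        r, d = ratio[mask], death[mask]
        if mask.sum() < min_cluster_size:
            warnings.warn(f"cluster {c}: fewer than {min_cluster_size} patients; "
                          "curve suppressed", stacklevel=2)
            continue
        if d.min() == d.max():
            warnings.warn(f"cluster {c}: single death class; curve suppressed",
                          stacklevel=2)
            continue
        try:
            knots = default_knots(r, 3)
        except ValueError:
            warnings.warn(f"cluster {c}: degenerate severity ratios; curve suppressed",
                          stacklevel=2)
            continue
        X = np.column_stack([np.ones(len(r)), rcs_basis(r, knots=knots)])
        beta, info = pirls(X, d.astype(float))
        if np.max(np.abs(beta)) > 25:   # separation: refit under a small ridge
            ridge = np.eye(X.shape[1]) * 1e-2
            ridge[0, 0] = 0.0
            beta, info = pirls(X, d.astype(float), ridge)
        null_beta, null_info = pirls(np.ones((len(d), 1)), d.astype(float))
        lrt = max(2.0 * (info["loglik"] - null_info["loglik"]), 0.0)
        lrt_p = float(stats.chi2.sf(lrt, df=X.shape[1] - 1))
        Xg = np.column_stack([np.ones(len(grid)),
                              rcs_basis(np.asarray(grid, float), knots=knots)])
        eta = Xg @ beta
        se = np.sqrt(np.maximum(
            np.einsum("ij,jk,ik->i", Xg, info["cov"], Xg), 0.0))
        expit = lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        out[c] = {
            "grid": np.asarray(grid, float),
            "prob": expit(eta),
            "ci_low": expit(eta - 1.96 * se),
            "ci_high": expit(eta + 1.96 * se),
            "lrt_p": lrt_p,
        }
    return out
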
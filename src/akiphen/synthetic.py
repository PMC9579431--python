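"""Synthetic ICU cohort generator with planted risk-factor phenotypes.

The generator emulates the statistical structure the phenotyping pipeline assumes,
with full ground truth:

* tabular covariates (demographics, severity scores, admission labs, treatments) drawn
  from per-covariate marginals, shifted per planted phenotype group so each group's AKI
  risk is dominated by a distinct factor;
* an additive nonlinear logistic AKI mechanism (linear, U-shaped and saturating effect
  shapes on standardized covariates) with the intercept calibrated by bisection so the
  cohort AKI rate hits a configured target;
* serum-creatinine trajectories that are KDIGO-consistent by construction: scoring them
  with :mod:`akiphen.outcomes` reproduces the planted AKI status and stage exactly;
* paired lactate/glucose series from group-specific regimes, sampled on a fixed clock
  (default every 4 h) during the ICU stay;
* recovery and death times from exponential hazards with group-specific ratios.

Everything is deterministic given the seed: one shared generator, seeded once per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .outcomes import CreatinineTrajectory, MetabolicSeries, assess_recovery, stage_kdigo

STAGE_PEAK_RATIO = {1: 1.6, 2: 2.2, 3: 3.5}   # peak / baseline creatinine per stage
RECOVERY_PLATEAU_RATIO = 1.55                  # non-recoverers settle just above 1.5
BASE_RECOVERY_MEAN_DAYS = 7.0                  # onset-to-recovery mean at hazard ratio 1


@dataclass
class CovariateSpec:
    name: str
    kind: str                   # "binary" | "continuous"
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5              # binary prevalence
    lo: float | None = None     # truncation bounds for continuous draws
    hi: float | None = None
    coef: float = 0.0           # effect on the logit scale (per SD for continuous)
    shape: str = "linear"       # "linear" | "u_shape" | "saturating"


def default_covariates() -> list[CovariateSpec]:
    """Covariate marginals loosely matching an ICU COVID-19 cohort's admission table."""
    return [
        CovariateSpec("age", "continuous", mean=62, sd=12, lo=20, hi=95),
        CovariateSpec("bmi", "continuous", mean=28, sd=5, lo=15, hi=55),
        CovariateSpec("apache", "continuous", mean=22, sd=8, lo=2, hi=60,
                      coef=1.8, shape="saturating"),
        CovariateSpec("egfr", "continuous", mean=75, sd=25, lo=8, hi=140,
                      coef=-2.2, shape="saturating"),
        CovariateSpec("fio2", "continuous", mean=60, sd=20, lo=21, hi=100,
                      coef=0.3, shape="u_shape"),
        CovariateSpec("crp", "continuous", mean=120, sd=70, lo=1, hi=400),
        CovariateSpec("diabetes", "binary", p=0.25, coef=0.9),
        CovariateSpec("lpv_r", "binary", p=0.35, coef=3.0),
        CovariateSpec("dexamethasone", "binary", p=0.5, coef=-1.8),
        CovariateSpec("mech_vent", "binary", p=0.6, coef=0.9),
    ]


def default_group_patterns() -> list[dict]:
    """Per-group covariate shifts: which factor dominates each phenotype.

    Continuous entries are shifts in SD units; binary entries replace the prevalence.
    Group 0 is driven by lopinavir/ritonavir exposure, group 1 by low baseline eGFR
    without dexamethasone, group 2 by high severity (APACHE) with low eGFR under
    dexamethasone — mirroring crisply separated risk-factor phenotypes.
    """
    return [
        {"lpv_r": 0.99, "dexamethasone": 0.9, "egfr": 0.5, "apache": -0.5,
         "diabetes": 0.9, "mech_vent": 0.1},
        {"egfr": -2.6, "dexamethasone": 0.01, "lpv_r": 0.01, "apache": -0.8,
         "diabetes": 0.03, "mech_vent": 0.9},
        {"apache": 3.2, "egfr": -1.8, "dexamethasone": 0.97, "lpv_r": 0.01,
         "mech_vent": 0.95, "diabetes": 0.03},
    ]


@dataclass
class GeneratorConfig:
    n_patients: int = 300
    n_groups: int = 3
    covariates: list[CovariateSpec] = field(default_factory=default_covariates)
    group_patterns: list[dict] = field(default_factory=default_group_patterns)
    target_aki_rate: float = 0.40
    stage_probs: tuple = ((0.55, 0.20, 0.25), (0.60, 0.25, 0.15), (0.80, 0.14, 0.06))
    rrt_prob_stage3: tuple = (0.8, 0.8, 0.5)
    recovery_hazard_ratio: tuple = (1.0, 1.0, 1.6)
    mortality_rate: tuple = (0.20, 0.25, 0.55)
    metabolic_every_hours: float = 4.0
    lactate_mean: tuple = (1.1, 1.2, 1.9)      # group geometric means, mmol/L
    glucose_mean: tuple = (7.5, 7.5, 7.0)
    missingness_rate: float = 0.0
    seed: int = 0

    def validate(self):
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not 0 < self.target_aki_rate < 1:
            raise ValueError("target_aki_rate must be in (0, 1)")
        if len(self.group_patterns) != self.n_groups:
            raise ValueError("group_patterns must have n_groups entries")
        for rates in (self.mortality_rate,):
            if any(not 0 <= r <= 1 for r in rates):
                raise ValueError("mortality rates must be probabilities")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    table: pd.DataFrame   # group, true_logit, true_aki, true_stage, rrt, ...


def _effect(z: np.ndarray, shape: str) -> np.ndarray:
    """Effect shape on a standardized covariate; all shapes are mean-centred-ish at 0."""
    if shape == "linear":
        return z
    if shape == "u_shape":
        return z**2 - 1.0
    if shape == "saturating":
        return 2.0 / (1.0 + np.exp(-1.5 * z)) - 1.0
    raise ValueError(f"unknown shape {shape!r}")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(risk: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisection on the mean simulated probability."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = _expit(mid + risk).mean()
        if abs(rate - target) < tol:
            return mid
        if rate < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def risk_contributions(covariate_table: pd.DataFrame,
                       specs: list[CovariateSpec]) -> pd.DataFrame:
    """Per-factor logit-scale risk contributions under the generative mechanism.

    One column per covariate with a nonzero coefficient; the row sum is the additive
    risk (without intercept).  This is the generator's ground-truth analogue of an
    attribution matrix.
    """
    out = {}
    for s in specs:
        if s.coef == 0.0:
            continue
        x = covariate_table[s.name].to_numpy(dtype=float)
        if s.kind == "binary":
            out[s.name] = s.coef * (x - s.p)
        else:
            z = (x - s.mean) / s.sd
            out[s.name] = s.coef * _effect(z, s.shape)
    return pd.DataFrame(out, index=covariate_table.index)


def compute_risk(covariate_table: pd.DataFrame, specs: list[CovariateSpec]) -> np.ndarray:
    """Additive logit-scale risk (without intercept) under the generative mechanism."""
    contrib = risk_contributions(covariate_table, specs)
    if contrib.empty:
        return np.zeros(len(covariate_table))
    return contrib.sum(axis=1).to_numpy()


def generate_cohort(config: GeneratorConfig | None = None):
    """Generate a complete cohort; returns ``(patients, trajectories, ground_truth)``.

    ``patients`` is the covariate table with the ``aki`` label; ``trajectories`` is a
    dict with ``creatinine`` (list of :class:`CreatinineTrajectory`) and ``metabolic``
    (list of :class:`MetabolicSeries`); ``ground_truth`` carries the planted group,
    logit, AKI status, KDIGO stage, RRT flag and outcome times.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    G = config.n_groups

    groups = rng.integers(0, G, n)

    # --- covariates with group shifts ------------------------------------
    data = {}
    for s in config.covariates:
        if s.kind == "binary":
            p = np.full(n, s.p)
            for g in range(G):
                if s.name in config.group_patterns[g]:
                    p[groups == g] = config.group_patterns[g][s.name]
            data[s.name] = (rng.random(n) < p).astype(float)
        else:
            shift = np.zeros(n)
            for g in range(G):
                if s.name in config.group_patterns[g]:
                    shift[groups == g] = config.group_patterns[g][s.name] * s.sd
            x = rng.normal(s.mean + shift, s.sd)
            if s.lo is not None or s.hi is not None:
                x = np.clip(x, s.lo, s.hi)
            data[s.name] = x
    patients = pd.DataFrame(data)
    patients.insert(0, "patient_id", np.arange(n))

    # --- AKI mechanism ----------------------------------------------------
    risk = compute_risk(patients, config.covariates)
    intercept = _calibrate_intercept(risk, config.target_aki_rate)
    true_logit = intercept + risk
    aki = rng.random(n) < _expit(true_logit)
    patients["aki"] = aki.astype(int)

    # --- per-patient clinical course --------------------------------------
    icu_admission = 1.0  # days from hospital admission, fixed by design
    stage = np.zeros(n, dtype=int)
    rrt = np.zeros(n, dtype=bool)
    died = np.zeros(n, dtype=bool)
    death_time = np.full(n, np.nan)
    onset = np.full(n, np.nan)
    icu_discharge = np.zeros(n)
    crea_trajs: list[CreatinineTrajectory] = []
    metab: list[MetabolicSeries] = []

    # baseline creatinine loosely inverse to eGFR, bounded so non-AKI jitter can
    # never trip the absolute (26.4 umol/L) criterion
    egfr = patients["egfr"].to_numpy() if "egfr" in patients else np.full(n, 75.0)
    baseline_crea = np.clip(6000.0 / np.maximum(egfr, 8.0), 45.0, 140.0)

    for i in range(n):
        g = int(groups[i])
        b = baseline_crea[i]
        died[i] = rng.random() < config.mortality_rate[g]
        if aki[i]:
            stage[i] = rng.choice([1, 2, 3], p=config.stage_probs[g])
            if stage[i] == 3:
                rrt[i] = rng.random() < config.rrt_prob_stage3[g]
            o = icu_admission + float(rng.integers(1, 7))   # onset day
            onset[i] = o
            hazard = config.recovery_hazard_ratio[g] / BASE_RECOVERY_MEAN_DAYS
            r_draw = rng.exponential(1.0 / hazard)
            recovers = r_draw <= 20.0
            stay_end = o + (min(r_draw, 20.0) + 3.0 if recovers else 8.0 + rng.exponential(5.0))
            if died[i]:
                death_time[i] = o + 1.0 + rng.exponential(8.0)
                stay_end = min(stay_end, death_time[i])
                stay_end = max(stay_end, o + 1.0)
            stay_end = min(stay_end, 45.0)
            icu_discharge[i] = stay_end

            times = [0.0]
            values = [b]
            peak = STAGE_PEAK_RATIO[stage[i]] * b
            t = 1.0
            while t < o - 1e-9:
                values.append(b * (1.0 + rng.uniform(-0.03, 0.03)))
                times.append(t)
                t += 1.0
            times.append(o)
            values.append(peak)
            # post-peak course: exponential approach to a target level
            target = 1.45 * b if recovers else RECOVERY_PLATEAU_RATIO * b
            if recovers:
                # decay rate chosen so the curve crosses 1.5*b near the drawn
                # recovery time (continuous); scoring snaps to the daily grid
                r_t = max(min(r_draw, 20.0), 0.8)
                k = -np.log((1.5 * b - target) / max(peak - target, 1e-9)) / r_t
            else:
                k = 0.35
            t = np.floor(o) + 1.0
            while t <= stay_end + 1e-9:
                values.append(target + (peak - target) * np.exp(-k * (t - o)))
                times.append(t)
                t += 1.0
            rrt_start = o + 0.2 if rrt[i] else None
            rrt_end = None
            if rrt[i] and recovers:
                rrt_end = min(o + 0.6 * max(r_draw, 1.0), times[-1] - 0.5)
                rrt_end = max(rrt_end, rrt_start + 0.5)
        else:
            stage[i] = 0
            stay_end = icu_admission + 3.0 + rng.exponential(6.0)
            if died[i]:
                death_time[i] = icu_admission + 1.0 + rng.exponential(8.0)
                stay_end = min(stay_end, max(death_time[i], icu_admission + 1.0))
            stay_end = min(stay_end, 45.0)
            icu_discharge[i] = stay_end
            times = [0.0]
            values = [b]
            t = 1.0
            while t <= stay_end + 1e-9:
                values.append(b * (1.0 + rng.uniform(-0.06, 0.06)))
                times.append(t)
                t += 1.0
            rrt_start = rrt_end = None

        traj = CreatinineTrajectory(
            patient_id=i, times=np.array(times), values=np.array(values),
            rrt=bool(rrt[i]), rrt_start=rrt_start, rrt_end=rrt_end,
            icu_admission=icu_admission, icu_discharge=float(icu_discharge[i]),
        )
        crea_trajs.append(traj)

        # paired lactate/glucose on a fixed clock during the ICU stay
        step = config.metabolic_every_hours / 24.0
        mt = np.arange(icu_admission, icu_discharge[i] + 1e-9, step)
        if len(mt) == 0:
            mt = np.array([icu_admission])
        lac = np.exp(rng.normal(np.log(config.lactate_mean[g]), 0.35, len(mt)))
        glu = np.exp(rng.normal(np.log(config.glucose_mean[g]), 0.25, len(mt)))
        metab.append(MetabolicSeries(patient_id=i, times=mt, lactate=lac, glucose=glu))

    # --- consistency guard: scoring must reproduce the planted truth -------
    expected = {0: None, 1: "1", 2: "2", 3: "3-noRRT"}
    for i, traj in enumerate(crea_trajs):
        scored = stage_kdigo(traj)
        want = "3-RRT" if rrt[i] else expected[stage[i]]
        if scored.aki != bool(aki[i]) or (aki[i] and scored.stage != want):
            raise RuntimeError(
                f"generator inconsistency for patient {i}: planted stage {stage[i]} "
                f"(rrt={rrt[i]}), scored {scored}"
            )

    truth = pd.DataFrame({
        "patient_id": np.arange(n),
        "group": groups,
        "true_logit": true_logit,
        "true_aki": aki.astype(int),
        "true_stage": stage,
        "rrt": rrt.astype(int),
        "onset": onset,
        "died": died.astype(int),
        "death_time": death_time,
        "icu_admission": icu_admission,
        "icu_discharge": icu_discharge,
    })

    if config.missingness_rate > 0:
        patients = inject_missingness(
            patients, config.missingness_rate, "MCAR",
            seed=int(rng.integers(2**31 - 1)),
        )
    return patients, {"creatinine": crea_trajs, "metabolic": metab}, GroundTruth(truth)


def inject_missingness(table: pd.DataFrame, rate: float, mechanism: str = "MCAR",
                       seed: int = 0, driver: str | None = None,
                       protect=("patient_id", "aki")) -> pd.DataFrame:
    """Mask covariate cells at the given rate; labels and identifiers are never masked.

    MCAR masks uniformly; MAR scales each row's masking probability linearly with the
    rank of a fully observed driver covariate (mean still ``rate``), so high-driver
    rows lose more cells.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return table.copy()
    out = table.copy()
    rng = np.random.default_rng(seed)
    cols = [c for c in table.columns if c not in protect]
    if mechanism == "MAR":
        if driver is None or driver not in table.columns:
            raise ValueError("MAR requires a named driver covariate")
        if table[driver].isna().any():
            raise ValueError("MAR driver must be fully observed")
        cols = [c for c in cols if c != driver]
        ranks = table[driver].rank(method="average").to_numpy()
        row_rate = rate * 2.0 * ranks / (len(ranks) + 1)
    elif mechanism == "MCAR":
        row_rate = np.full(len(table), rate)
    else:
        raise ValueError("mechanism must be MCAR or MAR")
    for c in cols:
        mask = rng.random(len(table)) < row_rate
        out.loc[mask, c] = np.nan
    return out


def write_cohort(outdir, patients: pd.DataFrame, trajectories: dict,
                 truth: GroundTruth) -> None:
    """Write the cohort as delimited text tables (timestamps in decimal days from
    hospital admission)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients.to_csv(outdir / "patients.csv", index=False)
    rows = []
    for traj in trajectories["creatinine"]:
        for t, v in zip(traj.times, traj.values):
            rows.append((traj.patient_id, t, v))
    pd.DataFrame(rows, columns=["patient_id", "time_days", "creatinine_umol_l"]).to_csv(
        outdir / "creatinine.csv", index=False)
    rows = []
    for s in trajectories["metabolic"]:
        for t, l, g in zip(s.times, s.lactate, s.glucose):
            rows.append((s.patient_id, t, l, g))
    pd.DataFrame(rows, columns=["patient_id", "time_days", "lactate_mmol_l",
                                "glucose_mmol_l"]).to_csv(
        outdir / "metabolic.csv", index=False)
    truth.table.to_csv(outdir / "ground_truth.csv", index=False)
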
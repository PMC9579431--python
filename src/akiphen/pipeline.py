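"""End-to-end orchestration of the three-step phenotyping analysis.

Step 1 — preprocessing and risk modelling: Yeo-Johnson normalisation with centring and
scaling, bagged-tree imputation, collinearity pruning, univariable screening (p < 0.2),
a penalized additive logistic fit, backward stepwise selection (p < 0.05, severity
score forced) and AUC / Hosmer-Lemeshow evaluation.

Step 2 — attribution and clustering: exact Shapley values of the final model for AKI
patients, UMAP embedding, DBSCAN clustering, cluster profiles.

Step 3 — outcome comparison: KDIGO staging and recovery scored from the creatinine
trajectories, metabolic-pattern summaries, Naive-Bayes posteriors per cluster with
bootstrap inference, and Cox models for recovery and mortality.

Every intermediate table is written as delimited text under the run directory, with a
manifest recording the configuration and a hash of every artifact, so a rerun with the
same configuration reproduces the directory bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as prep
from . import risk_model as rm
from .clustering import (ClusterConfig, EmbeddingConfig, NOISE, cluster_profiles,
                         dbscan, embed, svm_validate)
from .outcomes import (CreatinineTrajectory, MetabolicSeries, assess_recovery,
                       compute_metabolic_thresholds, cox_compare, metabolic_summary,
                       posterior_by_cluster, severity_mortality_curve, stage_kdigo)
from .shap_attribution import ShapMatrix, ValueFunctionConfig, shap_matrix
from .synthetic import GeneratorConfig, generate_cohort

ID_COLS = ("patient_id", "aki")


@dataclass
class RunConfig:
    outdir: str = "runs/latest"
    seed: int = 0
    synthetic: GeneratorConfig | None = None   # None -> read from input_dir
    input_dir: str | None = None
    screen_alpha: float = 0.2
    select_alpha: float = 0.05
    forced: tuple = ("apache",)
    shap_approach: str = "marginal"
    shap_sigma: float = 0.1
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    n_boot: int = 2000
    run_svm_validation: bool = True
    run_stepwise: bool = True

    def fingerprint(self) -> str:
        payload = {
            "seed": self.seed,
            "synthetic": asdict(self.synthetic) if self.synthetic else None,
            "input_dir": self.input_dir,
            "screen_alpha": self.screen_alpha,
            "select_alpha": self.select_alpha,
            "forced": list(self.forced),
            "shap": [self.shap_approach, self.shap_sigma],
            "embedding": asdict(self.embedding),
            "cluster": asdict(self.cluster),
            "n_boot": self.n_boot,
            "run_svm_validation": self.run_svm_validation,
            "run_stepwise": self.run_stepwise,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()


def read_cohort(input_dir):
    """Load a cohort written by :func:`akiphen.synthetic.write_cohort`.

    Returns ``(patients, trajectories, truth_or_None)``; validates monotone
    timestamps and positive creatinine, naming the offending row on failure.
    """
    input_dir = Path(input_dir)
    patients = pd.read_csv(input_dir / "patients.csv")
    crea = pd.read_csv(input_dir / "creatinine.csv")
    if (crea["creatinine_umol_l"] <= 0).any():
        bad = crea.index[crea["creatinine_umol_l"] <= 0][0]
        raise ValueError(f"non-positive creatinine at creatinine.csv row {bad}")
    metab = pd.read_csv(input_dir / "metabolic.csv")
    truth = None
    truth_path = input_dir / "ground_truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
    extent = None
    if truth is not None:
        extent = truth.set_index("patient_id")[["icu_admission", "icu_discharge"]]

    trajectories = {"creatinine": [], "metabolic": []}
    for pid, grp in crea.groupby("patient_id", sort=True):
        t = grp["time_days"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone timestamps for patient {pid} in creatinine.csv")
        icu_adm, icu_dis = (1.0, float(t[-1]))
        if extent is not None and pid in extent.index:
            icu_adm, icu_dis = extent.loc[pid]
        trajectories["creatinine"].append(CreatinineTrajectory(
            patient_id=pid, times=t, values=grp["creatinine_umol_l"].to_numpy(),
            icu_admission=float(icu_adm), icu_discharge=float(icu_dis)))
    for pid, grp in metab.groupby("patient_id", sort=True):
        trajectories["metabolic"].append(MetabolicSeries(
            patient_id=pid, times=grp["time_days"].to_numpy(),
            lactate=grp["lactate_mmol_l"].to_numpy(),
            glucose=grp["glucose_mmol_l"].to_numpy()))
    return patients, trajectories, truth


@dataclass
class PipelineResult:
    outdir: Path
    patients: pd.DataFrame
    processed: pd.DataFrame
    screen: rm.ScreenResult
    model: rm.AdditiveRiskModel
    evaluation: rm.ModelEvaluation
    shap: ShapMatrix
    embedding: np.ndarray
    labels: np.ndarray
    profiles: object
    svm_report: object
    outcome_tables: dict
    truth: pd.DataFrame | None
    manifest: dict


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline; see the module docstring for the stages."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = []

    def stage(msg):
        log.append(f"[{time.time() - t0:7.1f}s] {msg}")

    # ---- inputs ---------------------------------------------------------
    if config.synthetic is not None:
        patients, trajectories, gt = generate_cohort(config.synthetic)
        truth = gt.table
    elif config.input_dir is not None:
        patients, trajectories, truth = read_cohort(config.input_dir)
    else:
        raise ValueError("either synthetic config or input_dir is required")
    stage(f"cohort ready: {len(patients)} patients, "
          f"AKI rate {patients['aki'].mean():.3f}")
    _write(patients, outdir / "patients.csv")

    # ---- step 1: preprocessing -----------------------------------------
    covars = [c for c in patients.columns if c not in ID_COLS]
    params = prep.fit_transform_params(patients[covars])
    processed = prep.transform_table(patients[covars], params)
    if processed.isna().any().any():
        processed = prep.bagged_impute(processed, seed=config.seed)
    collin = prep.prune_collinear(processed, threshold=0.8)
    processed = processed.drop(columns=collin.removed)
    (outdir / "transform_params.txt").write_text(params.to_text())
    (outdir / "collinearity.txt").write_text(collin.to_text())
    stage(f"preprocessing done; removed collinear: {collin.removed}")

    y = patients["aki"].to_numpy(dtype=float)
    screen = rm.univariable_screen(processed, y, alpha=config.screen_alpha)
    _write(screen.table, outdir / "screen.csv")
    kept = screen.kept or list(processed.columns)
    smooth = [v for v in kept if not prep.is_binary(processed[v])]
    linear = [v for v in kept if prep.is_binary(processed[v])]
    forced = [f for f in config.forced if f in kept]
    for f in config.forced:
        if f not in kept and f in processed.columns:
            (smooth if not prep.is_binary(processed[f]) else linear).append(f)
            forced.append(f)
    if config.run_stepwise:
        model, trace = rm.stepwise_select(processed, y, smooth_vars=smooth,
                                          linear_vars=linear, forced=forced,
                                          alpha=config.select_alpha)
    else:
        model = rm.fit_additive_model(processed, y, smooth_vars=smooth,
                                      linear_vars=linear)
        trace = []
    evaluation = rm.evaluate_model(model, processed, y, n_boot=config.n_boot,
                                   seed=config.seed)
    (outdir / "model.txt").write_text(model.to_text())
    (outdir / "model_report.txt").write_text(
        f"selected\t{','.join(model.feature_names)}\n"
        f"dropped\t{','.join(n for n, _ in trace)}\n"
        f"auc\t{evaluation.auc:.6f}\n"
        f"auc_ci\t{evaluation.auc_ci[0]:.6f},{evaluation.auc_ci[1]:.6f}\n"
        f"hosmer_lemeshow\t{evaluation.hl_statistic:.6f} "
        f"(df={evaluation.hl_df}, p={evaluation.hl_p:.4f})\n")
    stage(f"risk model: {model.feature_names}, AUC {evaluation.auc:.3f}")

    # ---- step 2: attribution + clustering ------------------------------
    vf = ValueFunctionConfig(approach=config.shap_approach, background=processed,
                             sigma=config.shap_sigma)
    cohort_with_label = processed.copy()
    cohort_with_label["aki"] = y
    shap = shap_matrix(model, cohort_with_label, vf,
                       features=model.feature_names, restrict_to="aki")
    shap.write(outdir / "shap_matrix.csv")
    coords = embed(shap.values, config.embedding)
    labels = dbscan(coords, config.cluster)
    profiles = cluster_profiles(shap.values, labels)
    _write(pd.DataFrame({"patient_id": shap.values.index,
                         "umap_1": coords[:, 0], "umap_2": coords[:, 1],
                         "cluster": labels}), outdir / "clusters.csv")
    profiles.mean_phi.to_csv(outdir / "cluster_mean_phi.csv", index_label="cluster")
    n_clusters = len(set(labels) - {NOISE})
    stage(f"clustering: {n_clusters} clusters, {int((labels == NOISE).sum())} noise")

    svm_report = None
    if config.run_svm_validation and n_clusters >= 2:
        svm_report = svm_validate(coords, labels, n_boot=config.n_boot,
                                  seed=config.seed)
        lines = ["cluster\tcost\tauc_mean\tauc_sd"]
        for c, r in svm_report.per_cluster.items():
            lines.append(f"{c}\t{r['cost']:g}\t{r['auc_mean']:.6f}\t{r['auc_sd']:.6f}")
        (outdir / "svm_validation.txt").write_text("\n".join(lines) + "\n")

    # ---- step 3: outcomes ----------------------------------------------
    outcome_tables = compare_outcomes(
        patients, trajectories, truth, shap.values.index.to_numpy(), labels,
        n_boot=config.n_boot, seed=config.seed)
    for name, df in outcome_tables.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(outdir / f"outcome_{name}.csv")
    stage("outcome comparison done")

    manifest = {
        "config_hash": config.fingerprint(),
        "seed": config.seed,
        "n_patients": len(patients),
        "artifacts": {},
    }
    for f in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.txt")):
        manifest["artifacts"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    (outdir / "log.txt").write_text("\n".join(log) + "\n")
    return PipelineResult(outdir=outdir, patients=patients, processed=processed,
                          screen=screen, model=model, evaluation=evaluation,
                          shap=shap, embedding=coords, labels=labels,
                          profiles=profiles, svm_report=svm_report,
                          outcome_tables=outcome_tables, truth=truth,
                          manifest=manifest)


def compare_outcomes(patients, trajectories, truth, aki_ids, labels,
                     n_boot: int = 2000, seed: int = 0) -> dict:
    """Score renal/metabolic outcomes and compare them across clusters.

    ``aki_ids`` are the patient ids of the attribution-matrix rows, aligned with
    ``labels``; noise points are excluded from the comparisons.
    """
    crea = {t.patient_id: t for t in trajectories["creatinine"]}
    metab = {s.patient_id: s for s in trajectories["metabolic"]}

    # KDIGO scoring + recovery for all AKI patients
    rrt_flags = {}
    if truth is not None and "rrt" in truth.columns:
        rrt_flags = truth.set_index("patient_id")["rrt"].astype(bool).to_dict()
    rows = []
    for pid in aki_ids:
        traj = crea[pid]
        kd = stage_kdigo(traj, rrt=rrt_flags.get(pid, traj.rrt))
        rec, rec_time = assess_recovery(traj, kd)
        rows.append((pid, kd.stage, kd.onset, int(rec),
                     rec_time - (kd.onset or traj.times[0])))
    kdigo_table = pd.DataFrame(rows, columns=["patient_id", "stage", "onset",
                                              "recovered", "recovery_duration"])
    kdigo_table = kdigo_table.set_index("patient_id")

    # metabolic thresholds from the pooled cohort, summaries per AKI patient
    lac_all = np.concatenate([s.lactate for s in trajectories["metabolic"]])
    glu_all = np.concatenate([s.glucose for s in trajectories["metabolic"]])
    thresholds = compute_metabolic_thresholds(lac_all, glu_all)
    dominant = {}
    for pid in aki_ids:
        s = metab[pid]
        traj = crea[pid]
        end = traj.icu_discharge if traj.icu_discharge else s.times[-1]
        summ = metabolic_summary(s, thresholds, traj.icu_admission, max(end, s.times[-1]))
        dominant[pid] = summ.dominant
    kdigo_table["metabolic_pattern"] = pd.Series(dominant)

    keep = labels != NOISE
    ids = np.asarray(aki_ids)[keep]
    labs = np.asarray(labels)[keep]
    sub = kdigo_table.loc[ids]
    out = {"kdigo": kdigo_table.reset_index(),
           "thresholds": pd.DataFrame([vars(thresholds)])}
    if len(np.unique(labs)) >= 2:
        out["posterior_stage"] = posterior_by_cluster(
            labs, sub["stage"].to_numpy(), n_boot=n_boot, seed=seed).posterior
        out["posterior_metabolic"] = posterior_by_cluster(
            labs, sub["metabolic_pattern"].to_numpy(), n_boot=n_boot,
            seed=seed + 1).posterior
        if truth is not None and "died" in truth.columns:
            died = truth.set_index("patient_id").loc[ids, "died"].to_numpy()
            if len(np.unique(died)) > 1:
                out["posterior_mortality"] = posterior_by_cluster(
                    labs, died, n_boot=n_boot, seed=seed + 2).posterior
        rec_t = np.maximum(sub["recovery_duration"].to_numpy(dtype=float), 1e-3)
        rec_e = sub["recovered"].to_numpy(dtype=int)
        if rec_e.sum() > 0:
            cox = cox_compare(rec_t, rec_e, labs)
            out["cox_recovery"] = pd.DataFrame({
                "cluster": list(cox.hazard_ratio),
                "hr": list(cox.hazard_ratio.values()),
                "ci_low": list(cox.ci_low.values()),
                "ci_high": list(cox.ci_high.values()),
                "p": list(cox.p_value.values())})
        if truth is not None and "died" in truth.columns:
            died = truth.set_index("patient_id").loc[ids, "died"].to_numpy()
            ratios = np.array([crea[p].values.max() / crea[p].baseline
                               for p in ids])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                curves = severity_mortality_curve(labs, np.maximum(ratios, 1.0), died)
            if curves:
                rows = []
                for c, cu in curves.items():
                    for g, p_, lo, hi in zip(cu["grid"], cu["prob"],
                                             cu["ci_low"], cu["ci_high"]):
                        rows.append((c, g, p_, lo, hi, cu["lrt_p"]))
                out["severity_mortality"] = pd.DataFrame(
                    rows, columns=["cluster", "ratio", "death_prob",
                                   "ci_low", "ci_high", "lrt_p"])
    return out
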
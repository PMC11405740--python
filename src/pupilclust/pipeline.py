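"""Config-driven orchestration: cohort -> features -> clusters -> reports.

``run_pipeline`` executes the full analysis deterministically under the
seeds recorded in the config and writes a run directory of tidy CSVs plus
a JSON manifest (config hash, seeds, package versions, row counts at each
stage).  ``validate_run`` scores a synthetic-mode run against its ground
truth: adjusted Rand index of cluster recovery, the expected direction
pattern of the autonomic/oculomotor contrasts, and HRV parameter recovery.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pupilclust._version import __version__
from pupilclust.schedule import TaskSchedule, build_schedule, level_windows
from pupilclust.synthetic import CohortData, NoiseConfig, default_archetypes, generate_cohort
from pupilclust.pupil import trajectory_matrix, screen_outliers, PupilTrajectory
from pupilclust.cluster import kmeans_fit, align_labels, adjusted_rand
from pupilclust.autonomic import (filter_ecg, detect_r_peaks, clean_nn, segment_hrv,
                                  scr_metrics, rsp_metrics)
from pupilclust.ocular import aggregate_eye, aggregate_behavior
from pupilclust.stats import (report_levels, report_blocks, peak_reactions,
                              compare_groups, chi_square_2x2, _results_frame,
                              _iter_comparisons)

logger = logging.getLogger(__name__)

HRV_LEVEL_METRICS = ("hrv_mean_nn_ms", "hrv_sdnn_ms", "hrv_rmssd_ms",
                     "hrv_lf", "hrv_hf", "hrv_lf_hf")

# expected contrast directions on the synthetic default, aligned labels:
# +1 means cluster 0 mean above cluster 1, -1 the reverse
EXPECTED_SIGNS = {
    "hrv_mean_nn_ms": +1, "hrv_sdnn_ms": +1, "hrv_rmssd_ms": +1, "hrv_hf": +1,
    "saccade_count": -1, "fixation_count": -1, "blink_count": -1,
    "total_time_ms": -1,
}


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; hashable for the manifest."""

    mode: str = "synthetic"                 # synthetic | directory
    input_dir: str | None = None
    # schedule
    n_blocks: int = 3
    n_levels: int = 6
    n_trials: int = 17
    # generator
    n_per_archetype: tuple[int, int] = (33, 37)
    noise_scale: float = 1.0
    channels: tuple[str, ...] = ("pupil", "eye", "ecg", "eda", "rsp", "questionnaire")
    generator_seed: int = 0
    # pipeline
    smooth_window: int | None = 17
    contamination: float = 0.05
    drop_outliers: bool = False
    k: int = 2
    n_init: int = 25
    cluster_seed: int = 0
    outlier_seed: int = 0
    # stats
    alpha_normality: float = 0.05
    out_dir: str = "run_output"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "directory"):
            raise ValueError("mode must be 'synthetic' or 'directory'")
        if self.mode == "directory" and not self.input_dir:
            raise ValueError("directory mode requires input_dir")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("n_per_archetype", "channels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _autonomic_metrics(cohort: CohortData) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-level HRV and per-block peripheral metrics, long format."""
    level_rows, block_rows = [], []
    for pid in cohort.participants:
        spans = cohort.level_time_spans(pid)
        if pid in cohort.ecg:
            rec = cohort.ecg[pid]
            filtered = filter_ecg(np.asarray(rec["signal"], dtype=float), rec["fs"])
            nn = detect_r_peaks(filtered, rec["fs"])
            if len(nn.nn_ms) >= 3:
                nn = clean_nn(nn)
                for m in segment_hrv(nn, spans):
                    if len(m.segment) != 2:
                        continue        # block-span rows reported separately
                    block, level = m.segment
                    for name, value in (("hrv_mean_nn_ms", m.mean_nn_ms),
                                        ("hrv_sdnn_ms", m.sdnn_ms),
                                        ("hrv_rmssd_ms", m.rmssd_ms),
                                        ("hrv_lf", m.lf_power),
                                        ("hrv_hf", m.hf_power),
                                        ("hrv_lf_hf", m.lf_hf_ratio)):
                        level_rows.append({"participant": pid, "block": block,
                                           "level": level, "metric": name, "value": value})
        for block, sub in spans.groupby("block"):
            window = (float(sub["t_start_s"].min()), float(sub["t_end_s"].max()))
            if pid in cohort.eda:
                rec = cohort.eda[pid]
                count, amp = scr_metrics(np.asarray(rec["signal"], dtype=float),
                                         rec["fs"], window=window)
                block_rows.append({"participant": pid, "block": int(block),
                                   "metric": "scr_peak_count", "value": float(count)})
                block_rows.append({"participant": pid, "block": int(block),
                                   "metric": "scr_peak_amp_mean_uS", "value": amp})
            if pid in cohort.rsp:
                rec = cohort.rsp[pid]
                pm = rsp_metrics(np.asarray(rec["signal"], dtype=float),
                                 rec["fs"], window=window)
                for name, value in (("rsp_rate_mean_bpm", pm.rsp_rate_mean_bpm),
                                    ("rsp_amp_mean", pm.rsp_amp_mean),
                                    ("rsp_insp_s", pm.rsp_insp_s),
                                    ("rsp_exp_s", pm.rsp_exp_s),
                                    ("rsp_phase_ratio", pm.rsp_phase_ratio)):
                    block_rows.append({"participant": pid, "block": int(block),
                                       "metric": name, "value": value})
    return pd.DataFrame(level_rows), pd.DataFrame(block_rows)


def _eye_behavior_metrics(cohort: CohortData) -> pd.DataFrame:
    rows = []
    have_eye = len(cohort.saccades) > 0 or len(cohort.fixations) > 0 or len(cohort.blinks) > 0
    for pid in cohort.participants:
        trials = cohort.trial_table[cohort.trial_table["participant"] == pid]
        spans = cohort.level_time_spans(pid)
        beh = aggregate_behavior(trials)
        beh.insert(0, "participant", pid)
        rows.append(beh)
        if have_eye:
            eye = aggregate_eye(
                cohort.saccades[cohort.saccades["participant"] == pid],
                cohort.fixations[cohort.fixations["participant"] == pid],
                cohort.blinks[cohort.blinks["participant"] == pid],
                spans,
            )
            eye.insert(0, "participant", pid)
            rows.append(eye)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def _questionnaire_report(quest: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    merged = quest.merge(labels, on="participant")
    rows = []
    for col in ("ess", "bdi", "stai_state", "stai_trait", "taylor", "bmi"):
        if col not in merged:
            continue
        x0 = merged.loc[merged["cluster"] == 0, col].to_numpy(dtype=float)
        x1 = merged.loc[merged["cluster"] == 1, col].to_numpy(dtype=float)
        res = compare_groups(x0, x1, variable=col, segment=())
        rows.append({"variable": col, "test": res.test, "statistic": res.statistic,
                     "p_value": res.p_value, "mean0": res.mean0, "sd0": res.sd0,
                     "mean1": res.mean1, "sd1": res.sd1, "rbc": res.rbc, "cles": res.cles})
    if "smoker" in merged:
        tab = pd.crosstab(merged["cluster"], merged["smoker"]).reindex(
            index=[0, 1], columns=[False, True], fill_value=0).to_numpy()
        if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
            chi2, p = chi_square_2x2(tab)
            rows.append({"variable": "smoker", "test": "chi_square",
                         "statistic": chi2, "p_value": p,
                         "mean0": np.nan, "sd0": np.nan, "mean1": np.nan, "sd1": np.nan,
                         "rbc": np.nan, "cles": np.nan})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the in-memory artifacts and
    writes the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    schedule = build_schedule(config.n_blocks, config.n_levels, config.n_trials)
    if config.mode == "synthetic":
        cohort = generate_cohort(
            schedule=schedule,
            n_per_archetype=config.n_per_archetype,
            noise=NoiseConfig().scaled(config.noise_scale),
            seed=config.generator_seed,
            channels=config.channels,
        )
    else:
        cohort = CohortData.from_directory(config.input_dir)
        schedule = cohort.schedule
        for channel, table in (("trials", cohort.trial_table),):
            if table is None or len(table) == 0:
                raise FileNotFoundError(f"input directory missing channel: {channel}")
    counts["participants"] = len(cohort.participants)
    counts["trial_rows"] = len(cohort.trial_table)
    logger.info("cohort ready: %d participants", counts["participants"])

    # features
    matrix, pids = trajectory_matrix(cohort.trial_table,
                                     smooth_window=config.smooth_window)
    trajs = [PupilTrajectory(p, v, state="smoothed" if config.smooth_window else "normalized")
             for p, v in zip(pids, matrix)]
    outlier_mask = (screen_outliers(trajs, contamination=config.contamination,
                                    seed=config.outlier_seed)
                    if len(trajs) >= 10 else np.zeros(len(trajs), dtype=bool))
    flagged = [p for p, m in zip(pids, outlier_mask) if m]
    logger.info("outlier screening flagged: %s", flagged)
    if config.drop_outliers and outlier_mask.any():
        keep = ~outlier_mask
        matrix, pids = matrix[keep], [p for p, m in zip(pids, outlier_mask) if not m]
    counts["clustered_participants"] = len(pids)

    # clustering
    result = kmeans_fit(matrix, k=config.k, n_init=config.n_init,
                        seed=config.cluster_seed)
    if config.k == 2:
        result = align_labels(result, matrix, schedule)
    labels = pd.DataFrame({"participant": pids, "cluster": result.labels,
                           "outlier_flag": [p in flagged for p in pids]})

    # per-participant pupil metric rows (per-level mean of the z-scored trace)
    pupil_rows = []
    for pid, vec in zip(pids, matrix):
        for win in level_windows(schedule):
            seg = vec[win.first_trial:win.last_trial]
            pupil_rows.append({"participant": pid, "block": win.block, "level": win.level,
                               "metric": "pupil_norm_mean", "value": float(seg.mean())})
            pupil_rows.append({"participant": pid, "block": win.block, "level": win.level,
                               "metric": "pupil_norm_max", "value": float(seg.max())})
    pupil_metrics = pd.DataFrame(pupil_rows)

    hrv_levels, block_extra = _autonomic_metrics(cohort)
    eye_beh = _eye_behavior_metrics(cohort)
    level_metrics = pd.concat([df for df in (pupil_metrics, hrv_levels, eye_beh)
                               if len(df)], ignore_index=True)
    counts["level_metric_rows"] = len(level_metrics)

    level_report = report_levels(level_metrics, labels)
    block_report = report_blocks(level_metrics, labels)
    if len(block_extra):
        extra = _results_frame(_iter_comparisons(block_extra, labels, by=["block"]))
        block_report = pd.concat([block_report, extra], ignore_index=True)
    peaks = peak_reactions(level_metrics, labels, schedule)
    quest_report = (_questionnaire_report(cohort.questionnaires, labels)
                    if len(cohort.questionnaires) else pd.DataFrame())

    # persist
    schedule.to_frame().to_csv(out / "schedule.csv", index=False)
    pd.DataFrame(matrix, index=pids).to_csv(out / "trajectories.csv")
    labels.to_csv(out / "labels.csv", index=False)
    pd.DataFrame(result.centroids).to_csv(out / "centroids.csv", index=False)
    level_metrics.to_csv(out / "metrics_levels.csv", index=False)
    if len(block_extra):
        block_extra.to_csv(out / "metrics_blocks_peripheral.csv", index=False)
    level_report.to_csv(out / "report_levels.csv", index=False)
    block_report.to_csv(out / "report_blocks.csv", index=False)
    peaks.to_csv(out / "report_peaks.csv", index=False)
    if len(quest_report):
        quest_report.to_csv(out / "report_questionnaires.csv", index=False)
    if config.mode == "synthetic" and cohort.truth is not None:
        cohort.truth.to_csv(out / "truth.csv", index=False)
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seeds": {"generator": config.generator_seed, "cluster": config.cluster_seed,
                  "outlier": config.outlier_seed},
        "inertia": float(result.inertia),
        "cluster_sizes": np.bincount(result.labels, minlength=config.k).tolist(),
        "row_counts": counts,
        "outliers_flagged": flagged,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return {"cohort": cohort, "matrix": matrix, "participants": pids,
            "clustering": result, "labels": labels,
            "level_metrics": level_metrics, "block_extra": block_extra,
            "level_report": level_report, "block_report": block_report,
            "peaks": peaks, "questionnaire_report": quest_report,
            "manifest": manifest}


def validate_run(run_dir) -> dict:
    """Score a completed synthetic run against its ground truth.

    Reports ARI between recovered clusters and archetype labels, the
    fraction of expected contrast directions matched in the block report,
    and MeanNN parameter-recovery error.  Writes validation.json.
    """
    run_dir = Path(run_dir)
    labels = pd.read_csv(run_dir / "labels.csv")
    report = {"status": "ok"}
    truth_path = run_dir / "truth.csv"
    if not truth_path.exists():
        report["status"] = "skipped"
        report["note"] = "no truth file; validation applies to synthetic runs only"
    else:
        truth = pd.read_csv(truth_path)
        merged = labels.merge(truth, on="participant")
        ari = adjusted_rand(merged["cluster"].to_numpy(), merged["archetype"].to_numpy())
        report["ari"] = ari
        report["ari_pass"] = bool(ari >= 0.9)

        block_path = run_dir / "report_blocks.csv"
        if block_path.exists():
            blocks = pd.read_csv(block_path)
            checks = {}
            for metric, sign in EXPECTED_SIGNS.items():
                sub = blocks[blocks["variable"] == metric]
                if not len(sub):
                    continue
                diff = (sub["mean0"] - sub["mean1"]) * sign
                checks[metric] = bool((diff > 0).all())
            report["direction_checks"] = checks
            report["direction_pass"] = bool(checks) and all(checks.values())

        metrics_path = run_dir / "metrics_levels.csv"
        if metrics_path.exists() and "mean_nn_ms" in truth.columns:
            lm = pd.read_csv(metrics_path)
            mn = (lm[lm["metric"] == "hrv_mean_nn_ms"]
                  .groupby("participant")["value"].mean().rename("recovered"))
            rec = truth.set_index("participant").join(mn, how="inner")
            if len(rec):
                rel_err = float(np.nanmean(
                    np.abs(rec["recovered"] - rec["mean_nn_ms"]) / rec["mean_nn_ms"]))
                report["mean_nn_recovery_rel_err"] = rel_err
                report["recovery_pass"] = bool(rel_err < 0.02)
    with open(run_dir / "validation.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
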
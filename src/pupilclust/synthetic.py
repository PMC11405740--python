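"""Synthetic multimodal cohort with known archetype labels.

The generator emulates the statistical structure the downstream pipeline
assumes: two latent participant archetypes with

* distinct pupil-trajectory shapes over the 306-trial task — archetype 0
  starts each block elevated and declines within the block; archetype 1
  starts low, rises with difficulty, and shows an additive pupil peak on
  the deceptive-feedback cells (largest at block 2, level 3);
* archetype-dependent cardiac autonomic tone — archetype 0 has longer
  NN intervals, larger beat-to-beat variability and stronger
  high-frequency (respiratory-band) modulation;
* archetype-dependent oculomotor event rates (archetype 1 saccades,
  fixates and blinks more often);
* behavioral profiles: archetype 0 fast but error-prone with lower
  self-esteem ratings, archetype 1 slow but accurate.

Everything is deterministic under a seed: one ``numpy.random.SeedSequence``
is spawned per participant, so cohorts are reproducible element-for-element
and participants are independent streams.

Trials are self-paced; per-trial durations are stimulus exposure plus the
participant's simulated response time plus feedback, and those durations
anchor the continuous ECG/EDA/respiration traces in time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from pupilclust.schedule import TaskSchedule, build_schedule, level_windows

# LF / HF carrier frequencies for RR modulation: Task-Force band centers.
LF_CARRIER_HZ = 0.1
HF_CARRIER_HZ = 0.25

STIM_EXPOSURE_MS = 2000.0
FEEDBACK_MS = 600.0
RT_GAMMA_SHAPE = 8.0          # right-skewed, positive reaction times
RT_LEVEL_GAIN = 0.08          # fractional RT increase per difficulty level
DECEPTION_DECAY = 0.6         # pupil-bump decay over successive deceptive levels


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters of one participant archetype."""

    label: int
    # pupil shape, in units of the participant's own pupil SD
    pupil_start_offset: float
    pupil_block_slope: float
    deception_peak_amp: float
    # cardiac
    mean_nn_ms: float
    rmssd_target_ms: float
    lf_mod_amp: float
    hf_mod_amp: float
    # oculomotor event rates (events / s)
    saccade_rate_hz: float
    fixation_rate_hz: float
    blink_rate_hz: float
    # behavior
    rt_mean_ms: float
    error_prob_by_level: tuple[float, ...]
    self_esteem_bias: float

    def __post_init__(self) -> None:
        if not 300.0 < self.mean_nn_ms < 1500.0:
            raise ValueError(f"mean_nn_ms must be in (300, 1500), got {self.mean_nn_ms}")
        if len(self.error_prob_by_level) != 6:
            raise ValueError("error_prob_by_level must have length 6")
        if any(not 0.0 <= p <= 1.0 for p in self.error_prob_by_level):
            raise ValueError("error probabilities must lie in [0, 1]")
        for name in ("saccade_rate_hz", "fixation_rate_hz", "blink_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def default_archetypes() -> tuple[ArchetypeSpec, ArchetypeSpec]:
    """The two default phenotypes the cohort is built from.

    Archetype 0: strong orienting response at block onset that habituates
    within the block, high vagal tone, few eye events, fast but error-prone,
    pessimistic self-ratings.  Archetype 1: low pupil baseline that climbs
    with difficulty plus a pronounced reaction to deceptive feedback, low
    vagal tone, many eye events, slow but accurate, optimistic self-ratings.
    """
    arch0 = ArchetypeSpec(
        label=0,
        pupil_start_offset=1.4,
        pupil_block_slope=-1.8,
        deception_peak_amp=0.3,
        mean_nn_ms=860.0,
        rmssd_target_ms=45.0,
        lf_mod_amp=18.0,
        hf_mod_amp=30.0,
        saccade_rate_hz=2.0,
        fixation_rate_hz=2.2,
        blink_rate_hz=0.15,
        rt_mean_ms=950.0,
        error_prob_by_level=(0.06, 0.09, 0.13, 0.18, 0.24, 0.30),
        self_esteem_bias=-0.6,
    )
    arch1 = ArchetypeSpec(
        label=1,
        pupil_start_offset=-1.1,
        pupil_block_slope=1.4,
        deception_peak_amp=1.5,
        mean_nn_ms=760.0,
        rmssd_target_ms=25.0,
        lf_mod_amp=12.0,
        hf_mod_amp=12.0,
        saccade_rate_hz=3.0,
        fixation_rate_hz=3.2,
        blink_rate_hz=0.30,
        rt_mean_ms=1350.0,
        error_prob_by_level=(0.02, 0.04, 0.06, 0.08, 0.11, 0.15),
        self_esteem_bias=0.6,
    )
    return arch0, arch1


@dataclass(frozen=True)
class NoiseConfig:
    """Scales of the stochastic components around the archetype shapes."""

    pupil_noise_sd: float = 0.25      # per-trial pupil noise, SD units
    param_jitter_rel: float = 0.08    # relative participant-to-participant jitter
    rr_jitter_scale: float = 1.0      # multiplies the RMSSD-derived RR jitter

    def scaled(self, factor: float) -> "NoiseConfig":
        return NoiseConfig(
            self.pupil_noise_sd * factor,
            self.param_jitter_rel * factor,
            self.rr_jitter_scale * factor,
        )


@dataclass
class CohortData:
    """In-memory synthetic cohort: tidy tables plus continuous traces.

    ``truth`` carries the participant -> archetype map and generative
    parameters; the analysis pipeline never reads it (it is only consumed
    by validation code scoring cluster recovery).
    """

    schedule: TaskSchedule
    seed: int
    trial_table: pd.DataFrame
    saccades: pd.DataFrame
    fixations: pd.DataFrame
    blinks: pd.DataFrame
    questionnaires: pd.DataFrame
    ecg: dict = field(default_factory=dict)        # pid -> {fs, signal, r_sample_idx}
    eda: dict = field(default_factory=dict)        # pid -> {fs, signal, event_times_s}
    rsp: dict = field(default_factory=dict)        # pid -> {fs, signal}
    truth: pd.DataFrame | None = None

    @property
    def participants(self) -> list[str]:
        return list(self.trial_table["participant"].unique())

    def level_time_spans(self, participant: str) -> pd.DataFrame:
        """Wall-clock [start, end) of every (block, level) for one participant."""
        sub = self.trial_table[self.trial_table["participant"] == participant]
        grp = sub.groupby(["block", "level"], sort=True)
        spans = grp.agg(t_start_s=("t_start_s", "min"), t_end_s=("t_end_s", "max"))
        return spans.reset_index()

    def to_directory(self, path) -> None:
        """Write the tidy-CSV directory layout (truth in a separate file)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.trial_table.to_csv(path / "trials.csv", index=False)
        self.saccades.to_csv(path / "saccades.csv", index=False)
        self.fixations.to_csv(path / "fixations.csv", index=False)
        self.blinks.to_csv(path / "blinks.csv", index=False)
        self.questionnaires.to_csv(path / "questionnaires.csv", index=False)
        meta = {"seed": self.seed,
                "schedule": {"n_blocks": self.schedule.n_blocks,
                             "n_levels": self.schedule.n_levels_per_block,
                             "n_trials": self.schedule.n_trials_per_level,
                             "deceptive_cells": sorted(map(list, self.schedule.deceptive_cells))},
                "sampling_rates_hz": {}}
        for name, store in (("ecg", self.ecg), ("eda", self.eda), ("rsp", self.rsp)):
            if not store:
                continue
            sub = path / name
            sub.mkdir(exist_ok=True)
            for pid, rec in store.items():
                df = pd.DataFrame({"signal": rec["signal"]})
                df.to_csv(sub / f"{pid}.csv", index=False)
                meta["sampling_rates_hz"][name] = rec["fs"]
        with open(path / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        if self.truth is not None:
            self.truth.to_csv(path / "truth.csv", index=False)

    @classmethod
    def from_directory(cls, path) -> "CohortData":
        path = Path(path)
        with open(path / "metadata.json") as fh:
            meta = json.load(fh)
        sch = build_schedule(meta["schedule"]["n_blocks"], meta["schedule"]["n_levels"],
                             meta["schedule"]["n_trials"],
                             frozenset(tuple(c) for c in meta["schedule"]["deceptive_cells"]))
        stores = {}
        for name in ("ecg", "eda", "rsp"):
            stores[name] = {}
            sub = path / name
            if sub.is_dir():
                fs = meta["sampling_rates_hz"][name]
                for f in sorted(sub.glob("*.csv")):
                    stores[name][f.stem] = {
                        "fs": fs,
                        "signal": pd.read_csv(f)["signal"].to_numpy(),
                    }
        truth_path = path / "truth.csv"
        return cls(
            schedule=sch,
            seed=meta["seed"],
            trial_table=pd.read_csv(path / "trials.csv"),
            saccades=pd.read_csv(path / "saccades.csv"),
            fixations=pd.read_csv(path / "fixations.csv"),
            blinks=pd.read_csv(path / "blinks.csv"),
            questionnaires=pd.read_csv(path / "questionnaires.csv"),
            ecg=stores["ecg"], eda=stores["eda"], rsp=stores["rsp"],
            truth=pd.read_csv(truth_path) if truth_path.exists() else None,
        )


# ---------------------------------------------------------------------------
# channel generators
# ---------------------------------------------------------------------------

def pupil_trace(arch: ArchetypeSpec, schedule: TaskSchedule, noise_sd: float,
                rng: np.random.Generator) -> np.ndarray:
    """Per-trial mean pupil sizes (arbitrary SD units) for one participant.

    The deterministic part is piecewise linear in the within-block position,
    with an additive bump on deceptive cells that is largest on the first
    deceptive level and decays geometrically over later ones.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = schedule.total_trials
    per_block = schedule.trials_per_block
    t = np.arange(n)
    pos = (t % per_block) / per_block             # within-block position in [0, 1)
    values = arch.pupil_start_offset + arch.pupil_block_slope * pos

    deceptive_by_block: dict[int, list[int]] = {}
    for b, l in sorted(schedule.deceptive_cells):
        deceptive_by_block.setdefault(b, []).append(l)
    for win in level_windows(schedule):
        levels = deceptive_by_block.get(win.block, [])
        if win.level in levels:
            rank = levels.index(win.level)
            bump = arch.deception_peak_amp * DECEPTION_DECAY**rank
            values[win.first_trial : win.last_trial] += bump
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n)
    return values


def rr_series(arch: ArchetypeSpec, duration_s: float, rng: np.random.Generator,
              jitter_sd_ms: float | None = None) -> np.ndarray:
    """Successive RR intervals (ms) covering at least ``duration_s``.

    RR(t) = mean_nn + lf_amp sin(2 pi 0.1 t) + hf_amp sin(2 pi 0.25 t)
    plus white Gaussian jitter whose SD defaults to rmssd_target / sqrt(2)
    (white jitter of SD s yields RMSSD = s * sqrt(2)).
    """
    if duration_s < 60:
        raise ValueError("duration_s must be >= 60 s")
    if arch.mean_nn_ms - arch.lf_mod_amp - arch.hf_mod_amp <= 0:
        raise ValueError("modulation amplitudes imply non-positive RR intervals")
    if jitter_sd_ms is None:
        jitter_sd_ms = arch.rmssd_target_ms / np.sqrt(2.0)
    intervals = []
    t = 0.0
    while t < duration_s:
        rr = (arch.mean_nn_ms
              + arch.lf_mod_amp * np.sin(2 * np.pi * LF_CARRIER_HZ * t)
              + arch.hf_mod_amp * np.sin(2 * np.pi * HF_CARRIER_HZ * t))
        if jitter_sd_ms > 0:
            rr += rng.normal(0.0, jitter_sd_ms)
        rr = max(rr, 310.0)  # physiological floor; jitter never reaches it at defaults
        intervals.append(rr)
        t += rr / 1000.0
    return np.asarray(intervals)


def render_ecg(rr_ms: np.ndarray, fs: float = 250.0, qrs_amp: float = 1.0,
               baseline_noise_sd: float = 0.0,
               rng: np.random.Generator | None = None,
               qrs_sigma_s: float = 0.012,
               t_start_s: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Render an RR sequence as a waveform of narrow Gaussian QRS templates.

    Returns (signal, r_sample_idx) where ``r_sample_idx`` are the ground-truth
    R-peak sample positions.  Deliberately not a full PQRST morphology: the
    template only has to exercise the high-pass filter and peak detector.
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    r_times = t_start_s + np.concatenate([[0.0], np.cumsum(rr_ms) / 1000.0])
    n = int(np.ceil((r_times[-1] + 1.0) * fs))
    signal = np.zeros(n)
    half = int(np.ceil(4 * qrs_sigma_s * fs))
    for rt in r_times:
        center = rt * fs
        lo = max(0, int(np.floor(center)) - half)
        hi = min(n, int(np.ceil(center)) + half + 1)
        idx = np.arange(lo, hi)
        signal[lo:hi] += qrs_amp * np.exp(-0.5 * ((idx - center) / (qrs_sigma_s * fs)) ** 2)
    if baseline_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        signal = signal + rng.normal(0.0, baseline_noise_sd, size=n)
    return signal, np.round(r_times * fs).astype(int)


def eda_trace(duration_s: float, fs: float, rng: np.random.Generator,
              event_rate_hz: float = 0.05, amp_mean_uS: float = 0.3,
              tonic_uS: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Minimal electrodermal trace: tonic drift + exponential-recovery SCRs.

    SCR events occur at Poisson times; each rises over ~0.8 s and decays with
    a 3 s time constant.  Returns (signal, event_times_s).
    """
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    signal = tonic_uS + 0.1 * np.sin(2 * np.pi * t / duration_s)
    n_events = rng.poisson(event_rate_hz * duration_s)
    times = np.sort(rng.uniform(0, duration_s - 10.0, size=n_events))
    for t0 in times:
        amp = amp_mean_uS * rng.lognormal(0.0, 0.3)
        rel = t - t0
        shape = np.where(rel >= 0, (1 - np.exp(-np.maximum(rel, 0) / 0.25)) * np.exp(-np.maximum(rel, 0) / 3.0), 0.0)
        signal = signal + amp * shape / shape.max() if shape.max() > 0 else signal
    return signal, times


def rsp_trace(duration_s: float, fs: float, rng: np.random.Generator,
              period_mean_s: float = 4.0, period_sd_s: float = 0.3,
              amplitude: float = 1.0) -> np.ndarray:
    """Sinusoidal respiration with cycle-to-cycle jittered period."""
    n = int(duration_s * fs)
    periods = []
    total = 0.0
    while total < duration_s + period_mean_s:
        p = max(1.0, rng.normal(period_mean_s, period_sd_s))
        periods.append(p)
        total += p
    # instantaneous frequency piecewise-constant per cycle; integrate phase
    t = np.arange(n) / fs
    edges = np.concatenate([[0.0], np.cumsum(periods)])
    cycle = np.searchsorted(edges, t, side="right") - 1
    freq = 1.0 / np.asarray(periods)[cycle]
    phase = np.concatenate([[0.0], np.cumsum(2 * np.pi * freq[:-1] / fs)])
    return amplitude * np.sin(phase)


def eye_and_behavior(arch: ArchetypeSpec, schedule: TaskSchedule,
                     rng: np.random.Generator,
                     rt_mean_ms: float | None = None,
                     error_probs: np.ndarray | None = None,
                     self_esteem_bias: float | None = None):
    """Simulate trial-level behavior and Poisson eye events for one participant.

    Returns ``(trials, saccades, fixations, blinks)`` where ``trials`` carries
    per-trial RT (gamma, mean increasing with level), response correctness
    (Bernoulli per level), wall-clock trial start/end, and the level's single
    self-esteem rating (1..5 integer scale) repeated over its trials.
    """
    rt_mean_ms = arch.rt_mean_ms if rt_mean_ms is None else rt_mean_ms
    error_probs = np.asarray(arch.error_prob_by_level if error_probs is None else error_probs)
    bias = arch.self_esteem_bias if self_esteem_bias is None else self_esteem_bias

    rows = []
    t_clock = 0.0
    sac_rows, fix_rows, blink_rows = [], [], []
    for win in level_windows(schedule):
        level_mean_rt = rt_mean_ms * (1.0 + RT_LEVEL_GAIN * (win.level - 1))
        p_err = error_probs[min(win.level, len(error_probs)) - 1]
        esteem = int(np.clip(np.round(
            5.0 - 0.55 * (win.level - 1) + bias + rng.normal(0.0, 0.5)), 1, 5))
        level_start = t_clock
        for trial in range(win.first_trial, win.last_trial):
            rt = rng.gamma(RT_GAMMA_SHAPE, level_mean_rt / RT_GAMMA_SHAPE)
            correct = rng.random() >= p_err
            truth_key = int(rng.integers(1, 3))
            response = truth_key if correct else 3 - truth_key
            dur_s = (STIM_EXPOSURE_MS + rt + FEEDBACK_MS) / 1000.0
            rows.append({
                "trial": trial, "block": win.block, "level": win.level,
                "rt_ms": rt, "response": response, "correct": bool(correct),
                "self_esteem": esteem,
                "t_start_s": t_clock, "t_end_s": t_clock + dur_s,
            })
            t_clock += dur_s
        span = t_clock - level_start
        for store, rate, dur_med, dur_sig in (
            (sac_rows, arch.saccade_rate_hz, 40.0, 0.35),
            (fix_rows, arch.fixation_rate_hz, 250.0, 0.40),
            (blink_rows, arch.blink_rate_hz, 150.0, 0.30),
        ):
            count = rng.poisson(rate * span)
            onsets = np.sort(rng.uniform(level_start, t_clock, size=count))
            durs = dur_med * rng.lognormal(0.0, dur_sig, size=count)
            for onset, dur in zip(onsets, durs):
                store.append({"onset_s": onset, "duration_ms": dur})
    saccades = pd.DataFrame(sac_rows, columns=["onset_s", "duration_ms"])
    if len(saccades):
        saccades["amplitude_deg"] = 4.0 * rng.lognormal(0.0, 0.5, size=len(saccades))
        saccades["velocity_mean_deg_s"] = 150.0 * rng.lognormal(0.0, 0.3, size=len(saccades))
    else:
        saccades["amplitude_deg"] = pd.Series(dtype=float)
        saccades["velocity_mean_deg_s"] = pd.Series(dtype=float)
    fixations = pd.DataFrame(fix_rows, columns=["onset_s", "duration_ms"])
    blinks = pd.DataFrame(blink_rows, columns=["onset_s", "duration_ms"])
    trials = pd.DataFrame(rows)
    return trials, saccades, fixations, blinks


# ---------------------------------------------------------------------------
# whole-cohort assembly
# ---------------------------------------------------------------------------

ALL_CHANNELS = ("pupil", "eye", "ecg", "eda", "rsp", "questionnaire")


def _jitter(value: float, rel: float, rng: np.random.Generator) -> float:
    return value * (1.0 + rel * rng.normal()) if rel > 0 else value


def generate_cohort(schedule: TaskSchedule | None = None,
                    archetypes: tuple[ArchetypeSpec, ArchetypeSpec] | None = None,
                    n_per_archetype: tuple[int, int] = (33, 37),
                    noise: NoiseConfig | None = None,
                    seed: int = 0,
                    channels: tuple[str, ...] = ALL_CHANNELS,
                    ecg_fs: float = 250.0,
                    ecg_noise_sd: float = 0.02) -> CohortData:
    """Generate a deterministic cohort of labeled synthetic participants.

    Default counts (33, 37) mirror the study's reported two-cluster
    composition of its 70-participant cohort.  The ``channels`` tuple
    restricts which modalities are synthesized (continuous traces are the
    expensive ones); the trial/behavior table is always produced because it
    anchors every other channel in time.
    """
    schedule = schedule or build_schedule()
    archetypes = archetypes or default_archetypes()
    noise = noise if noise is not None else NoiseConfig()
    if any(n < 2 for n in n_per_archetype):
        raise ValueError("n_per_archetype counts must be >= 2 for downstream statistics")

    n_total = sum(n_per_archetype)
    streams = np.random.SeedSequence(seed).spawn(n_total)
    pids = [f"S{i + 1:03d}" for i in range(n_total)]
    labels = [0] * n_per_archetype[0] + [1] * n_per_archetype[1]

    trial_frames, truth_rows, quest_rows = [], [], []
    sac_frames, fix_frames, blink_frames = [], [], []
    ecg_store, eda_store, rsp_store = {}, {}, {}

    for pid, label, ss in zip(pids, labels, streams):
        rng = np.random.default_rng(ss)
        arch = archetypes[label]
        # participant-specific parameter jitter around the archetype
        j = noise.param_jitter_rel
        start = arch.pupil_start_offset + (abs(arch.pupil_start_offset) * j * rng.normal() if j else 0.0)
        slope = _jitter(arch.pupil_block_slope, j, rng)
        amp = _jitter(arch.deception_peak_amp, j, rng)
        indiv = ArchetypeSpec(
            label=arch.label,
            pupil_start_offset=start, pupil_block_slope=slope, deception_peak_amp=amp,
            mean_nn_ms=float(np.clip(_jitter(arch.mean_nn_ms, j / 2, rng), 301, 1499)),
            rmssd_target_ms=abs(_jitter(arch.rmssd_target_ms, j, rng)),
            lf_mod_amp=abs(_jitter(arch.lf_mod_amp, j, rng)),
            hf_mod_amp=abs(_jitter(arch.hf_mod_amp, j, rng)),
            saccade_rate_hz=abs(_jitter(arch.saccade_rate_hz, j, rng)),
            fixation_rate_hz=abs(_jitter(arch.fixation_rate_hz, j, rng)),
            blink_rate_hz=abs(_jitter(arch.blink_rate_hz, j, rng)),
            rt_mean_ms=abs(_jitter(arch.rt_mean_ms, j, rng)),
            error_prob_by_level=tuple(np.clip(arch.error_prob_by_level, 0, 1)),
            self_esteem_bias=arch.self_esteem_bias,
        )
        trials, sacc, fix, blink = eye_and_behavior(indiv, schedule, rng)
        trials.insert(0, "participant", pid)
        trials["pupil"] = pupil_trace(indiv, schedule, noise.pupil_noise_sd, rng)
        trials["deceptive"] = [
            (b, l) in schedule.deceptive_cells for b, l in zip(trials["block"], trials["level"])
        ]
        trial_frames.append(trials)
        if "eye" in channels:
            for df, frames in ((sacc, sac_frames), (fix, fix_frames), (blink, blink_frames)):
                df.insert(0, "participant", pid)
                frames.append(df)

        task_end = float(trials["t_end_s"].max()) + 5.0
        if "ecg" in channels:
            jitter_sd = (indiv.rmssd_target_ms / np.sqrt(2.0)) * noise.rr_jitter_scale
            rr = rr_series(indiv, max(task_end, 60.0), rng, jitter_sd_ms=jitter_sd)
            sig, r_idx = render_ecg(rr, fs=ecg_fs, baseline_noise_sd=ecg_noise_sd, rng=rng)
            ecg_store[pid] = {"fs": ecg_fs, "signal": sig.astype(np.float32),
                              "r_sample_idx": r_idx}
        if "eda" in channels:
            sig, events = eda_trace(task_end, ecg_fs, rng)
            eda_store[pid] = {"fs": ecg_fs, "signal": sig.astype(np.float32),
                              "event_times_s": events}
        if "rsp" in channels:
            rsp_store[pid] = {"fs": ecg_fs,
                              "signal": rsp_trace(task_end, ecg_fs, rng).astype(np.float32)}
        if "questionnaire" in channels:
            ess_mu, ess_sd = (9.78, 3.38) if label == 0 else (8.03, 3.81)
            quest_rows.append({
                "participant": pid,
                "ess": int(np.clip(np.round(rng.normal(ess_mu, ess_sd)), 0, 24)),
                "bdi": int(np.clip(np.round(rng.normal(8, 5)), 0, 63)),
                "stai_state": int(np.clip(np.round(rng.normal(38, 9)), 20, 80)),
                "stai_trait": int(np.clip(np.round(rng.normal(40, 9)), 20, 80)),
                "taylor": int(np.clip(np.round(rng.normal(15, 7)), 0, 50)),
                "bmi": float(np.round(rng.normal(23, 3), 1)),
                "smoker": bool(rng.random() < (0.45 if label == 0 else 0.20)),
            })
        truth_rows.append({"participant": pid, "archetype": label,
                           "mean_nn_ms": indiv.mean_nn_ms,
                           "rmssd_target_ms": indiv.rmssd_target_ms})

    empty_eye = pd.DataFrame(columns=["participant", "onset_s", "duration_ms"])
    return CohortData(
        schedule=schedule,
        seed=seed,
        trial_table=pd.concat(trial_frames, ignore_index=True),
        saccades=pd.concat(sac_frames, ignore_index=True) if sac_frames else empty_eye.copy(),
        fixations=pd.concat(fix_frames, ignore_index=True) if fix_frames else empty_eye.copy(),
        blinks=pd.concat(blink_frames, ignore_index=True) if blink_frames else empty_eye.copy(),
        questionnaires=pd.DataFrame(quest_rows),
        ecg=ecg_store, eda=eda_store, rsp=rsp_store,
        truth=pd.DataFrame(truth_rows),
    )
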
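"""Per-participant pupil trajectory vectors and their preprocessing.

Each participant is represented by one vector of per-trial mean pupil
sizes over the whole task (306 entries under the default lattice).  The
fixed preprocessing order is

    trial_means -> normalize -> smooth -> screen_outliers

Normalization is a per-participant z-score over the entire test period
(subtract the participant's mean pupil size, divide by their standard
deviation); smoothing is a moving average whose window equals the number
of trials per difficulty level, so level-scale structure survives while
trial-to-trial noise is averaged out.

The standard deviation uses the population (n) denominator, which makes
normalization idempotent; it is configurable via ``ddof``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

logger = logging.getLogger(__name__)

PIPELINE_ORDER = ("trial_means", "normalize", "smooth", "screen_outliers")


@dataclass(frozen=True)
class PupilTrajectory:
    """One participant's per-trial pupil vector with its processing state."""

    participant_id: str
    values: np.ndarray
    state: str = "raw"            # raw | normalized | smoothed

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.state not in ("raw", "normalized", "smoothed"):
            raise ValueError(f"unknown state {self.state!r}")

    def __len__(self) -> int:
        return len(self.values)


def trial_means(samples: dict[int, np.ndarray] | list[np.ndarray],
                participant_id: str = "",
                n_trials: int | None = None) -> PupilTrajectory:
    """Average raw pupil samples within each trial.

    ``samples`` maps trial index -> array of pupil samples (or is a list in
    trial order).  A trial with no valid samples becomes NaN and is logged;
    downstream interpolation or exclusion handles it.
    """
    if isinstance(samples, dict):
        if n_trials is None:
            n_trials = max(samples) + 1
        groups = [np.asarray(samples.get(t, []), dtype=float) for t in range(n_trials)]
    else:
        groups = [np.asarray(g, dtype=float) for g in samples]
    out = np.full(len(groups), np.nan)
    for t, g in enumerate(groups):
        g = g[np.isfinite(g)]
        if g.size:
            out[t] = g.mean()
        else:
            logger.warning("participant %s: trial %d has no valid pupil samples", participant_id, t)
    return PupilTrajectory(participant_id, out, state="raw")


def normalize(traj: PupilTrajectory, ddof: int = 0) -> PupilTrajectory:
    """Z-score the trajectory over the participant's entire test period.

    Missing (NaN) entries are ignored in the mean/SD and stay missing.
    """
    v = traj.values
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError(f"participant {traj.participant_id!r}: too few valid trials to normalize")
    mu = v[finite].mean()
    sd = v[finite].std(ddof=ddof)
    if sd == 0:
        raise ValueError(f"participant {traj.participant_id!r}: zero pupil variance, cannot normalize")
    return replace(traj, values=(v - mu) / sd, state="normalized")


def interpolate_missing(traj: PupilTrajectory, max_missing_frac: float = 0.05) -> PupilTrajectory:
    """Linearly interpolate NaN trials if the missing fraction is small.

    Raises if more than ``max_missing_frac`` of trials are missing — such a
    participant should be excluded (and the exclusion logged) rather than
    imputed.
    """
    v = traj.values
    miss = ~np.isfinite(v)
    if not miss.any():
        return traj
    frac = miss.mean()
    if frac > max_missing_frac:
        raise ValueError(
            f"participant {traj.participant_id!r}: {frac:.1%} trials missing "
            f"exceeds the {max_missing_frac:.0%} interpolation limit"
        )
    idx = np.arange(len(v))
    filled = v.copy()
    filled[miss] = np.interp(idx[miss], idx[~miss], v[~miss])
    logger.info("participant %s: interpolated %d missing trials", traj.participant_id, miss.sum())
    return replace(traj, values=filled)


def smooth(traj: PupilTrajectory, window: int = 17) -> PupilTrajectory:
    """Moving average with a uniform kernel of width ``window``.

    Output has the same length; near the edges the kernel shrinks to the
    available neighbors (a mean over the truncated window), so constant
    inputs are reproduced exactly everywhere.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = traj.values
    if window > len(v):
        raise ValueError(f"window {window} exceeds trajectory length {len(v)}")
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return replace(traj, values=num / den, state="smoothed")


def screen_outliers(trajs: list[PupilTrajectory], contamination: float = 0.05,
                    seed: int = 0) -> np.ndarray:
    """Isolation-forest screening of whole trajectory vectors.

    Returns a boolean mask, True = flagged as anomalous.  Exactly
    ``ceil(contamination * n)`` of the highest-anomaly trajectories are
    flagged; scoring is deterministic under ``seed``.  Flagging never drops
    participants by itself — exclusion is an explicit pipeline switch.
    """
    if len(trajs) < 10:
        raise ValueError("need at least 10 trajectories for outlier screening")
    if not 0.0 < contamination < 0.5:
        raise ValueError("contamination must be in (0, 0.5)")
    X = np.vstack([t.values for t in trajs])
    if not np.isfinite(X).all():
        raise ValueError("trajectories must be complete (interpolate or exclude first)")
    forest = IsolationForest(random_state=seed, contamination="auto")
    scores = -forest.fit(X).score_samples(X)      # higher = more anomalous
    n_flag = int(np.ceil(contamination * len(trajs)))
    order = np.argsort(scores)[::-1]
    mask = np.zeros(len(trajs), dtype=bool)
    mask[order[:n_flag]] = True
    flagged = [trajs[i].participant_id for i in np.nonzero(mask)[0]]
    logger.info("outlier screening flagged %d/%d trajectories: %s", n_flag, len(trajs), flagged)
    return mask


def trajectory_matrix(trial_table: pd.DataFrame, value_col: str = "pupil",
                      smooth_window: int | None = 17,
                      ddof: int = 0) -> tuple[np.ndarray, list[str]]:
    """Build the participants x trials matrix fed to clustering.

    Runs the fixed preprocessing order on each participant's per-trial
    means from a tidy trial table (columns participant, trial, value_col).
    ``smooth_window=None`` skips smoothing (clustering on unsmoothed
    z-vectors, kept as a toggle).
    """
    rows, pids = [], []
    for pid, sub in trial_table.groupby("participant", sort=True):
        v = sub.sort_values("trial")[value_col].to_numpy(dtype=float)
        traj = PupilTrajectory(str(pid), v, state="raw")
        traj = interpolate_missing(traj)
        traj = normalize(traj, ddof=ddof)
        if smooth_window is not None:
            traj = smooth(traj, window=smooth_window)
        rows.append(traj.values)
        pids.append(str(pid))
    return np.vstack(rows), pids
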
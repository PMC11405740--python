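"""Per-level aggregation of eye events and behavioral records.

Events (saccades, fixations, blinks) are assigned to a difficulty level by
their onset time against the participant's wall-clock level spans; events
falling outside every span are ignored with a logged count.  Behavioral
columns come straight off the trial table: mean reaction time, mistake
count, the level's single self-esteem rating and the summed response time.

The output is a long-format table keyed by (participant, block, level,
metric) so that the group-comparison stage can iterate uniformly over
every variable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EYE_METRICS = [
    "saccade_count", "saccade_velocity_mean_deg_s", "saccade_duration_sum_ms",
    "saccade_amplitude_mean_deg", "fixation_count", "fixation_duration_mean_ms",
    "blink_count", "blink_duration_mean_ms",
]
BEHAVIOR_METRICS = ["rt_mean_ms", "mistakes", "self_esteem", "total_time_ms"]


def _assign_windows(onsets: np.ndarray, spans: pd.DataFrame) -> np.ndarray:
    """Index of the (block, level) span containing each onset; -1 if none."""
    out = np.full(len(onsets), -1, dtype=int)
    for i, row in enumerate(spans.itertuples(index=False)):
        inside = (onsets >= row.t_start_s) & (onsets < row.t_end_s)
        out[inside] = i
    return out


def aggregate_eye(saccades: pd.DataFrame, fixations: pd.DataFrame,
                  blinks: pd.DataFrame, spans: pd.DataFrame) -> pd.DataFrame:
    """Long table of per-level eye metrics for one participant.

    ``spans`` must hold block, level, t_start_s, t_end_s.  Counts are 0 for
    empty windows; means over an empty window are NaN.
    """
    rows = []
    for name, table in (("saccade", saccades), ("fixation", fixations), ("blink", blinks)):
        onsets = table["onset_s"].to_numpy(dtype=float) if len(table) else np.empty(0)
        win = _assign_windows(onsets, spans)
        dropped = int((win < 0).sum())
        if dropped:
            logger.info("%d %s events outside all level windows ignored", dropped, name)
        for i, span in enumerate(spans.itertuples(index=False)):
            sub = table.iloc[np.flatnonzero(win == i)] if len(table) else table
            base = {"block": int(span.block), "level": int(span.level)}
            rows.append({**base, "metric": f"{name}_count", "value": float(len(sub))})
            mean_dur = float(sub["duration_ms"].mean()) if len(sub) else np.nan
            if name in ("fixation", "blink"):
                rows.append({**base, "metric": f"{name}_duration_mean_ms", "value": mean_dur})
            if name == "saccade":
                rows.append({**base, "metric": "saccade_duration_sum_ms",
                             "value": float(sub["duration_ms"].sum())})
                rows.append({**base, "metric": "saccade_amplitude_mean_deg",
                             "value": float(sub["amplitude_deg"].mean()) if len(sub) else np.nan})
                rows.append({**base, "metric": "saccade_velocity_mean_deg_s",
                             "value": float(sub["velocity_mean_deg_s"].mean()) if len(sub) else np.nan})
    return pd.DataFrame(rows)


def aggregate_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Long table of per-level behavioral metrics for one participant.

    Trials with a missing response are excluded from the RT mean and
    counted separately (metric ``missing_responses``); ``total_time_ms``
    is the participant's summed RT over the whole task, repeated on every
    level row so block/level reports can carry it uniformly.
    """
    rows = []
    valid_all = trials["rt_ms"].notna() & trials["response"].notna()
    total_time = float(trials.loc[valid_all, "rt_ms"].sum())
    for (block, level), sub in trials.groupby(["block", "level"], sort=True):
        base = {"block": int(block), "level": int(level)}
        valid = sub["rt_ms"].notna() & sub["response"].notna()
        n_missing = int((~valid).sum())
        rows.append({**base, "metric": "rt_mean_ms",
                     "value": float(sub.loc[valid, "rt_ms"].mean()) if valid.any() else np.nan})
        rows.append({**base, "metric": "mistakes",
                     "value": float((~sub.loc[valid, "correct"].astype(bool)).sum())})
        rows.append({**base, "metric": "self_esteem",
                     "value": float(sub["self_esteem"].iloc[0])})
        rows.append({**base, "metric": "total_time_ms", "value": total_time})
        if n_missing:
            rows.append({**base, "metric": "missing_responses", "value": float(n_missing)})
    return pd.DataFrame(rows)
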
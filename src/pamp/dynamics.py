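"""Migration measures derived from cell tracks.

From the time-ordered weighted-centre-of-gravity (WCG) path of a cell the
module computes:

* per-step speed  — |WCG(tₙ) − WCG(tₙ₋₁)| / (tₙ − tₙ₋₁)        [µm/h]
* path length     — Σ step lengths                              [µm]
* Euclidean distance — |WCG(tₙ) − WCG(t₀)|                      [µm]
* meandering index  — Euclidean distance / path length ∈ [0, 1]
  (1 for straight motion, 0 for a closed path; reported ×100 as %)
* period mean speed — mean step speed within an analysis window
* migration rose    — tracks translated to a common origin

No smoothing is applied to the WCG series: speeds are reported at the raw
sampling interval. Daughter tracks restart their own t₀ at the division
frame, so their meandering index is measured from birth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "step_speeds", "path_length", "euclidean_distance", "meandering_index",
    "period_mean_speed", "migration_rose", "track_summaries",
    "DEFAULT_PERIODS", "MIN_STEPS_PER_PERIOD",
]

#: analysis windows in hours: first and second half of a 20 h recording.
#: Half-open (a, b]: a step belongs to the window containing its end time,
#: so at 5-min sampling the windows cover 00:05–10:00 and 10:05–20:00.
DEFAULT_PERIODS: tuple[tuple[float, float], ...] = ((0.0, 10.0), (10.0, 20.0))

#: minimum steps a track needs inside a window to enter population stats (1 h)
MIN_STEPS_PER_PERIOD = 12


def _validate(times_h: np.ndarray, xy_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times_h = np.asarray(times_h, dtype=np.float64)
    xy_um = np.asarray(xy_um, dtype=np.float64)
    if times_h.ndim != 1 or xy_um.shape != (times_h.size, 2):
        raise ValueError("expected times (n,) and positions (n, 2)")
    if times_h.size < 2:
        raise ValueError("a track needs at least 2 points")
    dt = np.diff(times_h)
    if np.any(dt <= 0):
        raise ValueError("track times must be strictly increasing (no duplicates)")
    return times_h, xy_um


def step_speeds(times_h: np.ndarray, xy_um: np.ndarray) -> np.ndarray:
    """Per-interval speeds (µm/h), one value per consecutive point pair."""
    times_h, xy_um = _validate(times_h, xy_um)
    steps = np.hypot(*np.diff(xy_um, axis=0).T)
    return steps / np.diff(times_h)


def path_length(xy_um: np.ndarray) -> float:
    xy_um = np.asarray(xy_um, dtype=np.float64)
    return float(np.hypot(*np.diff(xy_um, axis=0).T).sum())


def euclidean_distance(xy_um: np.ndarray) -> float:
    xy_um = np.asarray(xy_um, dtype=np.float64)
    return float(np.hypot(*(xy_um[-1] - xy_um[0])))


def meandering_index(times_h: np.ndarray, xy_um: np.ndarray, up_to: float | None = None) -> float:
    """Net displacement over total path length on [t₀, up_to].

    Returns 0.0 for a zero-length path (stationary convention). Raises if
    ``up_to`` precedes the first time point.
    """
    times_h, xy_um = _validate(times_h, xy_um)
    if up_to is not None:
        if up_to < times_h[0]:
            raise ValueError("up_to precedes the start of the track")
        keep = times_h <= up_to
        if keep.sum() < 2:
            raise ValueError("fewer than 2 points up to the requested time")
        times_h, xy_um = times_h[keep], xy_um[keep]
    total = path_length(xy_um)
    if total == 0.0:
        return 0.0
    return euclidean_distance(xy_um) / total


def period_mean_speed(
    times_h: np.ndarray,
    xy_um: np.ndarray,
    period: tuple[float, float],
    min_steps: int = MIN_STEPS_PER_PERIOD,
) -> float:
    """Mean step speed of one track inside (t_a, t_b].

    A step belongs to the window containing its end time. Tracks with
    fewer than ``min_steps`` steps in the window return NaN and are
    excluded from population statistics.
    """
    times_h, xy_um = _validate(times_h, xy_um)
    t_a, t_b = period
    speeds = step_speeds(times_h, xy_um)
    ends = times_h[1:]
    sel = (ends > t_a) & (ends <= t_b)
    if sel.sum() < min_steps:
        return float("nan")
    return float(speeds[sel].mean())


def migration_rose(tracks: list[np.ndarray]) -> list[np.ndarray]:
    """Translate each track so its first point sits at the origin."""
    if len(tracks) == 0:
        raise ValueError("need at least one track")
    out = []
    for xy in tracks:
        xy = np.asarray(xy, dtype=np.float64)
        out.append(xy - xy[0])
    return out


def track_summaries(
    track_table: pd.DataFrame,
    frame_interval_min: float,
    periods: tuple[tuple[float, float], ...] = DEFAULT_PERIODS,
    min_steps: int = MIN_STEPS_PER_PERIOD,
) -> pd.DataFrame:
    """Per-track, per-period migration summary.

    ``track_table`` needs columns frame, track_id, x_um, y_um (linker
    output). Output columns: track_id, period, period_start_h,
    period_end_h, mean_speed_um_h, path_length_um, euclid_um,
    meandering_pct, n_steps. Population statistics are intended to be
    taken over the per-cell means of this table.
    """
    rows = []
    for tid, sub in track_table.groupby("track_id"):
        sub = sub.sort_values("frame")
        times = sub["frame"].to_numpy() * frame_interval_min / 60.0
        xy = sub[["x_um", "y_um"]].to_numpy()
        if len(times) < 2:
            continue
        speeds = step_speeds(times, xy)
        ends = times[1:]
        lengths = np.hypot(*np.diff(xy, axis=0).T)
        for k, (t_a, t_b) in enumerate(periods):
            sel = (ends > t_a) & (ends <= t_b)
            n = int(sel.sum())
            if n < min_steps:
                continue
            keep = (times >= t_a) & (times <= t_b)
            # include the step straddling the window start, if any
            xy_win = xy[np.flatnonzero(keep)]
            rows.append({
                "track_id": tid,
                "period": k,
                "period_start_h": t_a,
                "period_end_h": t_b,
                "mean_speed_um_h": float(speeds[sel].mean()),
                "path_length_um": float(lengths[sel].sum()),
                "euclid_um": float(np.hypot(*(xy_win[-1] - xy_win[0]))) if len(xy_win) >= 2 else np.nan,
                "meandering_pct": 100.0 * (np.hypot(*(xy_win[-1] - xy_win[0])) / lengths[sel].sum()
                                           if lengths[sel].sum() > 0 else 0.0) if len(xy_win) >= 2 else np.nan,
                "n_steps": n,
            })
    return pd.DataFrame(rows, columns=[
        "track_id", "period", "period_start_h", "period_end_h",
        "mean_speed_um_h", "path_length_um", "euclid_um", "meandering_pct", "n_steps"])
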
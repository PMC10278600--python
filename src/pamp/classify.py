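"""Phenotype classification and condition-level aggregation.

Three ingredients of the screening methodology live here:

1. circularity classes — cells are binned by circularity percentage into
   four morphology groups with biological annotations (very elongated
   cells are the probable invasive phenotype, rounded cells are dividing
   or dying);
2. the invasive-phenotype call — a cell is invasive at an evaluation
   time when its Euclidean displacement exceeds 100 µm AND its
   meandering index exceeds 25% (both strict), i.e. it travelled far and
   straight;
3. control quality control and per-period morphology summaries used to
   judge whether a candidate drug harms healthy cells.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .dynamics import DEFAULT_PERIODS, euclidean_distance, meandering_index, path_length

__all__ = [
    "CircularityClass", "classify_circularity", "InvasiveCall", "call_invasive",
    "invasive_fraction", "QCReport", "qc_control", "period_summaries",
    "INVASIVE_EUCLID_UM", "INVASIVE_MEANDERING_PCT",
]

#: invasive-phenotype thresholds (strict inequalities)
INVASIVE_EUCLID_UM = 100.0
INVASIVE_MEANDERING_PCT = 25.0


class CircularityClass(Enum):
    """Morphology bins by circularity percentage (upper bound exclusive,
    except Rounded which includes 100)."""

    VERY_ELONGATED = (0.0, 25.0, "Very elongated",
                      "Anomalous or migratory cell - probably invasive phenotype")
    ELONGATED = (25.0, 50.0, "Elongated", "Probably migratory")
    OVAL = (50.0, 75.0, "Oval", "Resting state")
    ROUNDED = (75.0, 100.0, "Rounded", "Dividing cell or cell undergoing cell death")

    def __init__(self, lo: float, hi: float, morphology: str, state: str):
        self.lo = lo
        self.hi = hi
        self.morphology = morphology
        self.state = state


def classify_circularity(value: float) -> CircularityClass:
    """Bin a circularity percentage; boundaries assign upward ([lo, hi))."""
    if not 0.0 < value <= 100.0:
        raise ValueError(f"circularity must lie in (0, 100], got {value}")
    for cls in CircularityClass:
        if cls.lo <= value < cls.hi:
            return cls
    return CircularityClass.ROUNDED  # value == 100


@dataclass(frozen=True)
class InvasiveCall:
    track_id: int
    eval_time_h: float
    euclid_um: float
    meandering_pct: float
    invasive: bool


def call_invasive(
    times_h: np.ndarray,
    xy_um: np.ndarray,
    eval_time_h: float,
    track_id: int = -1,
    euclid_threshold_um: float = INVASIVE_EUCLID_UM,
    meandering_threshold_pct: float = INVASIVE_MEANDERING_PCT,
) -> InvasiveCall:
    """Invasive-phenotype call for one track at an evaluation time.

    Displacement and meandering are measured from the track's own t₀ up
    to ``eval_time_h``; both thresholds are strict.
    """
    times_h = np.asarray(times_h, dtype=np.float64)
    xy_um = np.asarray(xy_um, dtype=np.float64)
    keep = times_h <= eval_time_h
    if keep.sum() < 2:
        raise ValueError("track has fewer than 2 points up to the evaluation time")
    sub = xy_um[keep]
    euclid = euclidean_distance(sub)
    mi = meandering_index(times_h[keep], sub)
    invasive = (euclid > euclid_threshold_um) and (100.0 * mi > meandering_threshold_pct)
    return InvasiveCall(track_id=track_id, eval_time_h=eval_time_h,
                        euclid_um=euclid, meandering_pct=100.0 * mi,
                        invasive=bool(invasive))


def invasive_fraction(
    track_table: pd.DataFrame,
    frame_interval_min: float,
    eval_time_h: float,
    euclid_threshold_um: float = INVASIVE_EUCLID_UM,
    meandering_threshold_pct: float = INVASIVE_MEANDERING_PCT,
) -> tuple[float, list[InvasiveCall]]:
    """Percentage of eligible tracks that are invasive at ``eval_time_h``.

    Eligible = tracks alive at the evaluation time (their observed span
    covers it, to within half a frame). Returns (percentage, calls);
    the percentage is NaN when no track is eligible.
    """
    tol = 0.5 * frame_interval_min / 60.0
    calls = []
    for tid, sub in track_table.groupby("track_id"):
        sub = sub.sort_values("frame")
        times = sub["frame"].to_numpy() * frame_interval_min / 60.0
        if (len(times) < 2 or times[-1] < eval_time_h - tol
                or (times <= eval_time_h + tol).sum() < 2):
            continue
        calls.append(call_invasive(
            times, sub[["x_um", "y_um"]].to_numpy(), eval_time_h + tol, track_id=tid,
            euclid_threshold_um=euclid_threshold_um,
            meandering_threshold_pct=meandering_threshold_pct))
    if not calls:
        return float("nan"), []
    frac = 100.0 * sum(c.invasive for c in calls) / len(calls)
    return frac, calls


@dataclass
class QCReport:
    """Advisory control-sample health report.

    A healthy control grows (cell count does not fall), keeps its mean
    mass and area roughly stable, and migrates at a roughly constant
    speed across the two analysis periods. Flags report violations; they
    never abort an analysis.
    """

    condition: str
    count_start: int
    count_end: int
    mass_change_pct: float
    area_change_pct: float
    speed_period1_um_h: float
    speed_period2_um_h: float
    speed_change_pct: float
    flag_count_decrease: bool
    flag_morphology_drift: bool
    flag_speed_drift: bool

    def to_dict(self) -> dict:
        return asdict(self)


def qc_control(
    features: pd.DataFrame,
    track_table: pd.DataFrame,
    frame_interval_min: float,
    condition: str = "control",
    periods: tuple[tuple[float, float], ...] = DEFAULT_PERIODS,
    tau_morph_pct: float = 30.0,
    tau_speed_pct: float = 50.0,
) -> QCReport:
    """Evaluate control-sample health from its feature and track tables."""
    from .dynamics import track_summaries

    frames = np.sort(features["frame"].unique())
    f0, f1 = frames[0], frames[-1]
    start = features[features.frame == f0]
    end = features[features.frame == f1]

    def rel_change(a: float, b: float) -> float:
        return 100.0 * (b - a) / a if a > 0 else float("nan")

    mass_change = rel_change(start["mass_pg"].mean(), end["mass_pg"].mean())
    area_change = rel_change(start["area_um2"].mean(), end["area_um2"].mean())

    summaries = track_summaries(track_table, frame_interval_min, periods=periods)
    sp = [summaries[summaries.period == k]["mean_speed_um_h"].mean() for k in (0, 1)]
    speed_change = rel_change(sp[0], sp[1]) if np.isfinite(sp[0]) else float("nan")

    return QCReport(
        condition=condition,
        count_start=int(len(start)),
        count_end=int(len(end)),
        mass_change_pct=float(mass_change),
        area_change_pct=float(area_change),
        speed_period1_um_h=float(sp[0]),
        speed_period2_um_h=float(sp[1]),
        speed_change_pct=float(speed_change),
        flag_count_decrease=bool(len(end) < len(start)),
        flag_morphology_drift=bool(
            (np.isfinite(mass_change) and abs(mass_change) > tau_morph_pct)
            or (np.isfinite(area_change) and abs(area_change) > tau_morph_pct)),
        flag_speed_drift=bool(np.isfinite(speed_change) and abs(speed_change) > tau_speed_pct),
    )


def period_summaries(
    features: pd.DataFrame,
    periods: tuple[tuple[float, float], ...] = DEFAULT_PERIODS,
    snapshot_times_h: tuple[float, ...] = (0.0, 10.0, 20.0),
    snapshot_tolerance_h: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-period pooled morphology and density snapshots.

    Returns ``(pooled, snapshots)``:

    * ``pooled`` — per-cell-per-frame circularity and density values
      pooled within each period (boxplot material); border-flagged cells
      are excluded since their area and perimeter are clipped.
    * ``snapshots`` — mean cell density at the frame nearest each
      snapshot time (within ±15 min, else NaN), plus the percent changes
      between consecutive snapshots and first→last.
    """
    feats = features[~features["border"].astype(bool)] if "border" in features else features
    pooled_parts = []
    for k, (t_a, t_b) in enumerate(periods):
        sel = feats.loc[(feats.time_h >= t_a) & (feats.time_h <= t_b),
                        ["track_id", "time_h", "circularity_pct", "density_pg_per_um2"]].copy()
        sel.insert(0, "period", k)
        pooled_parts.append(sel)
    pooled = pd.concat(pooled_parts, ignore_index=True) if pooled_parts else pd.DataFrame(
        columns=["period", "track_id", "time_h", "circularity_pct", "density_pg_per_um2"])

    times = np.sort(feats["time_h"].unique())
    snap_values = []
    for t in snapshot_times_h:
        if len(times) == 0:
            snap_values.append(float("nan"))
            continue
        nearest = times[np.argmin(np.abs(times - t))]
        if abs(nearest - t) > snapshot_tolerance_h:
            snap_values.append(float("nan"))
            continue
        snap_values.append(float(feats[feats.time_h == nearest]["density_pg_per_um2"].mean()))

    def pct(a: float, b: float) -> float:
        return 100.0 * (b - a) / a if np.isfinite(a) and a > 0 and np.isfinite(b) else float("nan")

    row = {f"density_{t:g}h": v for t, v in zip(snapshot_times_h, snap_values)}
    for (ta, va), (tb, vb) in zip(zip(snapshot_times_h, snap_values),
                                  list(zip(snapshot_times_h, snap_values))[1:]):
        row[f"change_{ta:g}_{tb:g}_pct"] = pct(va, vb)
    row[f"change_{snapshot_times_h[0]:g}_{snapshot_times_h[-1]:g}_pct"] = pct(
        snap_values[0], snap_values[-1])
    snapshots = pd.DataFrame([row])
    return pooled, snapshots
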
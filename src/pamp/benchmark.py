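"""Evaluation of the analysis chain against simulator ground truth.

These helpers quantify how well segmentation, tracking and dynamics
recover what the generator put into a synthetic movie: total dry mass,
population mean speed, and track identity. Identity is assessed on the
cells whose footprints never overlap another cell's during the whole
recording — for those, a correct tracker must produce exactly one
full-length track with a stable identity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .morphometrics import dry_mass_density

__all__ = ["clean_cell_ids", "identity_accuracy", "total_mass_error_pct",
           "speed_recovery_error_pct"]


def clean_cell_ids(gt) -> list[int]:
    """Cells whose 3σ footprint never overlaps another cell's footprint."""
    overlapping: set[int] = set()
    for _, sub in gt.frames.groupby("frame"):
        xy = sub[["x_um", "y_um"]].to_numpy()
        r = 3.0 * sub["sigma_major_um"].to_numpy()
        ids = sub["cell_id"].to_numpy()
        d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
        near = (d < r[:, None] + r[None, :]) & ~np.eye(len(ids), dtype=bool)
        overlapping.update(int(i) for i in ids[near.any(axis=1)])
    return sorted(set(int(i) for i in gt.frames.cell_id.unique()) - overlapping)


def identity_accuracy(gt, track_table: pd.DataFrame) -> tuple[float, int]:
    """Fraction (%) of never-overlapping cells tracked with a single,
    full-length, identity-stable track. Returns (accuracy_pct, n_clean)."""
    clean = clean_cell_ids(gt)
    if not clean:
        return float("nan"), 0
    gt_pos = {int(t): (sub[["x_um", "y_um"]].to_numpy(), sub["cell_id"].to_numpy())
              for t, sub in gt.frames.groupby("frame")}
    nearest = []
    for frame, x, y in zip(track_table["frame"], track_table["x_um"], track_table["y_um"]):
        xy, ids = gt_pos[int(frame)]
        nearest.append(int(ids[np.argmin(np.hypot(xy[:, 0] - x, xy[:, 1] - y))]))
    table = track_table.assign(gt_id=nearest)
    n_frames = gt.frames.frame.nunique()
    ok = 0
    for cid in clean:
        span = gt.frames[gt.frames.cell_id == cid].frame.nunique()
        sub = table[table.gt_id == cid]
        counts = sub.track_id.value_counts()
        if len(counts) == 1 and counts.iloc[0] == min(span, n_frames):
            ok += 1
    return 100.0 * ok / len(clean), len(clean)


def total_mass_error_pct(movie, labels: np.ndarray, gt) -> float:
    """|summed label mass − total generated mass| as % of the truth."""
    seg = 0.0
    for t in range(movie.n_frames):
        density = dry_mass_density(movie.frame(t), movie.wavelength_um,
                                   movie.alpha_um3_per_pg)
        n = labels[t].max()
        if n:
            seg += float(ndi.sum_labels(density, labels[t], np.arange(1, n + 1)).sum())
    seg *= movie.pixel_size_um ** 2
    truth = float(gt.frames.mass_pg.sum())
    return 100.0 * abs(seg - truth) / truth


def speed_recovery_error_pct(gt, summaries: pd.DataFrame) -> float:
    """|tracked population mean speed − true mean speed| as % of the truth.

    ``summaries`` is the per-track output of
    :func:`pamp.dynamics.track_summaries`; per-cell means are averaged on
    both sides.
    """
    recovered = float(summaries["mean_speed_um_h"].mean())
    truth = float(gt.cells["mean_speed_um_h"].mean())
    return 100.0 * abs(recovered - truth) / truth
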
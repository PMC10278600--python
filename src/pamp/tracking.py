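"""Frame-to-frame identity linking of segmented cells.

Detections (dry-mass-weighted centroids) are linked between consecutive
frames by optimal bipartite matching (Hungarian algorithm) on Euclidean
WCG distance, gated at ``max_link_distance_um`` per frame of separation.
A track missing from up to ``max_gap`` frames can be resumed. A division
is declared geometrically: an unmatched new detection whose nearest
previous-frame cell already has a successor closes the parent track and
starts two daughter tracks, with the lineage recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

from .morphometrics import dry_mass_density
from .segmentation import border_labels

__all__ = ["LabelMovie", "link_tracks"]

#: default linking gate, µm — ≈ 5 × (typical speed 35 µm/h × 5 min)
DEFAULT_MAX_LINK_DISTANCE_UM = 15.0


@dataclass
class LabelMovie:
    """Per-frame labels plus the frame-label → track-id mapping.

    ``table`` columns: frame, track_id, label, x_um, y_um, border.
    ``lineage`` maps a parent track id to its two daughter track ids.
    """

    labels: np.ndarray  # (T, H, W) int
    table: pd.DataFrame
    lineage: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_tracks(self) -> int:
        return self.table["track_id"].nunique()

    def track(self, track_id: int) -> pd.DataFrame:
        sub = self.table[self.table.track_id == track_id]
        return sub.sort_values("frame").reset_index(drop=True)


def _detections(labels: np.ndarray, density: np.ndarray, pixel_size_um: float) -> pd.DataFrame:
    """Mass-weighted centroids (falling back to geometric for zero mass)."""
    ids = np.arange(1, labels.max() + 1)
    if len(ids) == 0:
        return pd.DataFrame(columns=["label", "x_um", "y_um", "border"])
    present = np.isin(ids, labels)
    ids = ids[present]
    # negative densities (noise) are clipped for the weights only, so the
    # centroid cannot leave the cell footprint
    weights = np.clip(density, 0.0, None)
    centers = ndi.center_of_mass(weights, labels, ids)
    fallback = ndi.center_of_mass(np.ones_like(labels, dtype=np.float64), labels, ids)
    border = border_labels(labels)
    rows = []
    for lab, (cy, cx), (gy, gx) in zip(ids, centers, fallback):
        if not np.isfinite(cy) or not np.isfinite(cx):
            cy, cx = gy, gx
        rows.append({"label": int(lab), "x_um": cx * pixel_size_um,
                     "y_um": cy * pixel_size_um, "border": int(lab) in border})
    return pd.DataFrame(rows)


class _Track:
    __slots__ = ("tid", "last_frame", "x", "y", "closed")

    def __init__(self, tid, frame, x, y):
        self.tid = tid
        self.last_frame = frame
        self.x, self.y = x, y
        self.closed = False


def link_tracks(
    labels: np.ndarray,
    movie,
    max_link_distance_um: float = DEFAULT_MAX_LINK_DISTANCE_UM,
    max_gap: int = 2,
) -> LabelMovie:
    """Link per-frame labels into identity-stable tracks.

    ``labels`` is the (T, H, W) stack from :func:`pamp.segmentation.segment_movie`,
    ``movie`` the matching :class:`pamp.io.PhaseMovie`.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3 or labels.shape[0] != movie.n_frames:
        raise ValueError(
            f"label stack has {labels.shape[0] if labels.ndim == 3 else '?'} frames "
            f"but the movie has {movie.n_frames}")

    rows = []
    lineage: dict[int, tuple[int, int]] = {}
    active: list[_Track] = []
    next_tid = 0

    for t in range(movie.n_frames):
        density = dry_mass_density(movie.frame(t), movie.wavelength_um, movie.alpha_um3_per_pg)
        det = _detections(labels[t], density, movie.pixel_size_um)
        active = [tr for tr in active if not tr.closed and t - tr.last_frame <= max_gap + 1]

        assigned_det: dict[int, _Track] = {}
        if len(det) and active:
            txy = np.array([[tr.x, tr.y] for tr in active])
            dxy = det[["x_um", "y_um"]].to_numpy()
            dist = np.hypot(txy[:, None, 0] - dxy[None, :, 0],
                            txy[:, None, 1] - dxy[None, :, 1])
            gaps = np.array([t - tr.last_frame for tr in active], dtype=float)
            gate = max_link_distance_um * gaps[:, None]
            cost = np.where(dist <= gate, dist, 1e9)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] < 1e9:
                    assigned_det[j] = active[i]

        # division check: unmatched detection near an already-matched parent
        matched_tracks = set(id(tr) for tr in assigned_det.values())
        new_rows = []
        for j in range(len(det)):
            x, y, lab, brd = det.iloc[j][["x_um", "y_um", "label", "border"]]
            if j in assigned_det:
                tr = assigned_det[j]
                tr.x, tr.y, tr.last_frame = x, y, t
                new_rows.append((t, tr.tid, int(lab), x, y, bool(brd)))
                continue
            # candidate parents: matched at this frame, previously seen at t-1
            parent = None
            best = max_link_distance_um
            for tr in active:
                if id(tr) in matched_tracks and tr.last_frame == t:
                    d = np.hypot(tr.x - x, tr.y - y)
                    if d < best:
                        best, parent = d, tr
            if parent is not None and parent.tid not in lineage:
                # division: close the parent, re-home its successor as daughter 1
                d1 = _Track(next_tid, t, parent.x, parent.y)
                d2 = _Track(next_tid + 1, t, x, y)
                next_tid += 2
                lineage[parent.tid] = (d1.tid, d2.tid)
                for k, r in enumerate(new_rows):
                    if r[1] == parent.tid and r[0] == t:
                        new_rows[k] = (t, d1.tid, r[2], r[3], r[4], r[5])
                parent.closed = True
                new_rows.append((t, d2.tid, int(lab), x, y, bool(brd)))
                active.extend([d1, d2])
            else:
                tr = _Track(next_tid, t, x, y)
                next_tid += 1
                active.append(tr)
                new_rows.append((t, tr.tid, int(lab), x, y, bool(brd)))
        rows.extend(new_rows)

    table = pd.DataFrame(rows, columns=["frame", "track_id", "label", "x_um", "y_um", "border"])
    table = table.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return LabelMovie(labels=labels, table=table, lineage=lineage)
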
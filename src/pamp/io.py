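"""Calibrated phase-movie container and TIFF/CSV round-trip helpers.

A quantitative phase movie is a (T, H, W) stack of optical phase maps in
radians together with the acquisition calibration needed to turn phase into
dry mass: pixel size (µm), frame interval (min), illumination wavelength
(µm) and the specific refraction increment α (µm³/pg).

On disk a movie is a multi-page 32-bit float TIFF plus a JSON sidecar
(`<stem>.json`) holding the calibration, so the TIFF remains readable by
any viewer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: wavelength of the quasi-monochromatic LED illumination, µm
DEFAULT_WAVELENGTH_UM = 0.66
#: specific refraction increment α, µm³/pg
DEFAULT_ALPHA_UM3_PER_PG = 0.18


@dataclass
class PhaseMovie:
    """Time-lapse stack of quantitative phase maps (radians)."""

    data: np.ndarray  # (T, H, W) float
    pixel_size_um: float
    frame_interval_min: float
    wavelength_um: float = DEFAULT_WAVELENGTH_UM
    alpha_um3_per_pg: float = DEFAULT_ALPHA_UM3_PER_PG
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("phase movie must be a (T, H, W) array")
        for name in ("pixel_size_um", "frame_interval_min", "wavelength_um", "alpha_um3_per_pg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times_h(self) -> np.ndarray:
        """Acquisition time of each frame in hours (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval_min / 60.0

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_phase_movie(movie: PhaseMovie, path: str | Path) -> Path:
    """Write a multi-page float32 TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.data.astype(np.float32), photometric="minisblack")
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_min": movie.frame_interval_min,
        "wavelength_um": movie.wavelength_um,
        "alpha_um3_per_pg": movie.alpha_um3_per_pg,
    }
    meta.update(movie.meta)
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_phase_movie(path: str | Path) -> PhaseMovie:
    """Read a phase TIFF written by :func:`write_phase_movie`."""
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    known = {k: meta.pop(k) for k in (
        "pixel_size_um", "frame_interval_min", "wavelength_um", "alpha_um3_per_pg") if k in meta}
    return PhaseMovie(data=np.asarray(data, dtype=np.float64), meta=meta, **known)


def write_label_movie(labels: np.ndarray, path: str | Path) -> Path:
    """Write per-frame integer label images as a 16-bit multi-page TIFF."""
    labels = np.asarray(labels)
    if labels.max() >= 2 ** 16:
        raise ValueError("more than 65535 labels in a frame")
    path = Path(path)
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")
    return path


def read_label_movie(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.int32)
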
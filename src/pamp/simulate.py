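"""Synthetic quantitative-phase movies with known ground truth.

Emulates a 20 h time-lapse recording at 5-minute intervals (241 frames) of
adherent cells imaged by quantitative phase microscopy. Each cell is a
smooth anisotropic 2-D Gaussian dry-mass blob, truncated at 3σ and
normalised so that its truncated integral equals the cell's dry mass; the
blob's long axis follows the instantaneous velocity. Cell centres perform
a persistent random walk — an Ornstein–Uhlenbeck (OU) velocity process —
sampled exactly at frame times via the joint position/velocity transition
density, so motion statistics are free of integration error.

Speed calibration: ``speed_mean_um_h`` is defined as the expected
frame-to-frame step speed at the configured sampling interval. For an OU
velocity with per-axis stationary s.d. ``s`` and persistence time τ, the
displacement over Δt has per-axis variance 2 s² τ (Δt − τ(1 − e^{−Δt/τ})),
and the mean step length of the isotropic 2-D walk is √(π/2) times that
s.d.; ``s`` is chosen to invert this relation, so recovered mean step
speeds are unbiased by construction.

Divisions occur as a Poisson process per cell; a dividing cell rounds up
(axis ratio → 1) over the 3 frames before the split and is replaced by two
half-mass daughters.

The drug effect is modelled as a multiplicative speed factor plus a
circularity shift (percentage points, applied by adjusting the ellipse
axis ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import DEFAULT_ALPHA_UM3_PER_PG, DEFAULT_WAVELENGTH_UM, PhaseMovie

_TRUNC_SIGMA = 3.0  # blob truncation radius in units of σ
_TRUNC_MASS = 1.0 - np.exp(-_TRUNC_SIGMA ** 2 / 2.0)  # mass inside 3σ


@dataclass
class SimConfig:
    """Parameters of one synthetic acquisition.

    Defaults reproduce the study conditions: 20 h at 5-min intervals
    (241 frames), λ = 0.66 µm, α = 0.18 µm³/pg, 0.65 µm/pixel sampling
    with a 10×/0.3 objective-scale field.
    """

    n_cells: int = 20
    field_size: tuple[int, int] = (512, 512)  # (H, W) pixels
    pixel_size_um: float = 0.65
    frame_interval_min: float = 5.0
    n_frames: int = 241
    wavelength_um: float = DEFAULT_WAVELENGTH_UM
    alpha_um3_per_pg: float = DEFAULT_ALPHA_UM3_PER_PG
    cell_mass_mean_pg: float = 250.0
    cell_mass_sd_pg: float = 50.0
    cell_radius_mean_um: float = 15.0
    cell_radius_sd_um: float = 2.0
    speed_mean_um_h: float = 30.0
    persistence_time_min: float = 60.0
    elongation: float = 2.0  # axis ratio ≥ 1
    division_rate_per_h: float = 0.0  # events / cell / h
    mass_growth_rate_per_h: float = 0.0  # exponential dry-mass growth (0.035 ≈ one doubling / 20 h)
    drug_speed_factor: float = 1.0
    drug_circularity_shift: float = 0.0  # percentage points
    noise_sd_rad: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        positive = [
            "pixel_size_um", "frame_interval_min", "wavelength_um",
            "alpha_um3_per_pg", "cell_mass_mean_pg", "cell_radius_mean_um",
            "persistence_time_min", "drug_speed_factor",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("cell_mass_sd_pg", "cell_radius_sd_um", "speed_mean_um_h",
                     "division_rate_per_h", "noise_sd_rad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.elongation < 1:
            raise ValueError("elongation (axis ratio) must be >= 1")
        if not np.isfinite(self.mass_growth_rate_per_h):
            raise ValueError("mass_growth_rate_per_h must be finite")

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.field_size[0] * self.pixel_size_um,
                self.field_size[1] * self.pixel_size_um)

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min / 60.0


@dataclass
class GroundTruth:
    """Per-frame and per-cell truth of a simulated movie.

    ``frames``: frame, cell_id, x_um, y_um, mass_pg, sigma_major_um,
    sigma_minor_um, orientation_rad.
    ``cells``: cell_id, parent_id, first_frame, last_frame,
    mean_speed_um_h, meandering_index.
    """

    frames: pd.DataFrame
    cells: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)

    def path(self, cell_id: int) -> np.ndarray:
        sub = self.frames[self.frames.cell_id == cell_id].sort_values("frame")
        return sub[["x_um", "y_um"]].to_numpy()

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frames[["frame", "cell_id", "x_um", "y_um", "mass_pg"]].to_csv(path, index=False)
        return path


def _ellipse_circularity(axis_ratio: float) -> float:
    """Circularity (%) of a continuous ellipse with the given axis ratio."""
    a, b = np.sqrt(axis_ratio), 1.0 / np.sqrt(axis_ratio)
    area = np.pi * a * b
    h = ((a - b) / (a + b)) ** 2
    perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))  # Ramanujan
    return 100.0 * 4.0 * np.pi * area / perim ** 2


def _shifted_elongation(elongation: float, shift_pct: float) -> float:
    """Axis ratio whose ellipse circularity is shifted by ``shift_pct`` points."""
    if shift_pct == 0:
        return elongation
    target = float(np.clip(_ellipse_circularity(elongation) + shift_pct, 1.0, 100.0))
    if target >= 100.0:
        return 1.0
    return float(brentq(lambda e: _ellipse_circularity(e) - target, 1.0, 50.0))


def _ou_speed_scale(config: SimConfig) -> float:
    """Per-axis stationary velocity s.d. giving the configured mean step speed."""
    dt = config.frame_interval_min / 60.0  # h
    tau = config.persistence_time_min / 60.0
    target = config.speed_mean_um_h * config.drug_speed_factor
    if target == 0:
        return 0.0
    step_var_unit = 2.0 * tau * (dt - tau * (1.0 - np.exp(-dt / tau)))  # per unit s²
    return target * dt / (np.sqrt(np.pi / 2.0) * np.sqrt(step_var_unit))


def _ou_transition(dt: float, tau: float, s: float):
    """Exact OU (position, velocity) one-step transition.

    Returns the deterministic propagator and the Cholesky factor of the
    noise covariance for one axis (Gillespie's exact update).
    """
    e = np.exp(-dt / tau)
    var_v = s ** 2 * (1.0 - e ** 2)
    var_x = s ** 2 * tau ** 2 * (2.0 * dt / tau - 3.0 + 4.0 * e - e ** 2)
    cov_xv = s ** 2 * tau * (1.0 - e) ** 2
    cov = np.array([[var_x, cov_xv], [cov_xv, var_v]])
    # guard: zero-speed degenerate case
    if s == 0:
        chol = np.zeros((2, 2))
    else:
        chol = np.linalg.cholesky(cov + 1e-30 * np.eye(2))
    return e, tau * (1.0 - e), chol


class _Cell:
    __slots__ = ("cell_id", "parent", "mass", "radius", "x", "v",
                 "birth_frame", "division_frame", "positions", "frames")

    def __init__(self, cell_id, parent, mass, radius, x, v, birth_frame):
        self.cell_id = cell_id
        self.parent = parent
        self.mass = mass
        self.radius = radius
        self.x = np.asarray(x, dtype=np.float64)
        self.v = np.asarray(v, dtype=np.float64)
        self.birth_frame = birth_frame
        self.division_frame = None  # frame index at which the cell splits
        self.positions = []
        self.frames = []


def _reflect(x: np.ndarray, v: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Reflect position into [lo, hi] per axis, flipping velocity."""
    for ax in range(2):
        span = hi[ax] - lo[ax]
        if span <= 0:
            x[ax] = np.clip(x[ax], lo[ax], hi[ax])
            continue
        # fold into [lo, lo + 2 span) then mirror
        y = (x[ax] - lo[ax]) % (2 * span)
        if y > span:
            y = 2 * span - y
            v[ax] = -v[ax]
        x[ax] = lo[ax] + y
    return x, v


def simulate_movie(config: SimConfig) -> tuple[PhaseMovie, GroundTruth]:
    """Generate a phase movie and its ground truth.

    Deterministic for a fixed config (including seed). Raises if the
    expected total cell footprint exceeds 80% of the field (overcrowding).
    """
    return _simulate(config, render=True)


def simulate_tracks(config: SimConfig) -> GroundTruth:
    """Ground-truth kinematics only (no rasterisation, no phase stack).

    Uses the same random stream as :func:`simulate_movie`, so the
    trajectories are identical to the rendered movie's ground truth.
    """
    return _simulate(config, render=False)[1]


def _simulate(config: SimConfig, render: bool) -> tuple[PhaseMovie | None, GroundTruth]:
    config.validate()
    H, W = config.field_size
    field_h_um, field_w_um = config.field_um
    footprint = config.n_cells * np.pi * config.cell_radius_mean_um ** 2
    if footprint > 0.8 * field_h_um * field_w_um:
        raise ValueError(
            f"overcrowded field: expected cell footprint {footprint:.0f} µm² exceeds "
            f"80% of the {field_h_um * field_w_um:.0f} µm² field; enlarge the field "
            "or reduce n_cells")

    rng = np.random.default_rng(config.seed)
    dt_h = config.frame_interval_min / 60.0
    tau_h = config.persistence_time_min / 60.0
    s = _ou_speed_scale(config)
    e_prop, x_prop, chol = _ou_transition(dt_h, tau_h, s)
    elong = _shifted_elongation(config.elongation, config.drug_circularity_shift)

    def draw_radius():
        return float(np.clip(rng.normal(config.cell_radius_mean_um, config.cell_radius_sd_um),
                             0.3 * config.cell_radius_mean_um, 2.0 * config.cell_radius_mean_um))

    def draw_velocity():
        return rng.normal(0.0, s, size=2) if s > 0 else np.zeros(2)

    def schedule_division(frame):
        if config.division_rate_per_h <= 0:
            return None
        wait_h = rng.exponential(1.0 / config.division_rate_per_h)
        f = frame + int(np.ceil(wait_h / dt_h))
        return f if f < config.n_frames else None

    cells: list[_Cell] = []
    parent_of: dict[int, int] = {}
    for i in range(config.n_cells):
        mass = float(np.clip(rng.normal(config.cell_mass_mean_pg, config.cell_mass_sd_pg),
                             0.2 * config.cell_mass_mean_pg, None))
        radius = draw_radius()
        lo = np.array([radius, radius])
        hi = np.array([field_h_um - radius, field_w_um - radius])
        pos = rng.uniform(lo, hi)  # (y, x) in µm
        c = _Cell(i, -1, mass, radius, pos, draw_velocity(), 0)
        c.division_frame = schedule_division(0)
        parent_of[i] = -1
        cells.append(c)
    next_id = config.n_cells

    stack = np.zeros((config.n_frames, H, W), dtype=np.float32) if render else None
    gt_rows = []
    phase_per_density = 2.0 * np.pi * config.alpha_um3_per_pg / config.wavelength_um

    def rasterize(frame_ix, c: _Cell, axis_ratio, orientation):
        sigma = c.radius / _TRUNC_SIGMA
        sa, sb = sigma * np.sqrt(axis_ratio), sigma / np.sqrt(axis_ratio)
        amp = c.mass / (2.0 * np.pi * sa * sb * _TRUNC_MASS)  # peak density pg/µm²
        cy, cx = c.x  # µm
        extent = _TRUNC_SIGMA * sa
        px = config.pixel_size_um
        r0 = max(int(np.floor((cy - extent) / px)), 0)
        r1 = min(int(np.ceil((cy + extent) / px)) + 1, H)
        c0 = max(int(np.floor((cx - extent) / px)), 0)
        c1 = min(int(np.ceil((cx + extent) / px)) + 1, W)
        if r1 <= r0 or c1 <= c0:
            return
        dy = (np.arange(r0, r1) * px - cy)[:, None]
        dx = (np.arange(c0, c1) * px - cx)[None, :]
        ca, sa_ = np.cos(orientation), np.sin(orientation)
        u = dx * ca + dy * sa_
        w = -dx * sa_ + dy * ca
        rho2 = (u / sa) ** 2 + (w / sb) ** 2
        dens = np.where(rho2 <= _TRUNC_SIGMA ** 2, amp * np.exp(-rho2 / 2.0), 0.0)
        stack[frame_ix, r0:r1, c0:c1] += (dens * phase_per_density).astype(np.float32)

    for t in range(config.n_frames):
        newborn: list[_Cell] = []
        dead: list[_Cell] = []
        for c in cells:
            # rounding before division: axis ratio → 1 over 3 frames
            ar = elong
            if c.division_frame is not None:
                left = c.division_frame - t
                if 0 <= left <= 3:
                    ar = 1.0 + (elong - 1.0) * left / 4.0
            speed = np.hypot(*c.v)
            orientation = np.arctan2(c.v[0], c.v[1]) if speed > 1e-12 else 0.0
            if render:
                rasterize(t, c, ar, orientation)
            sigma = c.radius / _TRUNC_SIGMA
            gt_rows.append((t, c.cell_id, c.x[1], c.x[0], c.mass,
                            sigma * np.sqrt(ar), sigma / np.sqrt(ar), orientation))
            c.positions.append(c.x.copy())
            c.frames.append(t)

            if c.division_frame == t:
                # split into two half-mass daughters offset along the minor axis
                offset_dir = rng.normal(size=2)
                offset_dir /= np.hypot(*offset_dir)
                d_radius = c.radius / np.sqrt(2.0)
                lo = np.array([d_radius, d_radius])
                hi = np.array([field_h_um - d_radius, field_w_um - d_radius])
                for sign in (+1.0, -1.0):
                    pos = c.x + sign * offset_dir * 0.6 * c.radius
                    pos, _ = _reflect(pos.copy(), np.zeros(2), lo, hi)
                    d = _Cell(next_id, c.cell_id, c.mass / 2.0, d_radius,
                              pos, draw_velocity(), t + 1)
                    d.division_frame = schedule_division(t + 1)
                    parent_of[next_id] = c.cell_id
                    newborn.append(d)
                    next_id += 1
                dead.append(c)
                continue

            if t < config.n_frames - 1:
                c.mass *= np.exp(config.mass_growth_rate_per_h * dt_h)
                # exact OU step per axis
                for ax in range(2):
                    noise = chol @ rng.standard_normal(2)
                    c.x[ax] += x_prop * c.v[ax] + noise[0]
                    c.v[ax] = e_prop * c.v[ax] + noise[1]
                lo = np.array([c.radius, c.radius])
                hi = np.array([field_h_um - c.radius, field_w_um - c.radius])
                c.x, c.v = _reflect(c.x, c.v, lo, hi)
        for c in dead:
            cells.remove(c)
        cells.extend(newborn)

    if render and config.noise_sd_rad > 0:
        for t in range(config.n_frames):  # per-frame to bound memory
            stack[t] += rng.normal(0.0, config.noise_sd_rad, size=(H, W)).astype(np.float32)

    frames_df = pd.DataFrame(gt_rows, columns=[
        "frame", "cell_id", "x_um", "y_um", "mass_pg",
        "sigma_major_um", "sigma_minor_um", "orientation_rad"])
    cell_rows = []
    for cid, sub in frames_df.groupby("cell_id"):
        sub = sub.sort_values("frame")
        xy = sub[["x_um", "y_um"]].to_numpy()
        steps = np.hypot(*np.diff(xy, axis=0).T)
        path = steps.sum()
        euclid = float(np.hypot(*(xy[-1] - xy[0])))
        mi = euclid / path if path > 0 else 0.0
        mean_speed = steps.mean() / dt_h if len(steps) else 0.0
        cell_rows.append((cid, int(sub.frame.iloc[0]), int(sub.frame.iloc[-1]),
                          mean_speed, mi))
    cells_df = pd.DataFrame(cell_rows, columns=[
        "cell_id", "first_frame", "last_frame", "mean_speed_um_h", "meandering_index"])
    cells_df["parent_id"] = cells_df["cell_id"].map(parent_of).fillna(-1).astype(int)
    gt = GroundTruth(frames=frames_df, cells=cells_df, config=config)
    if not render:
        return None, gt
    movie = PhaseMovie(
        data=stack, pixel_size_um=config.pixel_size_um,
        frame_interval_min=config.frame_interval_min,
        wavelength_um=config.wavelength_um, alpha_um3_per_pg=config.alpha_um3_per_pg,
        meta={"seed": config.seed, "synthetic": True},
    )
    return movie, gt


def simulate_hologram(
    phase: np.ndarray,
    carrier_frequency: float | tuple[float, float],
    fringe_contrast: float = 0.8,
) -> np.ndarray:
    """Off-axis hologram forward model.

    Returns the non-negative interference intensity
    ``I(x, y) = 1 + contrast · cos(2π f·x + φ(x, y))`` for a tilted
    reference beam with carrier frequency ``f`` (cycles/pixel, scalar →
    fringes along x). The carrier must lie below Nyquist (0.5) and be
    large enough for the ±1 sidebands to separate from the DC term.
    """
    phase = np.asarray(phase, dtype=np.float64)
    if phase.ndim != 2:
        raise ValueError("phase must be a 2-D map")
    if np.isscalar(carrier_frequency):
        f = np.array([0.0, float(carrier_frequency)])
    else:
        f = np.asarray(carrier_frequency, dtype=np.float64)
    fmag = float(np.hypot(*f))
    if not fmag < 0.5:
        raise ValueError("carrier frequency must be below Nyquist (0.5 cycles/pixel)")
    min_carrier = 8.0 / min(phase.shape)
    if fmag < min_carrier:
        raise ValueError(
            f"carrier frequency {fmag:.4f} cycles/pixel too low to separate the "
            f"sidebands from the DC term (need >= {min_carrier:.4f})")
    if not 0.0 <= fringe_contrast <= 1.0:
        raise ValueError("fringe contrast must be within [0, 1]")
    yy, xx = np.mgrid[: phase.shape[0], : phase.shape[1]]
    psi = 2.0 * np.pi * (f[0] * yy + f[1] * xx) + phase
    return 1.0 + fringe_contrast * np.cos(psi)


def control_and_treated(base: SimConfig, drug_speed_factor: float,
                        drug_circularity_shift: float = 0.0,
                        seed_offset: int = 1) -> SimConfig:
    """Derive a treated-condition config from a control config."""
    return replace(base, drug_speed_factor=drug_speed_factor,
                   drug_circularity_shift=drug_circularity_shift,
                   seed=base.seed + seed_offset)
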
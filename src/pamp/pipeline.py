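"""End-to-end study orchestration.

A study config (YAML or dict) names one control and any number of
treated movies per batch; each movie is either a phase TIFF on disk, a
hologram TIFF to reconstruct first, or an inline simulation block. The
pipeline runs segment → track → features → dynamics → classify → stats
for every movie and compares each treated condition against the control
of its own batch (never across batches, since controls are only valid
for the acquisition they belong to).

Outputs: per-condition feature and track-summary CSVs, a speed-comparison
table (condition × period with means, medians, percent change, gated
t-test p and stars), an invasive-fraction table (condition × evaluation
time), per-condition density snapshot tables, a QC JSON for each control,
and optional figures (circularity/density boxplots, migration rose,
displacement-vs-meandering quadrant plot). Runs are reproducible: the
same config and seed yield byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (INVASIVE_EUCLID_UM, INVASIVE_MEANDERING_PCT,
                       invasive_fraction, period_summaries, qc_control)
from .dynamics import DEFAULT_PERIODS, MIN_STEPS_PER_PERIOD, track_summaries
from .holography import reconstruct_phase
from .io import PhaseMovie, read_phase_movie
from .morphometrics import build_feature_table
from .segmentation import segment_movie
from .simulate import SimConfig, simulate_movie
from .stats import compare_speed_samples
from .tracking import DEFAULT_MAX_LINK_DISTANCE_UM, link_tracks

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "analyze_movie", "MovieAnalysis"]


@dataclasses.dataclass
class MovieAnalysis:
    """All per-movie products of the analysis chain."""

    name: str
    condition: str
    batch: str
    is_control: bool
    features: pd.DataFrame
    track_table: pd.DataFrame
    summaries: pd.DataFrame
    pooled: pd.DataFrame
    snapshots: pd.DataFrame
    invasive: dict[float, float]
    ground_truth: object | None = None


def _load_movie(entry: dict, defaults: dict, seed_shift: int):
    """Materialise one movie from a config entry (file, hologram or sim)."""
    gt = None
    if "simulate" in entry:
        sim_kwargs = dict(entry["simulate"])
        if "seed" not in sim_kwargs:
            sim_kwargs["seed"] = int(defaults.get("seed", 0)) + seed_shift
        if "field_size" in sim_kwargs:
            sim_kwargs["field_size"] = tuple(sim_kwargs["field_size"])
        movie, gt = simulate_movie(SimConfig(**sim_kwargs))
    elif "path" in entry:
        movie = read_phase_movie(entry["path"])
        if entry.get("from_hologram"):
            carrier = entry.get("carrier_frequency")
            frames = [reconstruct_phase(movie.frame(t), carrier)
                      for t in range(movie.n_frames)]
            movie = PhaseMovie(
                data=np.stack(frames), pixel_size_um=movie.pixel_size_um,
                frame_interval_min=movie.frame_interval_min,
                wavelength_um=movie.wavelength_um,
                alpha_um3_per_pg=movie.alpha_um3_per_pg, meta=movie.meta)
    else:
        raise ValueError(f"movie entry {entry.get('name')!r} needs 'path' or 'simulate'")
    return movie, gt


def analyze_movie(
    movie: PhaseMovie,
    name: str = "movie",
    condition: str = "condition",
    batch: str = "1",
    is_control: bool = False,
    min_area_um2: float = 50.0,
    max_link_distance_um: float = DEFAULT_MAX_LINK_DISTANCE_UM,
    max_gap: int = 2,
    periods=DEFAULT_PERIODS,
    min_steps: int = MIN_STEPS_PER_PERIOD,
    eval_times_h: tuple[float, ...] = (10.0, 20.0),
    ground_truth=None,
) -> MovieAnalysis:
    """Run segment → track → features → dynamics → classify on one movie."""
    labels = segment_movie(movie, min_area_um2=min_area_um2)
    linked = link_tracks(labels, movie, max_link_distance_um=max_link_distance_um,
                         max_gap=max_gap)
    features = build_feature_table(movie, labels, linked.table)
    summaries = track_summaries(linked.table, movie.frame_interval_min,
                                periods=periods, min_steps=min_steps)
    pooled, snapshots = period_summaries(features, periods=periods)
    invasive = {}
    for t_eval in eval_times_h:
        frac, _ = invasive_fraction(linked.table, movie.frame_interval_min, t_eval)
        invasive[t_eval] = frac
    return MovieAnalysis(
        name=name, condition=condition, batch=str(batch), is_control=is_control,
        features=features, track_table=linked.table, summaries=summaries,
        pooled=pooled, snapshots=snapshots, invasive=invasive,
        ground_truth=ground_truth)


def _speed_samples(analysis: MovieAnalysis, period: int) -> np.ndarray:
    sub = analysis.summaries[analysis.summaries.period == period]
    return sub["mean_speed_um_h"].to_numpy()


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute a full study from a config mapping or YAML path.

    Returns a result bundle with per-movie analyses, the comparison and
    invasive tables, QC reports and (if ``out_dir`` or the config's
    ``out_dir`` is set) writes CSV/JSON/figure outputs.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    movies_cfg = config.get("movies", [])
    if not movies_cfg:
        raise ValueError("config lists no movies")
    analysis_cfg = config.get("analysis", {})
    periods = tuple(tuple(p) for p in analysis_cfg.get("periods", DEFAULT_PERIODS))
    eval_times = tuple(analysis_cfg.get("eval_times_h", (10.0, 20.0)))

    batches: dict[str, list[dict]] = {}
    for entry in movies_cfg:
        batches.setdefault(str(entry.get("batch", "1")), []).append(entry)
    for batch, entries in batches.items():
        n_ctrl = sum(bool(e.get("is_control")) for e in entries)
        if n_ctrl != 1:
            raise ValueError(
                f"batch {batch!r} has {n_ctrl} control movies; treated conditions are "
                "compared only against the single control acquired in the same batch")

    analyses: list[MovieAnalysis] = []
    for i, entry in enumerate(movies_cfg):
        movie, gt = _load_movie(entry, config, seed_shift=i)
        analyses.append(analyze_movie(
            movie,
            name=entry.get("name", f"movie{i}"),
            condition=entry.get("condition", entry.get("name", f"cond{i}")),
            batch=str(entry.get("batch", "1")),
            is_control=bool(entry.get("is_control")),
            min_area_um2=analysis_cfg.get("min_area_um2", 50.0),
            max_link_distance_um=analysis_cfg.get(
                "max_link_distance_um", DEFAULT_MAX_LINK_DISTANCE_UM),
            max_gap=analysis_cfg.get("max_gap", 2),
            periods=periods,
            min_steps=analysis_cfg.get("min_steps_per_period", MIN_STEPS_PER_PERIOD),
            eval_times_h=eval_times,
            ground_truth=gt,
        ))
        del movie  # free the stack before the next acquisition

    comparisons = []
    for batch, entries in batches.items():
        control = next(a for a in analyses if a.batch == batch and a.is_control)
        for a in analyses:
            if a.batch != batch or a.is_control:
                continue
            for k in range(len(periods)):
                treated = _speed_samples(a, k)
                ctrl = _speed_samples(control, k)
                if len(treated) < 2 or len(ctrl) < 2:
                    logger.warning("period %d of %s: too few tracks for inference", k, a.name)
                    continue
                comparisons.append(dataclasses.asdict(compare_speed_samples(
                    treated, ctrl, condition=a.condition,
                    control_name=control.condition, period=k,
                    period_bounds=periods[k])))
    comparison_table = pd.DataFrame(comparisons)

    invasive_rows = []
    for a in analyses:
        row = {"condition": a.condition, "batch": a.batch, "is_control": a.is_control}
        for t_eval, frac in a.invasive.items():
            row[f"invasive_pct_{t_eval:g}h"] = frac
        invasive_rows.append(row)
    invasive_table = pd.DataFrame(invasive_rows)

    density_rows = []
    for a in analyses:
        row = {"condition": a.condition, "batch": a.batch}
        row.update(a.snapshots.iloc[0].to_dict())
        density_rows.append(row)
    density_table = pd.DataFrame(density_rows)

    qc_reports = {}
    for a in analyses:
        if a.is_control and len(a.features):
            qc_reports[a.condition] = qc_control(
                a.features, a.track_table,
                frame_interval_min=_frame_interval(a), condition=a.condition,
                periods=periods).to_dict()

    result = {
        "analyses": analyses,
        "comparisons": comparison_table,
        "invasive": invasive_table,
        "density": density_table,
        "qc": qc_reports,
        "meta": {
            "pamp_version": __version__,
            "periods": [list(p) for p in periods],
            "eval_times_h": list(eval_times),
            "speed_statistic": "per-cell mean of raw step speeds",
            "invasive_thresholds": {
                "euclid_um": INVASIVE_EUCLID_UM,
                "meandering_pct": INVASIVE_MEANDERING_PCT,
            },
        },
    }

    out = out_dir or config.get("out_dir")
    if out:
        _write_outputs(result, Path(out), make_figures=config.get("figures", True))
    return result


def _frame_interval(analysis: MovieAnalysis) -> float:
    t = analysis.features["time_h"].to_numpy()
    f = analysis.features["frame"].to_numpy()
    nz = f > 0
    return float(60.0 * (t[nz] / f[nz]).mean()) if nz.any() else 5.0


def _write_outputs(result: dict, out_dir: Path, make_figures: bool = True) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for a in result["analyses"]:
        a.features.to_csv(out_dir / f"features_{a.name}.csv", index=False)
        a.summaries.to_csv(out_dir / f"track_summary_{a.name}.csv", index=False)
    result["comparisons"].to_csv(out_dir / "speed_comparisons.csv", index=False)
    result["invasive"].to_csv(out_dir / "invasive_fractions.csv", index=False)
    result["density"].to_csv(out_dir / "density_snapshots.csv", index=False)
    (out_dir / "qc_report.json").write_text(
        json.dumps(result["qc"], indent=2, sort_keys=True))
    (out_dir / "run_meta.json").write_text(
        json.dumps(result["meta"], indent=2, sort_keys=True))
    if make_figures:
        _write_figures(result, out_dir)


def _write_figures(result: dict, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    analyses = result["analyses"]
    # circularity and density boxplots per period
    for quantity in ("circularity_pct", "density_pg_per_um2"):
        fig, axes = plt.subplots(1, 2, figsize=(1.5 + 1.2 * len(analyses) * 2, 4),
                                 sharey=True)
        for k, ax in enumerate(axes):
            data = [a.pooled.loc[a.pooled.period == k, quantity].dropna() for a in analyses]
            ax.boxplot(data, tick_labels=[a.condition for a in analyses],
                       showmeans=True)
            ax.set_title(f"period {k + 1}")
            ax.tick_params(axis="x", rotation=45)
        axes[0].set_ylabel(quantity)
        fig.tight_layout()
        fig.savefig(out_dir / f"boxplot_{quantity}.png", dpi=120)
        plt.close(fig)
    # migration rose per condition
    fig, axes = plt.subplots(1, len(analyses), figsize=(4 * len(analyses), 4),
                             squeeze=False)
    for ax, a in zip(axes[0], analyses):
        for _, sub in a.track_table.groupby("track_id"):
            xy = sub.sort_values("frame")[["x_um", "y_um"]].to_numpy()
            xy = xy - xy[0]
            ax.plot(xy[:, 0], xy[:, 1], lw=0.6)
        ax.set_title(a.condition)
        ax.set_xlabel("x [µm]")
        ax.set_aspect("equal")
    axes[0][0].set_ylabel("y [µm]")
    fig.tight_layout()
    fig.savefig(out_dir / "migration_rose.png", dpi=120)
    plt.close(fig)
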
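"""End-to-end orchestration of the synthetic degradation study.

``run_all`` chains the full pipeline on synthetic inputs: render one image
series per blend and replicate, pick (or accept) a threshold, binarize,
compute remaining-% kinetics, fit and extract t50 per replicate, then
compare blends by ANOVA + Tukey with a compact letter display.  Every
stage's artifact is written as CSV/JSON under the output directory, and
the resolved configuration (with all derived seeds) is recorded alongside.

Samples are processed sequentially and independently: per-series seeds are
spawned from the master seed up front, so results do not depend on
processing order, and one failing sample is logged and skipped rather than
aborting the batch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .images import ThresholdRange, binarize_series, degradation_curve, suggest_threshold
from .io import (
    write_group_comparison,
    write_image_series,
    write_kinetics,
    write_t50_table,
    write_threshold_json,
)
from .kinetics import NoSignificantModel, T50Fit, fit_t50
from .stats import GroupComparison, compare_groups
from .synthetic import (
    SceneParams,
    SimulatedImageSeries,
    logistic_trajectory,
    simulate_image_series,
)

__all__ = ["StudyResult", "simulate_study", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Everything ``run_all`` computed, in memory."""

    fits: list[tuple[str, str, int, T50Fit]]  # (sample_id, blend, replicate, fit)
    comparison: GroupComparison | None
    t50_by_blend: dict[str, np.ndarray]
    outdir: Path | None


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent per-sample seeds spawned from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1)) for child in ss.spawn(n)]


def _scene_params(config: RunConfig, seed: int) -> SceneParams:
    kwargs: dict = {"seed": seed}
    if config.image_size is not None:
        kwargs["image_size"] = tuple(config.image_size)
    if config.grain_radius_range is not None:
        kwargs["grain_radius_range"] = tuple(config.grain_radius_range)
    for name in ("n_grains", "noise_sd", "illumination_gradient", "mycelium_growth_rate"):
        value = getattr(config, name)
        if value is not None:
            kwargs[name] = value
    return SceneParams(**kwargs)


def simulate_study(
    config: RunConfig, write_frames: bool = False
) -> list[tuple[str, str, int, SimulatedImageSeries]]:
    """Render one image series per (blend, replicate).

    Replicate trajectories jitter the blend's true t50 with a lognormal
    factor of coefficient of variation ``replicate_t50_cv``, emulating
    biological replicate-to-replicate variability; scene randomness (grain
    placement, mycelium paths, noise) is independent per series.
    """
    times = np.linspace(0.0, config.t_max_h, config.n_timepoints)
    n_series = len(config.blends) * config.n_replicates
    seeds = _child_seeds(config.seed, 2 * n_series)
    sims = []
    i = 0
    for blend, t50_true in config.blends.items():
        for rep in range(config.n_replicates):
            rng = np.random.default_rng(seeds[2 * i])
            t50_rep = float(t50_true * rng.lognormal(0.0, config.replicate_t50_cv))
            traj = logistic_trajectory(times, t50=t50_rep)
            sim = simulate_image_series(_scene_params(config, seeds[2 * i + 1]), traj)
            sim.series.sample_id = f"{blend}_r{rep}"
            sim.series.blend_label = blend
            sims.append((f"{blend}_r{rep}", blend, rep, sim))
            i += 1
    if write_frames and config.outdir:
        outdir = Path(config.outdir)
        rows = []
        for sample_id, _blend, _rep, sim in sims:
            df = write_image_series(sim.series, outdir / "frames")
            df["file"] = "frames/" + df["file"]  # manifest lives one level up
            p = sim.params
            df["well_center_y"], df["well_center_x"] = p.well_center
            df["well_radius"] = p.well_radius
            rows.append(df)
            sim.truth_table.assign(sample_id=sample_id).to_csv(
                outdir / "frames" / f"{sample_id}_truth.csv", index=False
            )
        pd.concat(rows).to_csv(outdir / "manifest.csv", index=False)
    return sims


def run_all(config: RunConfig, write_outputs: bool = True) -> StudyResult:
    """Simulate, binarize, fit t50 per replicate, and compare blends."""
    sims = simulate_study(config)
    outdir = Path(config.outdir) if write_outputs else None
    fits: list[tuple[str, str, int, T50Fit]] = []
    kin_entries = []
    thresholds: dict[str, list[float]] = {}
    for sample_id, blend, rep, sim in sims:
        try:
            if config.threshold == "auto":
                thr = suggest_threshold(sim.series)
            else:
                thr = ThresholdRange(*config.threshold)
            binary = binarize_series(sim.series, thr)
            curve = degradation_curve(binary)
            curve.replicate = rep
            kin_entries.append((binary, curve))
            thresholds[sample_id] = [thr.low, thr.high]
            fit = fit_t50(
                curve, max_degree=config.max_degree, alpha=config.alpha, level=config.level
            )
            fits.append((sample_id, blend, rep, fit))
        except (ValueError, NoSignificantModel) as exc:
            logger.error("sample %s failed: %s", sample_id, exc)

    t50_by_blend: dict[str, np.ndarray] = {}
    for _sid, blend, _rep, fit in fits:
        t50_by_blend.setdefault(blend, [])
        t50_by_blend[blend].append(np.nan if fit.t50 is None else fit.t50)
    t50_by_blend = {b: np.asarray(v) for b, v in t50_by_blend.items()}

    comparison = None
    usable = {b: v[np.isfinite(v)] for b, v in t50_by_blend.items()}
    usable = {b: v for b, v in usable.items() if v.size >= 2}
    if len(usable) >= 2:
        comparison = compare_groups(
            {b: t50_by_blend[b] for b in usable}, alpha=config.alpha
        )
    else:
        logger.warning("fewer than 2 blends with >= 2 uncensored t50: skipping comparison")

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        write_kinetics(kin_entries, outdir / "kinetics.csv")
        write_t50_table(fits, outdir / "t50.csv")
        if comparison is not None:
            write_group_comparison(comparison, outdir)
        for (sample_id, _b, _r, fit), _ in zip(fits, range(len(fits))):
            (outdir / "fits").mkdir(exist_ok=True)
            (outdir / "fits" / f"{sample_id}_fit.json").write_text(
                json.dumps(fit.to_dict(), indent=2)
            )
        run_record = {
            "phbdeg_version": __version__,
            "config": config.to_dict(),
            "thresholds": thresholds,
        }
        (outdir / "run.json").write_text(json.dumps(run_record, indent=2, sort_keys=True))
        if kin_entries:
            write_threshold_json(
                kin_entries[0][0].threshold,
                outdir / "threshold.json",
                note="per-sample thresholds in run.json",
            )
    return StudyResult(fits=fits, comparison=comparison, t50_by_blend=t50_by_blend, outdir=outdir)
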
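"""End-to-end analysis pipeline.

Given encounter-annotated tracks (read from GPX + annotations, or
simulated), the pipeline produces, in an output directory:

* ``hunt_summaries.csv``   — per-trip descriptives with Sum/Mean rows;
* ``lag_beta_summary.csv`` / ``lag_lognormal_summary.csv`` — posterior
  medians and 90% intervals of the lagged effect curves, plus
  ``lag_effects.png`` and a ``crossings.csv`` with the first lag at
  which each effect curve's interval reaches zero;
* ``waic_comparison.csv``  — the six-model step-size comparison;
* ``patch_stats.csv``      — the four patch-conditional regressions.

The same configuration and seed always reproduce identical tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import dist_fit, forager_sim, lagged_bayes, patch_stats, track_io
from ._inference import SamplerConfig
from .kinematics import PatchLabels, floor_steps, label_patches, to_polar


@dataclass
class PipelineConfig:
    tracks_dir: str | None = None       # directory of GPX files
    annotations: str | None = None      # GPX waypoints or CSV; optional
    simulate: str | None = None         # 'ars' or 'levy' instead of real tracks
    sim_config: forager_sim.SimConfig | None = None
    lags: int = 90                      # lag depth S
    patch_window: int = 50              # patch window W
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    seed: int = 0
    out_dir: str = "ars-report"
    fit_variants: bool = False          # also fit AR-1 robustness variants
    make_plots: bool = True


def _load_tracks(cfg: PipelineConfig) -> list[track_io.Track]:
    if cfg.simulate:
        sim_cfg = cfg.sim_config or forager_sim.SimConfig(seed=cfg.seed)
        return forager_sim.simulate_forager(sim_cfg, mode=cfg.simulate,
                                            seed=cfg.seed).tracks
    if not cfg.tracks_dir:
        raise ValueError("config must name a tracks directory or a simulation mode")
    tracks = track_io.read_tracks(cfg.tracks_dir)
    if cfg.annotations:
        ann = track_io.read_annotations(cfg.annotations)
        tracks = [track_io.align_encounters(t, ann) for t in tracks]
    return tracks


def _lag_plot(beta_fit, logn_fit, path):
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharex=True)
    for ax, fit, label, color in (
            (axes[0], beta_fit, r"turning-angle effect $\psi_s$", "tab:green"),
            (axes[1], logn_fit, r"step-size effect $\phi_s$", "tab:orange")):
        lag = fit.lag_summary()
        ax.fill_between(lag.index, lag["ci5"], lag["ci95"], alpha=0.3, color=color)
        ax.plot(lag.index, lag["median"], color=color)
        ax.axhline(0.0, color="tab:blue", lw=1)
        ax.set_xlabel("lag s (10 s steps)")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the report tables as a dict."""
    if cfg.lags < 1:
        raise ValueError("at least one lag required")
    os.makedirs(cfg.out_dir, exist_ok=True)
    if not os.access(cfg.out_dir, os.W_OK):
        raise PermissionError(f"output directory {cfg.out_dir!r} is not writable")

    tracks = _load_tracks(cfg)
    polars = [to_polar(t) for t in tracks]

    report: dict = {}
    fmt = lambda df: df.round(6)

    summaries = track_io.summary_table(tracks)
    summaries.to_csv(os.path.join(cfg.out_dir, "hunt_summaries.csv"))
    report["hunt_summaries"] = summaries

    # lagged Bayesian fits
    d_design = lagged_bayes.build_lag_design(polars, cfg.lags, outcome="delta")
    r_design = lagged_bayes.build_lag_design(polars, cfg.lags, outcome="r")
    beta_fit = lagged_bayes.fit_beta_lag(d_design, sampler_cfg=cfg.sampler,
                                         seed=cfg.seed)
    logn_fit = lagged_bayes.fit_lognormal_lag(r_design, sampler_cfg=cfg.sampler,
                                              seed=cfg.seed + 1)
    fmt(beta_fit.summary).to_csv(os.path.join(cfg.out_dir, "lag_beta_summary.csv"))
    fmt(logn_fit.summary).to_csv(
        os.path.join(cfg.out_dir, "lag_lognormal_summary.csv"))
    crossings = pd.DataFrame({
        "effect": ["turning_angle", "step_size"],
        "first_crossing_lag": [
            lagged_bayes.first_crossing_lag(beta_fit, side="above"),
            lagged_bayes.first_crossing_lag(logn_fit, side="below")],
    })
    crossings.to_csv(os.path.join(cfg.out_dir, "crossings.csv"), index=False)
    report["lag_beta"] = beta_fit
    report["lag_lognormal"] = logn_fit
    report["crossings"] = crossings
    if cfg.make_plots:
        _lag_plot(beta_fit, logn_fit, os.path.join(cfg.out_dir, "lag_effects.png"))

    if cfg.fit_variants:
        for name, design in (("beta", d_design), ("lognormal", r_design)):
            ar = lagged_bayes.fit_variants(design, "ar1",
                                           sampler_cfg=cfg.sampler, seed=cfg.seed)
            fmt(ar.summary).to_csv(
                os.path.join(cfg.out_dir, f"lag_{name}_ar1_summary.csv"))
            report[f"lag_{name}_ar1"] = ar

    # step-size distribution comparison
    r_all = floor_steps(np.concatenate([p.r for p in polars]))
    fits = dist_fit.fit_all_models(r_all, sampler_cfg=cfg.sampler, seed=cfg.seed)
    waic_table = dist_fit.compare_models(fits)
    fmt(waic_table).to_csv(os.path.join(cfg.out_dir, "waic_comparison.csv"),
                           index=False)
    report["waic_comparison"] = waic_table
    report["dist_fits"] = fits

    # patch-conditional regressions
    rows = []
    labels = [label_patches(p.E, cfg.patch_window, p.segment) for p in polars]
    merged_labels = PatchLabels(
        in_patch=np.concatenate([l.in_patch for l in labels]),
        window=cfg.patch_window)
    delta_all = np.concatenate([p.delta for p in polars])
    seg = _global_segments(polars)
    E_all = np.concatenate([p.E for p in polars])
    try:
        rows.append(patch_stats.regress_on_patch(delta_all, merged_labels,
                                                 "turning_angle"))
        rows.append(patch_stats.regress_on_patch(r_all, merged_labels,
                                                 "step_size"))
        rows.append(patch_stats.encounter_regression(E_all, delta_all,
                                                     "turning_angle", seg))
        rows.append(patch_stats.encounter_regression(E_all, r_all,
                                                     "step_size", seg))
    except ValueError as exc:
        report["patch_stats_warning"] = str(exc)
    patch_df = pd.DataFrame([r.__dict__ for r in rows])
    patch_df.round(6).to_csv(
        os.path.join(cfg.out_dir, "patch_stats.csv"), index=False)
    report["patch_stats"] = patch_df
    return report


def _global_segments(polars) -> np.ndarray:
    """Segment ids made unique across trips so lags never cross trips."""
    out, offset = [], 0
    for p in polars:
        out.append(p.segment + offset)
        offset += p.segment.max() + 1
    return np.concatenate(out)
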
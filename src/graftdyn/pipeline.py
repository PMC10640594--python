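"""End-to-end seeded pipeline: simulate -> preprocess -> modulation ->
population -> tracking -> stimulation -> blood flow -> summary tables.

The run is driven by a :class:`RunConfig`; every stage derives its seed
from the config seed through a ``SeedSequence``, and all outputs are
written deterministically, so a rerun with the same config reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from graftdyn import io as gio
from graftdyn import synth
from graftdyn.bloodflow import cell_vessel_distances, estimate_speed, segment_vessels
from graftdyn.modulation import anova_modulation, lme_correlation
from graftdyn.population import fa_sot
from graftdyn.preprocess import baseline_correct, bin_trials, segment_residuals, segment_trials
from graftdyn.stim import analyze_acs_session
from graftdyn.synth import FlowVideoSpec, TaskSessionSpec
from graftdyn.tracking import register_sessions, tracked_fraction

logger = logging.getLogger(__name__)

# (fraction of task-modulated cells, shared-over-total variance) for the
# four session phases the pipeline emulates: the early / mid / late
# training periods of a transplanted network and a healthy control.
DEFAULT_PHASES = {
    "early": (0.196, 0.45),
    "mid": (0.266, 0.548),
    "late": (0.489, 0.675),
    "healthy": (0.49, 0.641),
}


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 1
    phases: dict = field(default_factory=lambda: dict(DEFAULT_PHASES))
    n_cells: int = 60
    n_trials: int = 40
    task_window_s: tuple = (2.5, 2.5)
    segment_window_s: tuple = (5.0, 5.0)
    bin_s: float = 0.5
    alpha: float = 0.05
    q: int = 2
    transient_amp: float = 5.0
    track_n_base: int = 100
    track_n_sessions: int = 3
    track_jitter_px: float = 1.0
    track_retention: float = 0.55
    track_max_dist_px: float = 8.0
    track_footprint_sigma_px: float = 2.0
    track_min_footprint_corr: float = 0.6
    acs_n_cells: int = 60
    acs_frac_responsive: float = 0.75
    acs_frac_post_suppressed: float = 0.70
    acs_shuffles: int = 500
    flow_speed_um_s: float = 1000.0
    flow_pixel_um: float = 2.0
    flow_shape: tuple = (40, 200)
    flow_frames: int = 1800
    vessel_n_cells: int = 258
    vessel_max_dist_um: float = 76.2

    def validate(self):
        if self.bin_s <= 0 or not (0 < self.alpha < 1):
            raise ValueError("invalid bin_s or alpha")
        pre, post = self.task_window_s
        if (pre + post) % self.bin_s > 1e-9 and \
                abs((pre + post) % self.bin_s - self.bin_s) > 1e-9:
            raise ValueError("task window not divisible by bin_s")
        spre, spost = self.segment_window_s
        if spre < pre or spost < post:
            raise ValueError("segmentation window must contain the task window")

    def to_json(self):
        d = dataclasses.asdict(self)
        d.pop("outdir")      # runtime location, not an analysis parameter
        d["phases"] = {k: list(v) for k, v in self.phases.items()}
        return d

    @classmethod
    def from_json(cls, d):
        d = dict(d)
        if "phases" in d:
            d["phases"] = {k: tuple(v) for k, v in d["phases"].items()}
        for key in ("task_window_s", "segment_window_s", "flow_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        s = json.dumps(self.to_json(), sort_keys=True)
        return hashlib.sha256(s.encode()).hexdigest()[:16]


def _child_seeds(seed, n):
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write tables; returns the summary dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 8)
    summary = {"config_hash": config.config_hash, "seed": config.seed}
    t_start = time.time()

    # --- task sessions: preprocess, modulation, SOT -----------------------
    mod_rows, sot_rows = [], []
    phase_seeds = _child_seeds(seeds[0], len(config.phases))
    for (label, (frac_mod, shared)), ps in zip(config.phases.items(), phase_seeds):
        t0 = time.time()
        spec = TaskSessionSpec(
            n_cells=config.n_cells, n_trials=config.n_trials,
            trial_window_s=config.task_window_s, frac_modulated=frac_mod,
            shared_frac=shared, transient_amp=config.transient_amp,
            factor_scope="modulated", session_label=label, seed=ps)
        rec, gt = synth.gen_task_session(spec)
        tens = segment_trials(rec, "pellet_touch", config.segment_window_s)
        resid = segment_residuals(rec, "pellet_touch", config.segment_window_s)
        corrected = baseline_correct(tens, resid)
        binned = bin_trials(corrected, config.bin_s, config.task_window_s)
        res = anova_modulation(binned, alpha=config.alpha)
        pre, post = config.task_window_s
        t = tens.times_s
        task = corrected.data[:, :, (t >= -pre) & (t < post)]
        dec = fa_sot(task, q=config.q)
        mod_rows.append({"session": label, "frac_modulated_true": frac_mod,
                         "proportion_modulated": res.proportion,
                         "n_cells": config.n_cells})
        sot_rows.append({"session": label, "shared_frac_true": shared,
                         "sot": dec.sot})
        logger.info("phase %s done in %.1f s", label, time.time() - t0)
    mod_df = pd.DataFrame(mod_rows)
    sot_df = pd.DataFrame(sot_rows)
    gio.write_table(out / "modulation.csv", mod_df)
    gio.write_table(out / "sot.csv", sot_df)
    summary["proportion_modulated"] = dict(zip(mod_df.session, mod_df.proportion_modulated))
    summary["sot"] = dict(zip(sot_df.session, sot_df.sot))

    # --- behavior vs modulation correlation (LME) -------------------------
    beh = synth.gen_behavior_summary(seed=seeds[1])
    lme = lme_correlation(beh)
    gio.write_table(out / "behavior_summary.csv", beh)
    summary["lme"] = {k: lme[k] for k in ("r", "p", "random_r_sd",
                                          "random_intercept_sd")}

    # --- longitudinal tracking -------------------------------------------
    rng = np.random.default_rng(seeds[2])
    base = np.column_stack([rng.uniform(5, 195, config.track_n_base),
                            rng.uniform(5, 195, config.track_n_base)])
    maps, _ = synth.gen_multisession(
        base, config.track_n_sessions, jitter_px=config.track_jitter_px,
        retention_frac=config.track_retention,
        footprint_sigma_px=config.track_footprint_sigma_px, seed=seeds[3])
    tr = register_sessions(maps, max_dist_px=config.track_max_dist_px,
                           min_footprint_corr=config.track_min_footprint_corr)
    frac = tracked_fraction(tr, config.track_n_base)
    gio.write_table(out / "tracking_chains.csv", tr.chain_table())
    summary["tracking"] = {"full_span_fraction": frac["full_span"],
                          "adjacent_fractions": frac["adjacent"]}

    # --- stimulation session ---------------------------------------------
    t0 = time.time()
    acs, acs_gt = synth.gen_acs_session(
        n_cells=config.acs_n_cells,
        frac_responsive=config.acs_frac_responsive,
        frac_post_suppressed=config.acs_frac_post_suppressed, seed=seeds[4])
    acs_res = analyze_acs_session(acs, n_shuffles=config.acs_shuffles,
                                  seed=seeds[5])
    gio.write_table(out / "acs_cells.csv", acs_res.table())
    active = ~acs_res.inactive
    summary["acs"] = {
        "responsive_fraction": float(acs_res.responsive.mean()),
        "post_decreased_fraction":
            float((acs_res.event_class_post[active] == "decreased").mean()),
        "true_responsive_fraction": config.acs_frac_responsive,
    }
    logger.info("ACS stage done in %.1f s", time.time() - t0)

    # --- blood flow -------------------------------------------------------
    t0 = time.time()
    fspec = FlowVideoSpec(shape_px=config.flow_shape,
                          n_frames=config.flow_frames,
                          pixel_size_um=config.flow_pixel_um,
                          speed_um_per_s=config.flow_speed_um_s,
                          seed=seeds[6])
    frames, fgt = synth.gen_flow_video(fspec)
    vm = segment_vessels(frames, config.flow_pixel_um)
    field_ = estimate_speed(frames, vm.mask, fspec.rate_hz,
                            config.flow_pixel_um)
    # cell-to-vessel distances on a full-size field (600 x 950 um FOV)
    field_spec = FlowVideoSpec(shape_px=(300, 475),
                               pixel_size_um=config.flow_pixel_um,
                               vessel_polyline=np.array(
                                   [[20.0, 150.0], [240.0, 170.0], [460.0, 140.0]]))
    big_mask = synth.vessel_lumen_mask(field_spec)
    cents, cgt = synth.gen_cell_positions(
        config.vessel_n_cells, big_mask, config.vessel_max_dist_um,
        config.flow_pixel_um, seed=seeds[7])
    dist = cell_vessel_distances(cents, big_mask, config.flow_pixel_um)
    gio.write_table(out / "flow_boxes.csv", field_.boxes)
    gio.write_table(out / "vessel_distances.csv",
                    pd.DataFrame({"distance_um": dist["distances_um"]}))
    summary["bloodflow"] = {
        "median_speed_um_s": float(np.median(field_.pixel_speeds)),
        "true_speed_um_s": config.flow_speed_um_s,
        "n_speed_samples": int(len(field_.pixel_speeds)),
        "excluded_boxes": field_.n_excluded,
        "distance_median_um": dist["median"],
        "distance_p95_um": dist["p95"],
    }
    logger.info("blood-flow stage done in %.1f s", time.time() - t0)

    logger.info("pipeline done in %.1f s", time.time() - t_start)
    gio.write_json(out / "config.json", config.to_json())
    gio.write_json(out / "summary.json", summary)
    return summary
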
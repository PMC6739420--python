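"""End-to-end pipeline over a synthetic session: detect -> trials -> steps ->
triggered averages / tuning -> motor map.

All randomness flows from the single seed in the configuration, split per
stage with :class:`numpy.random.SeedSequence`; every CSV written carries the
configuration hash and seed in its header comment.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io, kinematics, motormap, optostim, synthetic, tuning
from .config import PipelineConfig

log = logging.getLogger("collic")


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_session(
    config: PipelineConfig,
    n_trials: int = 10,
    site: int = 5,
    site_vectors: dict[int, tuple[float, float, float]] | None = None,
):
    """Synthetic optogenetic session: trace + stimulation log + one unit.

    Each trial evokes the site's characteristic displacement bout 300 ms
    after light onset; an optotagged unit bursts ahead of each bout.
    """
    seeds = _stage_seeds(config.seed, 3)
    if site_vectors is None:
        site_vectors = synthetic.generate_site_grid_truth()
    vec = site_vectors[site]
    stim = synthetic.generate_stim_log(n_trials, inter_trial_s=10.0, duration_s=0.25,
                                       site=site)
    duration = float(stim.onsets[-1] + 10.0) if n_trials else 180.0
    duration = max(duration, config.shuffle_max_shift_s + 10.0)
    events = []
    for onset in stim.onsets:
        for axis, amp in zip(kinematics.AXES, vec):
            if amp != 0:
                events.append(synthetic.HeadEvent(axis, float(onset + 0.3), amp, 250.0))
    trace, truth = synthetic.generate_head_trace(
        duration, events, noise_sd=0.1, wander_sd=0.5, seed=seeds[0]
    )
    unit = synthetic.generate_spike_train(
        trace, truth, tuning_vector=vec, seed=seeds[1], light_pulses=stim
    )
    truth.site_vectors = dict(site_vectors)
    return trace, stim, unit, truth


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on a simulated session and write all artifacts.

    Returns a summary dict (also written as ``summary.json``); every output
    CSV header carries the config hash and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config={config.hash()} seed={config.seed}"
    trace, stim, unit, truth = simulate_session(config)
    io.write_trace_csv(trace, out / "trace.csv", tag)
    io.write_stim_csv(stim, out / "stim.csv", tag)
    io.write_spikes_csv(unit, out / "spikes.csv", tag)
    log.info("simulated session: %d samples, %d trials, %d spikes",
             trace.n, stim.onsets.size, unit.times.size)

    events_by_axis = {
        a: kinematics.detect_motion_events(
            trace, a, config.velocity_threshold_deg_s, config.min_event_bins
        )
        for a in kinematics.AXES
    }
    all_events = [e for evs in events_by_axis.values() for e in evs]
    io.write_events_csv(all_events, out / "events.csv", tag)

    trials = optostim.score_trials(
        trace, stim, events_by_axis, config.success_window_s, config.baseline_window_s
    )
    steps_by_trial = [
        optostim.detect_steps(
            trace,
            (t.onset_s, t.onset_s + config.success_window_s),
            "yaw",
            config.velocity_threshold_deg_s,
        )
        for t in trials
    ]
    summary_steps = optostim.step_statistics(
        steps_by_trial, truth.site_vectors[stim.site][0]
    )

    sta = tuning.triggered_average(
        trace, unit.times, "yaw", config.sta_pre_bins, config.sta_post_bins
    )
    lta = tuning.triggered_average(
        trace, stim.onsets, "yaw", config.sta_pre_bins, config.sta_post_bins
    )
    null = tuning.shuffle_null(
        trace, unit, "yaw",
        n_shuffles=min(config.shuffle_reps, 200),
        shift_range_s=(config.shuffle_min_shift_s, config.shuffle_max_shift_s),
        seed=_stage_seeds(config.seed, 4)[3],
        pre_bins=config.sta_pre_bins, post_bins=config.sta_post_bins,
    )
    tag_result = tuning.optotag(unit, stim, config.optotag_latency_ms)

    site_vectors = truth.site_vectors
    site_trials = {
        s: np.asarray([v], dtype=float) for s, v in site_vectors.items()
    }
    site_map = motormap.build_site_map(site_trials)
    smoothed = motormap.smooth_map(site_map, config.smoothing_sigma_um)
    grad = motormap.gradient_field(smoothed)
    mag = motormap.magnification(grad)
    io.write_site_map_csv(site_map, out / "site_map.csv", tag)

    summary = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_samples": int(trace.n),
        "n_trials": len(trials),
        "n_events_yaw": len(events_by_axis["yaw"]),
        "success_rate_yaw": optostim.success_rate(trials, "yaw"),
        "mean_amplitude_yaw_deg": optostim.mean_successful_amplitude(trials, "yaw"),
        "mean_steps_per_trial": summary_steps.mean_steps if summary_steps else None,
        "sta_vector_yaw_deg": sta.displacement_vector,
        "lta_vector_yaw_deg": lta.displacement_vector,
        "null_mean_yaw_deg": null.mean,
        "optotagged": tag_result.tagged,
        "median_optotag_latency_ms": tag_result.median_latency_ms,
        "median_magnification_mm2_deg2": float(np.nanmedian(mag.magnification)),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
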
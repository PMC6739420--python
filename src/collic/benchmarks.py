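"""Self-contained benchmark suites exercising every stage on synthetic data.

Each function generates its own ground-truthed inputs, runs the relevant
analysis stage, and returns the measured quantity.  They are used by the
acceptance checks and are convenient for regression profiling; problem sizes
are chosen so the full set runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from . import eyetrack, kinematics, motormap, optostim, periodicity, synthetic, tuning
from .config import PipelineConfig
from .kinematics import AXES
from .synthetic import HeadEvent


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def random_wander_trace(seed: int, duration_s: float = 10.0) -> kinematics.EulerTrace:
    """Trace with random bouts over wander + noise, for detector stress tests."""
    rng = np.random.default_rng(seed)
    events = []
    t = 1.0
    for _ in range(int(rng.integers(0, 5))):
        t += rng.uniform(0.3, 1.5)
        dur = rng.uniform(120, 500)
        if t + dur / 1000 > duration_s - 1:
            break
        events.append(
            HeadEvent(
                str(rng.choice(AXES)), float(t), float(rng.uniform(-30, 30)), float(dur)
            )
        )
        t += dur / 1000
    trace, _ = synthetic.generate_head_trace(
        duration_s, events, noise_sd=0.3, wander_sd=1.0, seed=seed
    )
    return trace


# ---------------------------------------------------------------- sensors

def sensor_expected_steps() -> dict[float, float]:
    """Expected per-bin displacement at 50 Hz for the rotation-table speeds."""
    out = {}
    for speed in (28.0, 40.0, 56.0, 80.0):
        trace = synthetic.generate_rotation_table_trace(speed, 1, 2.0)
        out[speed] = kinematics.validate_rotation(trace, speed).expected_step
    return out


def detector_threshold_constants(config: PipelineConfig | None = None) -> tuple[float, float]:
    """(velocity threshold in deg/bin, minimum event duration in ms)."""
    cfg = config or PipelineConfig()
    dt = 1.0 / cfg.sampling_rate_hz
    return cfg.velocity_threshold_deg_s * dt, cfg.min_event_bins * dt * 1000.0


# ----------------------------------------------------------- event detector

def detector_equivalence(n_traces: int = 1000, seed: int = 0) -> float:
    """Fraction of random traces where the detector matches brute force."""
    seeds = _child_seeds(seed, n_traces)
    agree = 0
    for s in seeds:
        trace = random_wander_trace(s)
        ok = True
        for axis in AXES:
            fast = kinematics.detect_motion_events(trace, axis)
            slow = kinematics.detect_motion_events_bruteforce(trace, axis)
            if [(e.onset_index, e.offset_index, e.direction) for e in fast] != [
                (e.onset_index, e.offset_index, e.direction) for e in slow
            ]:
                ok = False
                break
        agree += int(ok)
    return agree / n_traces


# ------------------------------------------------------------ STA recovery

def sta_vector_recovery(
    seed: int = 0,
    n_spikes: int = 500,
    amplitudes: tuple[float, ...] = (5.0, -10.0, 20.0, -40.0),
) -> float:
    """Worst relative error (%) of recovered characteristic vectors.

    One unit per (amplitude, axis): the trace carries ``n_spikes`` isolated
    bouts of the given amplitude, each preceded 100 ms earlier by a spike;
    low-amplitude sensor noise is added.  The spike-triggered displacement
    vector is compared with the injected amplitude.
    """
    seeds = iter(_child_seeds(seed, len(amplitudes) * len(AXES)))
    spacing = 4.0
    worst = 0.0
    for amp in amplitudes:
        for axis in AXES:
            s = next(seeds)
            events = [
                HeadEvent(axis, 3.0 + k * spacing, amp, 250.0)
                for k in range(n_spikes)
            ]
            duration = 3.0 + n_spikes * spacing + 3.0
            trace, _ = synthetic.generate_head_trace(
                duration, events, noise_sd=0.1, seed=s
            )
            triggers = np.array([e.onset_s - 0.1 for e in events])
            avg = tuning.triggered_average(trace, triggers, axis)
            err = abs(avg.displacement_vector - amp) / abs(amp)
            worst = max(worst, err)
    return worst * 100.0


def sta_type_i_rate(
    seed: int = 0, n_runs: int = 500, n_shuffles: int = 100
) -> float:
    """Type-I rate (%) of the shuffle-null test for motion-independent spikes.

    Spikes are homogeneous Poisson, independent of the head trace; a run
    counts as a false positive when the real displacement vector exceeds the
    null's 95th percentile.  Exchangeability puts the expected rate at
    ~5/101 per run.
    """
    trace_seed, spike_seed = _child_seeds(seed, 2)
    events = [
        HeadEvent(AXES[k % 3], 12.0 + 7.0 * k, (-1.0) ** k * 20.0, 250.0)
        for k in range(20)
    ]
    trace, _ = synthetic.generate_head_trace(
        160.0, events, noise_sd=0.1, wander_sd=1.0, seed=trace_seed
    )
    session = float(trace.time[-1])
    rng = np.random.default_rng(spike_seed)
    hits = 0
    for k in range(n_runs):
        n = rng.poisson(3.0 * session)
        times = np.sort(rng.uniform(0, session, size=n))
        unit = synthetic.SpikeTrain("u", times, session_length_s=session)
        real = tuning.triggered_average(trace, times, "yaw").displacement_vector
        null = tuning.shuffle_null(
            trace, unit, "yaw", n_shuffles=n_shuffles, seed=int(rng.integers(2**31))
        )
        hits += int(real > null.percentile(95))
    return 100.0 * hits / n_runs


# ---------------------------------------------------------- step staircases

def step_recovery(
    seed: int = 0, trials_per_k: int = 20, k_values: tuple[int, ...] = (1, 2, 3, 4, 5)
) -> tuple[float, float]:
    """(fraction of noiseless staircase trials with correct step count,
    worst absolute step-amplitude error in deg)."""
    rng = np.random.default_rng(seed)
    correct = 0
    worst_amp = 0.0
    total = 0
    for k in k_values:
        for _ in range(trials_per_k):
            amp = float(rng.uniform(8.0, 25.0))
            # bout edges on the 20 ms sample grid, so amplitudes are exact
            dur = 20.0 * int(rng.integers(8, 16))
            gap = 20.0 * int(rng.integers(6, 13))
            span = k * (dur + gap) / 1000.0
            trace, _ = synthetic.generate_staircase_trace(
                k, amp, dur, gap, start_s=1.0, duration_s=span + 2.5, profile="ramp"
            )
            steps = optostim.detect_steps(trace, (0.5, span + 2.0), "yaw")
            total += 1
            if len(steps) == k:
                correct += 1
                worst_amp = max(
                    worst_amp, max(abs(s.amplitude_deg - amp) for s in steps)
                )
    return correct / total, worst_amp


# ------------------------------------------------------------ magnification

def magnification_closed_form() -> float:
    """Magnification of the affine map Y = 2x, P = 3y (expected 1/6)."""
    coords = np.arange(3) * 0.5
    X, Yc = np.meshgrid(coords, coords)
    m = motormap.SiteVectorMap(
        coords, coords, 2.0 * X, 3.0 * Yc, np.zeros((3, 3)), np.ones((3, 3), int)
    )
    mag = motormap.magnification(motormap.gradient_field(m))
    return float(mag.magnification[1, 1])


# -------------------------------------------------------------- honeycomb

def honeycomb_recovery(
    seed: int = 0,
    n_runs: int = 50,
    lattices: tuple[float, ...] = (100.0, 130.0, 160.0),
    jitters: tuple[float, ...] = (0.0, 5.0, 10.0),
    voxel_um: float = 10.0,
    size: tuple[int, int, int] = (4, 192, 192),
) -> tuple[float, float]:
    """(fraction of runs with spacing recovered within 7 um of the generated
    lattice's true mean NN spacing, mean recovered spacing at L = 130 um with
    zero jitter)."""
    seeds = _child_seeds(seed, n_runs)
    ok = 0
    at_130 = []
    for i, s in enumerate(seeds):
        L = lattices[i % len(lattices)]
        j = jitters[(i // len(lattices)) % len(jitters)]
        vol, truth = synthetic.generate_honeycomb_volume(
            L, j, voxel_um, size, seed=s
        )
        dv = periodicity.DensityVolume(vol, (voxel_um,) * 3)
        stats_, _ = periodicity.honeycomb_spacing(dv, lattice_expected_um=L)
        d, _ = cKDTree(truth.centers_um).query(truth.centers_um, k=2)
        true_mean = float(d[:, 1].mean())
        if abs(stats_.mean_um - true_mean) <= 7.0:
            ok += 1
        if L == 130.0 and j == 0.0:
            at_130.append(stats_.mean_um)
    return ok / n_runs, float(np.mean(at_130)) if at_130 else float("nan")


# ------------------------------------------------------------------- pupil

def pupil_alpha_geometry() -> dict[str, float]:
    """alpha = arcsin(d/r) at d = 0, r/2 and r, in degrees."""
    r = 20.0
    out = {}
    for label, d in (("d0", 0.0), ("d_half_r", r / 2), ("d_r", r)):
        tr = eyetrack.PupilTrace(
            time_s=np.array([0.0]),
            center_x=np.array([80.0 + d]),
            center_y=np.array([60.0]),
            axis_a=np.array([10.0]),
            axis_b=np.array([10.0]),
            area_px2=np.array([np.pi * 100]),
            detected=np.array([True]),
        )
        out[label] = float(eyetrack.eye_amplitude(tr, (80.0, 60.0), r)[0])
    return out


def ellipse_fit_recovery(seed: int = 0, n_frames: int = 500) -> float:
    """Fraction of noisy synthetic frames recovered within 1 px / 5%.

    Axes are drawn from 8-30 px, centers wander over the frame, and the
    intensity noise SD is 10% of the pupil/background contrast.
    """
    rng = np.random.default_rng(seed)
    shape = (120, 160)
    good = 0
    for i in range(n_frames):
        a = float(rng.uniform(8.0, 30.0))
        b = float(rng.uniform(8.0, 30.0))
        pad = max(a, b) / min(a, b) + 2.0
        cx = float(rng.uniform(a + pad, shape[1] - 1 - a - pad))
        cy = float(rng.uniform(b + pad, shape[0] - 1 - b - pad))
        frames, _ = synthetic.generate_pupil_frames(
            1, np.array([[cx, cy]]), (a, b), noise_sd=18.0, shape=shape,
            seed=int(rng.integers(2**31)),
        )
        fit = eyetrack.fit_pupil(frames[0], smoothing_sigma_px=1.5)
        if fit is None:
            continue
        fa, fb = fit.axis_a, fit.axis_b
        ta, tb = (a, b) if a >= b else (b, a)
        ra, rb = (fa, fb) if fa >= fb else (fb, fa)
        if (
            abs(fit.center_x - cx) < 1.0
            and abs(fit.center_y - cy) < 1.0
            and abs(ra - ta) / ta < 0.05
            and abs(rb - tb) / tb < 0.05
        ):
            good += 1
    return good / n_frames
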
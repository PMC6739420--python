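"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (event detection, trial scoring, step
decomposition, triggered averages, motor maps, periodicity, pupil tracking)
can be exercised on data produced here, with the generating parameters
returned alongside so recovery can be checked exactly.  Every generator is a
pure function of its arguments including the seed.

Emulated structure:

* head traces: mean-reverting baseline wander plus discrete saccade-like
  displacement bouts with a smooth sigmoidal position profile, sampled at
  50 Hz;
* stimulation logs: trains of light pulses at fixed inter-trial intervals
  after an initial quiet period;
* spike trains: inhomogeneous Poisson, with the rate stepping up a fixed
  lead time before each direction-matched movement onset, and optional
  sub-5-ms optotag responses to light pulses;
* honeycomb density volumes: hexagonal lattices of low-density centers
  surrounded by high-density walls;
* pupil frame sequences: dark soft-edged ellipses on a bright background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .kinematics import AXES, EulerTrace

SAMPLING_RATE_HZ = 50.0
QUIET_PERIOD_S = 10.0  # no-stimulation lead-in of each session


@dataclass
class HeadEvent:
    """One injected displacement bout."""

    axis: str
    onset_s: float
    amplitude_deg: float
    duration_ms: float


@dataclass
class StimLog:
    """Light-onset events sharing duration, pulse rate and fiber site."""

    onsets: np.ndarray            # s
    duration_s: float
    frequency: float | str = "continuous"   # pulse rate in Hz, or continuous
    site: int = 1

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("stimulation onsets must be strictly increasing")


@dataclass
class SpikeTrain:
    """Spike times of one unit with an epoch label per session."""

    unit_id: str
    times: np.ndarray             # s, sorted
    epoch: str = "light"          # {"light", "dark"}
    session_length_s: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))


@dataclass
class GroundTruth:
    """Generating parameters embedded in each synthetic artifact."""

    seed: int
    events: list[HeadEvent] = field(default_factory=list)
    site_vectors: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    spike_lead_time_ms: float = float("nan")
    lattice_constant_um: float = float("nan")
    centers_um: np.ndarray | None = None
    pupil_centers: np.ndarray | None = None
    pupil_axes: tuple[float, float] | None = None

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("pupil_centers", "centers_um"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key]).tolist()
        return json.dumps(d, indent=2, default=str)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: C2 sigmoid, exactly 0 at u<=0 and 1 at u>=1."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * u * (u * (6.0 * u - 15.0) + 10.0)


def _event_profile(t: np.ndarray, ev: HeadEvent, profile: str) -> np.ndarray:
    if profile not in ("smoothstep", "ramp"):
        raise ValueError(f"unknown profile {profile!r}")
    u = (t - ev.onset_s) / (ev.duration_ms / 1000.0)
    # snap samples that land on the bout boundaries within float error, so
    # the profile is exactly flat outside the bout (no residual sign bins)
    eps = 1e-9
    out = np.zeros_like(t)
    inside = (u > eps) & (u < 1.0 - eps)
    out[inside] = _smoothstep(u[inside]) if profile == "smoothstep" else u[inside]
    out[u >= 1.0 - eps] = 1.0
    return ev.amplitude_deg * out


def generate_head_trace(
    duration_s: float,
    events: Sequence[HeadEvent] = (),
    noise_sd: float = 0.0,
    wander_sd: float = 0.0,
    wander_tau_s: float = 2.0,
    seed: int = 0,
    profile: str = "smoothstep",
    fs: float = SAMPLING_RATE_HZ,
) -> tuple[EulerTrace, GroundTruth]:
    """Head-over-body trace: baseline wander + displacement bouts + noise.

    The bout position profile is a compactly supported sigmoid (quintic
    smoothstep), so with ``noise_sd=0`` and ``wander_sd=0`` the net
    displacement across an isolated bout equals its amplitude exactly.  A
    piecewise-linear ``"ramp"`` profile (constant velocity during the bout)
    is available for exact-velocity tests.  Baseline wander is a discretized
    Ornstein-Uhlenbeck process with stationary SD ``wander_sd`` and
    reversion time ``wander_tau_s``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    per_axis: dict[str, list[HeadEvent]] = {a: [] for a in AXES}
    for ev in events:
        if ev.axis not in AXES:
            raise ValueError(f"unknown axis {ev.axis!r}")
        if ev.duration_ms <= 0:
            raise ValueError("event duration must be positive")
        per_axis[ev.axis].append(ev)
    for axis, evs in per_axis.items():
        evs.sort(key=lambda e: e.onset_s)
        for a, b in zip(evs, evs[1:]):
            if a.onset_s + a.duration_ms / 1000.0 > b.onset_s:
                raise ValueError("events overlap")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    dt = 1.0 / fs
    angles = {}
    for axis in AXES:
        x = np.zeros(n)
        if wander_sd > 0:
            # OU: x' = -x/tau + sqrt(2/tau)*sd*xi, exact discretization
            rho = np.exp(-dt / wander_tau_s)
            innov_sd = wander_sd * np.sqrt(1.0 - rho**2)
            w = np.empty(n)
            w[0] = rng.normal(0.0, wander_sd)
            steps = rng.normal(0.0, innov_sd, size=n - 1)
            # AR(1) recursion w[i] = rho*w[i-1] + steps[i-1]
            w[1:], _ = lfilter([1.0], [1.0, -rho], steps, zi=[rho * w[0]])
            x += w
        for ev in per_axis[axis]:
            x += _event_profile(t, ev, profile)
        if noise_sd > 0:
            x += rng.normal(0.0, noise_sd, size=n)
        angles[axis] = x
    trace = EulerTrace(t, angles["yaw"], angles["pitch"], angles["roll"])
    return trace, GroundTruth(seed=seed, events=list(events))


def generate_staircase_trace(
    n_steps: int,
    step_amplitude_deg: float = 15.0,
    step_duration_ms: float = 200.0,
    gap_ms: float = 150.0,
    start_s: float = 1.0,
    duration_s: float = 6.0,
    axis: str = "yaw",
    profile: str = "ramp",
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[EulerTrace, GroundTruth]:
    """Stepwise staircase of ``n_steps`` identical bouts separated by pauses."""
    events = [
        HeadEvent(
            axis,
            start_s + k * (step_duration_ms + gap_ms) / 1000.0,
            step_amplitude_deg,
            step_duration_ms,
        )
        for k in range(n_steps)
    ]
    return generate_head_trace(
        duration_s, events, noise_sd=noise_sd, seed=seed, profile=profile
    )


def generate_stim_log(
    n_trials: int,
    inter_trial_s: float = 10.0,
    duration_s: float = 0.25,
    frequency: float | str = "continuous",
    site: int = 1,
) -> StimLog:
    """Stimulation log: onsets every ``inter_trial_s`` after a 10 s quiet lead-in."""
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if n_trials and inter_trial_s <= duration_s:
        raise ValueError("inter-trial interval must exceed pulse duration")
    onsets = QUIET_PERIOD_S + inter_trial_s * np.arange(n_trials)
    return StimLog(onsets=onsets, duration_s=duration_s, frequency=frequency, site=site)


def _poisson_times(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def generate_spike_train(
    trace: EulerTrace,
    truth: GroundTruth,
    tuning_vector: tuple[float, float, float] = (20.0, 0.0, 0.0),
    lead_time_ms: float = 80.0,
    base_rate_hz: float = 5.0,
    burst_rate_hz: float = 40.0,
    seed: int = 0,
    light_pulses: StimLog | None = None,
    optotag_latency_ms: tuple[float, float] = (1.0, 4.0),
    unit_id: str = "u0",
    epoch: str = "light",
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes locked ahead of matched movements.

    The rate is ``base_rate_hz`` everywhere and ``burst_rate_hz`` inside
    windows starting ``lead_time_ms`` before the onset of every injected
    bout whose direction matches the sign of ``tuning_vector`` on that axis,
    lasting until the bout ends.  If ``light_pulses`` is given, one extra
    spike per pulse is injected at a uniform 1-4 ms latency, inside the 5 ms
    optotagging criterion.
    """
    if base_rate_hz < 0 or burst_rate_hz < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    session = float(trace.time[-1])
    tuning = dict(zip(AXES, tuning_vector))
    windows = []
    for ev in truth.events:
        g = tuning.get(ev.axis, 0.0)
        if g != 0 and np.sign(ev.amplitude_deg) == np.sign(g):
            t0 = ev.onset_s - lead_time_ms / 1000.0
            t1 = ev.onset_s + ev.duration_ms / 1000.0
            windows.append((max(t0, 0.0), min(t1, session)))
    windows.sort()

    spikes = [_poisson_times(rng, base_rate_hz, 0.0, session)]
    extra = burst_rate_hz - base_rate_hz
    for t0, t1 in windows:
        spikes.append(_poisson_times(rng, extra, t0, t1))
    if light_pulses is not None and light_pulses.onsets.size:
        lo, hi = optotag_latency_ms
        lat = rng.uniform(lo / 1000.0, hi / 1000.0, size=light_pulses.onsets.size)
        spikes.append(light_pulses.onsets + lat)
    times = np.sort(np.concatenate(spikes))
    times = times[(times >= 0) & (times <= session)]
    return SpikeTrain(unit_id=unit_id, times=times, epoch=epoch, session_length_s=session)


def hex_lattice(
    lattice_constant_um: float,
    extent_um: tuple[float, float],
    margin_um: float = 0.0,
) -> np.ndarray:
    """Hexagonal lattice points (y, x) in microns covering a rectangle."""
    L = lattice_constant_um
    row_pitch = L * np.sqrt(3.0) / 2.0
    ys, xs = [], []
    j = 0
    y = margin_um
    while y <= extent_um[0] - margin_um:
        offset = (L / 2.0) if (j % 2) else 0.0
        x = margin_um + offset
        while x <= extent_um[1] - margin_um:
            ys.append(y)
            xs.append(x)
            x += L
        y += row_pitch
        j += 1
    return np.column_stack([ys, xs]) if ys else np.empty((0, 2))


def generate_honeycomb_volume(
    lattice_constant_um: float = 130.0,
    jitter_sd_um: float = 0.0,
    voxel_um: float = 10.0,
    size: tuple[int, int, int] = (8, 192, 192),
    wall_level: float = 100.0,
    pit_depth: float = 90.0,
    pit_sigma_frac: float = 0.30,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Honeycomb density volume: high walls around low-density centers.

    Returns a (z, y, x) volume where each lattice center carries a Gaussian
    density pit (the low-density zone) and the surrounding material remains
    at ``wall_level``, forming hollow-barrel walls extended uniformly along
    z.  Centers are jittered by an isotropic Gaussian of SD ``jitter_sd_um``.
    """
    if lattice_constant_um <= 2 * voxel_um:
        raise ValueError("lattice constant must exceed two voxels")
    nz, ny, nx = size
    rng = np.random.default_rng(seed)
    extent = (ny * voxel_um, nx * voxel_um)
    margin = lattice_constant_um * 0.6
    centers = hex_lattice(lattice_constant_um, extent, margin_um=margin)
    if len(centers) < 2:
        raise ValueError("volume too small to contain at least 2 cells")
    if jitter_sd_um > 0:
        centers = centers + rng.normal(0.0, jitter_sd_um, size=centers.shape)
    yy = (np.arange(ny) + 0.5) * voxel_um
    xx = (np.arange(nx) + 0.5) * voxel_um
    gy, gx = np.meshgrid(yy, xx, indexing="ij")
    img = np.full((ny, nx), wall_level, dtype=float)
    s2 = (pit_sigma_frac * lattice_constant_um) ** 2
    for cy, cx in centers:
        img -= pit_depth * np.exp(-((gy - cy) ** 2 + (gx - cx) ** 2) / (2.0 * s2))
    img = np.clip(img, 0.0, None)
    vol = np.broadcast_to(img, (nz, ny, nx)).copy()
    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, size=vol.shape)
        vol = np.clip(vol, 0.0, None)
    truth = GroundTruth(
        seed=seed, lattice_constant_um=lattice_constant_um, centers_um=centers
    )
    return vol, truth


def generate_pupil_frames(
    n_frames: int,
    trajectory: np.ndarray,
    axes: tuple[float, float] = (20.0, 20.0),
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (120, 160),
    background: float = 220.0,
    pupil_level: float = 40.0,
    edge_softness_px: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Grayscale frames with a dark soft-edged elliptical pupil.

    ``trajectory`` gives per-frame pupil centers as (x, y) pixels; ``axes``
    are the (horizontal, vertical) semi-axes.  The ellipse must lie fully
    inside the frame.  Returns an (n_frames, h, w) float array.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.shape != (n_frames, 2):
        raise ValueError("trajectory must have shape (n_frames, 2)")
    a, b = axes
    h, w = shape
    pad = edge_softness_px * max(a, b) / min(a, b) + 1.0
    if (
        np.any(traj[:, 0] - a - pad < 0)
        or np.any(traj[:, 0] + a + pad > w - 1)
        or np.any(traj[:, 1] - b - pad < 0)
        or np.any(traj[:, 1] + b + pad > h - 1)
    ):
        raise ValueError("ellipse out of bounds")
    rng = np.random.default_rng(seed)
    ys = np.arange(h)[:, None]
    xs = np.arange(w)[None, :]
    frames = np.empty((n_frames, h, w))
    # edge softness expressed in the elliptical radial coordinate
    s = edge_softness_px / min(a, b)
    for i, (cx, cy) in enumerate(traj):
        rho = np.sqrt(((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2)
        inside = _smoothstep((1.0 + s - rho) / (2.0 * s))
        frames[i] = background + (pupil_level - background) * inside
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    truth = GroundTruth(seed=seed, pupil_centers=traj, pupil_axes=(float(a), float(b)))
    return frames, truth


def generate_rotation_table_trace(
    speed_deg_s: float,
    direction: int = 1,
    duration_s: float = 1.0,
    fs: float = SAMPLING_RATE_HZ,
) -> EulerTrace:
    """Exact constant-velocity heading ramp, as from a motorized table."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    yaw = speed_deg_s * direction * t
    z = np.zeros(n)
    return EulerTrace(t, yaw, z, z)


def generate_site_grid_truth(
    base_amplitude_deg: float = 10.0,
    ap_gain_deg: float = 8.0,
    pitch_gain_deg: float = 5.0,
    roll_deg: float = 2.0,
) -> dict[int, tuple[float, float, float]]:
    """Characteristic vectors for a 3x3 fiber grid with an AP amplitude gradient.

    Sites are numbered 1..9 row-major; row index grows anterior -> posterior
    and yaw amplitude grows with it, emulating the topographic organization
    of orienting amplitude over the collicular surface.
    """
    vectors = {}
    for site in range(1, 10):
        r, c = divmod(site - 1, 3)
        yaw = base_amplitude_deg + ap_gain_deg * r
        pitch = -pitch_gain_deg * (c - 1)
        vectors[site] = (float(yaw), float(pitch), float(roll_deg))
    return vectors
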
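"""Segmentation of head-over-body Euler-angle traces into motion events.

Head orientation relative to the body is expressed as three Euler angles
sampled uniformly at 50 Hz: yaw (positive = head pointing right), pitch
(positive = up) and roll (positive = clockwise).  A *motion event* on one
axis is a sustained rotation in a constant direction: the angular velocity
must exceed a threshold (default 25 deg/s, i.e. 0.5 deg per 20 ms bin) for a
minimum number of consecutive bins (default 5, i.e. 100 ms).  The event is
then extended backward from its onset and forward from its offset to the
last contiguous bins that share the event's direction, and its extent is the
summed per-bin velocity over the refined span.

Angles are treated as unwrapped continuous signals; head-over-body
excursions are far below 360 deg so no modular arithmetic is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

AXES = ("yaw", "pitch", "roll")

#: default motion-event criteria
VELOCITY_THRESHOLD_DEG_S = 25.0
MIN_EVENT_BINS = 5


@dataclass
class EulerTrace:
    """Uniformly sampled head-over-body orientation time series.

    time is in seconds with a constant step (nominally 20 ms); yaw, pitch
    and roll are in degrees.
    """

    time: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        n = self.time.size
        if any(a.size != n for a in (self.yaw, self.pitch, self.roll)):
            raise ValueError("time and angle arrays must have equal length")
        if n >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(steps) > 1e-6:
                raise ValueError("sampling step must be constant within 1e-6 s")
        for name in AXES:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        """Sampling step in seconds."""
        if self.time.size < 2:
            return 0.02
        return float(self.time[1] - self.time[0])

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def angles(self, axis: str) -> np.ndarray:
        if axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
        return getattr(self, axis)

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t``."""
        return int(round((t - self.time[0]) / self.dt))


class Velocity(NamedTuple):
    """Per-bin angular velocity in both unit conventions (length n-1)."""

    deg_per_bin: np.ndarray
    deg_per_s: np.ndarray


@dataclass
class MotionEvent:
    """One sustained same-direction rotation on a single axis."""

    axis: str
    onset_index: int
    offset_index: int
    direction: int            # +1 or -1
    extent_deg: float         # summed per-bin velocity over the event
    duration_ms: float
    onset_time: float
    offset_time: float


@dataclass
class HistogramFit:
    """Peak-normalized displacement histogram with a Gaussian fit."""

    bin_edges: np.ndarray
    normalized_counts: np.ndarray
    gauss_peak: float
    gauss_mean: float
    gauss_sigma: float


@dataclass
class SensorValidation:
    """Inertial-sensor validation summary (static or rotation-table)."""

    jitter: float                       # mean |per-bin shift|, deg
    cumulative_drift: float             # last - first heading, deg
    expected_step: float = float("nan")  # deg per bin, rotation test only
    error_per_degree: float = float("nan")


def angular_velocity(trace: EulerTrace, axis: str) -> Velocity:
    """First-difference angular velocity of one Euler component.

    Returns per-bin displacement (deg/bin) and its rate (deg/s); the series
    has length n-1, bin ``i`` covering samples ``i -> i+1``.
    """
    if trace.n < 2:
        raise ValueError("trace must have at least 2 samples")
    x = trace.angles(axis)
    per_bin = np.diff(x)
    return Velocity(per_bin, per_bin / trace.dt)


def detect_motion_events(
    trace: EulerTrace,
    axis: str,
    threshold_deg_per_s: float = VELOCITY_THRESHOLD_DEG_S,
    min_bins: int = MIN_EVENT_BINS,
) -> list[MotionEvent]:
    """Detect motion events on one axis.

    A candidate is >= ``min_bins`` consecutive velocity bins of identical
    sign, each strictly faster than the threshold.  Onset and offset are then
    refined outward to the last contiguous bin sharing the event's direction
    (a zero-velocity bin terminates the run).  Candidates refined into the
    same direction run merge into a single event, so events are disjoint.
    """
    v = angular_velocity(trace, axis).deg_per_bin
    thr = threshold_deg_per_s * trace.dt  # deg per bin
    sign = np.sign(v).astype(int)
    fast = np.abs(v) > thr

    events: list[MotionEvent] = []
    n = v.size
    i = 0
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        # maximal constant-sign run [i, j)
        j = i
        while j < n and sign[j] == sign[i]:
            j += 1
        # qualifies iff it contains >= min_bins consecutive fast bins
        run_fast = fast[i:j]
        best = cur = 0
        for f in run_fast:
            cur = cur + 1 if f else 0
            best = max(best, cur)
        if best >= min_bins:
            extent = float(np.sum(v[i:j]))
            events.append(
                MotionEvent(
                    axis=axis,
                    onset_index=i,
                    offset_index=j,
                    direction=int(sign[i]),
                    extent_deg=extent,
                    duration_ms=(j - i) * trace.dt * 1000.0,
                    onset_time=float(trace.time[i]),
                    offset_time=float(trace.time[j]),
                )
            )
        i = j
    return events


def detect_motion_events_bruteforce(
    trace: EulerTrace,
    axis: str,
    threshold_deg_per_s: float = VELOCITY_THRESHOLD_DEG_S,
    min_bins: int = MIN_EVENT_BINS,
) -> list[MotionEvent]:
    """Oracle detector by exhaustive window enumeration.

    Scans every window of ``min_bins`` velocity bins; a window whose bins all
    share one nonzero sign and all exceed the threshold seeds an event, which
    is then expanded to the maximal constant-sign run containing it.
    Quadratic and independent of :func:`detect_motion_events`.
    """
    v = angular_velocity(trace, axis).deg_per_bin
    thr = threshold_deg_per_s * trace.dt
    n = v.size
    spans: set[tuple[int, int]] = set()
    for a in range(0, n - min_bins + 1):
        w = v[a : a + min_bins]
        s = np.sign(w[0])
        if s == 0 or np.any(np.sign(w) != s) or np.any(np.abs(w) <= thr):
            continue
        lo = a
        while lo > 0 and np.sign(v[lo - 1]) == s:
            lo -= 1
        hi = a + min_bins
        while hi < n and np.sign(v[hi]) == s:
            hi += 1
        spans.add((lo, hi))
    events = []
    for lo, hi in sorted(spans):
        events.append(
            MotionEvent(
                axis=axis,
                onset_index=lo,
                offset_index=hi,
                direction=int(np.sign(v[lo])),
                extent_deg=float(np.sum(v[lo:hi])),
                duration_ms=(hi - lo) * trace.dt * 1000.0,
                onset_time=float(trace.time[lo]),
                offset_time=float(trace.time[hi]),
            )
        )
    return events


def _gauss(x, peak, mu, sigma):
    return peak * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def displacement_histogram(
    displacements: Sequence[float] | np.ndarray,
    bin_width: float = 10.0,
) -> HistogramFit:
    """Peak-normalized histogram of displacements with Gaussian fit.

    Displacements (deg) are grouped into ``bin_width`` bins aligned to
    multiples of the bin width, counts are normalized to the modal bin, and a
    Gaussian is least-squares fitted to the normalized bin heights.
    """
    x = np.asarray(displacements, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 displacement samples")
    if np.ptp(x) == 0:
        raise ValueError("zero variance")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi == lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    norm = counts / counts.max()
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (1.0, float(np.mean(x)), max(float(np.std(x)), bin_width / 4))
    try:
        popt, _ = curve_fit(_gauss, centers, norm, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - fit failure is data-driven
        raise ValueError("Gaussian fit did not converge") from exc
    peak, mu, sigma = popt
    return HistogramFit(edges, norm, float(peak), float(mu), float(abs(sigma)))


def validate_static(trace: EulerTrace, axis: str = "yaw") -> SensorValidation:
    """Static sensor check: per-bin jitter and cumulative heading drift."""
    x = trace.angles(axis)
    if x.size < 2:
        raise ValueError("trace must have at least 2 samples")
    steps = np.diff(x)
    return SensorValidation(
        jitter=float(np.mean(np.abs(steps))),
        cumulative_drift=float(x[-1] - x[0]),
    )


def validate_rotation(
    trace: EulerTrace, true_speed_deg_s: float, axis: str = "yaw"
) -> SensorValidation:
    """Rotation-table check against the expected per-bin displacement.

    At 50 Hz the expected per-bin step is ``true_speed / 50`` (e.g. 28 deg/s
    -> 0.56 deg); the per-degree measurement error is the mean absolute
    deviation of the measured steps from that expectation, divided by it.
    """
    if true_speed_deg_s == 0:
        raise ValueError("true_speed must be nonzero")
    x = trace.angles(axis)
    if x.size < 2:
        raise ValueError("trace must have at least 2 samples")
    expected = true_speed_deg_s * trace.dt
    steps = np.diff(x)
    err = float(np.mean(np.abs(steps - expected)) / abs(expected))
    return SensorValidation(
        jitter=float(np.mean(np.abs(np.diff(steps)))) if steps.size > 1 else 0.0,
        cumulative_drift=float(x[-1] - x[0]),
        expected_step=float(expected),
        error_per_degree=err,
    )
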
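"""Scoring of optogenetic trials and stepwise saccade decomposition.

A trial is *successful* on an axis when a motion event starts within 2 s of
light onset.  Its amplitude is the extremal head-over-body deviation within
that window from the baseline position (the mean over the 1 s preceding
light onset), signed.  Prolonged stimulation produces staircase kinematics:
trials are baseline-subtracted and decomposed into steps whose onsets are
velocity crossings of 25 deg/s and whose terminations are velocity
inversions, velocity troughs between consecutive peaks, or the trial's
maximum attained displacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .kinematics import (
    AXES,
    EulerTrace,
    MotionEvent,
    VELOCITY_THRESHOLD_DEG_S,
    detect_motion_events,
)
from .synthetic import StimLog

SUCCESS_WINDOW_S = 2.0
BASELINE_WINDOW_S = 1.0
TROUGH_FRACTION = 0.5  # a |v| local minimum below this fraction of flanking peaks splits steps


@dataclass
class TrialResult:
    """Per-axis outcome of one light-stimulation trial."""

    index: int
    onset_s: float
    success: dict[str, bool]
    amplitude: dict[str, float]   # NaN when no event in window
    baseline: dict[str, float]

    @property
    def any_success(self) -> bool:
        return any(self.success.values())


@dataclass
class StepSegment:
    """One motion step inside a trial (indices into the trial window)."""

    onset_index: int
    termination_index: int
    amplitude_deg: float
    duration_ms: float
    peak_velocity_deg_s: float
    direction: int


@dataclass
class StepSummary:
    """Mean +- SEM step metrics, amplitudes relative to a characteristic vector."""

    n_trials: int
    mean_steps: float
    sem_steps: float
    mean_amplitude_deg: float
    sem_amplitude_deg: float
    mean_relative_amplitude: float
    mean_velocity_deg_s: float
    mean_duration_ms: float
    fraction_by_step_count: dict[int, float] = field(default_factory=dict)


def score_trials(
    trace: EulerTrace,
    stim: StimLog,
    events_by_axis: dict[str, list[MotionEvent]] | None = None,
    success_window_s: float = SUCCESS_WINDOW_S,
    baseline_window_s: float = BASELINE_WINDOW_S,
) -> list[TrialResult]:
    """Score each stimulation trial for success and movement amplitude.

    Success on an axis requires a detected motion event whose onset falls in
    ``(onset, onset + success_window]``.  Amplitude is the deviation of
    largest magnitude from the pre-onset baseline within that window, with
    its sign retained; it is reported only for successful axes.  Trials
    lacking full pre/post context in the trace are dropped with a warning.
    """
    if events_by_axis is None:
        events_by_axis = {a: detect_motion_events(trace, a) for a in AXES}
    results = []
    t0, t1 = trace.time[0], trace.time[-1]
    for k, onset in enumerate(np.asarray(stim.onsets, dtype=float)):
        if onset - baseline_window_s < t0 or onset + success_window_s > t1:
            warnings.warn(f"trial {k} at {onset} s lacks pre/post context; dropped")
            continue
        i_on = trace.index_of(onset)
        i_pre = trace.index_of(onset - baseline_window_s)
        i_post = trace.index_of(onset + success_window_s)
        success, amplitude, baseline = {}, {}, {}
        for axis in AXES:
            x = trace.angles(axis)
            base = float(np.mean(x[i_pre:i_on]))
            hit = any(
                onset < ev.onset_time <= onset + success_window_s
                for ev in events_by_axis[axis]
            )
            success[axis] = hit
            baseline[axis] = base
            if hit:
                dev = x[i_on : i_post + 1] - base
                amplitude[axis] = float(dev[np.argmax(np.abs(dev))])
            else:
                amplitude[axis] = float("nan")
        results.append(TrialResult(k, float(onset), success, amplitude, baseline))
    return results


def success_rate(trials: list[TrialResult], axis: str) -> float:
    if not trials:
        return float("nan")
    return float(np.mean([t.success[axis] for t in trials]))


def mean_successful_amplitude(trials: list[TrialResult], axis: str) -> float:
    """Mean light-triggered displacement over successful trials only."""
    amps = [t.amplitude[axis] for t in trials if t.success[axis]]
    return float(np.mean(amps)) if amps else float("nan")


def _trough_indices(speed: np.ndarray, v: np.ndarray, threshold: float, frac: float) -> set[int]:
    """Velocity-bin indices of |v| local minima splitting consecutive steps."""
    peaks, _ = find_peaks(speed, height=threshold)
    troughs: set[int] = set()
    for p, q in zip(peaks, peaks[1:]):
        if np.sign(v[p]) != np.sign(v[q]):
            continue  # an inversion boundary handles this pair
        j = p + 1 + int(np.argmin(speed[p + 1 : q]))
        if speed[j] < frac * min(speed[p], speed[q]):
            troughs.add(j)
    return troughs


def detect_steps(
    trace: EulerTrace,
    window: tuple[float, float],
    axis: str,
    threshold_deg_s: float = VELOCITY_THRESHOLD_DEG_S,
    trough_fraction: float = TROUGH_FRACTION,
    baseline_window_s: float = BASELINE_WINDOW_S,
) -> list[StepSegment]:
    """Decompose one trial window into stepwise movements.

    The trial is baseline-subtracted (mean position over the second
    preceding the window).  Step onsets are the moments head speed exceeds
    the threshold; terminations are, whichever comes first, a velocity
    inversion, a speed trough between consecutive speed peaks falling below
    ``trough_fraction`` of both flanking peaks, or the point of maximum
    displacement attained during the trial.  A step ending while speed is
    still above threshold seeds the next step at its termination, so steps
    tile movement epochs without overlap.
    """
    i0 = max(trace.index_of(window[0]), 0)
    i1 = min(trace.index_of(window[1]), trace.n - 1)
    if i1 - i0 < 2:
        return []
    x = trace.angles(axis)
    b0 = max(trace.index_of(window[0] - baseline_window_s), 0)
    base = float(np.mean(x[b0:i0])) if i0 > b0 else float(x[i0])
    pos = x[i0 : i1 + 1] - base
    return segment_steps(pos, trace.dt, threshold_deg_s, trough_fraction)


def segment_steps(
    pos: np.ndarray,
    dt: float,
    threshold_deg_s: float = VELOCITY_THRESHOLD_DEG_S,
    trough_fraction: float = TROUGH_FRACTION,
) -> list[StepSegment]:
    """Step decomposition of a baseline-subtracted position array."""
    pos = np.asarray(pos, dtype=float)
    if pos.size < 3:
        return []
    v = np.diff(pos) / dt
    speed = np.abs(v)
    nb = v.size
    troughs = _trough_indices(speed, v, threshold_deg_s, trough_fraction)
    steps: list[StepSegment] = []
    j = 0
    onset: int | None = None
    while j < nb:
        if onset is None:
            if speed[j] > threshold_deg_s:
                onset = j
            else:
                j += 1
                continue
        d = int(np.sign(v[onset]))
        term = None
        k = onset + 1
        while k < nb:
            if np.sign(v[k]) == -d and speed[k] > 0:
                term = k  # velocity inverted direction
                break
            if k in troughs:
                term = k  # speed minimum between consecutive steps
                break
            k += 1
        if term is None:
            # final step: terminate at the maximum displacement attained
            rel = d * (pos[onset:] - pos[onset])
            term = onset + int(np.argmax(rel))
            if term <= onset:
                break
        steps.append(
            StepSegment(
                onset_index=onset,
                termination_index=term,
                amplitude_deg=float(pos[term] - pos[onset]),
                duration_ms=(term - onset) * dt * 1000.0,
                peak_velocity_deg_s=float(np.max(speed[onset:term])),
                direction=d,
            )
        )
        # continue from the termination: if still moving, it seeds the next step
        if term < nb and speed[term] > threshold_deg_s:
            onset = term
            j = term
        else:
            onset = None
            j = term + 1
    return steps


def step_count_table(steps_per_trial: list[int]) -> dict[int, float]:
    """Fraction of trials presenting each step count."""
    if not steps_per_trial:
        return {}
    counts = np.asarray(steps_per_trial)
    return {
        int(k): float(np.mean(counts == k)) for k in sorted(set(steps_per_trial))
    }


def step_statistics(
    steps_by_trial: list[list[StepSegment]],
    characteristic_vector_deg: float,
) -> StepSummary | None:
    """Mean +- SEM of steps/trial, amplitude, velocity and duration.

    Amplitudes are additionally reported relative to the site's
    characteristic vector (the single-step displacement from a brief 250 ms
    stimulus), as a ratio.
    """
    if characteristic_vector_deg == 0:
        raise ValueError("characteristic vector must be nonzero")
    all_steps = [s for trial in steps_by_trial for s in trial]
    if not all_steps:
        return None
    n_steps = np.array([len(trial) for trial in steps_by_trial], dtype=float)
    amps = np.array([s.amplitude_deg for s in all_steps])
    vels = np.array([s.peak_velocity_deg_s for s in all_steps])
    durs = np.array([s.duration_ms for s in all_steps])

    def sem(a: np.ndarray) -> float:
        return float(np.std(a, ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0

    return StepSummary(
        n_trials=len(steps_by_trial),
        mean_steps=float(np.mean(n_steps)),
        sem_steps=sem(n_steps),
        mean_amplitude_deg=float(np.mean(amps)),
        sem_amplitude_deg=sem(amps),
        mean_relative_amplitude=float(np.mean(amps / characteristic_vector_deg)),
        mean_velocity_deg_s=float(np.mean(vels)),
        mean_duration_ms=float(np.mean(durs)),
        fraction_by_step_count=step_count_table([len(t) for t in steps_by_trial]),
    )
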
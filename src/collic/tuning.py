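"""Spike/light-triggered movement tuning with wrap-around permutation nulls.

The spike-triggered average (STA) aligns head displacement to spike onsets:
for every trigger with full context, the angular velocity over the 50 bins
(1 s) preceding and 100 bins (2 s) following the trigger is cumulatively
summed into a displacement curve zeroed at the trigger.  Each trigger's
*displacement vector* is max - min of its curve, signed positive when the
minimum precedes the maximum; the unit's vector is the mean over triggers.
The light-triggered average (LTA) uses light onsets in place of spikes.

The null distribution is built by circularly shifting spike times by a
uniform random 20-150 s (wrap-around, preserving spike count and the
inter-spike interval structure up to the single wrap point) and recomputing
the mean displacement vector; 1000 repetitions by default.

A unit is *tuned* on an axis when its vector differs significantly (t test,
alpha 0.05) from the null mean in both light epochs and points in the same
direction in both.  Optotagged units are identified by sub-5-ms first-spike
latency to light pulses.  Firing onset relative to movement is the first run
of consecutive bins in which the movement-onset-triggered rate exceeds a
z-score criterion against the shuffled null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kinematics import EulerTrace, MotionEvent
from .synthetic import SpikeTrain, StimLog

STA_PRE_BINS = 50
STA_POST_BINS = 100
SHIFT_RANGE_S = (20.0, 150.0)
N_SHUFFLES = 1000
OPTOTAG_WINDOW_MS = 5.0
ONSET_Z = 1.96
ONSET_CONSECUTIVE_BINS = 3


@dataclass
class TriggeredAverage:
    """Mean displacement around triggers for one Euler component."""

    axis: str
    curve: np.ndarray             # mean displacement, (pre+post+1,), deg
    sem: np.ndarray
    n_triggers: int
    trigger_vectors: np.ndarray   # per-trigger signed min-max vectors, deg
    displacement_vector: float    # mean of trigger_vectors, deg
    pre_bins: int = STA_PRE_BINS
    post_bins: int = STA_POST_BINS

    @property
    def lags_s(self) -> np.ndarray:
        dt = 1.0 / 50.0
        return np.arange(-self.pre_bins, self.post_bins + 1) * dt


@dataclass
class ShuffleNull:
    """Mean displacement vectors from wrap-around shifted spike trains."""

    axis: str
    vectors: np.ndarray           # (n_shuffles,)
    shifts_s: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.vectors))

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.vectors, q))


@dataclass
class OptotagResult:
    tagged: bool
    median_latency_ms: float
    response_probability: float
    psth_edges_ms: np.ndarray
    psth_rate_hz: np.ndarray
    raster: list[np.ndarray]      # per-pulse spike latencies, ms


@dataclass
class TuningResult:
    axis: str
    tuned: bool
    p_values: dict[str, float]
    epoch_vectors: dict[str, float]
    characteristic_angle_deg: float


@dataclass
class FiringOnset:
    significant: bool
    onset_ms: float               # NaN when not significant
    lags_s: np.ndarray
    rate_hz: np.ndarray
    z: np.ndarray


@dataclass
class StaLtaComparison:
    axis: str
    direction_agreement: bool
    vector_difference_deg: float
    p_value: float


def _valid_trigger_indices(
    n_samples: int, trigger_idx: np.ndarray, pre: int, post: int
) -> np.ndarray:
    ok = (trigger_idx - pre >= 0) & (trigger_idx + post <= n_samples - 1)
    return trigger_idx[ok]


def _window_matrix(pos: np.ndarray, idx: np.ndarray, pre: int, post: int) -> np.ndarray:
    offs = np.arange(-pre, post + 1)
    M = pos[idx[:, None] + offs[None, :]]
    return M - M[:, pre][:, None]


def _signed_vectors(M: np.ndarray) -> np.ndarray:
    mx = M.max(axis=1)
    mn = M.min(axis=1)
    order = np.where(M.argmin(axis=1) < M.argmax(axis=1), 1.0, -1.0)
    return (mx - mn) * order


def triggered_average(
    trace: EulerTrace,
    trigger_times_s: np.ndarray,
    axis: str,
    pre_bins: int = STA_PRE_BINS,
    post_bins: int = STA_POST_BINS,
) -> TriggeredAverage:
    """Spike- or light-triggered average displacement on one axis.

    Triggers without full pre/post context are dropped; raises when none
    remain.
    """
    pos = trace.angles(axis)
    idx = np.round(
        (np.asarray(trigger_times_s, dtype=float) - trace.time[0]) / trace.dt
    ).astype(int)
    idx = _valid_trigger_indices(trace.n, idx, pre_bins, post_bins)
    if idx.size == 0:
        raise ValueError("no triggers with full pre/post context")
    M = _window_matrix(pos, idx, pre_bins, post_bins)
    vec = _signed_vectors(M)
    sem = (
        np.std(M, axis=0, ddof=1) / np.sqrt(M.shape[0])
        if M.shape[0] > 1
        else np.zeros(M.shape[1])
    )
    return TriggeredAverage(
        axis=axis,
        curve=M.mean(axis=0),
        sem=sem,
        n_triggers=int(idx.size),
        trigger_vectors=vec,
        displacement_vector=float(vec.mean()),
        pre_bins=pre_bins,
        post_bins=post_bins,
    )


def shuffle_null(
    trace: EulerTrace,
    unit: SpikeTrain,
    axis: str,
    n_shuffles: int = N_SHUFFLES,
    shift_range_s: tuple[float, float] = SHIFT_RANGE_S,
    seed: int = 0,
    pre_bins: int = STA_PRE_BINS,
    post_bins: int = STA_POST_BINS,
) -> ShuffleNull:
    """Permutation null of mean displacement vectors via wrap-around shifts.

    Each repetition shifts every spike time by the same uniform random
    amount in ``shift_range_s``, wraps modulo the session length, and
    recomputes the mean displacement vector.  Spike count is preserved
    exactly; the inter-spike interval multiset is preserved up to the single
    wrap point.
    """
    session = unit.session_length_s or float(trace.time[-1])
    if session <= shift_range_s[1]:
        raise ValueError("session must be longer than the maximum shift")
    rng = np.random.default_rng(seed)
    pos = trace.angles(axis)
    t0 = trace.time[0]
    shifts = rng.uniform(shift_range_s[0], shift_range_s[1], size=n_shuffles)
    vectors = np.empty(n_shuffles)
    for k, s in enumerate(shifts):
        shifted = (unit.times + s) % session
        idx = np.round((shifted - t0) / trace.dt).astype(int)
        idx = _valid_trigger_indices(trace.n, idx, pre_bins, post_bins)
        if idx.size == 0:
            vectors[k] = np.nan
            continue
        M = _window_matrix(pos, idx, pre_bins, post_bins)
        vectors[k] = _signed_vectors(M).mean()
    return ShuffleNull(axis=axis, vectors=vectors, shifts_s=shifts)


def optotag(
    unit: SpikeTrain,
    light_pulses: StimLog,
    latency_window_ms: float = OPTOTAG_WINDOW_MS,
    min_response_probability: float = 0.5,
    psth_bin_ms: float = 1.0,
    psth_window_ms: tuple[float, float] = (-10.0, 25.0),
) -> OptotagResult:
    """Classify a unit as light-activated from first-spike latencies.

    Tagged iff the median first-spike latency after pulse onset is below the
    latency window (5 ms) and the fraction of pulses answered within that
    window exceeds ``min_response_probability``.
    """
    pulses = np.asarray(light_pulses.onsets, dtype=float)
    if pulses.size == 0:
        raise ValueError("no light pulses")
    times = unit.times
    lat_ms = []
    raster = []
    for p in pulses:
        rel = (times - p) * 1000.0
        raster.append(rel[(rel >= psth_window_ms[0]) & (rel <= psth_window_ms[1])])
        after = rel[rel >= 0]
        lat_ms.append(after[0] if after.size else np.nan)
    lat_ms = np.asarray(lat_ms)
    responded = lat_ms < latency_window_ms
    prob = float(np.mean(responded))
    med = float(np.nanmedian(lat_ms)) if np.any(np.isfinite(lat_ms)) else float("nan")
    edges = np.arange(psth_window_ms[0], psth_window_ms[1] + psth_bin_ms, psth_bin_ms)
    counts, edges = np.histogram(np.concatenate(raster), bins=edges)
    rate = counts / (pulses.size * psth_bin_ms / 1000.0)
    tagged = bool(np.isfinite(med) and med < latency_window_ms and prob >= min_response_probability)
    return OptotagResult(tagged, med, prob, edges, rate, raster)


def characteristic_angle(
    events: list[MotionEvent], spike_times: np.ndarray, window_s: float = 2.0
) -> float:
    """Mean extent of motion events whose onset follows a spike within the window."""
    onsets = np.array([ev.onset_time for ev in events])
    extents = np.array([ev.extent_deg for ev in events])
    pooled = []
    for t in np.asarray(spike_times, dtype=float):
        m = (onsets > t) & (onsets <= t + window_s)
        pooled.extend(extents[m])
    return float(np.mean(pooled)) if pooled else float("nan")


def classify_tuning(
    epoch_averages: dict[str, TriggeredAverage],
    null: ShuffleNull,
    alpha: float = 0.05,
    characteristic_angle_deg: float = float("nan"),
) -> TuningResult:
    """Tuning decision from two light-epoch averages and the shuffled null.

    Per epoch, a one-sample t test compares the per-trigger displacement
    vectors against the null's mean vector; the unit is tuned when both
    epochs are significant at ``alpha`` and their mean vectors share a sign.
    """
    if len(epoch_averages) < 2:
        raise ValueError("two light epochs are required")
    null_mean = np.nanmean(null.vectors)
    p_values, signs, vectors = {}, [], {}
    for name, avg in epoch_averages.items():
        res = stats.ttest_1samp(avg.trigger_vectors, popmean=null_mean)
        p_values[name] = float(res.pvalue)
        vectors[name] = avg.displacement_vector
        signs.append(np.sign(avg.displacement_vector - null_mean))
    tuned = all(p < alpha for p in p_values.values()) and len(set(signs)) == 1
    axis = next(iter(epoch_averages.values())).axis
    return TuningResult(axis, bool(tuned), p_values, vectors, characteristic_angle_deg)


def _rate_curve(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    edges_s: np.ndarray,
) -> np.ndarray:
    rel = spike_times[None, :] - onsets[:, None]
    counts, _ = np.histogram(rel, bins=edges_s)
    bin_s = edges_s[1] - edges_s[0]
    return counts / (onsets.size * bin_s)


def firing_onset(
    unit: SpikeTrain,
    movement_onsets_s: np.ndarray,
    bin_s: float = 0.02,
    window_s: tuple[float, float] = (-1.0, 1.0),
    n_shuffles: int = 200,
    shift_range_s: tuple[float, float] = SHIFT_RANGE_S,
    z_criterion: float = ONSET_Z,
    n_consecutive: int = ONSET_CONSECUTIVE_BINS,
    seed: int = 0,
) -> FiringOnset:
    """Time of firing-rate rise around movement onset, against a shuffled null.

    The movement-onset-triggered rate (20 ms bins, -1..+1 s) is z-scored per
    bin against rate curves from wrap-around shifted spike trains; the onset
    is the first bin of the earliest run of at least ``n_consecutive`` bins
    with z above the criterion.
    """
    onsets = np.asarray(movement_onsets_s, dtype=float)
    if onsets.size < 20:
        raise ValueError("need at least 20 movement onsets")
    session = unit.session_length_s
    if session <= shift_range_s[1]:
        raise ValueError("session must be longer than the maximum shift")
    rng = np.random.default_rng(seed)
    edges = np.arange(window_s[0], window_s[1] + bin_s / 2, bin_s)
    real = _rate_curve(unit.times, onsets, edges)
    null = np.empty((n_shuffles, real.size))
    for k in range(n_shuffles):
        s = rng.uniform(*shift_range_s)
        null[k] = _rate_curve((unit.times + s) % session, onsets, edges)
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = (real - mu) / sd
    lags = edges[:-1]  # bin start, s
    hot = z > z_criterion
    onset_ms = float("nan")
    significant = False
    run = 0
    for i, h in enumerate(hot):
        run = run + 1 if h else 0
        if run >= n_consecutive:
            significant = True
            onset_ms = float(lags[i - n_consecutive + 1] * 1000.0)
            break
    return FiringOnset(significant, onset_ms, lags, real, z)


def sta_lta_compare(sta: TriggeredAverage, lta: TriggeredAverage) -> StaLtaComparison:
    """Direction agreement and vector difference between STA and LTA."""
    if sta.axis != lta.axis:
        raise ValueError("STA and LTA must be for the same axis")
    agree = np.sign(sta.displacement_vector) == np.sign(lta.displacement_vector)
    if sta.n_triggers > 1 and lta.n_triggers > 1:
        res = stats.ttest_ind(
            sta.trigger_vectors, lta.trigger_vectors, equal_var=False
        )
        p = float(res.pvalue)
    else:
        p = float("nan")
    return StaLtaComparison(
        axis=sta.axis,
        direction_agreement=bool(agree),
        vector_difference_deg=float(
            sta.displacement_vector - lta.displacement_vector
        ),
        p_value=p,
    )
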
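"""Pupil detection and eye-movement amplitude from grayscale frames.

Each frame is low-pass filtered, the pupil outline is extracted as the
level-crossing contour at a configurable intensity (midpoint of the frame's
range by default), and an ellipse is least-squares fitted to the outline.
The angular amplitude of an eye movement is alpha = arcsin(d / r), where d
is the pupil-center excursion from rest and r the eye radius (the eye
approximated as a sphere); alpha is signed by the horizontal direction of
the excursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import EllipseModel, find_contours

from . import tuning
from .synthetic import StimLog


@dataclass
class PupilFit:
    """Ellipse fitted to one frame's pupil outline."""

    center_x: float
    center_y: float
    axis_a: float            # semi-axis along the fitted major direction
    axis_b: float
    angle_rad: float
    area_px2: float


@dataclass
class PupilTrace:
    """Per-frame pupil geometry; NaN rows where detection failed."""

    time_s: np.ndarray
    center_x: np.ndarray
    center_y: np.ndarray
    axis_a: np.ndarray
    axis_b: np.ndarray
    area_px2: np.ndarray
    detected: np.ndarray

    @property
    def fs(self) -> float:
        if self.time_s.size < 2:
            raise ValueError("need at least two frames for a frame rate")
        return 1.0 / float(self.time_s[1] - self.time_s[0])


def fit_pupil(
    frame: np.ndarray,
    level: float | None = None,
    smoothing_sigma_px: float = 1.0,
) -> PupilFit | None:
    """Fit an ellipse to the pupil outline of one grayscale frame.

    ``level`` is the edge-detection intensity; defaults to the midpoint of
    the filtered frame's range.  Returns None (frame undetected) when fewer
    than 6 outline points are found or the fit fails.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be 2D grayscale")
    if smoothing_sigma_px > 0:
        img = gaussian_filter(img, smoothing_sigma_px)
    if level is None:
        level = 0.5 * (img.min() + img.max())
    contours = find_contours(img, level)
    if not contours:
        return None
    outline = max(contours, key=len)  # (row, col) points
    if outline.shape[0] < 6:
        return None
    pts = outline[:, ::-1]  # -> (x, y)
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            return None
        xc, yc = model.center
        a, b = model.axis_lengths
        theta = model.theta
    else:  # older scikit-image
        model = EllipseModel()
        if not model.estimate(pts):
            return None
        xc, yc, a, b, theta = model.params
    return PupilFit(
        center_x=float(xc),
        center_y=float(yc),
        axis_a=float(a),
        axis_b=float(b),
        angle_rad=float(theta),
        area_px2=float(np.pi * a * b),
    )


def track_pupil(
    frames: np.ndarray,
    fs: float = 50.0,
    level: float | None = None,
    smoothing_sigma_px: float = 1.0,
) -> PupilTrace:
    """Fit every frame of an (n, h, w) stack into a pupil trace."""
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    cols = {k: np.full(n, np.nan) for k in ("cx", "cy", "a", "b", "area")}
    detected = np.zeros(n, dtype=bool)
    for i in range(n):
        fit = fit_pupil(frames[i], level=level, smoothing_sigma_px=smoothing_sigma_px)
        if fit is None:
            continue
        detected[i] = True
        cols["cx"][i] = fit.center_x
        cols["cy"][i] = fit.center_y
        cols["a"][i] = fit.axis_a
        cols["b"][i] = fit.axis_b
        cols["area"][i] = fit.area_px2
    return PupilTrace(
        time_s=np.arange(n) / fs,
        center_x=cols["cx"],
        center_y=cols["cy"],
        axis_a=cols["a"],
        axis_b=cols["b"],
        area_px2=cols["area"],
        detected=detected,
    )


def eye_amplitude(
    trace: PupilTrace,
    rest_position_px: tuple[float, float],
    eye_radius_px: float,
) -> np.ndarray:
    """Angular eye-movement amplitude alpha = arcsin(d/r) in degrees.

    d is the Euclidean excursion of the pupil center from rest; the sign
    follows the horizontal direction of the excursion.  Samples with d > r
    (or undetected frames) are flagged NaN.
    """
    if eye_radius_px <= 0:
        raise ValueError("eye radius must be positive")
    dx = trace.center_x - rest_position_px[0]
    dy = trace.center_y - rest_position_px[1]
    d = np.hypot(dx, dy)
    alpha = np.full(d.shape, np.nan)
    ok = trace.detected & (d <= eye_radius_px)
    alpha[ok] = np.degrees(np.arcsin(d[ok] / eye_radius_px)) * np.where(
        dx[ok] < 0, -1.0, 1.0
    )
    return alpha


def rest_position(
    trace: PupilTrace, stim: StimLog, baseline_window_s: float = 1.0
) -> tuple[float, float]:
    """Median pupil center over the pre-stimulus baseline windows."""
    mask = np.zeros(trace.time_s.size, dtype=bool)
    for onset in stim.onsets:
        mask |= (trace.time_s >= onset - baseline_window_s) & (trace.time_s < onset)
    mask &= trace.detected
    if not np.any(mask):
        raise ValueError("no detected frames in the baseline windows")
    return (
        float(np.median(trace.center_x[mask])),
        float(np.median(trace.center_y[mask])),
    )


def eye_lta(
    trace: PupilTrace,
    stim: StimLog,
    eye_radius_px: float,
    rest_px: tuple[float, float] | None = None,
    pre_s: float = 1.0,
    post_s: float = 2.0,
) -> dict[str, tuning.TriggeredAverage]:
    """Light-triggered average of eye angle and pupil area (dilation).

    Reuses the head-movement triggered-average machinery on the alpha and
    area series; the area curve is zeroed at light onset so positive values
    indicate dilation relative to the pre-stimulus state.
    """
    if rest_px is None:
        rest_px = rest_position(trace, stim)
    fs = trace.fs
    alpha = eye_amplitude(trace, rest_px, eye_radius_px)
    pre = int(round(pre_s * fs))
    post = int(round(post_s * fs))
    out = {}
    for name, series in (("alpha_deg", alpha), ("area_px2", trace.area_px2)):
        series = np.nan_to_num(series, nan=np.nanmedian(series))
        fake = _series_average(series, trace.time_s, stim.onsets, pre, post, name)
        out[name] = fake
    return out


def _series_average(
    series: np.ndarray,
    time_s: np.ndarray,
    trigger_times: np.ndarray,
    pre: int,
    post: int,
    axis_name: str,
) -> tuning.TriggeredAverage:
    dt = float(time_s[1] - time_s[0])
    idx = np.round((np.asarray(trigger_times) - time_s[0]) / dt).astype(int)
    idx = tuning._valid_trigger_indices(series.size, idx, pre, post)
    if idx.size == 0:
        raise ValueError("no triggers with full pre/post context")
    M = tuning._window_matrix(series, idx, pre, post)
    vec = tuning._signed_vectors(M)
    sem = (
        np.std(M, axis=0, ddof=1) / np.sqrt(M.shape[0])
        if M.shape[0] > 1
        else np.zeros(M.shape[1])
    )
    return tuning.TriggeredAverage(
        axis=axis_name,
        curve=M.mean(axis=0),
        sem=sem,
        n_triggers=int(idx.size),
        trigger_vectors=vec,
        displacement_vector=float(vec.mean()),
        pre_bins=pre,
        post_bins=post,
    )
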
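"""Topographic motor maps from multi-fiber stimulation and their magnification.

Nine stimulation sites on a 3 x 3 grid (500 um fiber pitch) each carry a
characteristic movement vector (yaw, pitch, roll), the per-site mean over
successful trials.  Maps may be smoothed with a Gaussian kernel (250 um
default), differentiated with central differences to give per-site gradient
fields (deg/mm), and combined into the magnification factor

    M = 1 / |det J|,   J = [[dY/dx, dY/dy], [dP/dx, dP/dy]]

in mm^2/deg^2, i.e. the collicular surface area representing a unit of
(yaw, pitch) motor angle.  Sites where the Jacobian is singular are flagged
undefined rather than reported as infinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .optostim import TrialResult

GRID_PITCH_MM = 0.5
SMOOTH_SIGMA_UM = 250.0


@dataclass
class SiteVectorMap:
    """Per-site characteristic movement vectors on the fiber grid.

    x (ML) and y (AP) are site coordinates in mm; yaw/pitch/roll are (3, 3)
    arrays indexed [row (AP), col (ML)], in degrees.
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    n_trials: np.ndarray
    missing: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=bool))

    def component(self, name: str) -> np.ndarray:
        if name not in ("yaw", "pitch", "roll"):
            raise ValueError(f"unknown component {name!r}")
        return getattr(self, name)


@dataclass
class GradientField:
    """Spatial gradients of the yaw/pitch/roll maps, deg/mm per site."""

    dY_dx: np.ndarray
    dY_dy: np.ndarray
    dP_dx: np.ndarray
    dP_dy: np.ndarray
    dR_dx: np.ndarray
    dR_dy: np.ndarray

    def magnitude(self, component: str) -> np.ndarray:
        gx = getattr(self, f"d{component}_dx")
        gy = getattr(self, f"d{component}_dy")
        return np.hypot(gx, gy)

    def direction_rad(self, component: str) -> np.ndarray:
        gx = getattr(self, f"d{component}_dx")
        gy = getattr(self, f"d{component}_dy")
        return np.arctan2(gy, gx)


@dataclass
class MagnificationMap:
    """Inverse |Jacobian determinant| of the (yaw, pitch) map, mm^2/deg^2."""

    magnification: np.ndarray     # NaN where undefined
    undefined: np.ndarray         # bool mask where |det J| below tolerance
    det_j: np.ndarray


def build_site_map(
    site_trials: dict[int, list[TrialResult]] | dict[int, np.ndarray],
    pitch_mm: float = GRID_PITCH_MM,
    normalize_to: int | None = None,
) -> SiteVectorMap:
    """Average successful-trial movement vectors onto the 3 x 3 fiber grid.

    ``site_trials`` maps site ids 1..9 (row-major, row = AP, col = ML) to
    either scored :class:`TrialResult` lists or (n, 3) arrays of
    (yaw, pitch, roll) amplitudes.  Sites with no successful trial are
    marked missing.  With ``normalize_to`` set, every component is divided
    by the magnitude of that site's value for the same component.
    """
    coords = np.arange(3) * pitch_mm
    maps = {c: np.full((3, 3), np.nan) for c in ("yaw", "pitch", "roll")}
    n_trials = np.zeros((3, 3), dtype=int)
    missing = np.ones((3, 3), dtype=bool)
    for site in range(1, 10):
        if site not in site_trials:
            continue
        r, c = divmod(site - 1, 3)
        entry = site_trials[site]
        if len(entry) and isinstance(entry[0], TrialResult):
            rows = [
                [t.amplitude[a] for a in ("yaw", "pitch", "roll")]
                for t in entry
                if t.any_success
            ]
            arr = np.asarray(rows, dtype=float)
        else:
            arr = np.asarray(entry, dtype=float).reshape(-1, 3)
        if arr.size == 0:
            continue
        with np.errstate(invalid="ignore"):
            means = np.nanmean(arr, axis=0)
        for k, comp in enumerate(("yaw", "pitch", "roll")):
            maps[comp][r, c] = means[k]
        n_trials[r, c] = arr.shape[0]
        missing[r, c] = not np.any(np.isfinite(means))
    m = SiteVectorMap(
        x_mm=coords.copy(),
        y_mm=coords.copy(),
        yaw=maps["yaw"],
        pitch=maps["pitch"],
        roll=maps["roll"],
        n_trials=n_trials,
        missing=missing,
    )
    if normalize_to is not None:
        r, c = divmod(normalize_to - 1, 3)
        for comp in ("yaw", "pitch", "roll"):
            ref = abs(m.component(comp)[r, c])
            if ref > 0:
                setattr(m, comp, m.component(comp) / ref)
    return m


def interpolate_missing(m: SiteVectorMap) -> SiteVectorMap:
    """Fill missing sites with the mean of their valid 4-neighbors."""
    out = replace(m)
    for comp in ("yaw", "pitch", "roll"):
        a = m.component(comp).copy()
        bad = ~np.isfinite(a)
        for r, c in zip(*np.where(bad)):
            vals = [
                a[rr, cc]
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                if 0 <= rr < 3 and 0 <= cc < 3 and np.isfinite(a[rr, cc])
            ]
            if not vals:
                raise ValueError(f"cannot interpolate site at ({r}, {c})")
            a[r, c] = np.mean(vals)
        setattr(out, comp, a)
    return out


def smooth_map(
    m: SiteVectorMap,
    kernel_um: float = SMOOTH_SIGMA_UM,
    spacing_um: float = GRID_PITCH_MM * 1000.0,
    interpretation: str = "sigma",
) -> SiteVectorMap:
    """Gaussian smoothing of each component on the fiber grid.

    ``kernel_um`` is the Gaussian sigma by default; pass
    ``interpretation="fwhm"`` to treat it as full width at half maximum.
    Reflective boundaries preserve the map mean exactly for a symmetric
    kernel.
    """
    if kernel_um <= 0:
        raise ValueError("kernel width must be positive")
    if np.any(~np.isfinite(m.yaw)) or np.any(~np.isfinite(m.pitch)):
        raise ValueError("map has missing sites; interpolate first")
    sigma_um = kernel_um
    if interpretation == "fwhm":
        sigma_um = kernel_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    elif interpretation != "sigma":
        raise ValueError("interpretation must be 'sigma' or 'fwhm'")
    sig = sigma_um / spacing_um
    out = replace(m)
    for comp in ("yaw", "pitch", "roll"):
        setattr(out, comp, gaussian_filter(m.component(comp), sig, mode="reflect"))
    return out


def gradient_field(m: SiteVectorMap, spacing_mm: float = GRID_PITCH_MM) -> GradientField:
    """Finite-difference gradients: central interior, one-sided at edges."""
    grads = {}
    for comp, tag in (("yaw", "Y"), ("pitch", "P"), ("roll", "R")):
        a = m.component(comp)
        d_dy, d_dx = np.gradient(a, spacing_mm)  # rows = y (AP), cols = x (ML)
        grads[f"d{tag}_dx"] = d_dx
        grads[f"d{tag}_dy"] = d_dy
    return GradientField(**grads)


def magnification(grad: GradientField, tol: float = 1e-9) -> MagnificationMap:
    """Magnification factor 1/|det J| from the yaw and pitch gradients."""
    det = grad.dY_dx * grad.dP_dy - grad.dY_dy * grad.dP_dx
    undefined = np.abs(det) < tol
    mag = np.full(det.shape, np.nan)
    mag[~undefined] = 1.0 / np.abs(det[~undefined])
    return MagnificationMap(magnification=mag, undefined=undefined, det_j=det)
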
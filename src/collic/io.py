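"""Readers and writers for the pipeline's plain-text and TIFF artifacts.

CSV columns follow the documented contracts:

* trace:      ``time_s, yaw_deg, pitch_deg, roll_deg``
* events:     ``axis, onset_s, offset_s, direction, extent_deg, duration_ms``
* stim log:   ``onset_s, duration_s, frequency_hz, site``
* spikes:     ``unit_id, spike_time_s, epoch``
* site map:   ``site, x_mm, y_mm, yaw_deg, pitch_deg, roll_deg, n_trials``
* centroids:  ``x_um, y_um, nn_dist_um``
* pupil:      ``time_s, center_x_px, center_y_px, axis_a_px, axis_b_px, area_px2, detected``

Floats are written with pandas' default (shortest round-tripping) repr, so a
write-then-read cycle reproduces in-memory float64 values exactly.  An
optional header comment line (prefixed ``#``) carries provenance (config
hash, seed); readers skip it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .eyetrack import PupilTrace
from .kinematics import EulerTrace, MotionEvent
from .motormap import SiteVectorMap
from .periodicity import CentroidSet, DensityVolume
from .synthetic import SpikeTrain, StimLog


def _write_csv(df: pd.DataFrame, path, header_comment: str | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def write_trace_csv(trace: EulerTrace, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "yaw_deg": trace.yaw,
            "pitch_deg": trace.pitch,
            "roll_deg": trace.roll,
        }
    )
    _write_csv(df, path, header_comment)


def read_trace_csv(path) -> EulerTrace:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return EulerTrace(
        df["time_s"].to_numpy(),
        df["yaw_deg"].to_numpy(),
        df["pitch_deg"].to_numpy(),
        df["roll_deg"].to_numpy(),
    )


def write_events_csv(
    events: list[MotionEvent], path, header_comment: str | None = None
) -> None:
    df = pd.DataFrame(
        {
            "axis": [e.axis for e in events],
            "onset_s": [e.onset_time for e in events],
            "offset_s": [e.offset_time for e in events],
            "direction": [e.direction for e in events],
            "extent_deg": [e.extent_deg for e in events],
            "duration_ms": [e.duration_ms for e in events],
        }
    )
    _write_csv(df, path, header_comment)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_stim_csv(stim: StimLog, path, header_comment: str | None = None) -> None:
    freq = -1.0 if stim.frequency == "continuous" else float(stim.frequency)
    df = pd.DataFrame(
        {
            "onset_s": stim.onsets,
            "duration_s": stim.duration_s,
            "frequency_hz": freq,
            "site": stim.site,
        }
    )
    _write_csv(df, path, header_comment)


def read_stim_csv(path) -> StimLog:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        return StimLog(onsets=np.empty(0), duration_s=0.0)
    freq = df["frequency_hz"].iloc[0]
    return StimLog(
        onsets=df["onset_s"].to_numpy(),
        duration_s=float(df["duration_s"].iloc[0]),
        frequency="continuous" if freq < 0 else float(freq),
        site=int(df["site"].iloc[0]),
    )


def write_spikes_csv(unit: SpikeTrain, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "unit_id": unit.unit_id,
            "spike_time_s": unit.times,
            "epoch": unit.epoch,
        }
    )
    _write_csv(df, path, header_comment)


def read_spikes_csv(path, session_length_s: float = 0.0) -> list[SpikeTrain]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    units = []
    for (uid, epoch), grp in df.groupby(["unit_id", "epoch"], sort=True):
        units.append(
            SpikeTrain(
                unit_id=str(uid),
                times=grp["spike_time_s"].to_numpy(),
                epoch=str(epoch),
                session_length_s=session_length_s,
            )
        )
    return units


def write_site_map_csv(m: SiteVectorMap, path, header_comment: str | None = None) -> None:
    rows = []
    for site in range(1, 10):
        r, c = divmod(site - 1, 3)
        rows.append(
            {
                "site": site,
                "x_mm": m.x_mm[c],
                "y_mm": m.y_mm[r],
                "yaw_deg": m.yaw[r, c],
                "pitch_deg": m.pitch[r, c],
                "roll_deg": m.roll[r, c],
                "n_trials": m.n_trials[r, c],
            }
        )
    _write_csv(pd.DataFrame(rows), path, header_comment)


def read_site_map_csv(path) -> SiteVectorMap:
    df = pd.read_csv(path, comment="#", float_precision="round_trip").sort_values("site")
    maps = {k: np.full((3, 3), np.nan) for k in ("yaw", "pitch", "roll")}
    n_trials = np.zeros((3, 3), dtype=int)
    for _, row in df.iterrows():
        r, c = divmod(int(row["site"]) - 1, 3)
        maps["yaw"][r, c] = row["yaw_deg"]
        maps["pitch"][r, c] = row["pitch_deg"]
        maps["roll"][r, c] = row["roll_deg"]
        n_trials[r, c] = row["n_trials"]
    x = np.sort(df["x_mm"].unique())
    y = np.sort(df["y_mm"].unique())
    missing = ~np.isfinite(maps["yaw"])
    return SiteVectorMap(
        x_mm=x, y_mm=y, yaw=maps["yaw"], pitch=maps["pitch"], roll=maps["roll"],
        n_trials=n_trials, missing=missing,
    )


def write_centroids_csv(
    cents: CentroidSet, path, header_comment: str | None = None
) -> None:
    df = pd.DataFrame(
        {
            "x_um": cents.coords_um[:, 1],
            "y_um": cents.coords_um[:, 0],
            "nn_dist_um": cents.nn_dist_um,
        }
    )
    _write_csv(df, path, header_comment)


def write_pupil_csv(trace: PupilTrace, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "center_x_px": trace.center_x,
            "center_y_px": trace.center_y,
            "axis_a_px": trace.axis_a,
            "axis_b_px": trace.axis_b,
            "area_px2": trace.area_px2,
            "detected": trace.detected.astype(int),
        }
    )
    _write_csv(df, path, header_comment)


def read_pupil_csv(path) -> PupilTrace:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return PupilTrace(
        time_s=df["time_s"].to_numpy(),
        center_x=df["center_x_px"].to_numpy(),
        center_y=df["center_y_px"].to_numpy(),
        axis_a=df["axis_a_px"].to_numpy(),
        axis_b=df["axis_b_px"].to_numpy(),
        area_px2=df["area_px2"].to_numpy(),
        detected=df["detected"].to_numpy().astype(bool),
    )


def write_volume_tiff(vol: DensityVolume, path) -> None:
    """Multi-page TIFF plus a JSON sidecar recording the voxel size."""
    path = Path(path)
    tifffile.imwrite(path, vol.data.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"voxel_um": list(vol.voxel_um), "axes": ["DV", "AP", "ML"]}, fh)


def read_volume_tiff(path) -> DensityVolume:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    voxel = (1.0, 1.0, 1.0)
    if sidecar.exists():
        with open(sidecar) as fh:
            voxel = tuple(json.load(fh)["voxel_um"])
    return DensityVolume(data=np.asarray(data, dtype=float), voxel_um=voxel)
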
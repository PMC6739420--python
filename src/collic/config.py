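"""Pipeline configuration: the analysis constants in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    """All tunable analysis parameters with their standard defaults.

    Angles are degrees, times seconds, distances microns or millimetres as
    named; no implicit unit conversion is performed anywhere.
    """

    sampling_rate_hz: float = 50.0
    velocity_threshold_deg_s: float = 25.0
    min_event_bins: int = 5
    success_window_s: float = 2.0
    baseline_window_s: float = 1.0
    sta_pre_bins: int = 50
    sta_post_bins: int = 100
    shuffle_min_shift_s: float = 20.0
    shuffle_max_shift_s: float = 150.0
    shuffle_reps: int = 1000
    optotag_latency_ms: float = 5.0
    smoothing_sigma_um: float = 250.0
    lattice_expected_um: float = 130.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "sampling_rate_hz",
            "velocity_threshold_deg_s",
            "min_event_bins",
            "success_window_s",
            "baseline_window_s",
            "sta_pre_bins",
            "sta_post_bins",
            "shuffle_min_shift_s",
            "shuffle_max_shift_s",
            "shuffle_reps",
            "optotag_latency_ms",
            "smoothing_sigma_um",
            "lattice_expected_um",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        post_window_s = self.sta_post_bins / self.sampling_rate_hz
        if self.shuffle_min_shift_s <= post_window_s:
            raise ValueError("minimum shuffle shift must exceed the STA post-window")
        if self.shuffle_max_shift_s <= self.shuffle_min_shift_s:
            raise ValueError("shuffle shift range is empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        """Short content hash identifying this parameter set."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
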
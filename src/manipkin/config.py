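"""Analysis configuration: filter settings, event thresholds, conventions.

All tunables that the phase segmentation, pose estimation and event metrics
consume live here, with defaults chosen for 200 Hz marker / 1000 Hz force
trials.  Configs round-trip through YAML so a run is reproducible from its
config file alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["AnalysisConfig", "load_config", "dump_config"]


@dataclass
class AnalysisConfig:
    # -- filtering -----------------------------------------------------
    #: zero-phase Butterworth cutoff for marker trajectories (Hz)
    marker_cutoff_hz: float = 10.0
    #: zero-phase Butterworth cutoff for force channels (Hz)
    force_cutoff_hz: float = 50.0
    #: effective (forward+backward) filter order; must be even
    filter_order: int = 4

    # -- force-phase segmentation --------------------------------------
    #: minimum event amplitude above baseline to count as a manipulation (N)
    min_event_n: float = 50.0
    #: onset/return threshold floor (N); actual threshold is
    #: max(onset_floor_n, onset_frac * event amplitude) above baseline
    onset_floor_n: float = 10.0
    onset_frac: float = 0.05
    #: threshold crossings must be sustained this long (s)
    sustain_s: float = 0.05
    #: rule for point B: "local_min" (last pre-thrust local minimum) or
    #: "dfdt" (last upward zero crossing of dF/dt before the peak)
    b_rule: str = "local_min"
    #: prominence tolerance for the point-B backward scan:
    #: max(floor, frac * event amplitude)
    b_prominence_floor_n: float = 5.0
    b_prominence_frac: float = 0.02
    #: baseline window SD above this (N) triggers a quietness warning
    baseline_quiet_sd: float = 5.0
    #: flip raw plate Fz so pressing harder increases the value
    flip_fz_sign: bool = False

    # -- position-change artifact detection ----------------------------
    #: plate-1 must drop this far below its baseline (N); kept below typical
    #: head-weight baselines so a full head lift always crosses it
    artifact_drop_n: float = 30.0
    #: plate-2 must rise this far above its baseline (N)
    artifact_rise_n: float = 100.0
    #: trough and peak must coincide within this window (s)
    artifact_coincidence_s: float = 0.5
    #: half-width of the exclusion window centred on the artifact (s)
    artifact_exclusion_s: float = 0.6

    # -- rigid bodies and angles ---------------------------------------
    #: duration of the reference capture at trial start (s)
    reference_window_s: float = 0.5
    #: axial-angle decomposition: "twist_z" or "cardan_xyz"
    angle_convention: str = "twist_z"
    head_markers: tuple[str, ...] = (
        "crown",
        "temporal_left",
        "temporal_right",
        "occiput",
        "mastoid_left",
        "mastoid_right",
    )
    thorax_markers: tuple[str, ...] = (
        "shoulder_peak_left",
        "shoulder_peak_right",
        "scapula_inferior_left",
        "scapula_inferior_right",
        "t10_spinous",
    )

    # -- trigger time ---------------------------------------------------
    #: displacement filter cutoff for the trigger-time path (Hz); higher than
    #: the general marker cutoff to keep the onset sharp (10 Hz smearing
    #: biases the extracted duration by ~+10 ms)
    trigger_cutoff_hz: float = 20.0
    #: movement-onset rule: "quadratic_fit" extrapolates the locally
    #: quadratic displacement onset back to zero excursion (low bias under
    #: noise); "velocity_threshold" is the classic sustained-quiet rule
    onset_rule: str = "quadratic_fit"
    #: excursion band (fractions of peak) used by the quadratic onset fit
    onset_fit_lo_frac: float = 0.02
    onset_fit_hi_frac: float = 0.25
    #: movement-onset velocity threshold as a fraction of peak speed
    onset_velocity_frac: float = 0.05
    #: quiet period must be sustained this long to count as pre-thrust rest (s)
    onset_sustain_s: float = 0.025
    #: minimum displacement excursion to count as a thrust (m)
    thrust_floor_m: float = 0.002
    #: operator acromion used per trial side (mirror of the worked example)
    active_acromion: dict = field(
        default_factory=lambda: {
            "left_rotation": "op_shoulder_peak_right",
            "right_rotation": "op_shoulder_peak_left",
        }
    )

    # -- extension amplitude -------------------------------------------
    #: subtract the Gaussian expected-max of baseline-window noise from the
    #: stretch-window distance maximum (no-op on noise-free input)
    extension_noise_correction: bool = True

    # -- occlusion handling --------------------------------------------
    #: occlusion gaps up to this many frames are spline-interpolated
    max_gap_frames: int = 10

    # -- misc -----------------------------------------------------------
    #: marker-label alias map applied on read (file label -> canonical)
    alias_map: dict = field(default_factory=dict)
    #: declared force-vs-marker trigger offset (s); see align_clocks
    trigger_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.filter_order % 2 != 0 or self.filter_order < 2:
            raise ConfigError(f"filter_order must be even and >=2, got {self.filter_order}")
        if self.b_rule not in ("local_min", "dfdt"):
            raise ConfigError(f"unknown b_rule {self.b_rule!r}")
        if self.angle_convention not in ("twist_z", "cardan_xyz"):
            raise ConfigError(f"unknown angle_convention {self.angle_convention!r}")
        if self.onset_rule not in ("quadratic_fit", "velocity_threshold"):
            raise ConfigError(f"unknown onset_rule {self.onset_rule!r}")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["head_markers"] = list(d["head_markers"])
        d["thorax_markers"] = list(d["thorax_markers"])
        return d

    def config_hash(self) -> str:
        """Stable short hash recorded in metric provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("head_markers", "thorax_markers"):
        if key in data:
            data[key] = tuple(data[key])
    return AnalysisConfig(**data)


def dump_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
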
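"""Synthetic manipulation trials with exact ground truth.

Each simulated trial emulates the structure of a prone cervical HVLA
manipulation recording: quiet baseline, slow stretch ramp on plate 1, a
pre-thrust release dip, a brief raised-cosine thrust pulse, return to
baseline, a mid-trial position-change artifact on both plates (plate-1
trough + plate-2 peak), a mirrored right-rotation event, head axial
rotation ramping from rest to a per-side maximum, a few millimetres of
cranial translation during stretching, and the operator's active acromion
executing a half-cosine vertical excursion whose duration is the trigger
time.  Every quantity the analysis pipeline extracts is returned in a
:class:`GroundTruth` record, enabling exact recovery tests.

Waveform shapes are chosen for clean recovery semantics: force onsets and
returns use a square-root-of-sine profile (steep at baseline, flat at the
extremum) so threshold-based turning-point detection lands within a few
milliseconds of the designed times; the thrust is a raised cosine whose
width maps one-to-one to the trigger time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import ClassVar

import numpy as np

from .errors import ConfigError
from .trial_io import ForceChannel, MarkerTrajectory, Trial

__all__ = [
    "SubjectParams",
    "SimulationConfig",
    "GroundTruth",
    "simulate_trial",
    "simulate_cohort",
    "write_trial_bundle",
    "DEFAULT_DISTRIBUTIONS",
]

#: cohort parameter distributions (mean, SD) matching the study's reported
#: results; used as simulate_cohort defaults.
DEFAULT_DISTRIBUTIONS: dict = {
    "trigger_loaded": (476.75, 33.11),   # N
    "stretch_loaded": (274.79, 52.08),   # N
    "trigger_duration": (0.35, 0.03),    # s
    "extension": (4.39, 1.02),           # mm
    "rot_pre": (68.6, 2.37),             # deg
    "rot_post": (73.7, 1.34),            # deg
    "baseline1": (60.0, 8.0),            # N, head+neck resting load
    "baseline2": (300.0, 30.0),          # N, chest resting load
    "artifact_peak2": (514.1, 25.0),     # N
}


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class SubjectParams:
    """Ground-truth parameters of one simulated trial.

    ``*_right`` fields default to the left-side value when ``None``.  Setting
    ``artifact_time`` to ``None`` produces a single-sided (left only) trial
    with no position-change artifact.
    """

    baseline1: float = 60.0        # N, plate 1 resting load (head + neck)
    baseline2: float = 300.0       # N, plate 2 resting load (chest)
    stretch_loaded: float = 274.79  # N above baseline at the stretch peak
    trigger_loaded: float = 476.75  # N above baseline at the thrust peak
    trigger_duration: float = 0.35  # s, thrust pulse width == trigger time
    extension: float = 4.39        # mm cranial translation during stretch
    rot_pre: float = 68.6          # deg, axial rotation reached before thrust
    rot_post: float = 73.7         # deg, axial rotation reached at thrust
    artifact_time: float | None = 5.68   # s, position-change plate-2 peak
    artifact_peak2: float = 514.1  # N, absolute plate-2 peak at the artifact
    noise_sd_marker: float = 0.0   # mm, isotropic Gaussian marker noise
    noise_sd_force: float = 0.0    # N, Gaussian force noise
    seed: int = 0

    # optional right-side overrides
    stretch_loaded_right: float | None = None
    trigger_loaded_right: float | None = None
    trigger_duration_right: float | None = None
    extension_right: float | None = None
    rot_pre_right: float | None = None
    rot_post_right: float | None = None

    # timeline knobs (shared by both sides)
    left_onset: float = 1.0        # s, point A of the left event
    stretch_ramp_s: float = 1.6
    dip_s: float = 0.4
    dip_frac: float = 0.85         # pre-thrust release level / stretch peak
    return_s: float = 1.0
    plate2_coupling: float = 0.05  # fraction of thrust amplitude bracing plate 2
    marker_rate: float = 200.0
    force_rate: float = 1000.0

    def __post_init__(self):
        for name in (
            "baseline1", "baseline2", "stretch_loaded", "trigger_loaded",
            "trigger_duration", "extension", "artifact_peak2",
            "noise_sd_marker", "noise_sd_force",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def side_value(self, name: str, side: str):
        if side == "right_rotation":
            override = getattr(self, f"{name}_right")
            if override is not None:
                return override
        return getattr(self, name)


@dataclass
class SimulationConfig:
    """Cohort-level generator configuration.

    Per-parameter distributions are (mean, SD) of normals truncated at zero;
    per-subject (and per-side, where applicable) values are drawn with
    subject seeds spawned from the master seed.
    """

    n_subjects: int = 10
    distributions: dict = field(default_factory=lambda: dict(DEFAULT_DISTRIBUTIONS))
    artifact_time: float = 5.68
    noise_sd_marker: float = 0.0
    noise_sd_force: float = 0.0
    marker_rate: float = 200.0
    force_rate: float = 1000.0
    master_seed: int = 0

    #: parameters drawn independently for each side
    PER_SIDE: ClassVar[tuple] = (
        "trigger_loaded", "stretch_loaded", "trigger_duration",
        "extension", "rot_pre", "rot_post",
    )

    def __post_init__(self):
        for name, (mean, sd) in self.distributions.items():
            if not (np.isfinite(mean) and np.isfinite(sd) and sd >= 0):
                raise ConfigError(f"invalid distribution for {name}: ({mean}, {sd})")


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from one simulated trial."""

    sides: dict            # side -> {"A","B","C","D","stretch_loaded",...}
    baseline1: float
    baseline2: float
    artifact_time: float | None
    artifact_peak2: float | None
    plate1_trough: float | None
    params: SubjectParams

    def to_json(self) -> str:
        d = {
            "sides": self.sides,
            "baseline1": self.baseline1,
            "baseline2": self.baseline2,
            "artifact_time": self.artifact_time,
            "artifact_peak2": self.artifact_peak2,
            "plate1_trough": self.plate1_trough,
            "params": dataclasses.asdict(self.params),
        }
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _frac(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Clipped phase variable: 0 before t0, 1 after t1, linear in between."""
    return np.clip((t - t0) / (t1 - t0), 0.0, 1.0)


def _sharp_rise(s: np.ndarray) -> np.ndarray:
    """0 -> 1 with infinite initial slope, zero final slope: sqrt(sin(pi s / 2))."""
    return np.sqrt(np.sin(0.5 * np.pi * s))


def _sharp_fall(s: np.ndarray) -> np.ndarray:
    """1 -> 0 with zero initial slope, steep arrival at 0: sqrt(cos(pi s / 2))."""
    return np.sqrt(np.cos(np.clip(0.5 * np.pi * s, 0.0, 0.5 * np.pi)))


def _smoothstep(s: np.ndarray) -> np.ndarray:
    return s * s * (3.0 - 2.0 * s)


def _raised_cosine(s: np.ndarray) -> np.ndarray:
    """0 -> 1 -> 0 pulse over s in [0, 1], peak at s = 0.5, C1-smooth."""
    out = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(s, 0.0, 1.0)))
    out[(s < 0) | (s > 1)] = 0.0
    return out


# ---------------------------------------------------------------------------
# trial synthesis
# ---------------------------------------------------------------------------

#: body-fixed base positions (m) of the subject lying prone, head toward +Y.
_SUBJECT_BASE = {
    # head cluster
    "crown": (0.0, 0.30, 0.12),
    "temporal_left": (-0.07, 0.25, 0.10),
    "temporal_right": (0.07, 0.25, 0.10),
    "occiput": (0.0, 0.20, 0.13),
    "mastoid_left": (-0.06, 0.21, 0.06),
    "mastoid_right": (0.06, 0.21, 0.06),
    # neck / thorax cluster
    "c5_spinous": (0.0, 0.08, 0.11),
    "shoulder_peak_left": (-0.18, 0.0, 0.10),
    "shoulder_peak_right": (0.18, 0.0, 0.10),
    "scapula_inferior_left": (-0.10, -0.12, 0.08),
    "scapula_inferior_right": (0.10, -0.12, 0.08),
    "t10_spinous": (0.0, -0.25, 0.09),
    # limbs / pelvis (static context markers)
    "humerus_medial_left": (-0.25, -0.05, 0.07),
    "humerus_medial_right": (0.25, -0.05, 0.07),
    "humerus_lateral_left": (-0.30, -0.05, 0.08),
    "humerus_lateral_right": (0.30, -0.05, 0.08),
    "forearm_mid_left": (-0.28, -0.25, 0.06),
    "forearm_mid_right": (0.28, -0.25, 0.06),
    "psis_left": (-0.06, -0.55, 0.10),
    "psis_right": (0.06, -0.55, 0.10),
}

_HEAD_LABELS = ("crown", "temporal_left", "temporal_right", "occiput", "mastoid_left", "mastoid_right")

#: operator markers; only the active acromion moves during the thrust.
_OPERATOR_BASE = {
    "op_c7": (0.45, 0.05, 0.55),
    "op_sternum": (0.40, 0.15, 0.50),
    "op_shoulder_peak_left": (0.30, 0.18, 0.52),
    "op_shoulder_peak_right": (0.55, 0.18, 0.52),
    "op_scapula_inferior_left": (0.33, 0.02, 0.48),
    "op_scapula_inferior_right": (0.52, 0.02, 0.48),
    "op_humerus_medial_left": (0.28, 0.22, 0.40),
    "op_humerus_medial_right": (0.58, 0.22, 0.40),
    "op_humerus_lateral_left": (0.25, 0.22, 0.42),
    "op_humerus_lateral_right": (0.62, 0.22, 0.42),
    "op_radius_left": (0.22, 0.26, 0.30),
    "op_radius_right": (0.64, 0.26, 0.30),
    "op_ulna_left": (0.20, 0.24, 0.29),
    "op_ulna_right": (0.66, 0.24, 0.29),
    "op_mcp3_left": (0.15, 0.28, 0.20),
    "op_mcp3_right": (0.70, 0.28, 0.20),
    "op_palm_heel_left_1": (0.14, 0.26, 0.21),
    "op_palm_heel_left_2": (0.16, 0.25, 0.21),
    "op_palm_heel_right_1": (0.69, 0.26, 0.21),
    "op_palm_heel_right_2": (0.71, 0.25, 0.21),
    "op_upperarm_track_left": (0.27, 0.20, 0.45),
    "op_upperarm_track_right": (0.60, 0.20, 0.45),
    "op_forearm_track_left": (0.21, 0.25, 0.33),
    "op_forearm_track_right": (0.65, 0.25, 0.33),
}

_ACROMION_EXCURSION_M = 0.030  # operator acromion vertical thrust travel


def _side_schedule(params: SubjectParams, side: str, onset: float) -> dict:
    """Designed event times and targets for one side, origin at point A."""
    T = params.side_value("trigger_duration", side)
    A = onset
    B = A + params.stretch_ramp_s + params.dip_s
    C = B + T / 2.0
    D = B + T + params.return_s
    stretch = params.side_value("stretch_loaded", side)
    return {
        "A": A,
        "B": B,
        "C": C,
        "D": D,
        "thrust_start": B,
        "thrust_end": B + T,
        "dip_level": stretch * params.dip_frac,
        "stretch_loaded": stretch,
        "trigger_loaded": params.side_value("trigger_loaded", side),
        "trigger_time": T,
        "extension": params.side_value("extension", side),
        "rot_pre": params.side_value("rot_pre", side),
        "rot_post": params.side_value("rot_post", side),
    }


def _plate1_event(t: np.ndarray, sc: dict) -> np.ndarray:
    """Loaded (above-baseline) plate-1 force of one event."""
    stretch, trig = sc["stretch_loaded"], sc["trigger_loaded"]
    dip = sc["dip_level"]
    A, B = sc["A"], sc["B"]
    ramp_end = A + (B - A) * 0.8  # stretch ramp, then release dip
    out = np.zeros_like(t)
    out += stretch * _sharp_rise(_frac(t, A, ramp_end))
    out -= (stretch - dip) * _smoothstep(_frac(t, ramp_end, B))
    out += (trig - dip) * _raised_cosine((t - sc["thrust_start"]) / sc["trigger_time"])
    # return phase: drop from dip level back to baseline
    ret = dip * (1.0 - _sharp_fall(_frac(t, sc["thrust_end"], sc["D"])))
    out -= ret
    out[t >= sc["D"]] = 0.0
    return out


def _rotation_angle(t: np.ndarray, sc: dict, sign: float) -> np.ndarray:
    """Axial head rotation (deg) of one event: rest -> rot_pre -> rot_post -> rest."""
    A = sc["A"]
    theta = sc["rot_pre"] * _smoothstep(_frac(t, A - 0.45, A - 0.05))
    theta += (sc["rot_post"] - sc["rot_pre"]) * _smoothstep(
        _frac(t, sc["thrust_start"], sc["thrust_end"])
    )
    theta -= theta * _smoothstep(_frac(t, sc["D"], sc["D"] + 0.4))
    return sign * theta


def _extension_mm(t: np.ndarray, sc: dict) -> np.ndarray:
    """Cranial translation (mm) of one event: 0 -> extension during stretch -> 0."""
    delta = sc["extension"] * _smoothstep(_frac(t, sc["A"] + 0.05, sc["B"] - 0.1))
    delta -= delta * _smoothstep(_frac(t, sc["D"], sc["D"] + 0.4))
    return delta


def _acromion_z(t: np.ndarray, sc: dict, z0: float) -> np.ndarray:
    """Active acromion height: half-cosine thrust dip with a mirrored return.

    The return mirrors the thrust tempo so the displacement extremum is
    locally symmetric; an asymmetric peak would bias its filtered argmax
    toward the broader side.
    """
    T = sc["trigger_time"]
    s_thrust = _frac(t, sc["thrust_start"], sc["thrust_end"])
    s_return = _frac(t, sc["thrust_end"], sc["thrust_end"] + T)
    down = 0.5 * (1.0 - np.cos(np.pi * s_thrust))
    up = 0.5 * (1.0 - np.cos(np.pi * s_return))
    return z0 - _ACROMION_EXCURSION_M * (down - down * up)


def simulate_trial(params: SubjectParams) -> tuple[Trial, GroundTruth]:
    """Build one synthetic trial and its ground truth.

    Deterministic in ``params`` (including ``seed``): identical inputs give
    bit-identical trials.
    """
    rng = np.random.default_rng(params.seed)
    two_sided = params.artifact_time is not None

    schedules = {"left_rotation": _side_schedule(params, "left_rotation", params.left_onset)}
    if two_sided:
        left_end = schedules["left_rotation"]["D"] + 0.5
        if params.artifact_time - 0.4 < left_end:
            raise ConfigError(
                f"artifact at {params.artifact_time} s overlaps the left event ending {left_end:.2f} s"
            )
        right_onset = params.artifact_time + 1.82
        schedules["right_rotation"] = _side_schedule(params, "right_rotation", right_onset)

    last_D = max(sc["D"] for sc in schedules.values())
    duration = last_D + 0.8
    n_frames = int(np.ceil(duration * params.marker_rate))
    ratio = params.force_rate / params.marker_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigError("force_rate must be an integer multiple of marker_rate")
    n_force = n_frames * int(round(ratio))
    tm = np.arange(n_frames) / params.marker_rate
    tf = np.arange(n_force) / params.force_rate

    # ---- forces ----------------------------------------------------------
    fz1 = np.full(n_force, params.baseline1)
    fz2 = np.full(n_force, params.baseline2)
    fy1 = np.zeros(n_force)
    for sc in schedules.values():
        loaded = _plate1_event(tf, sc)
        fz1 += loaded
        fy1 += 0.10 * loaded  # small shear, keeps horizontal << vertical
        thrust_amp = sc["trigger_loaded"] - sc["dip_level"]
        fz2 += params.plate2_coupling * thrust_amp * _raised_cosine(
            (tf - sc["thrust_start"]) / sc["trigger_time"]
        )
    plate1_trough = None
    if two_sided:
        bump = _raised_cosine((tf - (params.artifact_time - 0.35)) / 0.7)
        fz2 += (params.artifact_peak2 - params.baseline2) * bump
        fz1 -= 0.9 * params.baseline1 * bump
        plate1_trough = params.baseline1 * 0.1

    if params.noise_sd_force > 0:
        fz1 = fz1 + rng.normal(0.0, params.noise_sd_force, n_force)
        fz2 = fz2 + rng.normal(0.0, params.noise_sd_force, n_force)
        fy1 = fy1 + rng.normal(0.0, params.noise_sd_force, n_force)
    plates = (
        ForceChannel(1, np.zeros(n_force), fy1, fz1, params.force_rate),
        ForceChannel(2, np.zeros(n_force), np.zeros(n_force), fz2, params.force_rate),
    )

    # ---- subject markers -------------------------------------------------
    theta_deg = np.zeros(n_frames)
    delta_mm = np.zeros(n_frames)
    for side, sc in schedules.items():
        sign = 1.0 if side == "left_rotation" else -1.0
        theta_deg += _rotation_angle(tm, sc, sign)
        delta_mm += _extension_mm(tm, sc)
    theta = np.radians(theta_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    ms = np.array(_SUBJECT_BASE["shoulder_peak_left"], dtype=float)
    ms = 0.5 * (ms + np.array(_SUBJECT_BASE["shoulder_peak_right"], dtype=float))
    crown0 = np.array(_SUBJECT_BASE["crown"], dtype=float)
    u0 = (crown0 - ms) / np.linalg.norm(crown0 - ms)

    markers: dict = {}
    for label, base in _SUBJECT_BASE.items():
        base = np.array(base, dtype=float)
        if label in _HEAD_LABELS:
            # rigid head: rotate about the vertical line through the
            # mid-shoulder point, translate along the (rotated) head axis
            v = base - ms + u0[None, :] * (delta_mm[:, None] / 1000.0)
            x = cos_t * v[:, 0] - sin_t * v[:, 1]
            y = sin_t * v[:, 0] + cos_t * v[:, 1]
            pos = np.column_stack([x + ms[0], y + ms[1], v[:, 2] + ms[2]])
        else:
            pos = np.tile(base, (n_frames, 1))
        markers[label] = pos

    # ---- operator markers ------------------------------------------------
    active = {"left_rotation": "op_shoulder_peak_right", "right_rotation": "op_shoulder_peak_left"}
    for label, base in _OPERATOR_BASE.items():
        base = np.array(base, dtype=float)
        pos = np.tile(base, (n_frames, 1))
        for side, sc in schedules.items():
            if active[side] == label:
                pos[:, 2] = np.where(
                    (tm >= sc["thrust_start"] - 1e-12) & (tm <= sc["thrust_end"] + 0.5),
                    _acromion_z(tm, sc, base[2]),
                    pos[:, 2],
                )
        markers[label] = pos

    if params.noise_sd_marker > 0:
        for label in markers:
            markers[label] = markers[label] + rng.normal(
                0.0, params.noise_sd_marker / 1000.0, markers[label].shape
            )

    trial = Trial(
        markers={
            lb: MarkerTrajectory(lb, pos, params.marker_rate) for lb, pos in markers.items()
        },
        plates=plates,
        meta={"synthetic": True, "seed": params.seed},
    )

    sides_truth = {
        side: {k: sc[k] for k in (
            "A", "B", "C", "D", "stretch_loaded", "trigger_loaded",
            "trigger_time", "extension", "rot_pre", "rot_post",
        )}
        for side, sc in schedules.items()
    }
    truth = GroundTruth(
        sides=sides_truth,
        baseline1=params.baseline1,
        baseline2=params.baseline2,
        artifact_time=params.artifact_time if two_sided else None,
        artifact_peak2=params.artifact_peak2 if two_sided else None,
        plate1_trough=plate1_trough,
        params=params,
    )
    return trial, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _draw_truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal truncated at zero via rejection (means here are far from 0)."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise ConfigError(f"truncated-normal rejection failed for mean={mean}, sd={sd}")


def simulate_cohort(config: SimulationConfig) -> list:
    """Simulate ``n_subjects`` trials with per-subject parameter draws.

    Returns a list of ``(Trial, GroundTruth)``; realized draws are recorded
    in each ground truth's ``params``.  Per-side parameters are drawn
    independently for the left and right events.
    """
    out = []
    children = np.random.SeedSequence(config.master_seed).spawn(config.n_subjects)
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        kwargs: dict = {
            "artifact_time": config.artifact_time,
            "noise_sd_marker": config.noise_sd_marker,
            "noise_sd_force": config.noise_sd_force,
            "marker_rate": config.marker_rate,
            "force_rate": config.force_rate,
            "seed": int(ss.generate_state(1)[0] % (2**31)),
        }
        for name, (mean, sd) in config.distributions.items():
            kwargs[name] = _draw_truncated_normal(rng, mean, sd)
            if name in config.PER_SIDE:
                kwargs[f"{name}_right"] = _draw_truncated_normal(rng, mean, sd)
        out.append(simulate_trial(SubjectParams(**kwargs)))
    return out


# ---------------------------------------------------------------------------
# output bundles
# ---------------------------------------------------------------------------

def write_trial_bundle(trial: Trial, truth: GroundTruth, out_dir: str | Path, fmt: str = "csv") -> None:
    """Write one trial as CSV pair (or C3D) plus its ground-truth JSON."""
    from .trial_io import write_trial_c3d, write_trial_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        write_trial_csv(trial, out_dir / "markers.csv", out_dir / "forces.csv")
    elif fmt == "c3d":
        write_trial_c3d(trial, out_dir / "trial.c3d")
    else:
        raise ConfigError(f"unknown format {fmt!r}")
    (out_dir / "ground_truth.json").write_text(truth.to_json())
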
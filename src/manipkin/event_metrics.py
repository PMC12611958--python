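"""Headline per-trial metrics: trigger time, neck extension, assembly.

``trigger_time`` measures the operator's thrust duration from the active
acromion's vertical displacement: point I is the movement onset (end of the
last sustained quiet period before the peak), point II the extremum of the
displacement excursion; the trigger time is t(II) - t(I).

``extension_amplitude`` measures cranial travel as the increase of the
head-vertex to mid-shoulder distance during stretching over its resting
value, reported in millimetres.

``compile_metrics`` assembles one :class:`ManipulationMetrics` record per
trial side, and ``analyze_trial`` runs the whole pipeline (baselines,
artifact exclusion, per-side segmentation, angles, marker metrics) on a
:class:`~manipkin.trial_io.Trial`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .config import AnalysisConfig
from .errors import ManipkinError, NoEventError, NoThrustError, WindowError
from .force_phases import (
    ArtifactEvent,
    BaselineEstimate,
    PhaseMetrics,
    PhasePoints,
    detect_position_change,
    estimate_baseline,
    loaded_forces,
    segment_phases,
    vertical_grf,
)
from .rigid_kinematics import (
    AngleSeries,
    angle_series,
    build_body,
    max_rotation_angle,
    virtual_points,
)
from .trial_io import Trial, lowpass_filter

log = logging.getLogger(__name__)

__all__ = [
    "ManipulationMetrics",
    "TrialAnalysis",
    "trigger_time",
    "extension_amplitude",
    "compile_metrics",
    "analyze_trial",
]


@dataclass
class ManipulationMetrics:
    """Per-side headline outputs of one manipulation trial.

    Fields that could not be computed are ``None``; ``missing`` names them
    together with the reason.
    """

    side: str
    trigger_time: float | None = None        # s
    extension_amplitude: float | None = None  # mm
    max_rotation_pre: float | None = None     # deg
    max_rotation_post: float | None = None    # deg
    stretch_loaded_max: float | None = None   # N
    trigger_loaded_max: float | None = None   # N
    missing: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.missing

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "trigger_time_s": self.trigger_time,
            "extension_amplitude_mm": self.extension_amplitude,
            "max_rotation_pre_deg": self.max_rotation_pre,
            "max_rotation_post_deg": self.max_rotation_post,
            "stretch_loaded_max_N": self.stretch_loaded_max,
            "trigger_loaded_max_N": self.trigger_loaded_max,
        }


@dataclass
class TrialAnalysis:
    """Everything the pipeline derived from one trial."""

    metrics: dict                 # side -> ManipulationMetrics
    phases: dict                  # side -> PhasePoints
    phase_metrics: dict           # side -> PhaseMetrics
    baselines: dict               # side -> BaselineEstimate
    angles: AngleSeries | None
    artifact: ArtifactEvent | None


# ---------------------------------------------------------------------------
# trigger time
# ---------------------------------------------------------------------------

def _onset_velocity_threshold(zw, tw, ii, dt, config) -> float:
    """Classic onset: end of the last sustained quiet period before II."""
    vel = np.gradient(zw, dt)
    vmax = float(np.max(np.abs(vel[: ii + 1]))) if ii > 0 else 0.0
    if vmax <= 0:
        raise NoThrustError("no velocity excursion before the displacement peak")
    quiet = np.abs(vel) < config.onset_velocity_frac * vmax
    n_sustain = max(1, int(round(config.onset_sustain_s / dt)))
    i_onset = None
    run_len = 0
    for k in range(ii):
        if quiet[k]:
            run_len += 1
            if run_len >= n_sustain:
                i_onset = k
        else:
            run_len = 0
    return float(tw[i_onset]) if i_onset is not None else float(tw[0])


def _onset_quadratic_fit(zw, tw, rest, ii, config) -> float:
    """Onset time by extrapolating the locally quadratic displacement start.

    Any C2 movement onset grows quadratically from rest; fitting
    ``c * max(t - t0, 0)^2`` over the low-excursion rise band gives an onset
    estimate whose bias under marker noise is a fraction of a frame, unlike
    threshold crossings that fire only once the signal emerges from noise.
    """
    from scipy.optimize import curve_fit

    exc = np.abs(zw - rest)
    peak = exc[ii]
    k_hi = ii
    while k_hi > 0 and exc[k_hi] > config.onset_fit_hi_frac * peak:
        k_hi -= 1
    k_lo = k_hi
    while k_lo > 0 and exc[k_lo] > config.onset_fit_lo_frac * peak:
        k_lo -= 1
    k_lo = max(0, k_lo - 10)  # include pre-onset rest samples
    if k_hi - k_lo < 3:
        return _onset_velocity_threshold(zw, tw, ii, float(np.median(np.diff(tw))), config)
    x = tw[k_lo: k_hi + 1]
    y = (np.sign(zw[ii] - rest) * (zw - rest))[k_lo: k_hi + 1]

    def model(t, t0, c):
        d = np.clip(t - t0, 0.0, None)
        return c * d * d

    try:
        popt, _ = curve_fit(model, x, y, p0=[x[len(x) // 2], 1.0], maxfev=5000)
        t0 = float(np.clip(popt[0], tw[0], tw[ii]))
    except RuntimeError:
        t0 = _onset_velocity_threshold(zw, tw, ii, float(np.median(np.diff(tw))), config)
    return t0


def trigger_time(
    z: np.ndarray,
    times: np.ndarray,
    thrust_window: tuple,
    config: AnalysisConfig | None = None,
) -> float:
    """Thrust duration from a vertical displacement series (metres).

    II is the sample of largest absolute excursion from the window's starting
    level; I is the movement onset, located by the configured
    ``onset_rule`` (quadratic extrapolation by default, sustained-quiet
    velocity threshold as the alternative).  Raises :class:`NoThrustError`
    when the excursion stays below the noise floor.
    """
    config = config or AnalysisConfig()
    t0, t1 = thrust_window
    sel = (times >= t0) & (times <= t1)
    if sel.sum() < 4:
        raise WindowError(f"thrust window [{t0}, {t1}] s too short")
    zw = z[sel]
    tw = times[sel]
    dt = float(np.median(np.diff(tw)))

    rest = np.median(zw[: max(2, int(round(0.05 / dt)))])
    excursion = zw - rest
    ii = int(np.argmax(np.abs(excursion)))
    if abs(excursion[ii]) < config.thrust_floor_m:
        raise NoThrustError(
            f"displacement excursion {abs(excursion[ii]) * 1000:.2f} mm below noise floor "
            f"{config.thrust_floor_m * 1000:.1f} mm"
        )

    if config.onset_rule == "quadratic_fit":
        onset_time = _onset_quadratic_fit(zw, tw, rest, ii, config)
    else:
        onset_time = _onset_velocity_threshold(zw, tw, ii, dt, config)
    return float(tw[ii] - onset_time)


# ---------------------------------------------------------------------------
# extension amplitude
# ---------------------------------------------------------------------------

def _expected_max_coefficient(n_eff: float) -> float:
    """E[max of n_eff iid standard normals], asymptotic Gumbel expansion."""
    n_eff = max(2.0, n_eff)
    ln = np.log(n_eff)
    return float(np.sqrt(2 * ln) - (np.log(ln) + np.log(4 * np.pi)) / (2 * np.sqrt(2 * ln)))


def extension_amplitude(
    head_vertex,
    mid_shoulder,
    times: np.ndarray,
    baseline_window: tuple,
    stretch_window: tuple,
    config: AnalysisConfig | None = None,
) -> float:
    """Cranial travel in mm: max stretch-window distance minus resting distance.

    Distances are Euclidean head-vertex <-> mid-shoulder, so the metric is
    invariant under any common rigid transform of all markers.  The distance
    series is low-pass filtered (marker cutoff) and, because a maximum over
    a noisy series is biased upward, the Gaussian expected-max of the
    residual noise (SD estimated from the baseline window, effective sample
    count from bandwidth x duration) is subtracted when
    ``config.extension_noise_correction`` is set.  On noise-free input both
    steps are exact no-ops.  A negative result (stretch max below baseline)
    is returned with a warning as it flags mis-windowing.
    """
    config = config or AnalysisConfig()
    dist = np.linalg.norm(head_vertex.positions - mid_shoulder.positions, axis=1)
    mask = head_vertex.masked | mid_shoulder.masked
    if not mask.any() and len(dist) > 18:
        dist = lowpass_filter(dist, config.marker_cutoff_hz, head_vertex.rate, config.filter_order)

    def _window_vals(win, name):
        sel = (times >= win[0]) & (times <= win[1]) & ~mask
        if not sel.any():
            raise WindowError(f"{name} window {win} empty or fully masked")
        return dist[sel]

    base_vals = _window_vals(baseline_window, "baseline")
    base = float(np.mean(base_vals))
    peak = float(np.max(_window_vals(stretch_window, "stretch")))
    correction = 0.0
    if config.extension_noise_correction:
        sigma = float(np.std(base_vals))
        n_eff = 2.0 * config.marker_cutoff_hz * (stretch_window[1] - stretch_window[0])
        correction = _expected_max_coefficient(n_eff) * sigma
    amplitude_mm = (peak - base - correction) * 1000.0
    if amplitude_mm < 0:
        log.warning("extension amplitude %.2f mm is negative; check windows", amplitude_mm)
    return amplitude_mm


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def compile_metrics(
    trial: Trial,
    phases: dict,
    phase_metrics: dict,
    angles: AngleSeries | None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Build one :class:`ManipulationMetrics` per side from component results.

    Component failures leave the corresponding field ``None`` and are listed
    in ``missing`` (partial-record contract); nothing is silently dropped.
    """
    config = config or AnalysisConfig()
    provenance = {"config_hash": config.config_hash(), "version": __version__}
    out: dict = {}
    vps = None
    try:
        vps = virtual_points(trial)
    except ManipkinError as exc:
        log.warning("virtual points unavailable: %s", exc)

    mtimes = trial.marker_times()
    for side, points in phases.items():
        m = ManipulationMetrics(side=side, provenance=dict(provenance))
        pm: PhaseMetrics | None = phase_metrics.get(side)
        if pm is not None:
            m.stretch_loaded_max = pm.stretch_loaded_max
            m.trigger_loaded_max = pm.trigger_loaded_max
        else:
            m.missing["stretch_loaded_max"] = "phase metrics unavailable"
            m.missing["trigger_loaded_max"] = "phase metrics unavailable"

        # trigger time from the operator's active acromion
        acromion = config.active_acromion.get(side)
        try:
            trial.require(acromion, context=f"trigger time ({side})")
            traj = trial.markers[acromion]
            zf = lowpass_filter(
                traj.positions[:, 2], config.trigger_cutoff_hz, traj.rate, config.filter_order
            )
            m.trigger_time = trigger_time(
                zf, mtimes, (points.B - 0.2, points.D), config
            )
        except ManipkinError as exc:
            m.missing["trigger_time"] = str(exc)
            log.warning("trigger time unavailable for %s: %s", side, exc)

        # extension amplitude: baseline 0.5 s before A, stretch A..B
        if vps is not None:
            try:
                m.extension_amplitude = extension_amplitude(
                    vps["head_vertex"],
                    vps["mid_shoulder"],
                    mtimes,
                    (points.A - 0.5, points.A),
                    (points.A, points.B),
                    config,
                )
            except ManipkinError as exc:
                m.missing["extension_amplitude"] = str(exc)
        else:
            m.missing["extension_amplitude"] = "virtual points unavailable"

        # rotation: pre window up to A, post window A..D; right side mirrored sign
        if angles is not None:
            sign = 1.0 if side == "left_rotation" else -1.0
            ref_end = config.reference_window_s
            try:
                m.max_rotation_pre = max_rotation_angle(angles, (ref_end, points.A), sign)
                m.max_rotation_post = max_rotation_angle(angles, (points.A, points.D), sign)
            except ManipkinError as exc:
                m.missing["max_rotation"] = str(exc)
        else:
            m.missing["max_rotation"] = "angle series unavailable"
        out[side] = m
    return out


def analyze_trial(trial: Trial, config: AnalysisConfig | None = None) -> TrialAnalysis:
    """Full pipeline on one two-sided trial.

    Detects the position-change artifact, splits the trial into left/right
    event windows around it (excluding the artifact window), re-baselines
    per side, segments phases, extracts loaded forces, the axial angle
    series, trigger times and extension amplitudes.
    """
    config = config or AnalysisConfig()
    fz1 = vertical_grf(trial.plate(1), config)
    fz2 = vertical_grf(trial.plate(2), config)
    ftimes = trial.force_times()
    t_end = float(ftimes[-1])

    # provisional global baselines from the quiet trial start
    bl0_win = (0.0, max(0.5, config.reference_window_s))
    bl1_global = estimate_baseline(fz1, ftimes, bl0_win, config)
    bl2_global = estimate_baseline(fz2, ftimes, bl0_win, config)

    artifact = detect_position_change(
        fz1, fz2, ftimes, bl1_global.value, bl2_global.value, config
    )
    if artifact is not None:
        ex0, ex1 = artifact.exclusion_window(config.artifact_exclusion_s)
        side_windows = {"left_rotation": (0.0, ex0), "right_rotation": (ex1, t_end)}
    else:
        side_windows = {"left_rotation": (0.0, t_end)}

    phases: dict = {}
    phase_metrics: dict = {}
    baselines: dict = {}
    for side, win in side_windows.items():
        try:
            bl_win = (win[0], min(win[0] + 0.5, win[1]))
            bl = estimate_baseline(fz1, ftimes, bl_win, config)
            points = segment_phases(fz1, ftimes, bl, config, window=win, side=side)
            phases[side] = points
            baselines[side] = bl
            phase_metrics[side] = loaded_forces(fz1, ftimes, points, bl)
        except ManipkinError as exc:
            log.warning("phase analysis failed for %s in window %s: %s", side, win, exc)

    angles = None
    try:
        head = build_body(trial, "head", config.head_markers, (0.0, config.reference_window_s))
        thorax = build_body(trial, "thorax", config.thorax_markers, (0.0, config.reference_window_s))
        convention = "twist_z" if config.angle_convention == "twist_z" else "cardan_xyz"
        angles = angle_series(trial, head, thorax, convention, config)
    except ManipkinError as exc:
        log.warning("angle series unavailable: %s", exc)

    metrics = compile_metrics(trial, phases, phase_metrics, angles, config)
    return TrialAnalysis(
        metrics=metrics,
        phases=phases,
        phase_metrics=phase_metrics,
        baselines=baselines,
        angles=angles,
        artifact=artifact,
    )
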
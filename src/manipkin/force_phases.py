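"""Vertical GRF analysis: baseline, A/B/C/D turning points, loaded forces.

A manipulation event on the vertical ground-reaction-force curve is divided
by four turning points into stretching (A-B), triggering (B-C) and return
(C-D) phases.  The headline kinetic metric is the loaded force: peak
vertical force minus the pre-manipulation baseline attributable to resting
segment weight.  The right-rotation event's points (E/F/G/H) follow the same
rules and map onto A/B/C/D with ``side="right_rotation"``.

A mid-trial subject position change shows up as a coincident plate-1 trough
and plate-2 peak; it is detected separately and excluded from phase metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import NoEventError, SegmentationError, WindowError
from .trial_io import ForceChannel, lowpass_filter

log = logging.getLogger(__name__)

__all__ = [
    "BaselineEstimate",
    "PhasePoints",
    "PhaseMetrics",
    "ArtifactEvent",
    "vertical_grf",
    "combined_force",
    "estimate_baseline",
    "segment_phases",
    "loaded_forces",
    "detect_position_change",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class BaselineEstimate:
    """Resting vertical load (N) over a quiet pre-event window."""

    value: float
    window: tuple  # (t0, t1) s
    sd: float = 0.0
    quiet: bool = True


@dataclass
class PhasePoints:
    """Turning points A < B < C < D (seconds from trial start).

    For ``side="right_rotation"`` these are the E/F/G/H points of the mirrored event;
    field names stay A..D so downstream code is side-agnostic.
    """

    A: float
    B: float
    C: float
    D: float
    side: str = "left_rotation"

    def __post_init__(self):
        if not (self.A < self.B < self.C < self.D):
            raise SegmentationError(
                f"turning points must be ordered A<B<C<D, got "
                f"{self.A:.4f}, {self.B:.4f}, {self.C:.4f}, {self.D:.4f}"
            )


@dataclass
class PhaseMetrics:
    """Per-phase loaded forces (N) and durations (s)."""

    baseline: float
    stretch_loaded_max: float   # max over A-B minus baseline
    trigger_loaded_max: float   # peak at C minus baseline
    phase_durations: dict       # {"stretch": s, "trigger": s, "return": s}

    def __post_init__(self):
        if self.stretch_loaded_max < 0 or self.trigger_loaded_max < 0:
            raise SegmentationError(
                "negative loaded force (baseline above peak) indicates mis-segmentation: "
                f"stretch={self.stretch_loaded_max:.2f} N, trigger={self.trigger_loaded_max:.2f} N"
            )


@dataclass
class ArtifactEvent:
    """Coincident plate-1 trough / plate-2 peak from a subject position change."""

    time: float          # time of the plate-2 peak (s)
    plate1_trough: float  # N
    plate2_peak: float    # N

    def exclusion_window(self, half_width: float) -> tuple:
        return (self.time - half_width, self.time + half_width)


# ---------------------------------------------------------------------------
# series extraction
# ---------------------------------------------------------------------------

def vertical_grf(channel: ForceChannel, config: AnalysisConfig | None = None) -> np.ndarray:
    """Filtered vertical force series, sign-normalized (pressing harder -> larger).

    The raw plate convention is handled by ``config.flip_fz_sign``; filtering
    is the configured zero-phase Butterworth.
    """
    config = config or AnalysisConfig()
    fz = -channel.fz if config.flip_fz_sign else channel.fz
    return lowpass_filter(fz, config.force_cutoff_hz, channel.rate, config.filter_order)


def combined_force(channel: ForceChannel) -> np.ndarray:
    """Per-sample Euclidean norm of the three force components (N)."""
    return np.sqrt(channel.fx**2 + channel.fy**2 + channel.fz**2)


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def estimate_baseline(
    fz: np.ndarray,
    times: np.ndarray,
    pre_window: tuple,
    config: AnalysisConfig | None = None,
) -> BaselineEstimate:
    """Median vertical force over a quiet pre-event window.

    A window SD above ``config.baseline_quiet_sd`` logs a warning (the value
    is still returned, flagged ``quiet=False``).
    """
    config = config or AnalysisConfig()
    t0, t1 = pre_window
    if t1 - t0 < 0.25:
        raise WindowError(f"baseline window [{t0}, {t1}] s shorter than 0.25 s")
    sel = (times >= t0) & (times <= t1)
    if not sel.any():
        raise WindowError(f"baseline window [{t0}, {t1}] s outside series")
    vals = fz[sel]
    sd = float(np.std(vals))
    quiet = sd <= config.baseline_quiet_sd
    if not quiet:
        log.warning("baseline window SD %.2f N exceeds quietness threshold %.2f N", sd, config.baseline_quiet_sd)
    return BaselineEstimate(float(np.median(vals)), (t0, t1), sd, quiet)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _sustained_crossing(above: np.ndarray, n_sustain: int, start: int, stop: int, forward: bool = True):
    """First index in [start, stop) where ``above`` holds for n_sustain samples."""
    rng = range(start, stop) if forward else range(stop - 1, start - 1, -1)
    for i in rng:
        j = min(i + n_sustain, len(above))
        if above[i:j].all() and (j - i) >= min(n_sustain, len(above) - i):
            return i
    return None


def segment_phases(
    fz: np.ndarray,
    times: np.ndarray,
    baseline: BaselineEstimate,
    config: AnalysisConfig | None = None,
    window: tuple | None = None,
    side: str = "left_rotation",
) -> PhasePoints:
    """Locate the A/B/C/D turning points of one manipulation event.

    Rules (thresholds relative to baseline and event amplitude, so the
    segmentation is amplitude-equivariant):

    * C: time of the global maximum inside the analysis window (earliest
      sample on a plateau tie, logged).
    * A: first time the series exceeds baseline + max(floor, frac*amplitude)
      sustained for ``sustain_s`` before C.
    * B: last local minimum in (A, C) preceding the final monotone rise to C
      (``b_rule="local_min"``), or the last upward zero crossing of dF/dt in
      (A, C) (``b_rule="dfdt"``).
    * D: first time after C the series returns within the threshold of
      baseline, sustained.
    """
    config = config or AnalysisConfig()
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        if not sel.any():
            raise WindowError(f"analysis window {window} outside series")
        lo = int(np.flatnonzero(sel)[0])
        fz_w = fz[sel]
        times_w = times[sel]
    else:
        lo = 0
        fz_w, times_w = fz, times
    dt = float(np.median(np.diff(times_w)))
    n_sustain = max(1, int(round(config.sustain_s / dt)))

    c_idx = int(np.argmax(fz_w))  # argmax returns the earliest maximal sample
    peak = float(fz_w[c_idx])
    amplitude = peak - baseline.value
    if amplitude < config.min_event_n:
        raise NoEventError(
            f"no event: peak {peak:.1f} N is only {amplitude:.1f} N above baseline "
            f"{baseline.value:.1f} N (threshold {config.min_event_n} N)"
        )
    if np.sum(np.isclose(fz_w, peak, atol=1e-12)) > 1:
        log.info("plateau at the event maximum; earliest sample chosen as C")

    thr = baseline.value + max(config.onset_floor_n, config.onset_frac * amplitude)
    above = fz_w > thr

    a_idx = _sustained_crossing(above, n_sustain, 0, c_idx + 1)
    if a_idx is None:
        raise NoEventError("no sustained onset crossing found before the peak")

    # B: last local minimum before the final rise to C.  Scanning backward
    # from C we track the running minimum and stop once the signal has risen
    # a prominence tolerance above it, so sample-level noise on the thrust
    # flank cannot truncate the walk early.
    if config.b_rule == "local_min":
        tol = max(config.b_prominence_floor_n, config.b_prominence_frac * amplitude)
        run_min_idx = c_idx
        j = c_idx
        while j > a_idx + 1:
            j -= 1
            if fz_w[j] < fz_w[run_min_idx]:
                run_min_idx = j
            elif fz_w[j] > fz_w[run_min_idx] + tol:
                break
        b_idx = run_min_idx
    else:  # dfdt: last non-positive derivative sample before C
        dfdt = np.gradient(fz_w, dt)
        b_idx = c_idx
        while b_idx > a_idx + 1 and dfdt[b_idx - 1] > 0:
            b_idx -= 1
    if b_idx <= a_idx:
        b_idx = a_idx + 1

    below = fz_w < thr
    d_idx = _sustained_crossing(below, n_sustain, c_idx + 1, len(fz_w))
    if d_idx is None:
        raise NoEventError("series never returns to baseline after the peak")

    return PhasePoints(
        A=float(times_w[a_idx]),
        B=float(times_w[b_idx]),
        C=float(times_w[c_idx]),
        D=float(times_w[d_idx]),
        side=side,
    )


def loaded_forces(
    fz: np.ndarray,
    times: np.ndarray,
    points: PhasePoints,
    baseline: BaselineEstimate,
) -> PhaseMetrics:
    """Loaded forces: raw per-phase peaks minus the initial (baseline) force."""
    stretch_sel = (times >= points.A) & (times <= points.B)
    if not stretch_sel.any():
        raise WindowError("empty stretch window A-B")
    c_idx = int(np.argmin(np.abs(times - points.C)))
    stretch_max = float(np.max(fz[stretch_sel]))
    return PhaseMetrics(
        baseline=baseline.value,
        stretch_loaded_max=stretch_max - baseline.value,
        trigger_loaded_max=float(fz[c_idx]) - baseline.value,
        phase_durations={
            "stretch": points.B - points.A,
            "trigger": points.C - points.B,
            "return": points.D - points.C,
        },
    )


# ---------------------------------------------------------------------------
# position-change artifact
# ---------------------------------------------------------------------------

def detect_position_change(
    plate1_fz: np.ndarray,
    plate2_fz: np.ndarray,
    times: np.ndarray,
    baseline1: float,
    baseline2: float,
    config: AnalysisConfig | None = None,
    search_window: tuple | None = None,
) -> ArtifactEvent | None:
    """Find the coincident plate-1 trough / plate-2 peak of a position change.

    The subject lifting and turning the head unloads plate 1 (trough below
    ``baseline1 - artifact_drop_n``) while loading plate 2 (peak above
    ``baseline2 + artifact_rise_n``); the two extrema must coincide within
    ``artifact_coincidence_s``.  Returns ``None`` when no coincident pair
    exists.  The caller excludes the returned window from phase analysis.
    """
    config = config or AnalysisConfig()
    if len(plate1_fz) != len(plate2_fz):
        raise ValueError("plate series must share one clock")
    sel = np.ones(len(times), dtype=bool)
    if search_window is not None:
        sel = (times >= search_window[0]) & (times <= search_window[1])
        if not sel.any():
            return None
    idx = np.flatnonzero(sel)
    p2 = plate2_fz[idx]
    rise_ok = p2 > baseline2 + config.artifact_rise_n
    if not rise_ok.any():
        return None
    # candidate plate-2 peak: global max among threshold-exceeding samples
    cand = idx[np.argmax(np.where(rise_ok, p2, -np.inf))]
    t_peak = times[cand]
    near = np.abs(times - t_peak) <= config.artifact_coincidence_s
    trough_val = float(np.min(plate1_fz[near]))
    if trough_val > baseline1 - config.artifact_drop_n:
        return None  # plate-2 peak without a coincident plate-1 trough
    return ArtifactEvent(
        time=float(t_peak),
        plate1_trough=trough_val,
        plate2_peak=float(plate2_fz[cand]),
    )
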
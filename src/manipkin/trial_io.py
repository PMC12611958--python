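"""Trial data model and I/O: markers + two force plates on a common clock.

A :class:`Trial` bundles marker trajectories (typically 200 Hz) and two
3-axis force-plate channels (typically 1000 Hz).  Raw samples are never
resampled; each stream maps sample index -> seconds through its rate and a
per-stream offset, and analyses query by time.

Supported formats
-----------------
* C3D (binary capture interchange; minimal float-storage subset, see
  :mod:`manipkin._c3d`)
* a documented CSV dialect:

  ``markers.csv``  header ``time,<label>_X,<label>_Y,<label>_Z,...`` with a
  leading comment line ``# rate_hz=<rate>``; occluded frames are empty/NaN.

  ``forces.csv``   header ``time,plate1_Fx,plate1_Fy,plate1_Fz,plate2_Fx,
  plate2_Fy,plate2_Fz`` with the same rate comment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .errors import DialectError, FilterError, MissingForceError, MissingMarkerError
from . import _c3d

log = logging.getLogger(__name__)

__all__ = [
    "LabFrame",
    "MarkerTrajectory",
    "ForceChannel",
    "Trial",
    "lowpass_filter",
    "align_clocks",
    "interpolate_gaps",
    "read_trial_csv",
    "write_trial_csv",
    "read_trial_c3d",
    "write_trial_c3d",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabFrame:
    """Laboratory axis conventions shared by markers and force plates.

    X is the frontal axis (left negative, right positive), Y the sagittal
    axis (back negative, front positive), Z vertical (up positive).  Units:
    metres, newtons, seconds.
    """

    axis_meanings: dict = field(
        default_factory=lambda: {
            "X": "frontal (left-/right+)",
            "Y": "sagittal (back-/front+)",
            "Z": "vertical (down-/up+)",
        }
    )

    def __post_init__(self):
        if set(self.axis_meanings) != {"X", "Y", "Z"}:
            raise ValueError("LabFrame requires exactly axes X, Y, Z")


@dataclass
class MarkerTrajectory:
    """One marker's positions (metres) with an occlusion mask."""

    label: str
    positions: np.ndarray  # (n, 3) float
    rate: float  # samples / s
    occluded: np.ndarray | None = None  # (n,) bool, True = missing

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (n, 3), got {self.positions.shape}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.occluded is None:
            self.occluded = ~np.isfinite(self.positions).all(axis=1)
        self.occluded = np.asarray(self.occluded, dtype=bool)
        if len(self.occluded) != len(self.positions):
            raise ValueError("occlusion mask length mismatch")
        visible = self.positions[~self.occluded]
        if visible.size and not np.isfinite(visible).all():
            raise ValueError(f"non-finite position in non-occluded frame of {self.label!r}")

    def __len__(self) -> int:
        return len(self.positions)

    def times(self, offset: float = 0.0) -> np.ndarray:
        return np.arange(len(self)) / self.rate + offset


@dataclass
class ForceChannel:
    """Three-axis force signal (newtons) from one plate."""

    plate_id: int
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    rate: float

    def __post_init__(self):
        self.fx = np.asarray(self.fx, dtype=float)
        self.fy = np.asarray(self.fy, dtype=float)
        self.fz = np.asarray(self.fz, dtype=float)
        if not (len(self.fx) == len(self.fy) == len(self.fz)):
            raise ValueError("fx, fy, fz must have equal length")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.plate_id not in (1, 2):
            raise ValueError("plate_id must be 1 or 2")

    def __len__(self) -> int:
        return len(self.fz)

    def times(self, offset: float = 0.0) -> np.ndarray:
        return np.arange(len(self)) / self.rate + offset


@dataclass
class Trial:
    """One manipulation recording: markers + two plates on a common clock."""

    markers: dict  # label -> MarkerTrajectory
    plates: tuple  # (ForceChannel, ForceChannel)
    frame: LabFrame = field(default_factory=LabFrame)
    meta: dict = field(default_factory=dict)
    #: seconds added to index/rate to obtain trial time, per stream
    marker_offset: float = 0.0
    force_offset: float = 0.0
    #: (t0, t1) overlap window set by align_clocks; None = full extent
    analysis_window: tuple | None = None

    def __post_init__(self):
        if len(self.plates) != 2:
            raise ValueError("Trial requires exactly two force plates")

    # -- clocks --------------------------------------------------------
    @property
    def marker_rate(self) -> float:
        return next(iter(self.markers.values())).rate

    @property
    def force_rate(self) -> float:
        return self.plates[0].rate

    def marker_times(self) -> np.ndarray:
        return next(iter(self.markers.values())).times(self.marker_offset)

    def force_times(self) -> np.ndarray:
        return self.plates[0].times(self.force_offset)

    def duration(self) -> float:
        m = len(next(iter(self.markers.values()))) / self.marker_rate
        f = len(self.plates[0]) / self.force_rate
        return min(m + self.marker_offset, f + self.force_offset)

    # -- access --------------------------------------------------------
    def require(self, *labels: str, context: str = "") -> None:
        """Raise :class:`MissingMarkerError` naming every absent label."""
        missing = [lb for lb in labels if lb not in self.markers]
        if missing:
            raise MissingMarkerError(missing, context)

    def plate(self, plate_id: int) -> ForceChannel:
        for ch in self.plates:
            if ch.plate_id == plate_id:
                return ch
        raise KeyError(f"no plate {plate_id}")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def lowpass_filter(signal: np.ndarray, cutoff: float, rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass of effective order ``order``.

    The filter is applied forward and backward (``sosfiltfilt``), so a
    Butterworth of order ``order // 2`` yields the stated effective order
    with no phase lag.  DC is preserved exactly in the passband sense.

    Parameters
    ----------
    signal : 1-D or (n, k) array; filtering is along axis 0.
    cutoff : cutoff frequency in Hz, must be below Nyquist.
    rate : sampling rate in Hz.
    order : effective order, even, >= 2.
    """
    signal = np.asarray(signal, dtype=float)
    if cutoff >= rate / 2:
        raise FilterError(f"cutoff {cutoff} Hz >= Nyquist {rate / 2} Hz")
    if cutoff <= 0:
        raise FilterError("cutoff must be positive")
    if order % 2 != 0 or order < 2:
        raise FilterError(f"order must be even and >= 2, got {order}")
    sos = butter(order // 2, cutoff, btype="low", fs=rate, output="sos")
    return sosfiltfilt(sos, signal, axis=0)


# ---------------------------------------------------------------------------
# occlusion gap filling
# ---------------------------------------------------------------------------

def interpolate_gaps(traj: MarkerTrajectory, max_gap: int = 10) -> MarkerTrajectory:
    """Cubic-spline fill of occlusion gaps up to ``max_gap`` frames.

    Longer gaps (and gaps touching the trial boundary) are left occluded;
    downstream metrics over such frames fail loudly by design.
    """
    occ = traj.occluded.copy()
    pos = traj.positions.copy()
    if not occ.any():
        return traj
    n = len(occ)
    valid_idx = np.flatnonzero(~occ)
    if len(valid_idx) < 4:
        return traj
    spline = CubicSpline(valid_idx, pos[valid_idx], axis=0)
    # find occlusion runs
    i = 0
    while i < n:
        if occ[i]:
            j = i
            while j < n and occ[j]:
                j += 1
            gap = j - i
            interior = i > 0 and j < n
            if gap <= max_gap and interior:
                idx = np.arange(i, j)
                pos[idx] = spline(idx)
                occ[idx] = False
            i = j
        else:
            i += 1
    return MarkerTrajectory(traj.label, pos, traj.rate, occ)


# ---------------------------------------------------------------------------
# clock alignment
# ---------------------------------------------------------------------------

def align_clocks(trial: Trial, trigger_offset_s: float = 0.0, simultaneous_start: bool = True) -> Trial:
    """Put marker and force streams on one time base without resampling.

    With ``simultaneous_start`` both streams share t=0; a declared
    ``trigger_offset_s`` means the force stream started that many seconds
    *before* the markers, so marker t=0 maps to force sample
    ``trigger_offset_s * force_rate``.  If the stream durations disagree by
    more than 10% a warning is logged and the analysis window is truncated
    to the overlap.  Raw samples are never altered.
    """
    if not simultaneous_start and trigger_offset_s == 0.0:
        raise ValueError("without simultaneous start a trigger offset must be declared")
    marker_offset = 0.0
    force_offset = -float(trigger_offset_s)

    m_dur = len(next(iter(trial.markers.values()))) / trial.marker_rate
    f_dur = len(trial.plates[0]) / trial.force_rate + force_offset
    t0 = max(0.0 + marker_offset, force_offset)
    t1 = min(m_dur + marker_offset, f_dur)
    longer, shorter = max(m_dur, f_dur), min(m_dur, f_dur)
    if shorter > 0 and (longer - shorter) / longer > 0.10:
        log.warning(
            "marker (%.3f s) and force (%.3f s) durations differ by >10%%; truncating to overlap [%.3f, %.3f] s",
            m_dur, f_dur, t0, t1,
        )
    return Trial(
        markers=trial.markers,
        plates=trial.plates,
        frame=trial.frame,
        meta=trial.meta,
        marker_offset=marker_offset,
        force_offset=force_offset,
        analysis_window=(t0, t1),
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _read_rate_comment(path: Path) -> float | None:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "rate_hz" in first:
        try:
            return float(first.split("=")[1])
        except (IndexError, ValueError) as exc:
            raise DialectError(f"{path}: malformed rate comment {first!r}") from exc
    return None


def _read_numeric_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise DialectError(
                    f"{path}: non-numeric cell in column {col!r} at data row {row}"
                )
            df[col] = coerced
    return df


def read_trial_csv(
    marker_path: str | Path,
    force_path: str | Path,
    marker_rate: float | None = None,
    force_rate: float | None = None,
    alias_map: dict | None = None,
    meta: dict | None = None,
) -> Trial:
    """Read a trial from the documented ``markers.csv`` / ``forces.csv`` pair.

    Rates are taken from the ``# rate_hz=`` comment line unless given
    explicitly.  Marker labels pass through ``alias_map`` before storage.
    """
    marker_path, force_path = Path(marker_path), Path(force_path)
    alias_map = alias_map or {}

    m_rate = marker_rate if marker_rate is not None else _read_rate_comment(marker_path)
    f_rate = force_rate if force_rate is not None else _read_rate_comment(force_path)
    if m_rate is None or f_rate is None:
        raise DialectError("rate not declared: pass marker_rate/force_rate or add '# rate_hz=' comments")

    mdf = _read_numeric_csv(marker_path)
    if "time" not in mdf.columns:
        raise DialectError(f"{marker_path}: missing 'time' column")
    labels = []
    for col in mdf.columns:
        if col == "time":
            continue
        if not col.endswith(("_X", "_Y", "_Z")):
            raise DialectError(f"{marker_path}: column {col!r} does not end in _X/_Y/_Z")
        base = col[:-2]
        if base not in labels:
            labels.append(base)
    markers: dict = {}
    for base in labels:
        cols = [f"{base}_{ax}" for ax in "XYZ"]
        missing = [c for c in cols if c not in mdf.columns]
        if missing:
            raise DialectError(f"{marker_path}: marker {base!r} missing column(s) {missing}")
        pos = mdf[cols].to_numpy(dtype=float)
        label = alias_map.get(base, base)
        markers[label] = MarkerTrajectory(label, pos, m_rate)

    fdf = _read_numeric_csv(force_path)
    plates = []
    for pid in (1, 2):
        cols = [f"plate{pid}_F{ax.lower()}" for ax in "XYZ"]
        missing = [c for c in cols if c not in fdf.columns]
        if missing:
            raise DialectError(f"{force_path}: missing column(s) {missing}")
        plates.append(
            ForceChannel(pid, fdf[cols[0]].to_numpy(), fdf[cols[1]].to_numpy(), fdf[cols[2]].to_numpy(), f_rate)
        )
    return Trial(markers=markers, plates=tuple(plates), meta=meta or {})


def write_trial_csv(trial: Trial, marker_path: str | Path, force_path: str | Path) -> None:
    """Write a trial as the documented CSV pair; occluded frames become NaN."""
    marker_path, force_path = Path(marker_path), Path(force_path)
    mcols = {"time": trial.marker_times()}
    for label, traj in trial.markers.items():
        pos = traj.positions.copy()
        pos[traj.occluded] = np.nan
        for k, ax in enumerate("XYZ"):
            mcols[f"{label}_{ax}"] = pos[:, k]
    with open(marker_path, "w") as fh:
        fh.write(f"# rate_hz={trial.marker_rate}\n")
        pd.DataFrame(mcols).to_csv(fh, index=False, float_format="%.9g")

    fcols = {"time": trial.force_times()}
    for ch in trial.plates:
        fcols[f"plate{ch.plate_id}_Fx"] = ch.fx
        fcols[f"plate{ch.plate_id}_Fy"] = ch.fy
        fcols[f"plate{ch.plate_id}_Fz"] = ch.fz
    with open(force_path, "w") as fh:
        fh.write(f"# rate_hz={trial.force_rate}\n")
        pd.DataFrame(fcols).to_csv(fh, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# C3D
# ---------------------------------------------------------------------------

def read_trial_c3d(path: str | Path, alias_map: dict | None = None, meta: dict | None = None) -> Trial:
    """Read a trial from a C3D file (float storage).

    Analog channels named ``plate<k>_F<x|y|z>`` (case-insensitive) are mapped
    to the two force plates; a file without force analogs raises
    :class:`MissingForceError` listing whatever channels it does carry.
    """
    alias_map = alias_map or {}
    data = _c3d.read_c3d(Path(path))
    markers: dict = {}
    for i, raw_label in enumerate(data.point_labels):
        label = alias_map.get(raw_label, raw_label)
        pos = data.points[:, i, :3] / 1000.0  # stored in mm
        occluded = data.points[:, i, 3] < 0
        pos = pos.copy()
        pos[occluded] = np.nan
        markers[label] = MarkerTrajectory(label, pos, data.point_rate, occluded)

    chan_by_name = {lb.lower(): data.analog[:, i] for i, lb in enumerate(data.analog_labels)}
    plates = []
    for pid in (1, 2):
        names = [f"plate{pid}_f{ax}" for ax in "xyz"]
        if not all(n in chan_by_name for n in names):
            raise MissingForceError(
                f"{path}: force channels for plate {pid} not found; available analog channels: "
                f"{sorted(chan_by_name) or '(none)'}"
            )
        plates.append(
            ForceChannel(pid, chan_by_name[names[0]], chan_by_name[names[1]], chan_by_name[names[2]], data.analog_rate)
        )
    return Trial(markers=markers, plates=tuple(plates), meta=meta or {})


def write_trial_c3d(trial: Trial, path: str | Path) -> None:
    """Write a trial to C3D (float storage, positions in mm)."""
    labels = list(trial.markers)
    n_frames = len(next(iter(trial.markers.values())))
    points = np.zeros((n_frames, len(labels), 4))
    for i, lb in enumerate(labels):
        traj = trial.markers[lb]
        points[:, i, :3] = traj.positions * 1000.0
        points[:, i, 3] = np.where(traj.occluded, -1.0, 0.0)
        points[traj.occluded, i, :3] = 0.0
    analog_labels = []
    analog_cols = []
    for ch in trial.plates:
        for ax, arr in zip("xyz", (ch.fx, ch.fy, ch.fz)):
            analog_labels.append(f"plate{ch.plate_id}_F{ax}")
            analog_cols.append(arr)
    analog = np.column_stack(analog_cols) if analog_cols else np.zeros((0, 0))
    ratio = trial.force_rate / trial.marker_rate
    if analog_cols and abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("C3D requires an integer force/marker rate ratio")
    _c3d.write_c3d(
        Path(path),
        _c3d.C3DData(
            points=points,
            point_labels=labels,
            point_rate=trial.marker_rate,
            analog=analog,
            analog_labels=analog_labels,
            analog_rate=trial.force_rate,
        ),
    )
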
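"""Marker-based rigid bodies: pose estimation and head-on-thorax axial angle.

The head and thorax are modelled as named marker clusters.  A per-frame pose
(rotation + translation, least squares via SVD/Kabsch with a reflection
guard) maps each body's reference shape onto the observed markers; the axial
rotation of the head relative to the thorax is the twist of the relative
rotation about the thorax vertical axis (left rotation positive), with a
Cardan X-Y-Z alternative selectable for comparison with other software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .config import AnalysisConfig
from .errors import DegenerateFrameError, RankDeficiencyError, WindowError
from .trial_io import MarkerTrajectory, Trial, lowpass_filter

log = logging.getLogger(__name__)

__all__ = [
    "RigidBodyDef",
    "Pose",
    "AngleSeries",
    "VirtualPoint",
    "build_body",
    "estimate_pose",
    "axial_rotation_angle",
    "angle_series",
    "max_rotation_angle",
    "virtual_points",
]

#: markers closer than this to a common line are treated as collinear
_COLLINEARITY_TOL = 1e-10


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class RigidBodyDef:
    """A named marker cluster with its body-fixed reference shape.

    ``reference_shape`` rows are marker coordinates in the body frame; the
    body frame origin is the reference centroid (enforced on construction).
    """

    name: str
    marker_labels: tuple
    reference_shape: np.ndarray  # (n, 3), centroid at origin

    def __post_init__(self):
        self.marker_labels = tuple(self.marker_labels)
        self.reference_shape = np.asarray(self.reference_shape, dtype=float)
        if len(self.marker_labels) < 3:
            raise ValueError(f"rigid body {self.name!r} needs >=3 markers")
        if self.reference_shape.shape != (len(self.marker_labels), 3):
            raise ValueError("reference_shape must be (n_markers, 3)")
        _check_not_collinear(self.reference_shape, self.name)
        self.reference_shape = self.reference_shape - self.reference_shape.mean(axis=0)


@dataclass
class Pose:
    """Rigid transform body frame -> lab frame: x_lab = R @ x_body + t."""

    rotation: np.ndarray   # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,)
    residual_rmsd: float = 0.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det} != +1")
        if self.residual_rmsd < 0:
            raise ValueError("residual_rmsd must be >= 0")


@dataclass
class AngleSeries:
    """Per-frame head-on-thorax axial angle (degrees, left rotation positive)."""

    times: np.ndarray
    axial_angle: np.ndarray  # degrees; NaN where masked
    masked: np.ndarray       # bool, True = pose failed this frame
    convention_tag: str
    gimbal_flag: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "axial_angle_deg": self.axial_angle, "masked": self.masked}
        )


@dataclass
class VirtualPoint:
    """A derived per-frame point (e.g. mid-shoulder, head vertex)."""

    label: str
    positions: np.ndarray  # (n, 3); NaN where masked
    rate: float
    masked: np.ndarray = field(default=None)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.masked is None:
            self.masked = ~np.isfinite(self.positions).all(axis=1)


# ---------------------------------------------------------------------------
# pose estimation
# ---------------------------------------------------------------------------

def _check_not_collinear(points: np.ndarray, name: str) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if len(s) < 2 or s[1] <= _COLLINEARITY_TOL * max(s[0], 1.0):
        raise RankDeficiencyError(f"markers of {name!r} are collinear; rotation unobservable")


def build_body(
    trial: Trial,
    name: str,
    marker_labels,
    reference_window: tuple = (0.0, 0.5),
) -> RigidBodyDef:
    """Capture a body's reference shape by averaging a quiet trial window.

    All of the body's markers must be visible throughout the window.
    """
    trial.require(*marker_labels, context=f"rigid body {name!r}")
    t0, t1 = reference_window
    ref = []
    for lb in marker_labels:
        traj = trial.markers[lb]
        times = traj.times(trial.marker_offset)
        sel = (times >= t0) & (times <= t1)
        if not sel.any():
            raise WindowError(f"reference window [{t0}, {t1}] s outside trial for {lb!r}")
        if traj.occluded[sel].any():
            raise WindowError(f"marker {lb!r} occluded inside reference window")
        ref.append(traj.positions[sel].mean(axis=0))
    return RigidBodyDef(name, tuple(marker_labels), np.array(ref))


def estimate_pose(body: RigidBodyDef, frame_markers: dict) -> Pose:
    """Least-squares rigid pose of ``body`` given observed marker positions.

    Orthogonal Procrustes via SVD (Kabsch) with a reflection guard; works on
    any >=3-marker non-collinear subset of the body's labels present in
    ``frame_markers``.
    """
    pairs = [
        (i, frame_markers[lb])
        for i, lb in enumerate(body.marker_labels)
        if lb in frame_markers and np.isfinite(frame_markers[lb]).all()
    ]
    if len(pairs) < 3:
        raise DegenerateFrameError(
            f"{body.name!r}: only {len(pairs)} visible marker(s), need >=3"
        )
    idx = [i for i, _ in pairs]
    obs = np.array([p for _, p in pairs], dtype=float)
    ref = body.reference_shape[idx]
    _check_not_collinear(obs, body.name)
    _check_not_collinear(ref, body.name)

    ref_c = ref - ref.mean(axis=0)
    obs_c = obs - obs.mean(axis=0)
    h = ref_c.T @ obs_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = obs.mean(axis=0) - rot @ ref.mean(axis=0)
    resid = obs - (ref @ rot.T + trans)
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return Pose(rot, trans, rmsd)


# ---------------------------------------------------------------------------
# axial angle
# ---------------------------------------------------------------------------

def _twist_about_z(rel: np.ndarray) -> float:
    """Twist (deg) of rotation ``rel`` about the +Z axis via quaternion swing-twist."""
    q = Rotation.from_matrix(rel).as_quat()  # (x, y, z, w)
    z, w = q[2], q[3]
    norm = np.hypot(z, w)
    if norm < 1e-12:
        # pure 180-degree swing: twist undefined, report 0
        return 0.0
    angle = 2.0 * np.arctan2(z, w)
    # wrap to (-180, 180]
    deg = np.degrees(angle)
    if deg > 180.0:
        deg -= 360.0
    elif deg <= -180.0:
        deg += 360.0
    return float(deg)


def axial_rotation_angle(
    head: Pose,
    thorax: Pose,
    convention: str = "twist_z",
    return_flag: bool = False,
):
    """Axial component (degrees) of the head rotation relative to the thorax.

    The relative rotation is ``thorax.R^T @ head.R``; its component about the
    thorax vertical (+Z) axis is extracted by quaternion swing-twist
    (``twist_z``, default) or as the Z angle of a Cardan X-Y-Z sequence
    (``cardan_xyz``).  Left rotation is positive.  For the Cardan sequence a
    gimbal flag is raised when the mid axis is within 1 degree of +/-90.
    """
    rel = thorax.rotation.T @ head.rotation
    flag = False
    if convention == "twist_z":
        angle = _twist_about_z(rel)
    elif convention == "cardan_xyz":
        xyz = Rotation.from_matrix(rel).as_euler("xyz", degrees=True)
        angle = float(xyz[2])
        if abs(abs(xyz[1]) - 90.0) < 1.0:
            flag = True
            log.warning("cardan_xyz near gimbal lock (Y=%.2f deg)", xyz[1])
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if return_flag:
        return angle, flag
    return angle


def _batch_kabsch(ref: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stacked Kabsch: ref (k, 3) body shape, obs (m, k, 3) -> (m, 3, 3) R, (m,) ok.

    Frames whose observed cluster is rank-deficient are flagged not-ok.
    """
    ref_c = ref - ref.mean(axis=0)
    obs_c = obs - obs.mean(axis=1, keepdims=True)
    h = np.einsum("ki,mkj->mij", ref_c, obs_c)
    u, s, vt = np.linalg.svd(h)
    ok = s[:, 1] > _COLLINEARITY_TOL * np.maximum(s[:, 0], 1.0)
    d = np.sign(np.linalg.det(np.transpose(vt, (0, 2, 1)) @ np.transpose(u, (0, 2, 1))))
    flip = np.eye(3)[None, :, :].repeat(len(obs), axis=0)
    flip[:, 2, 2] = d
    rot = np.transpose(vt, (0, 2, 1)) @ flip @ np.transpose(u, (0, 2, 1))
    return rot, ok


def _batch_relative_rotation(head_def, thorax_def, filt, ok_idx, masked) -> np.ndarray:
    """Relative rotations thorax^-1 @ head for the unmasked frames.

    Mutates ``masked`` in place for frames that turn out degenerate.
    """
    def stack(body):
        return np.stack([filt[lb][0][ok_idx] for lb in body.marker_labels], axis=1)

    rot_h, ok_h = _batch_kabsch(head_def.reference_shape, stack(head_def))
    rot_t, ok_t = _batch_kabsch(thorax_def.reference_shape, stack(thorax_def))
    good = ok_h & ok_t
    masked[ok_idx[~good]] = True
    return np.transpose(rot_t[good], (0, 2, 1)) @ rot_h[good]


def angle_series(
    trial: Trial,
    head_def: RigidBodyDef,
    thorax_def: RigidBodyDef,
    convention: str = "twist_z",
    config: AnalysisConfig | None = None,
    filtered: bool = True,
) -> AngleSeries:
    """Per-frame axial angle of the head relative to the thorax.

    Frames where either pose fails (occlusion, collinearity) are masked, not
    interpolated; a summary warning reports the masked count.
    """
    config = config or AnalysisConfig()
    labels = list(dict.fromkeys(head_def.marker_labels + thorax_def.marker_labels))
    trial.require(*labels, context="angle_series")
    n = len(next(iter(trial.markers.values())))
    times = trial.marker_times()

    filt: dict = {}
    for lb in labels:
        traj = trial.markers[lb]
        pos = traj.positions
        if filtered and not traj.occluded.any():
            pos = lowpass_filter(pos, config.marker_cutoff_hz, traj.rate, config.filter_order)
        elif filtered and traj.occluded.any():
            pos = pos.copy()  # occluded gaps: leave raw, mask handles them
        filt[lb] = (pos, traj.occluded)

    angles = np.full(n, np.nan)
    masked = np.zeros(n, dtype=bool)
    gimbal = np.zeros(n, dtype=bool)

    # frames missing any body marker are masked outright (no interpolation)
    for lb in labels:
        masked |= filt[lb][1]
    ok = np.flatnonzero(~masked)
    if ok.size:
        rel = _batch_relative_rotation(head_def, thorax_def, filt, ok, masked)
        ok = np.flatnonzero(~masked)  # degenerate frames masked inside
        if ok.size:
            if convention == "twist_z":
                # swing-twist via quaternions, vectorized
                quats = Rotation.from_matrix(rel[: ok.size]).as_quat().reshape(-1, 4)
                z, w = quats[:, 2], quats[:, 3]
                deg = np.degrees(2.0 * np.arctan2(z, w))
                deg = np.where(deg > 180.0, deg - 360.0, deg)
                deg = np.where(deg <= -180.0, deg + 360.0, deg)
                angles[ok] = deg
            else:
                xyz = Rotation.from_matrix(rel[: ok.size]).as_euler("xyz", degrees=True)
                angles[ok] = xyz[:, 2]
                gimbal[ok] = np.abs(np.abs(xyz[:, 1]) - 90.0) < 1.0
    if masked.any():
        log.warning("angle_series: %d/%d frames masked (pose failures)", int(masked.sum()), n)
    tag = "twist_Z" if convention == "twist_z" else "cardan_XYZ"
    return AngleSeries(times, angles, masked, tag, gimbal)


def max_rotation_angle(series: AngleSeries, window: tuple, sign: float = 1.0) -> float:
    """Maximum axial angle over ``window`` (s); ``sign=-1`` for right rotation."""
    t0, t1 = window
    sel = (series.times >= t0) & (series.times <= t1) & ~series.masked
    if not sel.any():
        raise WindowError(f"window [{t0}, {t1}] s is empty or fully masked")
    return float(np.max(sign * series.axial_angle[sel]))


# ---------------------------------------------------------------------------
# virtual points
# ---------------------------------------------------------------------------

def virtual_points(trial: Trial) -> dict:
    """Mid-shoulder (acromion midpoint, a T1 proxy) and head-vertex points.

    Frames with either acromion occluded are masked in ``mid_shoulder``.
    """
    trial.require("shoulder_peak_left", "shoulder_peak_right", "crown", context="virtual_points")
    left = trial.markers["shoulder_peak_left"]
    right = trial.markers["shoulder_peak_right"]
    crown = trial.markers["crown"]
    mid = 0.5 * (left.positions + right.positions)
    mid_mask = left.occluded | right.occluded
    mid = mid.copy()
    mid[mid_mask] = np.nan
    vert = crown.positions.copy()
    vert[crown.occluded] = np.nan
    return {
        "mid_shoulder": VirtualPoint("mid_shoulder", mid, left.rate, mid_mask),
        "head_vertex": VirtualPoint("head_vertex", vert, crown.rate, crown.occluded.copy()),
    }
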
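"""Independent oracles for dual-route checks.

Each function here re-derives a quantity by brute force (exhaustive scan,
grid search, direct formula) without touching the implementation path it
validates.  Tests compare package output against these.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats


# ---------------------------------------------------------------------------
# phase segmentation by exhaustive scan
# ---------------------------------------------------------------------------

def brute_force_phase_points(
    fz: np.ndarray,
    times: np.ndarray,
    baseline: float,
    onset_floor: float = 10.0,
    onset_frac: float = 0.05,
    sustain_s: float = 0.05,
):
    """Literal scan implementing the A/B/C/D definitions with plain loops."""
    dt = float(np.median(np.diff(times)))
    n_sustain = max(1, int(round(sustain_s / dt)))
    n = len(fz)

    # C: earliest sample attaining the global maximum
    peak = max(fz)
    c = min(i for i in range(n) if fz[i] == peak)
    amp = peak - baseline
    thr = baseline + max(onset_floor, onset_frac * amp)

    # A: first index whose next n_sustain samples all exceed thr
    a = None
    for i in range(c + 1):
        seg = fz[i: i + n_sustain]
        if len(seg) and all(v > thr for v in seg):
            a = i
            break
    assert a is not None, "oracle: no onset"

    # B: last weak local minimum strictly inside (A, C)
    b = None
    for j in range(a + 1, c):
        if fz[j] <= fz[j - 1] and fz[j] <= fz[j + 1]:
            b = j
    if b is None:
        b = a + 1

    # D: first index after C whose next n_sustain samples are all below thr
    d = None
    for i in range(c + 1, n):
        seg = fz[i: i + n_sustain]
        if len(seg) and all(v < thr for v in seg):
            d = i
            break
    assert d is not None, "oracle: no return"
    return times[a], times[b], times[c], times[d]


# ---------------------------------------------------------------------------
# rigid rotation by hierarchical grid search
# ---------------------------------------------------------------------------

def _euler_xyz(ax: float, ay: float, az: float) -> np.ndarray:
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def grid_search_rotation(ref: np.ndarray, obs: np.ndarray, max_deg: float = 40.0) -> np.ndarray:
    """Best-fit rotation by coarse-to-fine Euler grid search (0.1 deg final step).

    ``ref`` and ``obs`` are centred (k, 3) clusters; translation is removed
    by centring, so only the rotation is searched.
    """
    ref_c = ref - ref.mean(axis=0)
    obs_c = obs - obs.mean(axis=0)

    def cost(r):
        return float(np.sum((ref_c @ r.T - obs_c) ** 2))

    best = (0.0, 0.0, 0.0)
    for half, step in ((max_deg, 5.0), (7.5, 0.5), (0.75, 0.1)):
        grid = np.arange(-half, half + step / 2, step)
        best_cost = np.inf
        bx, by, bz = best
        for dx in grid:
            for dy in grid:
                for dz in grid:
                    r = _euler_xyz(*np.radians([bx + dx, by + dy, bz + dz]))
                    c = cost(r)
                    if c < best_cost:
                        best_cost = c
                        new = (bx + dx, by + dy, bz + dz)
        best = new
    return _euler_xyz(*np.radians(best))


def rotation_geodesic_deg(r1: np.ndarray, r2: np.ndarray) -> float:
    """Angle (deg) of the rotation taking r1 to r2."""
    c = (np.trace(r1.T @ r2) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def twist_about_z_by_search(rel: np.ndarray) -> float:
    """Twist (deg) about +Z as the closest pure-Z rotation to ``rel``.

    Independent of the quaternion swing-twist route: maximizes
    trace(Rz(phi)^T rel) over a fine grid then refines parabolically.
    """
    phis = np.arange(-np.pi, np.pi, 1e-4)
    # trace(Rz(phi)^T rel) = cos(phi)(r00+r11) + sin(phi)(r10-r01) + r22
    a = rel[0, 0] + rel[1, 1]
    b = rel[1, 0] - rel[0, 1]
    vals = np.cos(phis) * a + np.sin(phis) * b
    k = int(np.argmax(vals))
    # parabolic refinement around the grid maximum
    if 0 < k < len(phis) - 1:
        y0, y1, y2 = vals[k - 1: k + 2]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        phi = phis[k] + shift * 1e-4
    else:
        phi = phis[k]
    return float(np.degrees(phi))


# ---------------------------------------------------------------------------
# statistics by direct formula
# ---------------------------------------------------------------------------

def paired_t_formula(x, y) -> tuple[float, float]:
    """Paired t via mean(d) * sqrt(n) / sd(d) and the t distribution."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    t = np.mean(d) * np.sqrt(n) / np.std(d, ddof=1)
    p = 2.0 * sstats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
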
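"""Trajectory linking and polar motility statistics.

The chemotaxis index of a single frame-to-frame step is

    CI = v_hat . (-r_hat)

the dot product of the unit velocity direction with the inward radial
unit vector (the direction of the attractant gradient), evaluated at the
step's start point.  CI ranges between 1 (straight toward the device
center) and -1 (straight away); the mean CI pooled over all valid steps
of all cells summarizes how efficiently a population follows the
gradient.  Net radial displacement of a cell is r(first) - r(last),
positive toward the center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import DEFAULT_PIXEL_SIZE_UM, DeviceGeometry

logger = logging.getLogger("chemoguide")

#: displacements below this are treated as detection jitter (half a pixel
#: at the default magnification) and excluded from CI/speed averages
DEFAULT_MIN_DISPLACEMENT_UM = 0.5 * DEFAULT_PIXEL_SIZE_UM


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered positions of one cell, optionally with polar transforms."""

    cell_id: int
    times_h: np.ndarray
    positions_um: np.ndarray  # (n, 2) as (x, y)
    r_um: np.ndarray | None = None
    theta_rad: np.ndarray | None = None
    valid: np.ndarray | None = None  # per-point quality flags

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        p = np.asarray(self.positions_um, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] != t.shape[0]:
            raise ValueError("positions_um must be (n, 2) matching times_h")
        if t.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 time points")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0]):
            raise ValueError("frame spacing must be constant (no gaps)")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "positions_um", p)

    @property
    def n_points(self) -> int:
        return len(self.times_h)

    @property
    def dt_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])

    @property
    def duration_h(self) -> float:
        return float(self.times_h[-1] - self.times_h[0])


@dataclass(frozen=True)
class StepVector:
    """One frame-to-frame displacement in chemotactic coordinates."""

    v_hat: np.ndarray  # unit velocity direction (zero vector if degenerate)
    speed_um_per_h: float
    inward_hat: np.ndarray  # -r_hat at the step's start point
    valid: bool  # False for zero/near-zero displacement


@dataclass(frozen=True)
class MotilitySummary:
    n_cells: int
    n_steps: int
    mean_speed_um_per_h: float
    mean_ci: float  # pooled over all valid steps (primary)
    mean_ci_per_cell: float  # mean of per-cell step means (secondary)
    mean_net_radial_displacement_um: float  # positive = toward center


# ---------------------------------------------------------------------------
# linking


def link_trajectories(
    detections: list[np.ndarray],
    max_step_um: float = 30.0,
    frame_interval_h: float = 1.0,
) -> list[Trajectory]:
    """Greedy mutual-nearest-neighbor frame-to-frame linking.

    ``detections[k]`` holds the (x, y) centroids (um) detected in frame k.
    A detection pair is linked when each is the other's nearest neighbor
    and their distance is below ``max_step_um``; ties resolve to the
    lowest index (deterministic).  Unmatched detections start new tracks;
    a track that misses a frame terminates (trajectories are contiguous
    with constant spacing).  Tracks with fewer than 2 points are dropped.
    """
    if max_step_um <= 0:
        raise ValueError("max_step_um must be positive")

    tracks: list[list[tuple[float, np.ndarray]]] = []  # closed + open
    open_tracks: dict[int, int] = {}  # detection index in prev frame -> track index

    prev_pts: np.ndarray | None = None
    for k, pts in enumerate(detections):
        pts = np.atleast_2d(np.asarray(pts, dtype=float)) if len(pts) else np.empty((0, 2))
        t = k * frame_interval_h
        new_open: dict[int, int] = {}
        if prev_pts is not None and len(prev_pts) and len(pts):
            d = cdist(prev_pts, pts)
            nn_fwd = np.argmin(d, axis=1)  # ties -> lowest index
            nn_bwd = np.argmin(d, axis=0)
            for i in range(len(prev_pts)):
                j = nn_fwd[i]
                if nn_bwd[j] == i and d[i, j] <= max_step_um and i in open_tracks:
                    ti = open_tracks[i]
                    tracks[ti].append((t, pts[j]))
                    new_open[j] = ti
        # unmatched detections start new tracks
        for j in range(len(pts)):
            if j not in new_open:
                tracks.append([(t, pts[j])])
                new_open[j] = len(tracks) - 1
        open_tracks = new_open
        prev_pts = pts

    out: list[Trajectory] = []
    cid = 0
    for tr in tracks:
        if len(tr) < 2:
            continue
        times = np.array([p[0] for p in tr])
        pos = np.vstack([p[1] for p in tr])
        out.append(Trajectory(cell_id=cid, times_h=times, positions_um=pos))
        cid += 1
    return out


# ---------------------------------------------------------------------------
# polar transforms and chemotaxis index


def to_polar(traj: Trajectory, geometry: DeviceGeometry) -> Trajectory:
    """Fill ``r_um`` and unwrapped ``theta_rad`` (pure; returns a new object).

    A point exactly at the device center has undefined azimuth: it is
    flagged invalid and carries the previous point's theta (or the next
    defined one, if it opens the track).
    """
    pos = traj.positions_um
    r = np.array([geometry.radius_um(p) for p in pos])
    theta = np.array([geometry.azimuth_rad(p) for p in pos])
    valid = r > 0
    if not valid.all():
        logger.warning("trajectory %d passes through the device center", traj.cell_id)
        defined = np.nonzero(valid)[0]
        if len(defined) == 0:
            theta[:] = 0.0
        else:
            for i in np.nonzero(~valid)[0]:
                prev = defined[defined < i]
                theta[i] = theta[prev[-1]] if len(prev) else theta[defined[0]]
    theta = np.unwrap(theta)
    return replace(traj, r_um=r, theta_rad=theta, valid=valid)


def delta_r(traj: Trajectory, geometry: DeviceGeometry) -> np.ndarray:
    """Radial displacement relative to the first time point, r(t) - r(0)."""
    tr = traj if traj.r_um is not None else to_polar(traj, geometry)
    return tr.r_um - tr.r_um[0]


def trajectory_steps(
    traj: Trajectory,
    geometry: DeviceGeometry,
    min_displacement_um: float = DEFAULT_MIN_DISPLACEMENT_UM,
) -> list[StepVector]:
    """Decompose a trajectory into frame-to-frame :class:`StepVector` s.

    The inward direction is evaluated at each step's start point.  Steps
    shorter than ``min_displacement_um`` are flagged invalid (v_hat is
    undefined at zero displacement and jitter would dominate).
    """
    pos = traj.positions_um
    dt = traj.dt_h
    steps: list[StepVector] = []
    for i in range(len(pos) - 1):
        disp = pos[i + 1] - pos[i]
        norm = float(np.hypot(disp[0], disp[1]))
        inward = -geometry.radial_unit(pos[i])
        if norm < min_displacement_um:
            steps.append(StepVector(np.zeros(2), 0.0, inward, valid=False))
        else:
            steps.append(StepVector(disp / norm, norm / dt, inward, valid=True))
    return steps


def chemotaxis_index(step: StepVector) -> float:
    """CI of one step: v_hat . (-r_hat), in [-1, 1]."""
    if not step.valid:
        raise ValueError("chemotaxis index undefined for a zero-displacement step")
    return float(np.clip(np.dot(step.v_hat, step.inward_hat), -1.0, 1.0))


def motility_summary(
    trajs: list[Trajectory],
    geometry: DeviceGeometry,
    min_displacement_um: float = DEFAULT_MIN_DISPLACEMENT_UM,
) -> MotilitySummary:
    """Population motility statistics.

    Mean speed and mean CI pool all valid one-frame steps across cells
    (the primary CI; the per-cell mean of means is reported alongside).
    Net radial displacement per cell is r(first) - r(last), positive
    toward the center, averaged over cells.
    """
    if not trajs:
        raise ValueError("motility_summary requires at least one trajectory")
    all_ci: list[float] = []
    all_speed: list[float] = []
    per_cell_ci: list[float] = []
    net_radial: list[float] = []
    for traj in trajs:
        steps = trajectory_steps(traj, geometry, min_displacement_um)
        cis = [chemotaxis_index(s) for s in steps if s.valid]
        speeds = [s.speed_um_per_h for s in steps if s.valid]
        all_ci.extend(cis)
        all_speed.extend(speeds)
        if cis:
            per_cell_ci.append(float(np.mean(cis)))
        r = np.array([geometry.radius_um(p) for p in traj.positions_um])
        net_radial.append(float(r[0] - r[-1]))
    if not all_ci:
        raise ValueError("no valid steps in any trajectory")
    return MotilitySummary(
        n_cells=len(trajs),
        n_steps=len(all_ci),
        mean_speed_um_per_h=float(np.mean(all_speed)),
        mean_ci=float(np.mean(all_ci)),
        mean_ci_per_cell=float(np.mean(per_cell_ci)),
        mean_net_radial_displacement_um=float(np.mean(net_radial)),
    )


def trajectories_to_dataframe(
    trajs: list[Trajectory], geometry: DeviceGeometry
) -> pd.DataFrame:
    """Long-format table: one row per (cell, time) with polar coordinates."""
    rows = []
    for traj in trajs:
        tr = to_polar(traj, geometry)
        dr = tr.r_um - tr.r_um[0]
        for i in range(tr.n_points):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "t_h": tr.times_h[i],
                    "x_um": tr.positions_um[i, 0],
                    "y_um": tr.positions_um[i, 1],
                    "r_um": tr.r_um[i],
                    "theta_rad": tr.theta_rad[i],
                    "dr_um": dr[i],
                }
            )
    return pd.DataFrame(rows)
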
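"""Collective-motion order parameters as time series.

Five scalar summaries per frame:

* ``P`` — polarisation, |sum v_i| / sum |v_i|: global agreement on heading.
* ``M_ang`` — angular momentum about the instantaneous centre of mass,
  |sum r_i x v_i| / sum |r_i||v_i|: coherent group rotation.
* ``M_abs`` — absolute angular momentum, sum |r_i x v_i| / sum |r_i||v_i|:
  rotation irrespective of orientation (counter-rotating vortices score
  high here while cancelling in ``M_ang``).
* ``d_a`` — mean distance to nearest neighbour (m).
* ``Mov%`` — percentage of present agents in the moving state.

Velocities are one-frame backward differences, so all series start at
frame 1.  Agents masked out by tracking dropouts are excluded frame-wise;
frames where a quantity is undefined carry NaN rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TrajectorySet, nearest_neighbor_distances

__all__ = [
    "OrderParamSeries",
    "MOTION_THRESHOLD",
    "velocities_from_positions",
    "classify_motion_states",
    "polarization",
    "angular_momentum",
    "absolute_angular_momentum",
    "mean_nn_distance",
    "percent_moving",
    "compute_all_series",
]

#: Displacement (m) at or below which a tracked animal counts as stationary.
MOTION_THRESHOLD = 1e-4

SERIES_NAMES = ("P", "M_ang", "M_abs", "d_a", "Mov%")
_UNITS = {"P": "", "M_ang": "", "M_abs": "", "d_a": "m", "Mov%": "%"}


@dataclass
class OrderParamSeries:
    """One named scalar time series on a frame grid (NaN = undefined)."""

    name: str
    values: np.ndarray
    times: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=int)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")


def velocities_from_positions(traj: TrajectorySet) -> tuple[np.ndarray, np.ndarray]:
    """Backward-difference velocities (m/frame) and their validity mask.

    Returns ``(vel, defined)`` with shapes (T-1, N, 2) and (T-1, N); row s
    corresponds to frame s+1.  A velocity is defined only where the agent
    is present in both frames of the difference.
    """
    if traj.n_frames < 2:
        raise ValueError("velocities need at least 2 frames")
    vel = np.diff(traj.positions, axis=0)
    defined = traj.present[1:] & traj.present[:-1]
    vel = np.where(defined[..., None], vel, np.nan)
    return vel, defined


def classify_motion_states(
    traj: TrajectorySet, threshold: float = MOTION_THRESHOLD
) -> np.ndarray:
    """Threshold displacements into moving/stationary states.

    Returns a (T, N) boolean grid (True = moving).  An agent is stationary
    at frame t iff its displacement from frame t-1 is <= ``threshold``
    (ties count as stationary).  Frame 0, having no predecessor, is marked
    stationary.  Used for experimental-style data; simulated trajectories
    carry exact states from the model.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if traj.n_frames < 2:
        raise ValueError("classification needs at least 2 frames")
    disp = np.linalg.norm(np.diff(traj.positions, axis=0), axis=-1)
    states = np.zeros((traj.n_frames, traj.n_agents), dtype=bool)
    states[1:] = disp > threshold
    return states


def _finite_rows(*arrays):
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        mask &= np.all(np.isfinite(np.atleast_2d(a).reshape(len(a), -1)), axis=1)
    return mask


def polarization(velocities) -> float:
    """|sum v_i| / sum |v_i| over agents with defined velocity; 0 if all still."""
    v = np.asarray(velocities, dtype=float)
    v = v[_finite_rows(v)]
    if len(v) == 0:
        return np.nan
    speeds = np.linalg.norm(v, axis=1)
    denom = speeds.sum()
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(v.sum(axis=0)) / denom)


def _momentum_terms(positions, velocities):
    p = np.asarray(positions, dtype=float)
    v = np.asarray(velocities, dtype=float)
    keep = _finite_rows(p, v)
    p, v = p[keep], v[keep]
    if len(p) == 0:
        return None
    r = p - p.mean(axis=0)  # relative to centre of mass of contributing agents
    cross = r[:, 0] * v[:, 1] - r[:, 1] * v[:, 0]
    denom = (np.linalg.norm(r, axis=1) * np.linalg.norm(v, axis=1)).sum()
    return cross, denom


def angular_momentum(positions, velocities) -> float:
    """|sum r_i x v_i| / sum |r_i||v_i|, r_i relative to the centre of mass."""
    terms = _momentum_terms(positions, velocities)
    if terms is None:
        return np.nan
    cross, denom = terms
    return 0.0 if denom == 0 else float(abs(cross.sum()) / denom)


def absolute_angular_momentum(positions, velocities) -> float:
    """sum |r_i x v_i| / sum |r_i||v_i| — ignores rotation orientation."""
    terms = _momentum_terms(positions, velocities)
    if terms is None:
        return np.nan
    cross, denom = terms
    return 0.0 if denom == 0 else float(np.abs(cross).sum() / denom)


def mean_nn_distance(positions) -> float:
    """Mean nearest-neighbour distance (m); NaN when fewer than 2 points."""
    p = np.asarray(positions, dtype=float)
    p = p[_finite_rows(p)]
    if len(p) < 2:
        return np.nan
    return float(nearest_neighbor_distances(p).mean())


def percent_moving(states, present=None) -> float:
    """100 x (moving present agents) / (present agents); NaN if none present."""
    states = np.asarray(states, dtype=bool)
    present = np.ones_like(states) if present is None else np.asarray(present, bool)
    n = present.sum()
    if n == 0:
        return np.nan
    return float(100.0 * (states & present).sum() / n)


def compute_all_series(
    traj: TrajectorySet, threshold: float = MOTION_THRESHOLD
) -> dict[str, OrderParamSeries]:
    """All five order-parameter series on the common frame grid 1..T-1.

    Motion states come from the trajectory itself when the generating model
    recorded them, otherwise from the displacement threshold.  Missing
    values (dropouts leaving a quantity undefined) propagate as NaN.
    """
    if traj.n_frames < 2:
        raise ValueError("order-parameter series need at least 2 frames")
    T = traj.n_frames
    vel, defined = velocities_from_positions(traj)
    states = traj.states if traj.states_recorded else classify_motion_states(traj, threshold)

    times = np.arange(1, T)
    out = {name: np.empty(T - 1) for name in SERIES_NAMES}
    masked_pos = np.where(traj.present[..., None], traj.positions, np.nan)

    for s, t in enumerate(times):
        v = vel[s]
        p = masked_pos[t]
        out["P"][s] = polarization(v)
        out["M_ang"][s] = angular_momentum(p, v)
        out["M_abs"][s] = absolute_angular_momentum(p, v)
        out["d_a"][s] = mean_nn_distance(p)
        out["Mov%"][s] = percent_moving(states[t], traj.present[t])

    return {
        name: OrderParamSeries(name, out[name], times, _UNITS[name])
        for name in SERIES_NAMES
    }
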
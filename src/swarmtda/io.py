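"""Plain-text file formats: trajectory CSV and crocker CSV.

Trajectory dialect: one row per *present* (frame, agent) pair with columns
``frame, agent_id, x, y, state, heading`` — coordinates in arena-centred
metres, state in {moving, stationary, unknown}.  Absent pairs are simply
missing rows; frames with zero present agents still advance the frame
index (T is max frame + 1).  Rows are written frame-major, then by agent
id, so output bytes are deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import ArenaConfig
from .simulate import TrajectorySet
from .topology import Crocker

__all__ = ["read_trajectory", "write_trajectory", "read_crocker", "write_crocker"]

_STATE_NAMES = {True: "moving", False: "stationary"}


def write_trajectory(traj: TrajectorySet, path) -> None:
    """Write a trajectory to the CSV dialect (present records only)."""
    frames, agents = np.nonzero(traj.present)
    df = pd.DataFrame(
        {
            "frame": frames,
            "agent_id": agents,
            "x": traj.positions[frames, agents, 0],
            "y": traj.positions[frames, agents, 1],
            "state": [
                _STATE_NAMES[bool(s)] if traj.states_recorded else "unknown"
                for s in traj.states[frames, agents]
            ],
            "heading": traj.headings[frames, agents],
        }
    )
    df = df.sort_values(["frame", "agent_id"], kind="stable")
    df.to_csv(path, index=False, float_format="%.10g")


def read_trajectory(path, arena: ArenaConfig | None = None) -> TrajectorySet:
    """Read the trajectory CSV back into dense (T, N) grids.

    (frame, agent) pairs absent from the file get ``present=False``.
    Duplicate pairs and non-numeric coordinates are rejected with the
    offending row number (1-based, counting the header as row 1).
    """
    df = pd.read_csv(path, dtype=str)
    required = ["frame", "agent_id", "x", "y", "state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file is missing columns {missing}")

    num = {}
    for col in ["frame", "agent_id", "x", "y"] + (["heading"] if "heading" in df.columns else []):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() & df[col].notna())
        if len(bad):
            raise ValueError(f"non-numeric {col!r} value at file row {bad[0] + 2}")
        if vals.isna().any():
            raise ValueError(f"empty {col!r} value at file row {int(np.flatnonzero(vals.isna())[0]) + 2}")
        num[col] = vals.to_numpy()

    frames = num["frame"].astype(int)
    agents = num["agent_id"].astype(int)
    if frames.min(initial=0) < 0 or agents.min(initial=0) < 0:
        raise ValueError("frame and agent_id must be nonnegative")
    dup = pd.DataFrame({"f": frames, "a": agents}).duplicated()
    if dup.any():
        raise ValueError(f"duplicate (frame, agent_id) pair at file row {int(np.flatnonzero(dup)[0]) + 2}")

    agent_ids = np.unique(agents)
    id_map = {aid: i for i, aid in enumerate(agent_ids)}
    T = int(frames.max()) + 1
    N = len(agent_ids)
    positions = np.zeros((T, N, 2))
    headings = np.zeros((T, N))
    states = np.zeros((T, N), dtype=bool)
    present = np.zeros((T, N), dtype=bool)

    cols = np.array([id_map[a] for a in agents])
    present[frames, cols] = True
    positions[frames, cols, 0] = num["x"]
    positions[frames, cols, 1] = num["y"]
    if "heading" in num:
        headings[frames, cols] = num["heading"]

    state_str = df["state"].to_numpy()
    known = ~np.isin(state_str, ["unknown"])
    bad_state = ~np.isin(state_str, ["moving", "stationary", "unknown"])
    if bad_state.any():
        raise ValueError(f"unknown state label at file row {int(np.flatnonzero(bad_state)[0]) + 2}")
    states[frames, cols] = state_str == "moving"

    return TrajectorySet(
        positions=positions,
        states=states,
        headings=headings,
        present=present,
        arena=arena or ArenaConfig(),
        states_recorded=bool(known.all()),
    )


def write_crocker(crocker: Crocker, path) -> None:
    """Lossless text serialisation of a crocker (header lines + matrix)."""
    betti = np.asarray(crocker.betti)
    real = not np.issubdtype(betti.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write("# swarmtda-crocker v1\n")
        fh.write(f"# mode={crocker.mode} k={crocker.k} real={int(real)}\n")
        fh.write("# eps=" + ",".join(repr(float(e)) for e in crocker.eps_grid) + "\n")
        fh.write("# times=" + ",".join(str(int(t)) for t in crocker.times) + "\n")
        fmt = "%.17g" if real else "%d"
        np.savetxt(fh, betti, fmt=fmt, delimiter=",")


def read_crocker(path) -> Crocker:
    """Read a crocker written by :func:`write_crocker`."""
    with open(path) as fh:
        magic = fh.readline().strip()
        if not magic.startswith("# swarmtda-crocker"):
            raise ValueError("not a swarmtda crocker file")
        meta = dict(item.split("=", 1) for item in fh.readline().strip("#\n ").split())
        eps = np.array([float(v) for v in fh.readline().split("=", 1)[1].split(",")])
        times = np.array([int(v) for v in fh.readline().split("=", 1)[1].split(",")])
        betti = np.loadtxt(fh, delimiter=",", ndmin=2)
    if int(meta.get("real", "0")) == 0:
        betti = betti.astype(int)
    if betti.shape != (len(eps), len(times)):
        raise ValueError(
            f"crocker matrix shape {betti.shape} does not match grids ({len(eps)}, {len(times)})"
        )
    return Crocker(betti=betti, eps_grid=eps, times=times, k=int(meta["k"]), mode=meta["mode"])
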
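"""Vietoris–Rips Betti numbers over time and scale: crocker matrices.

A crocker ("Contour Realization Of Computed k-dimensional hole Evolution in
the Rips complex") records the Betti number b_k(t, eps) of the Vietoris–Rips
complex built on the group's point cloud at sampled frame t and proximity
scale eps.  b_0 counts connected components, b_1 independent loops.

Two independent computational routes are provided:

* :func:`vr_intervals` — persistence intervals of the Rips filtration.
  H0 comes from single-linkage merge heights (exactly the component-merge
  scales of the filtration); H1 from standard boundary-matrix reduction
  over GF(2) with bitset columns.  Betti curves count intervals with
  ``birth <= eps < death`` (half-open convention).
* :func:`betti_oracle` — a brute-force boundary-matrix *rank* computation
  at one fixed scale, b_k = n_k - rank d_k - rank d_{k+1} over GF(2).
  Intended for small clouds and used to cross-check the persistence route.

A k-simplex exists at scale eps whenever its k+1 vertices are pairwise
within eps (closed condition, distance <= eps).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .orderparams import velocities_from_positions
from .simulate import TrajectorySet

__all__ = [
    "PointCloudSequence",
    "Crocker",
    "build_point_clouds",
    "vr_intervals",
    "rips_betti_curve",
    "betti_oracle",
    "compute_crocker",
    "average_crocker",
    "concatenate_crockers",
    "connectivity_scale",
    "crocker_contour_plot",
    "POS_MAX_EPS",
    "POSVEL_MAX_EPS",
    "POS_SCALE",
    "VEL_SCALE",
]

POS_MAX_EPS = 0.2  # m; equals the arena radius
POSVEL_MAX_EPS = 1.5  # on the normalised 4-D scale
POS_SCALE = 0.2  # m, position normalisation for posvel clouds
VEL_SCALE = 0.0013  # m/frame, the fitted maximum step length
N_EPS = 50
TIME_STRIDE = 4


@dataclass
class PointCloudSequence:
    """Point clouds at sampled frames; cloud sizes may vary with dropouts."""

    clouds: list
    times: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.clouds = [np.asarray(c, dtype=float).reshape(len(c), -1) for c in self.clouds]
        self.times = np.asarray(self.times, dtype=int)
        dims = {c.shape[1] for c in self.clouds if len(c)}
        if len(dims) > 1:
            raise ValueError("all clouds must share one dimension")


@dataclass
class Crocker:
    """Matrix of Betti numbers indexed (eps index, time index)."""

    betti: np.ndarray
    eps_grid: np.ndarray
    times: np.ndarray
    k: int
    mode: str

    def __post_init__(self) -> None:
        self.betti = np.asarray(self.betti)
        self.eps_grid = np.asarray(self.eps_grid, dtype=float)
        self.times = np.asarray(self.times, dtype=int)
        if self.betti.shape != (len(self.eps_grid), len(self.times)):
            raise ValueError("betti matrix shape must be (n_eps, n_times)")
        if self.k not in (0, 1):
            raise ValueError("homology dimension k must be 0 or 1")


def build_point_clouds(
    traj: TrajectorySet,
    mode: str = "pos",
    time_stride: int = TIME_STRIDE,
    pos_scale: float = POS_SCALE,
    vel_scale: float = VEL_SCALE,
) -> PointCloudSequence:
    """Per-frame point clouds of present agents, downsampled in time.

    ``mode="pos"`` uses raw 2-D positions in metres.  ``mode="posvel"``
    concatenates position and one-frame velocity, each divided by its
    characteristic scale (arena radius 0.2 m; maximum step 0.0013 m) so
    the four coordinates are comparable; it starts at frame 1, the first
    with a defined velocity, and omits agents lacking one.
    """
    if time_stride < 1:
        raise ValueError("time_stride must be >= 1")
    if pos_scale <= 0 or vel_scale <= 0:
        raise ValueError("scales must be positive")
    if mode == "pos":
        times = np.arange(0, traj.n_frames, time_stride)
        clouds = [traj.positions[t][traj.present[t]] for t in times]
    elif mode == "posvel":
        vel, defined = velocities_from_positions(traj)
        times = np.arange(1, traj.n_frames, time_stride)
        clouds = []
        for t in times:
            keep = defined[t - 1]
            pts = np.concatenate(
                [traj.positions[t][keep] / pos_scale, vel[t - 1][keep] / vel_scale],
                axis=1,
            )
            clouds.append(pts)
    else:
        raise ValueError(f"unknown point-cloud mode {mode!r}")
    return PointCloudSequence(clouds=clouds, times=times, mode=mode)


def _h0_merge_heights(dm_condensed: np.ndarray, n: int) -> np.ndarray:
    """The n-1 scales at which single-linkage (= Rips components) merge."""
    if n < 2:
        return np.empty(0)
    return linkage(dm_condensed, method="single")[:, 2]


def _h1_intervals(dm: np.ndarray, max_eps: float) -> list[tuple[float, float]]:
    """H1 persistence of the Rips filtration truncated at scale ``max_eps``.

    Boundary-matrix reduction over GF(2).  Edge columns are handled
    implicitly via union-find (an edge is negative iff it merges two
    components); triangle columns are reduced with Python-int bitsets over
    edge indices.  Deaths beyond ``max_eps`` are reported as +inf.
    """
    n = dm.shape[0]
    edges = [
        (dm[i, j], i, j) for i in range(n) for j in range(i + 1, n) if dm[i, j] <= max_eps
    ]
    edges.sort()
    edge_index = {(i, j): idx for idx, (_, i, j) in enumerate(edges)}
    edge_val = np.array([e[0] for e in edges])

    # union-find: find positive edges (cycle births)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    positive = set()
    for idx, (_, i, j) in enumerate(edges):
        ri, rj = find(i), find(j)
        if ri == rj:
            positive.add(idx)
        else:
            parent[ri] = rj

    # triangles with all three edges in range, filtration value = longest edge
    adj = [set() for _ in range(n)]
    for _, i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    triangles = []
    for _, i, j in edges:
        for k in adj[i] & adj[j]:
            if k > j:
                val = max(dm[i, j], dm[i, k], dm[j, k])
                triangles.append((val, edge_index[(i, j)], edge_index[(i, k)], edge_index[(j, k)]))
    triangles.sort()

    pivots: dict[int, int] = {}
    intervals: list[tuple[float, float]] = []
    for val, e1, e2, e3 in triangles:
        col = (1 << e1) | (1 << e2) | (1 << e3)
        while col:
            low = col.bit_length() - 1
            if low in pivots:
                col ^= pivots[low]
            else:
                break
        if col:
            pivots[low] = col
            birth = edge_val[low]
            if val > birth:
                intervals.append((birth, val))
    killed = set(pivots)
    for idx in positive - killed:
        intervals.append((edge_val[idx], np.inf))
    return intervals


def vr_intervals(points, max_dim: int = 1, max_eps: float | None = None) -> dict:
    """Persistence intervals of the Rips filtration, by homology dimension.

    Returns ``{k: [(birth, death), ...]}`` with half-open interval
    semantics: the class exists at scales ``birth <= eps < death``.  When
    ``max_eps`` is given the filtration is truncated there and unresolved
    deaths are +inf (correct for any Betti evaluation at eps <= max_eps).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    out: dict[int, list] = {0: [], 1: []}
    if n == 0:
        return out
    pts = pts.reshape(n, -1)
    if n == 1:
        out[0] = [(0.0, np.inf)]
        return out
    cond = pdist(pts)
    heights = _h0_merge_heights(cond, n)
    out[0] = [(0.0, float(h)) for h in heights] + [(0.0, np.inf)]
    if max_dim >= 1:
        limit = float(cond.max()) if max_eps is None else float(max_eps)
        out[1] = _h1_intervals(squareform(cond), limit)
    return out


def betti_from_intervals(intervals, eps_grid) -> np.ndarray:
    """Count intervals alive at each grid scale (birth <= eps < death)."""
    eps_grid = np.asarray(eps_grid, dtype=float)
    counts = np.zeros(len(eps_grid), dtype=int)
    for birth, death in intervals:
        counts += (eps_grid >= birth) & (eps_grid < death)
    return counts


def rips_betti_curve(points, eps_grid, max_dim: int = 1) -> np.ndarray:
    """Betti curves b_k(eps) on an ascending scale grid.

    Returns an array of shape (max_dim + 1, len(eps_grid)).
    """
    if max_dim not in (0, 1):
        raise ValueError("max_dim must be 0 or 1")
    eps_grid = np.asarray(eps_grid, dtype=float)
    if len(eps_grid) > 1 and np.any(np.diff(eps_grid) < 0):
        raise ValueError("eps_grid must be ascending")
    ivals = vr_intervals(points, max_dim=max_dim, max_eps=float(eps_grid[-1]))
    return np.stack([betti_from_intervals(ivals[k], eps_grid) for k in range(max_dim + 1)])


def _gf2_rank(columns: list[int]) -> int:
    pivots: dict[int, int] = {}
    rank = 0
    for col in columns:
        while col:
            low = col.bit_length() - 1
            if low in pivots:
                col ^= pivots[low]
            else:
                pivots[low] = col
                rank += 1
                break
    return rank


def betti_oracle(points, eps: float, k: int, max_points: int = 25) -> int:
    """Brute-force Betti number of the Rips complex at one fixed scale.

    Enumerates every 0/1/2-simplex present at scale ``eps`` and computes
    b_k = n_k - rank d_k - rank d_{k+1} over GF(2) (with rank d_0 = 0).
    Deliberately independent of the persistence implementation; refuses
    clouds larger than ``max_points`` to guard the combinatorial blow-up.
    """
    if k not in (0, 1):
        raise ValueError("k must be 0 or 1")
    pts = np.asarray(points, dtype=float).reshape(len(points), -1)
    n = len(pts)
    if n > max_points:
        raise ValueError(f"betti_oracle is limited to {max_points} points, got {n}")
    if n == 0:
        return 0
    dm = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))
    edges = [(i, j) for i, j in combinations(range(n), 2) if dm[i, j] <= eps]
    edge_cols = [(1 << i) | (1 << j) for i, j in edges]
    rank_d1 = _gf2_rank(edge_cols)
    if k == 0:
        return n - rank_d1
    edge_idx = {e: m for m, e in enumerate(edges)}
    tri_cols = []
    for i, j, l in combinations(range(n), 3):
        if dm[i, j] <= eps and dm[i, l] <= eps and dm[j, l] <= eps:
            tri_cols.append(
                (1 << edge_idx[(i, j)]) | (1 << edge_idx[(i, l)]) | (1 << edge_idx[(j, l)])
            )
    rank_d2 = _gf2_rank(tri_cols)
    return len(edges) - rank_d1 - rank_d2


def default_max_eps(mode: str) -> float:
    return POS_MAX_EPS if mode == "pos" else POSVEL_MAX_EPS


def compute_crocker(
    traj: TrajectorySet,
    mode: str = "pos",
    k: int = 0,
    max_eps: float | None = None,
    n_eps: int = N_EPS,
    time_stride: int = TIME_STRIDE,
) -> Crocker:
    """Crocker matrix b_k over ``n_eps`` uniform scales from 0 to ``max_eps``.

    Defaults follow the study design: 50 scales, time downsampled by 4,
    maximum scale 0.2 m for position clouds and 1.5 for normalised
    position+velocity clouds.  Columns are computed independently per
    sampled frame on the cloud of present agents.
    """
    if k not in (0, 1):
        raise ValueError("k must be 0 or 1")
    seq = build_point_clouds(traj, mode=mode, time_stride=time_stride)
    if max_eps is None:
        max_eps = default_max_eps(mode)
    eps_grid = np.linspace(0.0, max_eps, n_eps)
    betti = np.zeros((n_eps, len(seq.clouds)), dtype=int)
    for col, cloud in enumerate(seq.clouds):
        n = len(cloud)
        if n == 0:
            continue
        if k == 0:
            if n == 1:
                betti[:, col] = 1
            else:
                heights = np.sort(_h0_merge_heights(pdist(cloud), n))
                betti[:, col] = n - np.searchsorted(heights, eps_grid, side="right")
        else:
            ivals = _h1_intervals(squareform(pdist(cloud)), float(max_eps)) if n >= 3 else []
            betti[:, col] = betti_from_intervals(ivals, eps_grid)
    return Crocker(betti=betti, eps_grid=eps_grid, times=seq.times, k=k, mode=mode)


def average_crocker(crockers: list[Crocker]) -> Crocker:
    """Element-wise mean of crockers on identical grids (real-valued)."""
    if not crockers:
        raise ValueError("need at least one crocker")
    first = crockers[0]
    for c in crockers[1:]:
        if (
            c.k != first.k
            or c.betti.shape != first.betti.shape
            or not np.allclose(c.eps_grid, first.eps_grid)
            or not np.array_equal(c.times, first.times)
        ):
            raise ValueError("crockers must share grids and homology dimension")
    mean = np.mean([c.betti for c in crockers], axis=0)
    return Crocker(mean, first.eps_grid.copy(), first.times.copy(), first.k, first.mode)


def concatenate_crockers(a: Crocker, b: Crocker) -> np.ndarray:
    """Stack two crockers on a shared time grid into one matrix.

    The Frobenius distance between two such stacks is
    sqrt(d(a1, a2)^2 + d(b1, b2)^2) by block additivity, letting the
    comparison metric see both homology dimensions at once.
    """
    if not np.array_equal(a.times, b.times):
        raise ValueError("crockers must share the time grid")
    return np.concatenate([np.asarray(a.betti, float), np.asarray(b.betti, float)], axis=0)


def connectivity_scale(crocker: Crocker, level: float = 1.0) -> np.ndarray:
    """Per time column, the smallest grid scale with b_0 <= ``level``.

    The scale at which the whole group merges into ``level`` component(s);
    columns never reaching it return the top of the grid.  Rising values
    over time indicate group dispersal (contours trending upward).
    """
    betti = np.asarray(crocker.betti, dtype=float)
    out = np.empty(betti.shape[1])
    tol = 1e-9
    for col in range(betti.shape[1]):
        hits = np.flatnonzero(betti[:, col] <= level + tol)
        out[col] = crocker.eps_grid[hits[0]] if len(hits) else crocker.eps_grid[-1]
    return out


def crocker_contour_plot(
    crocker: Crocker,
    max_contour: int = 11,
    path: str | None = None,
    ax=None,
    cmap: str = "viridis",
):
    """Contour rendering of a crocker: time horizontal, scale vertical.

    The contour labelled n separates the regions b < n and b >= n; levels
    above ``max_contour`` are suppressed as topological noise.  Returns the
    matplotlib Axes; writes an image when ``path`` is given.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    levels = np.arange(0.5, max_contour + 1, 1.0)
    tt, ee = np.meshgrid(crocker.times, crocker.eps_grid)
    cs = ax.contour(tt, ee, crocker.betti, levels=levels, cmap=cmap)
    ax.clabel(cs, fmt=lambda lv: f"{int(round(lv + 0.5))}", fontsize=7)
    ax.set_xlabel("frame")
    ax.set_ylabel(r"proximity scale $\epsilon$" + (" (m)" if crocker.mode == "pos" else ""))
    ax.set_title(f"$b_{crocker.k}$({crocker.mode}) crocker")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
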
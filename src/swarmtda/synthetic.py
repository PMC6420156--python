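"""Synthetic stand-ins for the undeposited aphid tracking data.

The original experiments (nine trials, 7–33 animals, ~45 min at 0.5 s per
frame in a 0.4 m arena) are not publicly archived, so this module generates
the structures the analysis assumes: initial point configurations inside
the arena, pseudo-experimental trajectories produced by the interactive
model, and optional motion-tracking dropouts in which agents vanish for
short runs of frames and reappear — a known artefact of the tracking
software used on the real footage.

Because a pseudo-experiment is, by construction, one realisation of the
interactive model, "interactive preferred" is the known ground truth for
every self-consistency model-selection study run on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ArenaConfig, ModelParams
from .simulate import TrajectorySet, simulate

__all__ = [
    "TRIAL_SIZES",
    "InitialConfiguration",
    "generate_initial_conditions",
    "generate_pseudo_experiment",
]

#: Group sizes of the nine original experimental trials.
TRIAL_SIZES: tuple[int, ...] = (19, 28, 27, 33, 27, 30, 26, 7, 9)

PATTERNS = ("clustered", "dispersed", "ring")


@dataclass
class InitialConfiguration:
    """N starting positions inside the arena, with the pattern that made them."""

    positions: np.ndarray
    pattern: str = "from_file"
    arena: ArenaConfig = field(default_factory=ArenaConfig)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")
        if len(self.positions) < 2:
            raise ValueError("an initial configuration needs at least 2 agents")
        if np.any(np.linalg.norm(self.positions, axis=1) > self.arena.radius * (1 + 1e-9)):
            raise ValueError("initial positions must lie inside the arena disk")

    @property
    def n_agents(self) -> int:
        return len(self.positions)


def _uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    phi = rng.uniform(-np.pi, np.pi, n)
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=-1)


def generate_initial_conditions(
    n_agents: int,
    pattern: str,
    arena: ArenaConfig | None = None,
    seed: int | None = None,
    *,
    cluster_fraction: float = 0.25,
) -> InitialConfiguration:
    """Draw an initial configuration of ``n_agents`` points in the arena.

    Patterns
    --------
    ``clustered``
        Uniform draw inside a sub-disk of radius ``cluster_fraction *
        arena.radius`` whose centre is itself placed uniformly so the
        sub-disk stays inside the arena — mimics the tightly grouped
        starts seen in several experimental trials.
    ``dispersed``
        Uniform draw over the whole arena disk.
    ``ring``
        Evenly spaced angles near 70% of the arena radius with small
        radial/angular jitter.
    """
    arena = arena or ArenaConfig()
    if n_agents < 2:
        raise ValueError("n_agents must be >= 2")
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {PATTERNS}")
    rng = np.random.default_rng(seed)
    R = arena.radius
    margin = 1e-6 * R  # keep points strictly inside

    if pattern == "clustered":
        sub_r = cluster_fraction * R
        center = _uniform_disk(rng, 1, R - sub_r - margin)[0]
        pts = center + _uniform_disk(rng, n_agents, sub_r)
    elif pattern == "dispersed":
        pts = _uniform_disk(rng, n_agents, R - margin)
    else:  # ring
        phi = np.linspace(-np.pi, np.pi, n_agents, endpoint=False)
        phi = phi + rng.normal(0, 0.2 / n_agents, n_agents)
        r = 0.7 * R + rng.normal(0, 0.03 * R, n_agents)
        r = np.clip(r, 0, R - margin)
        pts = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=-1)

    return InitialConfiguration(positions=pts, pattern=pattern, arena=arena)


def generate_pseudo_experiment(
    ic: InitialConfiguration,
    model: ModelParams | None = None,
    n_frames: int = 500,
    dropout_rate: float = 0.0,
    mean_dropout_len: int = 3,
    seed: int | None = None,
    **simulate_kwargs,
) -> TrajectorySet:
    """Simulate a reference trajectory with optional tracking dropouts.

    Each agent independently begins an absence run in any frame t >= 1 with
    per-frame probability ``dropout_rate``; run lengths are geometric with
    the given mean.  Positions are retained internally, but the presence
    mask marks dropped frames as missing, and every downstream consumer
    (order parameters, point clouds, crockers) ignores masked entries —
    emulating animals lost and re-acquired by motion-tracking software.

    With ``dropout_rate=0`` the output is identical to a plain
    :func:`~swarmtda.simulate.simulate` run with the same seed.
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must lie in [0, 1)")
    if mean_dropout_len < 1:
        raise ValueError("mean_dropout_len must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    model = model or ModelParams()
    traj = simulate(ic, model, n_frames, seed=seed, **simulate_kwargs)

    if dropout_rate > 0.0:
        # Separate stream so the walk itself is unchanged by masking.
        mask_rng = np.random.default_rng(
            np.random.SeedSequence([0 if seed is None else seed, 0xD20]).generate_state(1)[0]
        )
        present = traj.present.copy()
        T, N = present.shape
        p_geom = 1.0 / mean_dropout_len
        for a in range(N):
            t = 1
            while t < T:
                if mask_rng.random() < dropout_rate:
                    run = int(mask_rng.geometric(p_geom))
                    present[t : t + run, a] = False
                    t += run
                t += 1
        traj.present = present
    return traj
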
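"""Fitted motion-model parameters and their distance-response functions.

Pea aphids move intermittently: each animal is either *moving* or
*stationary* in every video frame, and a moving animal performs an unbiased
correlated random walk.  In the *interactive* model the two state-transition
probabilities, the step length and the turning-angle concentration all
respond to the focal animal's distance ``d`` to its nearest neighbour; the
*control* model freezes every response at its ``d -> inf`` limit, removing
the social coupling while keeping everything else identical.

All lengths are metres, all probabilities dimensionless, and one time step
is one video frame (0.5 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ArenaConfig",
    "ModelParams",
    "p_move_to_stop",
    "p_stop_to_move",
    "step_length",
    "spread_param",
    "wrapped_cauchy_pdf",
    "sample_turning_angle",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Circular experimental arena.

    Parameters
    ----------
    radius
        Arena radius in metres.  The experiments used a 40 cm diameter
        dish, hence the 0.2 m default.
    frame_duration
        Duration of one video frame in seconds (0.5 s in the experiments).
        Carried as metadata only: every computation is indexed by frame.
    """

    radius: float = 0.2
    frame_duration: float = 0.5

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"arena radius must be positive, got {self.radius}")
        if not self.frame_duration > 0:
            raise ValueError(
                f"frame duration must be positive, got {self.frame_duration}"
            )


@dataclass(frozen=True)
class ModelParams:
    """The twelve fitted constants of the stop–start random-walk model.

    Default values are the published fits.  ``kind`` selects between the
    ``"interactive"`` model (distance-dependent responses) and the
    ``"control"`` model (every response held at its large-distance limit).
    """

    pms_inf: float = 0.1280
    pms_0: float = 0.5508
    d_ms: float = 0.0134
    psm_0: float = 0.1587
    psm_inf: float = 0.3552
    d_sm: float = 0.0079
    delta_sm: float = 0.0739
    ell_inf: float = 0.0013
    ell_0: float = 0.0003
    d_ell: float = 0.0074
    rho_inf: float = 0.9013
    rho_0: float = 0.1387
    d_rho: float = 0.0044
    kind: str = "interactive"

    def __post_init__(self) -> None:
        for name in ("pms_inf", "pms_0", "psm_0", "psm_inf"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        for name in ("d_ms", "d_sm", "delta_sm", "ell_inf", "ell_0", "d_ell", "d_rho"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be a positive length, got {v}")
        for name in ("rho_0", "rho_inf"):
            r = getattr(self, name)
            if not 0.0 < r < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {r}")
        if self.kind not in ("interactive", "control"):
            raise ValueError(
                f"kind must be 'interactive' or 'control', got {self.kind!r}"
            )

    def as_control(self) -> "ModelParams":
        """The same fit with social coupling removed (d -> inf limits)."""
        return replace(self, kind="control")

    def as_interactive(self) -> "ModelParams":
        return replace(self, kind="interactive")


def _effective_distance(d, params: ModelParams):
    """Validate ``d`` and apply the control-model d -> inf override."""
    d = np.asarray(d, dtype=float)
    if np.any(d[np.isfinite(d)] < 0):
        raise ValueError("nearest-neighbour distance d must be nonnegative")
    if params.kind == "control":
        d = np.full_like(d, np.inf)
    return d


def p_move_to_stop(d, params: ModelParams | None = None):
    """Probability that a moving animal stops in the next frame.

    ``P_MS(d) = P_MS^inf + (P_MS^0 - P_MS^inf) exp(-d / d_MS)`` — a moving
    animal near a neighbour is far more likely to stop (0.5508 at contact)
    than an isolated one (0.1280 in the limit).
    """
    params = params or ModelParams()
    d = _effective_distance(d, params)
    out = params.pms_inf + (params.pms_0 - params.pms_inf) * np.exp(-d / params.d_ms)
    return out if out.ndim else float(out)


def p_stop_to_move(d, params: ModelParams | None = None):
    """Probability that a stationary animal starts moving in the next frame.

    ``P_SM(d) = P_SM^0 exp(-d / d_SM) + P_SM^inf d / (d + Delta_SM)``:
    0.1587 at contact, rising to 0.3552 for isolated animals.
    """
    params = params or ModelParams()
    d = _effective_distance(d, params)
    with np.errstate(invalid="ignore"):
        saturating = np.where(np.isinf(d), 1.0, d / (d + params.delta_sm))
    out = params.psm_0 * np.exp(-d / params.d_sm) + params.psm_inf * saturating
    return out if out.ndim else float(out)


def step_length(d, params: ModelParams | None = None):
    """Per-frame step length (m) of a moving animal.

    ``ell(d) = ell^inf + (ell^0 - ell^inf) exp(-d / d_ell)``, increasing
    from 0.0003 m at contact to the 0.0013 m free-walking maximum.
    """
    params = params or ModelParams()
    d = _effective_distance(d, params)
    out = params.ell_inf + (params.ell_0 - params.ell_inf) * np.exp(-d / params.d_ell)
    return out if out.ndim else float(out)


def spread_param(d, params: ModelParams | None = None):
    """Wrapped-Cauchy concentration rho(d) of the turning-angle distribution.

    ``rho(d) = rho^inf + (rho^0 - rho^inf) exp(-d / d_rho)``.  Isolated
    animals walk nearly straight (rho -> 0.9013); crowded ones turn widely
    (rho -> 0.1387).
    """
    params = params or ModelParams()
    d = _effective_distance(d, params)
    out = params.rho_inf + (params.rho_0 - params.rho_inf) * np.exp(-d / params.d_rho)
    return out if out.ndim else float(out)


def _check_rho(rho) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho >= 1)):
        raise ValueError("wrapped-Cauchy spread rho must lie in [0, 1)")
    return rho


def wrapped_cauchy_pdf(theta, rho):
    """Density of the zero-centred wrapped Cauchy distribution on (-pi, pi].

    ``f(theta) = (1 - rho^2) / (2 pi (1 + rho^2 - 2 rho cos theta))``.
    rho = 0 reduces to the uniform circular density 1/(2 pi).
    """
    rho = _check_rho(rho)
    theta = np.asarray(theta, dtype=float)
    out = (1.0 - rho**2) / (2.0 * math.pi * (1.0 + rho**2 - 2.0 * rho * np.cos(theta)))
    return out if out.ndim else float(out)


def sample_turning_angle(rho, rng: np.random.Generator, size=None):
    """Draw turning angles in (-pi, pi] from the wrapped Cauchy distribution.

    Inverse-CDF sampling: with U uniform on (0, 1),
    ``theta = 2 atan( (1 - rho)/(1 + rho) * tan(pi (U - 1/2)) )``.
    ``rho`` may be an array, in which case one angle is drawn per entry.
    """
    rho = _check_rho(rho)
    if size is None:
        size = rho.shape if rho.ndim else None
    u = rng.random(size)
    theta = 2.0 * np.arctan(((1.0 - rho) / (1.0 + rho)) * np.tan(np.pi * (u - 0.5)))
    return theta if np.ndim(theta) else float(theta)
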
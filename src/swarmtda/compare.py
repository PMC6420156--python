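"""Model selection: distances to a reference and Bonferroni-corrected verdicts.

For each summary measure (an order-parameter time series or a crocker
matrix) the distance from the reference trajectory's summary to each run
of a model ensemble is a Euclidean/Frobenius norm.  With ensemble means
D_int and D_con, the decision statistic is D = D_con - D_int with a
Bonferroni-corrected 95% confidence radius R95: the interval
[D - R95, D + R95] excluding zero declares one model significantly more
faithful to the reference (D > 0: interactive; D < 0: control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .orderparams import OrderParamSeries
from .topology import Crocker

__all__ = [
    "DistanceSample",
    "ComparisonResult",
    "series_distance",
    "crocker_distance",
    "ensemble_mean_distance",
    "compare_models",
    "results_table",
]

#: Comparisons in the full study: nine measures on nine experiments.
DEFAULT_N_COMPARISONS = 81


@dataclass
class DistanceSample:
    """Per-run distances of the two model ensembles to one reference."""

    measure: str
    interactive: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        self.interactive = np.asarray(self.interactive, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        for name, arr in (("interactive", self.interactive), ("control", self.control)):
            if arr.size == 0:
                raise ValueError(f"{name} distance list is empty")
            if np.any(arr < 0):
                raise ValueError("distances must be nonnegative")


@dataclass
class ComparisonResult:
    """Decision for one measure: D = D_con - D_int with its 95% radius."""

    measure: str
    d_int: float
    d_con: float
    d: float
    r95: float
    alpha_corrected: float
    verdict: str

    def __post_init__(self) -> None:
        expected = _verdict(self.d, self.r95)
        if self.verdict != expected:
            raise ValueError(f"verdict {self.verdict!r} violates the interval rule")


def _verdict(d: float, r95: float) -> str:
    if d - r95 > 0:
        return "interactive"
    if d + r95 < 0:
        return "control"
    return "inconclusive"


def series_distance(a: OrderParamSeries, b: OrderParamSeries) -> float:
    """Euclidean distance between two series on their common frames.

    Frames where either value is missing (NaN, e.g. tracking dropouts)
    are excluded pairwise before the norm.
    """
    common, ia, ib = np.intersect1d(a.times, b.times, return_indices=True)
    if len(common) == 0:
        raise ValueError("series share no frames")
    va, vb = a.values[ia], b.values[ib]
    keep = np.isfinite(va) & np.isfinite(vb)
    if not np.any(keep):
        raise ValueError("series share no frames with defined values")
    return float(np.sqrt(np.sum((va[keep] - vb[keep]) ** 2)))


def crocker_distance(a, b) -> float:
    """Frobenius distance between two crockers (or stacked crocker matrices)."""
    ma = np.asarray(a.betti if isinstance(a, Crocker) else a, dtype=float)
    mb = np.asarray(b.betti if isinstance(b, Crocker) else b, dtype=float)
    if ma.shape != mb.shape:
        raise ValueError(f"crocker grids differ: {ma.shape} vs {mb.shape}")
    if isinstance(a, Crocker) and isinstance(b, Crocker):
        if not np.allclose(a.eps_grid, b.eps_grid) or not np.array_equal(a.times, b.times):
            raise ValueError("crocker grids differ")
    return float(np.linalg.norm(ma - mb))


def ensemble_mean_distance(reference, runs, metric) -> tuple[float, np.ndarray]:
    """Mean distance of an ensemble to the reference, plus per-run values."""
    if len(runs) < 2:
        raise ValueError("an ensemble needs at least 2 runs")
    per_run = np.array([metric(reference, run) for run in runs], dtype=float)
    return float(per_run.mean()), per_run


def compare_models(
    reference,
    int_runs,
    con_runs,
    metric,
    measure: str = "",
    n_comparisons: int = DEFAULT_N_COMPARISONS,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Welch two-sample interval on D = D_con - D_int at level alpha/n.

    ``reference`` and the runs are summaries (series or crockers) fed to
    ``metric``; per-run distances are treated as independent samples.  The
    unpooled-variance (Satterthwaite) t interval is used; the verdict is
    ``interactive`` when the corrected interval lies above zero, ``control``
    below, else ``inconclusive``.
    """
    d_int, samp_int = ensemble_mean_distance(reference, int_runs, metric)
    d_con, samp_con = ensemble_mean_distance(reference, con_runs, metric)
    return compare_distance_samples(
        DistanceSample(measure, samp_int, samp_con),
        n_comparisons=n_comparisons,
        alpha=alpha,
    )


def compare_distance_samples(
    sample: DistanceSample,
    n_comparisons: int = DEFAULT_N_COMPARISONS,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Decision from precomputed per-run distance lists."""
    if len(sample.interactive) < 2 or len(sample.control) < 2:
        raise ValueError("each ensemble needs at least 2 runs")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    xi, xc = sample.interactive, sample.control
    d = float(xc.mean() - xi.mean())
    vi, vc = xi.var(ddof=1), xc.var(ddof=1)
    ni, nc = len(xi), len(xc)
    se2 = vi / ni + vc / nc
    alpha_corr = alpha / n_comparisons
    if se2 == 0:
        r95 = 0.0
    else:
        df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vc / nc) ** 2 / (nc - 1))
        r95 = float(stats.t.ppf(1 - alpha_corr / 2, df) * np.sqrt(se2))
    return ComparisonResult(
        measure=sample.measure,
        d_int=float(xi.mean()),
        d_con=float(xc.mean()),
        d=d,
        r95=r95,
        alpha_corrected=alpha_corr,
        verdict=_verdict(d, r95),
    )


def results_table(results: list[ComparisonResult], experiment: str | None = None) -> pd.DataFrame:
    """Tabular report: one row per measure with D, R95 and the verdict."""
    rows = []
    for r in results:
        row = {
            "measure": r.measure,
            "D_int": r.d_int,
            "D_con": r.d_con,
            "D": r.d,
            "R95": r.r95,
            "alpha_corrected": r.alpha_corrected,
            "verdict": r.verdict,
        }
        if experiment is not None:
            row = {"experiment": experiment, **row}
        rows.append(row)
    columns = (["experiment"] if experiment is not None else []) + [
        "measure", "D_int", "D_con", "D", "R95", "alpha_corrected", "verdict",
    ]
    return pd.DataFrame(rows, columns=columns)
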
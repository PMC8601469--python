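"""Summary statistics of simulated messenger fields.

Implements every scalar and series diagnostic used to characterise a run:
the spatial mean field ``ubar(t)``, the spatial standard deviation
``sigma(t)`` of the messenger, the von Neumann nearest-neighbor covariance
``Cov(t)``, the synchrony index ``S = < Cov(t) / sigma^2(t) >_t``, the
exponential-growth fit of ``log sigma`` with its plateau level and crossover
time, and space-time kymographs.

All spatial sums run over the full ``N^2`` grid, empty sites included, with
``1/N^2`` normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .dynamics import Trajectory, neighbor_sum

__all__ = [
    "SummarySeries",
    "mean_field",
    "spatial_std",
    "neighbor_covariance",
    "synchrony_index",
    "fit_growth_line",
    "plateau_level",
    "crossover_time",
    "kymograph",
    "summarize",
    "UndefinedSynchronyError",
]


class UndefinedSynchronyError(ValueError):
    """The synchrony index is undefined (no sample with spatial variance)."""


def mean_field(u: np.ndarray) -> float:
    """Arithmetic mean of the messenger over all grid sites."""
    u = np.asarray(u)
    if u.size == 0:
        raise ValueError("cannot take the mean field of an empty grid")
    return float(u.mean())


def spatial_std(u: np.ndarray) -> float:
    """Population (divide-by-N^2) RMS deviation of u from its spatial mean."""
    return float(np.asarray(u).std())


def neighbor_covariance(u: np.ndarray, bc: str = "noflux") -> float:
    """Mean centered product with the 4 von Neumann neighbors.

    ``Cov = N^-2 sum_ij (1/4) sum_b (u_ij - ubar)(u_b - ubar)`` where ``b``
    runs over the von Neumann neighborhood; edge neighbors are mirrored under
    no-flux and wrapped under periodic, matching the simulator's stencil.
    """
    u = np.asarray(u, dtype=float)
    if u.shape[0] < 2 or u.shape[1] < 2:
        raise ValueError("neighbor covariance needs a grid of at least 2x2")
    ubar = u.mean()
    du = u - ubar
    return float(np.mean(du * 0.25 * (neighbor_sum(u, bc=bc) - 4.0 * ubar)))


@dataclass
class SummarySeries:
    """Per-iteration summary series of one run plus derived scalars."""

    iterations: np.ndarray
    ubar: np.ndarray
    sigma: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.iterations)
        if not (len(self.ubar) == len(self.sigma) == len(self.cov) == n):
            raise ValueError("all summary series must share one iteration axis")

    @classmethod
    def from_trajectory(cls, traj: Trajectory) -> "SummarySeries":
        return cls(
            iterations=np.asarray(traj.iterations),
            ubar=np.asarray(traj.ubar),
            sigma=np.asarray(traj.sigma),
            cov=np.asarray(traj.cov),
        )


def synchrony_index(
    series: SummarySeries,
    window: Optional[Tuple[int, int]] = None,
    sigma_floor: float = 1e-12,
    n_head: int = 300,
) -> float:
    """Time average of ``Cov(t)/sigma^2(t)``; 1 for perfect synchrony.

    The default window discards the first ``n_head`` iterations (the
    exponential-growth transient) so that S characterises the oscillatory
    regime.  Iterations with ``sigma^2 <= sigma_floor`` are excluded; if none
    remain the medium is dead and S is undefined.
    """
    it = series.iterations
    if window is None:
        keep = it > n_head
    else:
        keep = (it >= window[0]) & (it <= window[1])
    var = series.sigma**2
    keep &= var > sigma_floor
    if not np.any(keep):
        raise UndefinedSynchronyError(
            "synchrony index undefined: no iteration in the window has "
            f"spatial variance above {sigma_floor}"
        )
    return float(np.mean(series.cov[keep] / var[keep]))


def fit_growth_line(log_sigma: np.ndarray, n_head: int = 300) -> Tuple[float, float]:
    """OLS fit of ``log sigma`` against iteration over the first ``n_head``
    samples; returns ``(slope, intercept)`` of the growth regime."""
    log_sigma = np.asarray(log_sigma, dtype=float)
    if len(log_sigma) < n_head:
        raise ValueError(
            f"series has {len(log_sigma)} samples, need at least n_head={n_head}"
        )
    head = log_sigma[:n_head]
    if not np.all(np.isfinite(head)):
        raise ValueError(
            "log(sigma) is undefined in the head window (sigma = 0 somewhere); "
            "seed more firing cells so the growth phase has nonzero width"
        )
    t = np.arange(1, n_head + 1, dtype=float)
    slope, intercept = np.polyfit(t, head, 1)
    return float(slope), float(intercept)


def plateau_level(log_sigma: np.ndarray, n_tail: int = 3000) -> float:
    """Mean of the last ``n_tail`` values of ``log sigma`` (saturated regime)."""
    log_sigma = np.asarray(log_sigma, dtype=float)
    if len(log_sigma) < n_tail:
        raise ValueError(
            f"series has {len(log_sigma)} samples, need at least n_tail={n_tail}"
        )
    return float(np.mean(log_sigma[-n_tail:]))


def crossover_time(
    series: SummarySeries, n_head: int = 300, n_tail: int = 3000
) -> float:
    """Iteration where the early growth line meets the late plateau level.

    ``log sigma(t)`` grows linearly at first and then oscillates around a
    saturated value; the crossover ``T = (plateau - intercept)/slope`` marks
    the transition between the two dynamical regimes.
    """
    log_sigma = np.log(series.sigma)
    slope, intercept = fit_growth_line(log_sigma, n_head=n_head)
    if slope <= 0:
        raise ValueError(
            f"no growth regime: the head-window slope is {slope:.3g} <= 0"
        )
    plateau = plateau_level(log_sigma, n_tail=n_tail)
    return float((plateau - intercept) / slope)


def kymograph(traj: Trajectory, row: Optional[int] = None, last_n: int = 2000) -> np.ndarray:
    """Space-time matrix of ``sqrt(u)`` along one lattice row.

    Uses the recorded field snapshots whose iteration stamps fall in the
    last ``last_n`` iterations; rows of the result are snapshots in time,
    columns are lattice sites.  Defaults to the middle row.  Tiny negative
    round-off in ``u`` is clipped to 0 before the square root.
    """
    if traj.u_snapshots is None or len(traj.snapshot_iterations) == 0:
        raise ValueError("trajectory has no recorded field snapshots")
    N = traj.u_snapshots.shape[1]
    if row is None:
        row = N // 2
    if not 0 <= row < N:
        raise IndexError(f"row {row} out of range for lattice of size {N}")
    t_end = int(traj.iterations[-1])
    keep = traj.snapshot_iterations > t_end - last_n
    if not np.any(keep):
        raise ValueError(
            f"no snapshots fall inside the last {last_n} iterations"
        )
    strip = traj.u_snapshots[keep, row, :]
    return np.sqrt(np.clip(strip, 0.0, None))


def summarize(
    traj: Trajectory,
    n_head: int = 300,
    n_tail: int = 3000,
    sigma_floor: float = 1e-12,
) -> dict:
    """All scalar diagnostics of a run in one dictionary.

    Returns S, the growth slope and intercept, the plateau level, the
    crossover time T and the post-crossover time average of ubar.  Scalars
    whose preconditions fail (dead medium, short series) come back as None
    rather than aborting, so surveys can tabulate degenerate cells.
    """
    series = SummarySeries.from_trajectory(traj)
    out: dict = {}
    try:
        out["S"] = synchrony_index(series, sigma_floor=sigma_floor, n_head=n_head)
    except UndefinedSynchronyError:
        out["S"] = None
    with np.errstate(divide="ignore"):
        log_sigma = np.log(series.sigma)
    try:
        slope, intercept = fit_growth_line(log_sigma, n_head=n_head)
        out["growth_slope"], out["growth_intercept"] = slope, intercept
    except (ValueError, FloatingPointError):
        out["growth_slope"] = out["growth_intercept"] = None
    try:
        out["plateau_level"] = plateau_level(log_sigma, n_tail=n_tail)
    except ValueError:
        out["plateau_level"] = None
    try:
        out["crossover_T"] = crossover_time(series, n_head=n_head, n_tail=n_tail)
    except ValueError:
        out["crossover_T"] = None
    # mean field over the oscillatory (post-crossover) regime; falls back to
    # the post-head window when no crossover is identifiable
    t_start = n_head
    if out["crossover_T"] is not None and np.isfinite(out["crossover_T"]):
        t_start = max(n_head, out["crossover_T"])
    post = series.iterations > t_start
    if not np.any(post):
        post = series.iterations > n_head
    out["ubar_mean"] = float(np.mean(series.ubar[post])) if np.any(post) else None
    return out
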
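"""Heuristic classification of wave patterns via phase-singularity counting.

The underlying study distinguishes circular (target) waves, spiral waves and
pattern-free noisy media by visual inspection of snapshots.  This module
replaces the eye with a transparent topological heuristic: a local phase is
assigned to every site from its position in the (u, v) excursion plane, and
spiral tips are counted as the plaquettes around which that phase winds by
+-2pi.  Sustained tips mean spirals; wave activity without sustained tips
means target waves.  The label is advisory - thresholds are configurable and
the rule is deliberately simple rather than a substitute for judgment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dynamics import Trajectory

__all__ = [
    "phase_field",
    "count_phase_singularities",
    "classify_pattern",
    "PatternReport",
]

#: pattern labels
NONE, CIRCULAR, SPIRAL, NOISY = "NONE", "CIRCULAR", "SPIRAL", "NOISY"


@dataclass
class PatternReport:
    """Per-snapshot spiral-tip counts and the resulting advisory label."""

    tip_counts: np.ndarray
    sustained_tip_fraction: float
    wave_activity: bool
    sigma_plateau: float
    label: str


def phase_field(
    u: np.ndarray,
    v: np.ndarray,
    u_ref: float = 0.3,
    v_ref: float = 0.05,
) -> np.ndarray:
    """Local phase ``atan2(v - v_ref, u - u_ref)`` in (-pi, pi].

    The reference point must sit strictly inside the excursion loop traced in
    the (u, v) plane during a pulse, so that a full excursion winds the phase
    once around it.  The default sits between the rest state near (0, 0) and
    the excited plateau near (1, v_peak).
    """
    return np.arctan2(np.asarray(v) - v_ref, np.asarray(u) - u_ref)


def _wrap(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences into (-pi, pi]."""
    return (dphi + np.pi) % (2.0 * np.pi) - np.pi


def count_phase_singularities(theta: np.ndarray) -> int:
    """Number of 2x2 plaquettes with winding number +-1.

    The wrapped phase differences around each elementary plaquette are
    summed; a total of +-2pi marks a phase singularity (spiral tip).
    """
    t00 = theta[:-1, :-1]
    t01 = theta[:-1, 1:]
    t11 = theta[1:, 1:]
    t10 = theta[1:, :-1]
    winding = (
        _wrap(t01 - t00) + _wrap(t11 - t01) + _wrap(t10 - t11) + _wrap(t00 - t10)
    )
    return int(np.count_nonzero(np.abs(winding) > np.pi))


def classify_pattern(
    traj: Trajectory,
    window: slice | None = None,
    activity_floor: float = 1e-3,
    spiral_fraction: float = 0.5,
    circular_fraction: float = 0.1,
    smooth_sigma: float = 2.0,
    u_ref: float = 0.3,
    v_ref: float = 0.05,
) -> PatternReport:
    """Advisory pattern label for a recorded trajectory.

    Decision rule: ``NONE`` if the late sigma plateau sits below
    ``activity_floor`` (no waves, only local flicker); otherwise ``SPIRAL``
    if at least ``spiral_fraction`` of the window's snapshots contain a
    phase singularity, ``CIRCULAR`` if fewer than ``circular_fraction`` do,
    and ``NOISY`` in between.  Fields are lightly Gaussian-smoothed before
    phase extraction so single-site occupancy noise does not register as a
    singularity.
    """
    if traj.u_snapshots is None or len(traj.snapshot_iterations) == 0:
        raise ValueError("trajectory has no recorded field snapshots to classify")
    window = window if window is not None else slice(None)
    u_snaps = traj.u_snapshots[window]
    v_snaps = traj.v_snapshots[window]
    if len(u_snaps) == 0:
        raise ValueError("classification window contains no snapshots")

    counts = np.empty(len(u_snaps), dtype=int)
    for k, (us, vs) in enumerate(zip(u_snaps, v_snaps)):
        if smooth_sigma > 0:
            us = ndimage.gaussian_filter(us, smooth_sigma)
            vs = ndimage.gaussian_filter(vs, smooth_sigma)
        counts[k] = count_phase_singularities(phase_field(us, vs, u_ref, v_ref))

    n_tail = min(len(traj.sigma), 3000)
    sigma_plateau = float(np.mean(traj.sigma[-n_tail:]))
    active = sigma_plateau > activity_floor
    frac = float(np.mean(counts > 0))

    if not active:
        label = NONE
    elif frac >= spiral_fraction:
        label = SPIRAL
    elif frac < circular_fraction:
        label = CIRCULAR
    else:
        label = NOISY
    return PatternReport(
        tip_counts=counts,
        sustained_tip_fraction=frac,
        wave_activity=active,
        sigma_plateau=sigma_plateau,
        label=label,
    )
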
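"""Tiny deterministic lattices and synthetic fields for tests and demos.

Everything here is generated programmatically and is small enough to
eyeball; the synthetic phase/spiral fields carry a known topological charge
so tip-counting can be checked against construction.
"""

from __future__ import annotations

import numpy as np

from .lattice import PopulationLattice, generate_lattice

__all__ = [
    "tiny_lattice",
    "full_lattice",
    "spiral_phase",
    "target_wave_u",
    "two_regime_log_sigma",
]


def tiny_lattice(N: int = 10, phi1: float = 0.5, phi2: float = 0.2, seed: int = 7) -> PopulationLattice:
    """A small mixed lattice with fixed seed, for fast deterministic tests."""
    return generate_lattice(N, phi1, phi2, seed)


def full_lattice(N: int = 16, phi2: float = 0.0, seed: int = 0) -> PopulationLattice:
    """Fully occupied lattice (phi1 = 1), optionally with reactive cells."""
    return generate_lattice(N, 1.0, phi2, seed)


def spiral_phase(N: int, center: tuple[float, float] | None = None, charge: int = 1) -> np.ndarray:
    """Phase field of a single Archimedean spiral with winding ``charge``.

    The phase winds by ``2*pi*charge`` around ``center`` (default: the grid
    midpoint offset off-lattice so no site sits exactly on the singularity).
    """
    if center is None:
        center = (N / 2 - 0.5 + 0.25, N / 2 - 0.5 + 0.25)
    i, j = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    theta = np.arctan2(j - center[1], i - center[0])
    return np.angle(np.exp(1j * charge * theta))


def target_wave_u(N: int, radius: float, width: float = 3.0) -> np.ndarray:
    """A circular excitation ring of the messenger, centered on the grid."""
    i, j = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    r = np.hypot(i - (N - 1) / 2, j - (N - 1) / 2)
    return np.exp(-((r - radius) ** 2) / (2.0 * width**2))


def two_regime_log_sigma(
    n: int = 6000,
    slope: float = 0.01,
    intercept: float = -6.0,
    plateau: float = -1.0,
) -> np.ndarray:
    """Piecewise log-sigma series: linear growth that saturates at a plateau.

    The exact regression/plateau intersection is at
    ``T = (plateau - intercept) / slope``, which makes the series a
    closed-form oracle for crossover-time recovery.
    """
    t = np.arange(1, n + 1, dtype=float)
    return np.minimum(intercept + slope * t, plateau)
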
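"""Kinetic, noise, and numerical parameters of the two-type excitable model.

Local kinetics (per occupied site)::

    du/dt = f(u, v) + D_u * laplacian(u)
    dv/dt = u - v + eta
    deta/dt = -lam * eta + sqrt(2 * D * lam) * xi(t)        (Ornstein-Uhlenbeck)

with ``f(u, v) = (1/epsilon) * u * (1 - u) * (u - u_th)`` for proactive
(amplifying) cells and ``f(u, v) = u - u_th`` for reactive cells, where the
excitation threshold is ``u_th = (v + b) / a``.  Empty sites only diffuse
``u``.

The defaults below are a one-time calibration to the circular-wave regime of
a pure population: a stable rest state, propagating target waves re-emitted
by noise-nucleated pacemakers at occupancies of 0.4 and above, and sustained
noise-driven activity in amplifier-poor mixtures.  See ``docs/methods.md``
for the calibration protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

__all__ = ["ModelParams", "BOUNDARY_CONDITIONS"]

BOUNDARY_CONDITIONS = ("noflux", "periodic")


@dataclass(frozen=True)
class ModelParams:
    """All model constants for a run.

    Parameters
    ----------
    a, b
        Controlling parameters of the excitation threshold
        ``u_th = (v + b)/a``; the rest state is excitable for ``b > 0``.
    epsilon
        Time-scale ratio of the fast activator ``u`` to the slow recovery
        variable ``v``; smaller values give sharper, faster pulses.
    delta
        Boundary-layer size: a proactive site with ``u < delta`` is treated
        as at rest and its reaction is skipped (fast-slow simplification);
        ``u > delta`` is also the excitation predicate used in reporting.
    D
        Intensity (stationary variance) of the Ornstein-Uhlenbeck noise fed
        into the recovery equation.
    lam
        OU rate; ``1/lam`` is the noise correlation time.  The default
        (slow, persistent noise with a ~3-time-unit memory) lets transient
        sub-threshold cells act as pacemakers; :meth:`fast_noise` switches
        to a cutoff at the fast kinetic rate ``1/epsilon``.
    dt
        Integration time step.
    h
        Lattice spacing (one cell diameter).
    D_u
        Diffusion coefficient of the messenger ``u``.
    bc
        Boundary condition, ``"noflux"`` (mirrored edges) or ``"periodic"``.
    decay
        Optional linear degradation rate of ``u`` on empty sites (default 0:
        the messenger is only transported, never destroyed, between cells).
    u_cap
        Optional guard ceiling; exceeding it aborts the run with a
        diagnostic instead of silently clipping.
    shared_noise
        If True, one OU sample per step is shared by every occupied site
        (sensitivity-analysis mode); default is independent noise per site.
    """

    a: float = 0.75
    b: float = 0.04
    epsilon: float = 0.02
    delta: float = 1e-4
    D: float = 0.005
    lam: float = 0.3
    dt: float = 0.01
    h: float = 0.55
    D_u: float = 1.0
    bc: str = "noflux"
    decay: float = 0.0
    u_cap: Optional[float] = None
    shared_noise: bool = False

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.lam < 0:
            raise ValueError(f"lam must be non-negative, got {self.lam}")
        if self.D < 0:
            raise ValueError(f"D must be non-negative, got {self.D}")
        if self.decay < 0:
            raise ValueError(f"decay must be non-negative, got {self.decay}")
        if self.bc not in BOUNDARY_CONDITIONS:
            raise ValueError(
                f"unknown boundary condition {self.bc!r}; expected one of {BOUNDARY_CONDITIONS}"
            )
        stab = self.D_u * self.dt / self.h**2
        if stab > 0.25:
            raise ValueError(
                f"explicit diffusion unstable: D_u*dt/h^2 = {stab:.3g} > 1/4; "
                "reduce dt or D_u, or increase h"
            )

    @classmethod
    def fast_noise(cls, **overrides) -> "ModelParams":
        """Preset with the noise cutoff at ``lam = 1/epsilon`` (white-ish
        noise at the fast kinetic rate) instead of the slow default."""
        eps = overrides.get("epsilon", cls.epsilon)
        overrides.setdefault("lam", 1.0 / eps)
        return cls(**overrides)

    @classmethod
    def slow_noise(cls, **overrides) -> "ModelParams":
        """Preset with the noise cutoff at ``lam = epsilon`` (quasi-static
        cell-to-cell heterogeneity)."""
        eps = overrides.get("epsilon", cls.epsilon)
        overrides.setdefault("lam", eps)
        return cls(**overrides)

    def to_dict(self) -> dict:
        return asdict(self)
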
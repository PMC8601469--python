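"""Time integration of the two-type stochastic reaction-diffusion system.

The activator update of proactive cells uses the fast-slow semi-implicit
scheme of the Barkley excitable-media model: the cubic reaction
``(1/eps) u (1-u)(u - u_th)`` is advanced with the factor ``(u - u_th)``
frozen over the step and the remaining logistic part treated implicitly in
whichever direction is destabilising.  This keeps ``u`` inside ``[0, 1]``
for arbitrary ``dt/eps`` and preserves the character of the fast jumps.
Below the boundary layer ``u < delta`` the reaction is skipped entirely and
a site's local dynamics reduces to exponential decay of ``v``.

Reactive (non-amplifying) cells replace the cubic by the mild linear term
``u - u_th``, integrated with explicit Euler and clamped to the physical
concentration range [0, excited plateau]: the floor keeps a resting cell
pinned at ``u = 0`` (instead of draining toward the negative root
``b/(a-1)`` of the linear kinetics) while still letting it fire
spontaneously whenever noise drives its threshold negative, and the cap
bounds the relay at the same level where the cubic's growth stops.  Empty
sites only diffuse ``u``.  The Ornstein-Uhlenbeck noise ``eta`` on the recovery
equation is advanced with its exact one-step transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .lattice import FieldState, PopulationLattice, initialize_state
from .params import ModelParams

__all__ = [
    "u_threshold",
    "proactive_rate",
    "reactive_rate",
    "ou_update",
    "laplacian",
    "step",
    "simulate",
    "Trajectory",
    "NumericalInstabilityError",
]


class NumericalInstabilityError(RuntimeError):
    """Raised when a field becomes non-finite (or exceeds the guard ceiling)."""


def u_threshold(v, params: ModelParams):
    """Excitation threshold ``u_th = (v + b) / a`` of the activator."""
    return (np.asarray(v) + params.b) / params.a


def proactive_rate(u, v, params: ModelParams):
    """Cubic amplifying kinetics ``(1/eps) u (1 - u)(u - u_th)``.

    Zero at the rest state ``u = 0``, the excited plateau ``u = 1`` and the
    threshold ``u = u_th``; negative below threshold, positive above.
    """
    u = np.asarray(u, dtype=float)
    return u * (1.0 - u) * (u - u_threshold(v, params)) / params.epsilon


def reactive_rate(u, v, params: ModelParams):
    """Linear non-amplifying kinetics ``u - u_th`` (no fast 1/eps factor)."""
    return np.asarray(u, dtype=float) - u_threshold(v, params)


def ou_update(eta, params: ModelParams, rng: np.random.Generator):
    """Advance the OU noise by one step with the exact transition density.

    ``eta' = eta * exp(-lam dt) + sqrt(D (1 - exp(-2 lam dt))) * z`` with
    ``z`` standard normal; the stationary law is N(0, D) and the
    autocorrelation at lag ``tau`` is ``exp(-lam tau)``.
    """
    eta = np.asarray(eta, dtype=float)
    decay = np.exp(-params.lam * params.dt)
    sd = np.sqrt(params.D * (1.0 - decay**2))
    return eta * decay + sd * rng.standard_normal(eta.shape)


def laplacian(f: np.ndarray, bc: str = "noflux", h: float = 1.0) -> np.ndarray:
    """Five-point discrete Laplacian with mirrored (no-flux) or wrapped edges."""
    if bc == "periodic":
        s = (
            np.roll(f, 1, axis=0)
            + np.roll(f, -1, axis=0)
            + np.roll(f, 1, axis=1)
            + np.roll(f, -1, axis=1)
        )
    elif bc == "noflux":
        fp = np.pad(f, 1, mode="edge")
        s = fp[:-2, 1:-1] + fp[2:, 1:-1] + fp[1:-1, :-2] + fp[1:-1, 2:]
    else:
        raise ValueError(f"unknown boundary condition {bc!r}")
    return (s - 4.0 * f) / h**2


def neighbor_sum(f: np.ndarray, bc: str = "noflux") -> np.ndarray:
    """Sum of the 4 von Neumann neighbors under the given edge convention."""
    return laplacian(f, bc=bc, h=1.0) + 4.0 * f


@dataclass
class _SiteIndex:
    """Precomputed flat index arrays for one lattice (private step helper)."""

    occ: np.ndarray
    pro: np.ndarray
    rea: np.ndarray
    empty: np.ndarray

    @classmethod
    def from_lattice(cls, lattice: PopulationLattice) -> "_SiteIndex":
        flat = lattice.type_map.ravel()
        return cls(
            occ=np.flatnonzero(flat),
            pro=np.flatnonzero(flat == 1),
            rea=np.flatnonzero(flat == 2),
            empty=np.flatnonzero(flat == 0),
        )


def _barkley_update(u: np.ndarray, uth: np.ndarray, dt_over_eps: float) -> np.ndarray:
    """Semi-implicit one-step advance of du/dt = (1/eps) u (1-u)(u - uth).

    With alpha = (dt/eps)(u - uth) frozen, the growing branch treats (1-u)
    implicitly and the decaying branch treats u implicitly, so the map is a
    contraction onto [0, 1] whichever way the cubic pushes.
    """
    alpha = dt_over_eps * (u - uth)
    grow = alpha > 0
    out = np.empty_like(u)
    # decay toward 0: u' = u / (1 - alpha (1 - u))
    np.copyto(out, u / (1.0 - alpha * (1.0 - u)))
    # growth toward 1: 1 - u' = (1 - u) / (1 + alpha u)
    out[grow] = 1.0 - (1.0 - u[grow]) / (1.0 + alpha[grow] * u[grow])
    return out


def step(
    state: FieldState,
    lattice: PopulationLattice,
    params: ModelParams,
    rng: np.random.Generator,
    _idx: Optional[_SiteIndex] = None,
) -> FieldState:
    """Advance the full system by one time step ``dt`` (returns a new state).

    Per-site contract: empty sites diffuse ``u`` only (plus the optional
    linear decay); proactive sites with ``u >= delta`` take the semi-implicit
    cubic update plus diffusion; proactive sites below the boundary layer
    skip the reaction; reactive sites take the explicit linear update,
    clamped to [0, max(u, 1)], plus diffusion.  ``v`` relaxes as
    ``dv = dt (u - v + eta)`` on occupied sites and ``eta`` is refreshed
    everywhere occupied by the exact OU transition.
    """
    idx = _idx if _idx is not None else _SiteIndex.from_lattice(lattice)
    u, v, eta = state.u, state.v, state.eta
    dt = params.dt

    diff = dt * params.D_u * laplacian(u, bc=params.bc, h=params.h)

    u_new = u + diff
    uf, vf = u.ravel(), v.ravel()
    unf = u_new.ravel()

    if params.decay > 0 and idx.empty.size:
        unf[idx.empty] -= dt * params.decay * uf[idx.empty]

    if idx.pro.size:
        up = uf[idx.pro]
        active = up >= params.delta
        if np.any(active):
            act = idx.pro[active]
            uth = (vf[act] + params.b) / params.a
            unf[act] = _barkley_update(uf[act], uth, dt / params.epsilon) + diff.ravel()[act]

    if idx.rea.size:
        ua = uf[idx.rea]
        uth = (vf[idx.rea] + params.b) / params.a
        # Linear relay, clamped to the physical concentration range: the
        # reaction can neither push u below 0 (so a resting reactive cell is
        # pinned at the floor instead of draining toward the negative root
        # b/(a-1) of its kinetics, yet fires spontaneously whenever noise
        # drives u_th negative) nor raise it beyond the excited plateau u=1
        # (finite secretion capacity; unbounded, the trace-zero linear
        # kinetics is a neutrally stable center that wave-driven media pump
        # to arbitrary amplitude).  Diffusion is unrestricted.
        u_react = np.clip(ua + dt * (ua - uth), 0.0, None)
        np.minimum(u_react, np.maximum(ua, 1.0), out=u_react)
        unf[idx.rea] = u_react + diff.ravel()[idx.rea]

    v_new = v.copy()
    eta_new = eta.copy()
    if idx.occ.size:
        vnf, enf = v_new.ravel(), eta_new.ravel()
        vnf[idx.occ] = vf[idx.occ] + dt * (uf[idx.occ] - vf[idx.occ] + eta.ravel()[idx.occ])
        decay_fac = np.exp(-params.lam * dt)
        sd = np.sqrt(params.D * (1.0 - decay_fac**2))
        if params.shared_noise:
            z = rng.standard_normal()
        else:
            z = rng.standard_normal(idx.occ.size)
        enf[idx.occ] = eta.ravel()[idx.occ] * decay_fac + sd * z

    new = FieldState(u=u_new, v=v_new, eta=eta_new, iteration=state.iteration + 1)
    _check_finite(new, params)
    return new


def _check_finite(state: FieldState, params: ModelParams) -> None:
    for name, f in (("u", state.u), ("v", state.v), ("eta", state.eta)):
        if not np.all(np.isfinite(f)):
            i, j = np.unravel_index(int(np.argmin(np.isfinite(f))), f.shape)
            raise NumericalInstabilityError(
                f"non-finite {name} at site ({i}, {j}) after iteration "
                f"{state.iteration}; the time step dt={params.dt} is likely too large"
            )
    if params.u_cap is not None:
        amax = float(np.abs(state.u).max())
        if amax > params.u_cap:
            i, j = np.unravel_index(int(np.abs(state.u).argmax()), state.u.shape)
            raise NumericalInstabilityError(
                f"|u| = {amax:.3g} exceeded the guard ceiling u_cap={params.u_cap} "
                f"at site ({i}, {j}), iteration {state.iteration}"
            )


@dataclass
class Trajectory:
    """Recorded time series of a simulation run.

    ``iterations`` stamps every recorded summary sample; the per-iteration
    series ``ubar`` (spatial mean of u), ``sigma`` (spatial standard
    deviation) and ``cov`` (von Neumann neighbor covariance) are recorded at
    every step.  Field snapshots, if requested, are stored every
    ``record_every`` steps together with their own iteration stamps.
    """

    iterations: np.ndarray
    ubar: np.ndarray
    sigma: np.ndarray
    cov: np.ndarray
    snapshot_iterations: np.ndarray
    u_snapshots: Optional[np.ndarray] = None
    v_snapshots: Optional[np.ndarray] = None
    lattice: Optional[PopulationLattice] = None
    params: Optional[ModelParams] = None
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.iterations) <= 0):
            raise ValueError("iteration stamps must be strictly increasing")


def _grid_stats(u: np.ndarray, bc: str) -> tuple[float, float, float]:
    """(mean, std, neighbor covariance) of u over all N^2 sites."""
    ubar = float(u.mean())
    du = u - ubar
    sigma = float(np.sqrt(np.mean(du * du)))
    cov = float(np.mean(du * (neighbor_sum(u, bc=bc) - 4.0 * ubar) * 0.25))
    return ubar, sigma, cov


def simulate(
    lattice: PopulationLattice,
    params: ModelParams,
    n_iter: int,
    record_every: int = 60,
    seed: int = 0,
    record_fields: bool = False,
    state: Optional[FieldState] = None,
    f_fire: float = 0.01,
    u_fire: float = 1.0,
    progress: Optional[object] = None,
) -> Trajectory:
    """Run ``n_iter`` integration steps and record the summary series.

    The initial state is drawn by :func:`initialize_state` (a fraction
    ``f_fire`` of the occupied sites excited at ``u = u_fire``) unless an
    explicit ``state`` is supplied.  Two independent random streams are
    derived from ``seed``: one for the initial firing pattern, one for the
    OU noise, so the same seed reproduces the run bit for bit.

    ``progress`` may be a callable ``(iteration, ubar, sigma, max_u)``
    invoked at every 10% milestone.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be at least 1, got {n_iter}")
    if record_every < 1:
        raise ValueError(f"record_every must be at least 1, got {record_every}")

    ss = np.random.SeedSequence(seed)
    init_seed, noise_seed = ss.spawn(2)
    rng = np.random.default_rng(noise_seed)
    if state is None:
        state = initialize_state(
            lattice,
            f_fire=f_fire,
            u_fire=u_fire,
            seed=init_seed,
            delta=params.delta,
        )
    else:
        state = state.copy()

    idx = _SiteIndex.from_lattice(lattice)
    iters = np.arange(1, n_iter + 1)
    ubar = np.empty(n_iter)
    sigma = np.empty(n_iter)
    cov = np.empty(n_iter)
    snap_iters: list[int] = []
    u_snaps: list[np.ndarray] = []
    v_snaps: list[np.ndarray] = []
    milestone = max(1, n_iter // 10)

    for k in range(n_iter):
        try:
            state = step(state, lattice, params, rng, _idx=idx)
        except NumericalInstabilityError as err:
            raise NumericalInstabilityError(f"iteration {k + 1}: {err}") from err
        ubar[k], sigma[k], cov[k] = _grid_stats(state.u, params.bc)
        if record_fields and (k + 1) % record_every == 0:
            snap_iters.append(k + 1)
            u_snaps.append(state.u.copy())
            v_snaps.append(state.v.copy())
        if progress is not None and (k + 1) % milestone == 0:
            progress(k + 1, ubar[k], sigma[k], float(state.u.max()))

    return Trajectory(
        iterations=iters,
        ubar=ubar,
        sigma=sigma,
        cov=cov,
        snapshot_iterations=np.asarray(snap_iters, dtype=int),
        u_snapshots=np.stack(u_snaps) if u_snaps else None,
        v_snapshots=np.stack(v_snaps) if v_snaps else None,
        lattice=lattice,
        params=params,
        seed=seed,
        meta={"f_fire": f_fire, "u_fire": u_fire, "record_every": record_every},
    )
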
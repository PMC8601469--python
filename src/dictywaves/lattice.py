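"""Random mixed-population lattices and initial field states.

The simulated medium is an N x N square lattice.  A fraction ``phi1`` of the
sites is occupied by cells; among the occupied sites a fraction ``phi2``
carries the *reactive* (non-amplifying, linear-kinetics) phenotype, the rest
are *proactive* (signal-amplifying, cubic-kinetics) cells.  Empty sites carry
no cell but still transport the extracellular messenger by diffusion.

Both fractions are realised by exact sampling without replacement, so the
occupied and reactive counts are deterministic functions of ``(N, phi1,
phi2)`` and only the *placement* is random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EMPTY",
    "PROACTIVE",
    "REACTIVE",
    "PopulationLattice",
    "FieldState",
    "generate_lattice",
    "initialize_state",
    "save_lattice",
    "load_lattice",
]

# site labels in the type map
EMPTY: int = 0
PROACTIVE: int = 1
REACTIVE: int = 2


@dataclass(frozen=True)
class PopulationLattice:
    """Static occupancy and cell-type map of the grid.

    Attributes
    ----------
    size
        Number of sites per side; the grid is ``size x size``.
    type_map
        Integer array of shape ``(size, size)`` with entries in
        ``{EMPTY, PROACTIVE, REACTIVE}``.  Row-major, 0-based indexing.
    phi1
        Fraction of all sites that are occupied by a cell.
    phi2
        Fraction of *occupied* sites that are reactive.
    seed
        Seed used to place the cells.
    """

    size: int
    type_map: np.ndarray = field(repr=False)
    phi1: float
    phi2: float
    seed: int

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of occupied sites."""
        return self.type_map != EMPTY

    @property
    def proactive(self) -> np.ndarray:
        return self.type_map == PROACTIVE

    @property
    def reactive(self) -> np.ndarray:
        return self.type_map == REACTIVE

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.type_map))

    @property
    def n_reactive(self) -> int:
        return int(np.count_nonzero(self.type_map == REACTIVE))


@dataclass
class FieldState:
    """Instantaneous fields over the grid.

    ``u`` is the extracellular messenger (cAMP) level and is defined on every
    site because the messenger diffuses through the whole medium.  ``v`` is
    the receptor/recovery state and ``eta`` the colored-noise value; both are
    meaningful only on occupied sites and are held at 0 on empty sites.
    """

    u: np.ndarray
    v: np.ndarray
    eta: np.ndarray
    iteration: int = 0

    def copy(self) -> "FieldState":
        return FieldState(self.u.copy(), self.v.copy(), self.eta.copy(), self.iteration)


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


def generate_lattice(N: int, phi1: float, phi2: float, seed: int) -> PopulationLattice:
    """Place cells uniformly at random on an ``N x N`` grid.

    Exactly ``round(phi1 * N**2)`` sites are occupied, chosen uniformly
    without replacement; exactly ``round(phi2 * n_occupied)`` of those are
    labelled reactive, again chosen uniformly.  Identical arguments yield
    identical lattices.
    """
    if not isinstance(N, (int, np.integer)) or isinstance(N, bool):
        raise TypeError(f"N must be an integer, got {N!r}")
    if N < 2:
        raise ValueError(f"N must be at least 2, got {N}")
    phi1 = _check_fraction("phi1", phi1)
    phi2 = _check_fraction("phi2", phi2)

    rng = np.random.default_rng(seed)
    n_sites = N * N
    n_occ = int(round(phi1 * n_sites))
    n_rea = int(round(phi2 * n_occ))

    flat = np.zeros(n_sites, dtype=np.int8)
    occ_idx = rng.choice(n_sites, size=n_occ, replace=False)
    flat[occ_idx] = PROACTIVE
    if n_rea:
        rea_idx = rng.choice(occ_idx, size=n_rea, replace=False)
        flat[rea_idx] = REACTIVE
    return PopulationLattice(
        size=int(N),
        type_map=flat.reshape(N, N),
        phi1=phi1,
        phi2=phi2,
        seed=int(seed),
    )


def initialize_state(
    lattice: PopulationLattice,
    f_fire: float = 0.01,
    u_fire: float = 1.0,
    seed: int = 0,
    delta: float = 1e-4,
) -> FieldState:
    """Seed the medium with a random sprinkling of firing cells.

    A fraction ``f_fire`` of the occupied sites receives ``u = u_fire``
    (excited); every other site starts at rest, ``u = 0``.  The recovery
    variable ``v`` and the noise ``eta`` start at 0 everywhere.

    ``u_fire`` must exceed the boundary-layer size ``delta``: a sub-threshold
    "firing" amplitude decays immediately and the medium is silently dead.
    """
    f_fire = _check_fraction("f_fire", f_fire)
    if f_fire > 0 and u_fire <= delta:
        raise ValueError(
            f"u_fire={u_fire} does not exceed the boundary layer delta={delta}; "
            "firing cells would not be excited"
        )
    N = lattice.size
    u = np.zeros((N, N))
    rng = np.random.default_rng(seed)
    occ_flat = np.flatnonzero(lattice.type_map.ravel())
    n_fire = int(round(f_fire * occ_flat.size))
    if n_fire:
        fire_idx = rng.choice(occ_flat, size=n_fire, replace=False)
        u.ravel()[fire_idx] = u_fire
    return FieldState(u=u, v=np.zeros((N, N)), eta=np.zeros((N, N)), iteration=0)


def save_lattice(lattice: PopulationLattice, path: str | Path) -> None:
    """Dump the type map as plain text with a JSON provenance sidecar."""
    path = Path(path)
    np.savetxt(path, lattice.type_map, fmt="%d")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "N": lattice.size,
                "phi1": lattice.phi1,
                "phi2": lattice.phi2,
                "seed": lattice.seed,
            },
            indent=1,
        )
    )


def load_lattice(path: str | Path) -> PopulationLattice:
    path = Path(path)
    type_map = np.loadtxt(path, dtype=np.int8)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PopulationLattice(
        size=meta["N"],
        type_map=type_map,
        phi1=meta["phi1"],
        phi2=meta["phi2"],
        seed=meta["seed"],
    )
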
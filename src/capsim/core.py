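"""DPD engine: force field, simulation state, forces and integrator.

Standard Groot–Warren DPD in a periodic orthorhombic box: soft conservative
repulsion ``a_ij (1 - r/r_c)``, pairwise dissipative and random forces
satisfying the fluctuation–dissipation relation ``sigma^2 = 2 gamma kBT``,
harmonic bonds, a cosine bending term for chain rigidity, and the modified
velocity-Verlet integrator with coupling parameter lambda.  Beads of the
central nanosphere are frozen: they act as force sources but are excluded
from integration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .errors import (
    InstabilityError,
    InvalidParameterError,
    TopologyError,
    UndefinedObservableError,
)

#: bead species labels; O is the central sphere, N an alias species for
#: additional spheres, A the adsorbable monomer bead, B the polymerizable
#: monomer bead, C the crosslinker bead, I the initiator, W solvent, and
#: E the hydrophilic (PEG-like) chain bead.
SPECIES = ("O", "N", "A", "B", "C", "I", "W", "E")
S_O, S_N, S_A, S_B, S_C, S_I, S_W, S_E = range(8)
SPECIES_INDEX = {s: i for i, s in enumerate(SPECIES)}


@dataclass(frozen=True)
class SimulationBox:
    """Periodic orthorhombic box with edges in r_c."""

    edges: np.ndarray
    periodic: tuple = (True, True, True)

    def __post_init__(self):
        object.__setattr__(
            self, "edges", np.asarray(self.edges, dtype=float).reshape(3)
        )
        if np.any(self.edges <= 2.0):
            raise InvalidParameterError(
                "box edges must exceed 2 r_c for a valid cell list"
            )

    @property
    def volume(self) -> float:
        return float(np.prod(self.edges))


@dataclass
class ForceField:
    """Pairwise and bonded interaction parameters in reduced units."""

    a_matrix: np.ndarray
    gamma: float = 4.5
    sigma: float = 3.0
    bond_k: float = 100.0
    bond_r0: float = 0.7
    angle_k: float = 0.0
    angle_theta0: float = 180.0
    cutoff: float = 1.0

    def __post_init__(self):
        self.a_matrix = np.asarray(self.a_matrix, dtype=float)
        if self.a_matrix.shape != (8, 8):
            raise InvalidParameterError("a_matrix must be 8x8 (one row per species)")
        if not np.allclose(self.a_matrix, self.a_matrix.T):
            raise InvalidParameterError("a_matrix must be symmetric")
        if self.angle_k < 0:
            raise InvalidParameterError("angle_k must be non-negative")

    @property
    def kBT(self) -> float:
        """Temperature implied by fluctuation–dissipation: sigma^2/(2 gamma)."""
        return self.sigma**2 / (2.0 * self.gamma)

    @classmethod
    def standard(
        cls,
        alpha_OA: float = 6.0,
        alpha_WB: float = 28.0,
        angle_k: float = 0.0,
        a_ii: float = 25.0,
        **kwargs,
    ) -> "ForceField":
        """Canonical parameter set: all pairs at a_ii except the two knobs.

        alpha_OA controls monomer adsorption onto the sphere (lower =
        stronger effective attraction); alpha_WB controls the
        hydrophobicity of the polymerizable bead (higher = more
        hydrophobic; 28 is the low end of the hydrophobic window where
        regular capsules form).  The sphere alias species N copies the O
        row.
        """
        a = np.full((8, 8), float(a_ii))
        for o in (S_O, S_N):
            a[o, S_A] = a[S_A, o] = alpha_OA
        a[S_W, S_B] = a[S_B, S_W] = alpha_WB
        return cls(a_matrix=a, angle_k=angle_k, **kwargs)


@dataclass
class SimulationState:
    """Positions, velocities, species and topology of every bead."""

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    box: SimulationBox
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    angles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    frozen: np.ndarray | None = None
    molecule: np.ndarray | None = None
    time: float = 0.0
    step_count: int = 0
    forces: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.angles = np.ascontiguousarray(self.angles, dtype=np.int64).reshape(-1, 3)
        if self.frozen is None:
            self.frozen = np.zeros(self.n, dtype=bool)
        self.frozen = np.asarray(self.frozen, dtype=bool)
        if self.molecule is None:
            self.molecule = np.full(self.n, -1, dtype=np.int64)
        self.velocities[self.frozen] = 0.0
        if self.bonds.size:
            key = self.bonds.min(axis=1) * self.n + self.bonds.max(axis=1)
            if len(np.unique(key)) != len(key):
                raise TopologyError("duplicate bonds in topology")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def n_unfrozen(self) -> int:
        return int((~self.frozen).sum())

    def copy(self) -> "SimulationState":
        return SimulationState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            box=self.box,
            bonds=self.bonds.copy(),
            angles=self.angles.copy(),
            frozen=self.frozen.copy(),
            molecule=None if self.molecule is None else self.molecule.copy(),
            time=self.time,
            step_count=self.step_count,
            forces=None if self.forces is None else self.forces.copy(),
        )

    def wrap(self) -> None:
        self.positions %= self.box.edges


def _cell_counts(box: SimulationBox, cutoff: float) -> tuple[int, int, int]:
    """Cells per axis: half-cutoff cells when the box is large enough.

    The stencil radius is ceil(cutoff/cell); the axis must hold at least
    2*radius + 1 cells for the half-stencil sweep.  0 signals fall-back to
    the all-pairs path.
    """
    counts = []
    for e in box.edges:
        nc = int(e // cutoff)
        counts.append(nc if nc >= 3 else 0)
    return tuple(counts)


def compute_nonbonded_forces(
    state: SimulationState,
    ff: ForceField,
    seed: int = 0,
    step: int | None = None,
    dt: float = 0.04,
    use_cell_list: bool = True,
    velocities: np.ndarray | None = None,
) -> np.ndarray:
    """Conservative + dissipative + random pairwise DPD forces.

    ``seed``/``step`` index the counter-based noise stream; passing the
    same values reproduces the same random forces regardless of whether
    the cell list or the all-pairs path is used.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if step is None:
        step = state.step_count
    vel = state.velocities if velocities is None else velocities
    forces = np.zeros_like(state.positions)
    inv_sqrt_dt = 1.0 / math.sqrt(dt)
    ncx, ncy, ncz = _cell_counts(state.box, ff.cutoff)
    if use_cell_list and min(ncx, ncy, ncz) > 0:
        overlaps = _kernels.nonbonded_celllist(
            state.positions, vel, state.species, ff.a_matrix, ff.gamma,
            ff.sigma, ff.cutoff, state.box.edges, seed, step, inv_sqrt_dt,
            forces, ncx, ncy, ncz,
        )
    else:
        overlaps = _kernels.nonbonded_allpairs(
            state.positions, vel, state.species, ff.a_matrix, ff.gamma,
            ff.sigma, ff.cutoff, state.box.edges, seed, step, inv_sqrt_dt,
            forces,
        )
    if overlaps:
        warnings.warn(
            f"{overlaps} coincident bead pair(s); applied fallback-axis repulsion",
            RuntimeWarning,
            stacklevel=2,
        )
    return forces


def compute_bond_forces(state: SimulationState, ff: ForceField) -> np.ndarray:
    """Harmonic bond forces; raises TopologyError on a bond spanning > box/2."""
    forces = np.zeros_like(state.positions)
    if state.bonds.size == 0:
        return forces
    max_len = _kernels.bond_forces(
        state.positions, state.bonds, ff.bond_k, ff.bond_r0, state.box.edges,
        forces,
    )
    if max_len > 0.5 * float(state.box.edges.min()):
        raise TopologyError(
            f"bond of minimum-image length {max_len:.3f} exceeds half the box; "
            "likely an unwrapping bug"
        )
    return forces


def compute_angle_forces(state: SimulationState, ff: ForceField) -> np.ndarray:
    """Bending forces for E = k_angle (1 + cos theta); zero when k_angle = 0."""
    forces = np.zeros_like(state.positions)
    if state.angles.size == 0 or ff.angle_k == 0.0:
        return forces
    _kernels.angle_forces(
        state.positions, state.angles, ff.angle_k, state.box.edges, forces
    )
    return forces


def compute_forces(
    state: SimulationState,
    ff: ForceField,
    seed: int = 0,
    step: int | None = None,
    dt: float = 0.04,
    velocities: np.ndarray | None = None,
) -> np.ndarray:
    """Total force: nonbonded + bonds + angles (accumulated in one array)."""
    f = compute_nonbonded_forces(
        state, ff, seed=seed, step=step, dt=dt, velocities=velocities
    )
    if state.bonds.size:
        max_len = _kernels.bond_forces(
            state.positions, state.bonds, ff.bond_k, ff.bond_r0,
            state.box.edges, f,
        )
        if max_len > 0.5 * float(state.box.edges.min()):
            raise TopologyError(
                f"bond of minimum-image length {max_len:.3f} exceeds half "
                "the box; likely an unwrapping bug"
            )
    if state.angles.size and ff.angle_k != 0.0:
        _kernels.angle_forces(
            state.positions, state.angles, ff.angle_k, state.box.edges, f
        )
    return f


def integrate_step(
    state: SimulationState,
    ff: ForceField,
    dt: float = 0.04,
    lambda_vv: float = 0.65,
    seed: int = 0,
    force_cap: float | None = None,
) -> SimulationState:
    """One modified velocity-Verlet step (Groot–Warren scheme), in place.

    r += dt v + dt^2/2 f;  v_pred = v + lambda dt f;  recompute forces with
    the predicted velocities;  v += dt/2 (f_old + f_new).  Frozen beads are
    immobile throughout.  ``force_cap`` clips force magnitudes (used only
    during initial relaxation of freshly built systems).
    """
    if state.forces is None:
        state.forces = _capped(
            compute_forces(state, ff, seed=seed, step=state.step_count, dt=dt),
            force_cap,
        )
    f_old = state.forces
    # float mask multiplies avoid boolean fancy-indexing copies in the
    # per-step hot path
    free_f = getattr(state, "_free_f", None)
    if free_f is None or free_f.shape[0] != state.n:
        free_f = (~state.frozen).astype(float)[:, None]
        state._free_f = free_f
    disp = (dt * state.velocities + (0.5 * dt * dt) * f_old) * free_f
    max_disp = float(np.abs(disp).max()) if disp.size else 0.0
    if max_disp > ff.cutoff:
        raise InstabilityError(
            f"step displacement {max_disp:.3f} r_c exceeds the cutoff; "
            "reduce dt or cap forces"
        )
    state.positions += disp
    state.wrap()
    v_pred = (state.velocities + (lambda_vv * dt) * f_old) * free_f
    f_new = _capped(
        compute_forces(
            state, ff, seed=seed, step=state.step_count + 1, dt=dt,
            velocities=v_pred,
        ),
        force_cap,
    )
    state.velocities += (0.5 * dt) * (f_old + f_new) * free_f
    state.forces = f_new
    state.time += dt
    state.step_count += 1
    return state


def _capped(forces: np.ndarray, cap: float | None) -> np.ndarray:
    if cap is None:
        return forces
    mag = np.linalg.norm(forces, axis=1)
    over = mag > cap
    if np.any(over):
        forces[over] *= (cap / mag[over])[:, None]
    return forces


def run_dpd(
    state: SimulationState,
    ff: ForceField,
    steps: int,
    dt: float = 0.04,
    lambda_vv: float = 0.65,
    seed: int = 0,
    force_cap: float | None = None,
    callback=None,
    callback_every: int = 0,
) -> SimulationState:
    """Advance ``steps`` integration steps; optional periodic callback."""
    for k in range(steps):
        integrate_step(state, ff, dt=dt, lambda_vv=lambda_vv, seed=seed,
                       force_cap=force_cap)
        if callback is not None and callback_every and (k + 1) % callback_every == 0:
            callback(state)
    return state


def kinetic_temperature(state: SimulationState) -> float:
    """Instantaneous kBT estimate, 2 KE / (3 N) over unfrozen beads."""
    free = ~state.frozen
    n = int(free.sum())
    if n < 2:
        raise UndefinedObservableError(
            "kinetic temperature undefined with fewer than 2 unfrozen beads"
        )
    ke = 0.5 * float((state.velocities[free] ** 2).sum())
    return 2.0 * ke / (3.0 * n)


def bonded_energy(state: SimulationState, ff: ForceField) -> float:
    """Potential energy of bond + angle terms (diagnostic)."""
    return float(
        _kernels.bond_angle_energy(
            state.positions, state.bonds, ff.bond_k, ff.bond_r0,
            state.angles, ff.angle_k, state.box.edges,
        )
    )


def maxwell_velocities(
    n: int, kBT: float, rng: np.random.Generator, frozen: np.ndarray | None = None
) -> np.ndarray:
    """Maxwell–Boltzmann velocities with zero net drift (unit mass)."""
    v = rng.normal(0.0, math.sqrt(kBT), size=(n, 3))
    if frozen is not None:
        v[frozen] = 0.0
        free = ~frozen
        if free.any():
            v[free] -= v[free].mean(axis=0)
    else:
        v -= v.mean(axis=0)
    return v
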
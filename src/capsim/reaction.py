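"""Stochastic free-radical polymerization interleaved with DPD dynamics.

The chemistry is a minimal radical model: every initiator bead I starts as
a radical carrier; during a reaction sweep each radical looks for the
nearest eligible polymerizable bead (monomer bead B, or crosslinker bead C
with spare valence) inside the reaction radius and, with probability P_r,
forms a permanent bond and hands the radical to the acceptor.  Valence
bookkeeping limits B and C beads to two backbone bonds and initiators to
one; radical–radical combination (termination) is off by default, so the
number of radical carriers is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    S_B, S_C, S_I, S_N, S_O, S_W,
    ForceField, SimulationState, integrate_step,
)
from .errors import InstabilityError, UndefinedObservableError

#: maximum number of polymerization bonds per species (index = species id)
VALENCE_MAX = np.array([0, 0, 0, 2, 2, 1, 0, 0], dtype=np.int64)


@dataclass
class ReactiveState:
    """Mutable bookkeeping of the polymerization."""

    n_beads: int
    P_r: float = 0.005
    reaction_radius: float = 1.0
    attempt_interval: int = 10
    activation: float = 1.0
    termination: bool = False
    radical_holders: list[int] = field(default_factory=list)
    polymer_bonds: list[tuple[int, int]] = field(default_factory=list)
    valence_used: np.ndarray | None = None
    reacted: np.ndarray | None = None
    adjacency: dict[int, set] = field(default_factory=dict)
    initiated: bool = False

    def __post_init__(self):
        if self.valence_used is None:
            self.valence_used = np.zeros(self.n_beads, dtype=np.int64)
        if self.reacted is None:
            self.reacted = np.zeros(self.n_beads, dtype=bool)

    @classmethod
    def for_state(cls, state: SimulationState, **kwargs) -> "ReactiveState":
        rs = cls(n_beads=state.n, **kwargs)
        for i, j in state.bonds:
            rs.adjacency.setdefault(int(i), set()).add(int(j))
            rs.adjacency.setdefault(int(j), set()).add(int(i))
        return rs

    def copy(self) -> "ReactiveState":
        rs = ReactiveState(
            n_beads=self.n_beads,
            P_r=self.P_r,
            reaction_radius=self.reaction_radius,
            attempt_interval=self.attempt_interval,
            activation=self.activation,
            termination=self.termination,
            radical_holders=list(self.radical_holders),
            polymer_bonds=list(self.polymer_bonds),
            valence_used=self.valence_used.copy(),
            reacted=self.reacted.copy(),
            adjacency={k: set(v) for k, v in self.adjacency.items()},
            initiated=self.initiated,
        )
        return rs

    def all_bonds(self, state: SimulationState) -> np.ndarray:
        """Builder bonds plus reaction-created bonds."""
        if not self.polymer_bonds:
            return state.bonds
        pb = np.asarray(self.polymer_bonds, dtype=np.int64).reshape(-1, 2)
        return np.vstack((state.bonds, pb))


def initiate(
    reactive: ReactiveState, state: SimulationState, rng: np.random.Generator
) -> ReactiveState:
    """Activate initiator beads into radical carriers."""
    idx = np.flatnonzero(state.species == S_I)
    for i in idx:
        if reactive.activation >= 1.0 or rng.random() < reactive.activation:
            reactive.radical_holders.append(int(i))
    reactive.initiated = True
    return reactive


def _within_two_bonds(reactive: ReactiveState, i: int, j: int) -> bool:
    adj = reactive.adjacency
    ni = adj.get(i, ())
    if j in ni:
        return True
    for k in ni:
        if j in adj.get(k, ()):
            return True
    return False


def propagation_sweep(
    reactive: ReactiveState, state: SimulationState, rng: np.random.Generator
) -> int:
    """One reaction sweep over all radicals (random order); returns new bonds.

    A radical with spare valence bonds, with probability P_r, to the
    nearest eligible acceptor inside the reaction radius (ties broken by
    lower bead index).  Acceptors: unreacted B beads, or C beads with
    valence_used < 2 that do not themselves carry a radical, excluding
    beads within two bonds of the radical (prevents trivial ring closure).
    The radical transfers to the acceptor.
    """
    if not reactive.radical_holders:
        return 0
    sp = state.species
    eligible = ((sp == S_B) & ~reactive.reacted) | (
        (sp == S_C) & (reactive.valence_used < 2)
    )
    holders = np.asarray(reactive.radical_holders, dtype=np.int64)
    eligible[holders] = False
    cand = np.flatnonzero(eligible)
    if cand.size == 0:
        return 0
    edges = state.box.edges
    r2max = reactive.reaction_radius**2
    order = rng.permutation(len(reactive.radical_holders))
    new_bonds = 0
    for oi in order:
        i = reactive.radical_holders[oi]
        if reactive.valence_used[i] >= VALENCE_MAX[sp[i]]:
            continue  # stuck radical: no spare valence to donate
        d = state.positions[cand] - state.positions[i]
        d -= edges * np.round(d / edges)
        dd = (d * d).sum(axis=1)
        in_range = dd <= r2max
        if not np.any(in_range):
            continue
        # nearest eligible, ties by lower index (argmin returns first hit)
        local = np.flatnonzero(in_range)
        best = None
        best_d = np.inf
        for li in local[np.argsort(dd[local], kind="stable")]:
            j = int(cand[li])
            if not eligible[j]:
                continue  # consumed earlier in this sweep
            if _within_two_bonds(reactive, i, j):
                continue
            best = j
            best_d = dd[li]
            break
        if best is None:
            continue
        if rng.random() < reactive.P_r:
            j = best
            reactive.polymer_bonds.append((min(i, j), max(i, j)))
            reactive.valence_used[i] += 1
            reactive.valence_used[j] += 1
            reactive.reacted[i] = True
            reactive.reacted[j] = True
            reactive.adjacency.setdefault(i, set()).add(j)
            reactive.adjacency.setdefault(j, set()).add(i)
            # radical transfer; the acceptor now carries the radical and
            # cannot be an acceptor again this sweep
            reactive.radical_holders[oi] = j
            eligible[j] = False
            new_bonds += 1
    return new_bonds


def _sync_topology(
    reactive: ReactiveState, state: SimulationState, base_bonds: int,
    base_angles: int, add_angles: bool,
) -> None:
    """Push reaction bonds (and backbone angles) into the dynamic state."""
    pb = np.asarray(reactive.polymer_bonds, dtype=np.int64).reshape(-1, 2)
    state.bonds = np.vstack((state.bonds[:base_bonds], pb))
    if add_angles:
        sp = state.species
        backbone = {S_B, S_C, S_I}
        adj: dict[int, set] = {}
        for i, j in pb:
            adj.setdefault(int(i), set()).add(int(j))
            adj.setdefault(int(j), set()).add(int(i))
        # include the crosslinker C-C builder bond as backbone
        for i, j in state.bonds[:base_bonds]:
            i, j = int(i), int(j)
            if sp[i] == S_C and sp[j] == S_C:
                adj.setdefault(i, set()).add(j)
                adj.setdefault(j, set()).add(i)
        trips = []
        for mid, nbrs in adj.items():
            if sp[mid] not in backbone or len(nbrs) < 2:
                continue
            nb = sorted(nbrs)
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    trips.append((nb[x], mid, nb[y]))
        trips_arr = (
            np.asarray(trips, dtype=np.int64).reshape(-1, 3)
            if trips
            else np.empty((0, 3), dtype=np.int64)
        )
        state.angles = np.vstack((state.angles[:base_angles], trips_arr))


def conversion(reactive: ReactiveState, state: SimulationState) -> float:
    """Fraction of polymerizable beads (B and C) that have reacted."""
    polymerizable = (state.species == S_B) | (state.species == S_C)
    n = int(polymerizable.sum())
    if n == 0:
        raise UndefinedObservableError("no polymerizable beads in the system")
    return float((reactive.reacted & polymerizable).sum()) / n


def reaction_efficiency(
    reactive: ReactiveState, state: SimulationState, shell_members: set[int]
) -> float:
    """eta_react: fraction of reactive molecules with a bead in any shell.

    Reactive molecules are monomers, crosslinkers and CE10 chains (their
    molecule ids contain a B or C bead and are not initiators or spheres).
    """
    if state.molecule is None:
        raise UndefinedObservableError("state carries no molecule ids")
    sp = state.species
    reactive_mol = np.unique(
        state.molecule[((sp == S_B) | (sp == S_C)) & (state.molecule >= 0)]
    )
    if reactive_mol.size == 0:
        raise UndefinedObservableError("no reactive molecules in the system")
    if not shell_members:
        return 0.0
    members = np.fromiter(shell_members, dtype=np.int64)
    in_shell = np.unique(state.molecule[members])
    hit = np.isin(reactive_mol, in_shell)
    return float(hit.sum()) / reactive_mol.size


def run_reactive_simulation(
    state: SimulationState,
    ff: ForceField,
    reactive: ReactiveState,
    steps: int,
    dt: float = 0.04,
    lambda_vv: float = 0.65,
    seed: int = 0,
    record_every: int = 0,
    sphere_specs=None,
    attach_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Interleave DPD integration with reaction sweeps; record shell growth.

    Reaction sweeps run every ``reactive.attempt_interval`` steps.  When
    ``record_every`` > 0 a growth record (time, N_shell, conversion,
    eta_react, bond count) is taken at that cadence; N_shell and eta_react
    need ``sphere_specs``.  Deterministic given the seed.  On integrator
    instability the last good frame is kept in ``state`` and the partial
    record is returned with an ``aborted`` attribute set.
    """
    from .observables import shell_membership  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    if not reactive.initiated:
        initiate(reactive, state, rng)
    base_bonds = state.bonds.shape[0]
    base_angles = state.angles.shape[0]
    add_angles = ff.angle_k > 0.0
    records = []
    aborted = False

    def record(now: float):
        if sphere_specs:
            members, n_shell = shell_membership(
                state, reactive, sphere_specs, attach_cutoff=attach_cutoff
            )
            eta = reaction_efficiency(reactive, state, members)
        else:
            n_shell, eta = 0, float("nan")
        records.append(
            {
                "time_tau": now,
                "N_shell": n_shell,
                "conversion": conversion(reactive, state),
                "eta_react": eta,
                "n_polymer_bonds": len(reactive.polymer_bonds),
            }
        )

    if record_every:
        record(state.time)
    interval = max(1, int(reactive.attempt_interval))
    for k in range(steps):
        try:
            integrate_step(state, ff, dt=dt, lambda_vv=lambda_vv, seed=seed)
        except InstabilityError:
            aborted = True
            break
        if (k + 1) % interval == 0:
            n_new = propagation_sweep(reactive, state, rng)
            if n_new:
                _sync_topology(reactive, state, base_bonds, base_angles, add_angles)
        if record_every and (k + 1) % record_every == 0:
            record(state.time)
    df = pd.DataFrame(
        records,
        columns=["time_tau", "N_shell", "conversion", "eta_react", "n_polymer_bonds"],
    )
    df.attrs["aborted"] = aborted
    return df
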
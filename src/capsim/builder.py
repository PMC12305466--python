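"""System construction: reaction mixtures and analytic test fixtures.

Builds the simulated reaction mixture — a frozen bead sphere mimicking the
enzyme, A–B monomer dimers, C–C crosslinker dimers, single initiator beads I,
hydrophilic CE10 chains (one polymerizable C bead + ten E beads), and W
solvent filling the box to the standard DPD density rho = 3 — plus the
analytic fixtures (uniform gases, spherical shells, worm-like chains) that
the observable estimators are validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core import (
    S_A, S_B, S_C, S_E, S_I, S_N, S_O, S_W,
    SimulationBox, SimulationState, maxwell_velocities,
)
from .errors import CapacityError, InvalidParameterError, StoichiometryError

#: Avogadro's number x (1 nm)^3 in L, i.e. molecules per nm^3 per mol/L
_MOLPERL_TO_PERNM3 = 6.02214076e23 / 1e24


@dataclass(frozen=True)
class Stoichiometry:
    """Reactive-component census: N_M monomers at ratio_M:ratio_C:ratio_I."""

    N_M: int
    ratio_M: int = 75
    ratio_C: int = 14
    ratio_I: int = 1
    N_E10: int = 0
    E_length: int = 10

    def __post_init__(self):
        if self.N_M < 0 or self.N_E10 < 0:
            raise StoichiometryError("counts must be non-negative")
        if min(self.ratio_M, self.ratio_C, self.ratio_I) <= 0:
            raise StoichiometryError("ratios must be positive")


def resolve_stoichiometry(spec: Stoichiometry) -> tuple[int, int, int]:
    """Exact integer counts (N_M, N_C, N_I) implied by the ratio.

    Uses rational arithmetic; a ratio that implies a fractional crosslinker
    or initiator count is rejected rather than rounded.
    """
    counts = {}
    for name, ratio in (("crosslinker", spec.ratio_C), ("initiator", spec.ratio_I)):
        exact = Fraction(spec.N_M) * Fraction(ratio, spec.ratio_M)
        if exact.denominator != 1:
            raise StoichiometryError(
                f"N_M={spec.N_M} at ratio {spec.ratio_M}:{spec.ratio_C}:"
                f"{spec.ratio_I} implies a non-integer {name} count ({exact})"
            )
        counts[name] = int(exact)
    return spec.N_M, counts["crosslinker"], counts["initiator"]


@dataclass(frozen=True)
class SphereSpec:
    """Rigid nanosphere built from frozen beads."""

    center: tuple = (0.0, 0.0, 0.0)
    radius: float = 5.0
    surface_bead_spacing: float = 0.5
    species: str = "O"

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidParameterError("sphere radius must be positive")
        if self.surface_bead_spacing <= 0:
            raise InvalidParameterError("bead spacing must be positive")
        if self.surface_bead_spacing >= self.radius:
            raise InvalidParameterError("spacing must be smaller than the radius")


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n near-uniform points on a sphere (golden-spiral lattice)."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return radius * np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def build_sphere(spec: SphereSpec) -> np.ndarray:
    """Deterministic filled bead sphere: concentric Fibonacci layers.

    Layer radii step inward by the bead spacing; each layer carries enough
    beads that nearest neighbours sit about one spacing apart.
    """
    s = spec.surface_bead_spacing
    layers = [np.zeros((1, 3))]
    r = spec.radius
    while r > 0.5 * s:
        n = max(1, int(round(4.0 * math.pi * r * r / (s * s))))
        layers.append(_fibonacci_sphere(n, r))
        r -= s
    pts = np.vstack(layers) + np.asarray(spec.center, dtype=float)
    return pts


def make_uniform_gas(n: int, box: SimulationBox, seed: int = 0) -> np.ndarray:
    """n iid-uniform points in the box."""
    if n <= 0:
        raise InvalidParameterError("n must be positive")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(n, 3)) * box.edges


def make_shell_cloud(
    radius: float, n: int, seed: int = 0, center=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """n points uniform on a sphere surface of the given radius."""
    if n <= 0:
        raise InvalidParameterError("n must be positive")
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return radius * v + np.asarray(center, dtype=float)


def make_wormlike_chain(
    n_beads: int,
    bond_length: float = 0.7,
    correlation: float = 0.0,
    seed: int = 0,
    start=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Worm-like chain with exact per-step bond-orientation correlation.

    Each bond direction is drawn on a cone of half-angle arccos(c) around
    the previous direction with uniform azimuth, so <cos theta(1)> = c
    exactly and, by the Markov property of an azimuthally symmetric walk,
    <cos theta(s)> = c^s.  Ground-truth persistence length:
    l_p = -bond_length / ln(c).
    """
    c = correlation
    if not 0.0 <= c < 1.0:
        raise InvalidParameterError(
            "correlation must lie in [0, 1); use a rod fixture for c = 1"
        )
    if n_beads < 2:
        raise InvalidParameterError("a chain needs at least 2 beads")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    sin_t = math.sqrt(1.0 - c * c)
    pos = np.empty((n_beads, 3))
    pos[0] = np.asarray(start, dtype=float)
    for k in range(1, n_beads):
        # orthonormal frame around u
        a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        u = c * u + sin_t * (math.cos(phi) * e1 + math.sin(phi) * e2)
        u /= np.linalg.norm(u)
        pos[k] = pos[k - 1] + bond_length * u
    return pos


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def assemble_system(
    stoich: Stoichiometry,
    sphere_specs: list[SphereSpec] | None,
    box: SimulationBox,
    target_density: float = 3.0,
    seed: int = 0,
    bond_r0: float = 0.7,
    min_separation_factor: float = 0.8,
    max_tries: int = 2000,
) -> SimulationState:
    """Assemble the full reaction mixture at the target bead density.

    Structured molecules (monomer and crosslinker dimers, initiators, CE10
    chains) are inserted by random rejection sampling so that no two
    structured beads start closer than ``min_separation_factor * bond_r0``
    and none sits inside a sphere; the remainder of ``rho * V`` beads is
    plain solvent.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    edges = box.edges
    n_total = int(round(target_density * box.volume))
    n_m, n_c, n_i = resolve_stoichiometry(stoich)

    sphere_specs = list(sphere_specs or [])
    positions: list[np.ndarray] = []
    species: list[int] = []
    molecule: list[int] = []
    bonds: list[tuple[int, int]] = []
    angles: list[tuple[int, int, int]] = []
    frozen_parts: list[np.ndarray] = []
    mol_id = 0

    for k, spec in enumerate(sphere_specs):
        pts = build_sphere(spec) % edges
        positions.append(pts)
        sp = S_O if k == 0 else S_N
        species.extend([sp] * len(pts))
        molecule.extend([mol_id] * len(pts))
        frozen_parts.append(np.ones(len(pts), dtype=bool))
        mol_id += 1

    centers = [np.asarray(s.center, dtype=float) for s in sphere_specs]
    radii = [s.radius for s in sphere_specs]

    def inside_sphere(p: np.ndarray) -> bool:
        for c0, r0 in zip(centers, radii):
            d = p - c0
            d -= edges * np.round(d / edges)
            if float(d @ d) < (r0 + 0.5) ** 2:
                return True
        return False

    placed: list[np.ndarray] = []  # structured, non-frozen beads
    min_sep = min_separation_factor * bond_r0

    def clashes(p: np.ndarray) -> bool:
        if inside_sphere(p):
            return True
        if placed:
            d = p - np.asarray(placed)
            d -= edges * np.round(d / edges)
            if float((d * d).sum(axis=1).min()) < min_sep * min_sep:
                return True
        return False

    def place_chain(n_beads: int) -> np.ndarray:
        for _ in range(max_tries):
            pts = [rng.uniform(0.0, 1.0, 3) * edges]
            if clashes(pts[0]):
                continue
            ok = True
            for _ in range(n_beads - 1):
                good = False
                for _ in range(30):
                    q = (pts[-1] + bond_r0 * _random_unit(rng)) % edges
                    if inside_sphere(q):
                        continue
                    # bonded predecessor sits at exactly bond_r0 > min_sep,
                    # so a plain nearest-neighbour check suffices
                    d = q - np.vstack(placed + pts if placed else pts)
                    d -= edges * np.round(d / edges)
                    if float((d * d).sum(axis=1).min()) >= min_sep * min_sep:
                        good = True
                        pts.append(q)
                        break
                if not good:
                    ok = False
                    break
            if ok:
                return np.asarray(pts)
        raise CapacityError(
            "could not place a molecule without clashes; the box is too "
            f"crowded (edges {edges.tolist()})"
        )

    def add_molecule(spl: list[int], chain_angles: bool = False):
        nonlocal mol_id
        pts = place_chain(len(spl))
        base = sum(len(p) for p in positions)
        positions.append(pts)
        species.extend(spl)
        molecule.extend([mol_id] * len(spl))
        for i in range(len(spl) - 1):
            bonds.append((base + i, base + i + 1))
        if chain_angles:
            for i in range(len(spl) - 2):
                angles.append((base + i, base + i + 1, base + i + 2))
        frozen_parts.append(np.zeros(len(spl), dtype=bool))
        placed.extend(pts)
        mol_id += 1

    for _ in range(n_m):
        add_molecule([S_A, S_B])
    for _ in range(n_c):
        add_molecule([S_C, S_C])
    for _ in range(n_i):
        add_molecule([S_I])
    for _ in range(stoich.N_E10):
        add_molecule([S_C] + [S_E] * stoich.E_length, chain_angles=True)

    n_structured = sum(len(p) for p in positions)
    n_w = n_total - n_structured
    if n_w < 0:
        needed = (n_structured / target_density) ** (1.0 / 3.0)
        raise CapacityError(
            f"box holds {n_total} beads at rho={target_density} but the "
            f"composition needs {n_structured}; minimum cubic edge ~{needed:.1f} r_c"
        )
    if n_w > 0:
        positions.append(rng.uniform(0.0, 1.0, size=(n_w, 3)) * edges)
        species.extend([S_W] * n_w)
        molecule.extend([-1] * n_w)
        frozen_parts.append(np.zeros(n_w, dtype=bool))

    frozen = np.concatenate(frozen_parts) if frozen_parts else np.zeros(0, dtype=bool)
    pos = np.vstack(positions) % edges
    state = SimulationState(
        positions=pos,
        velocities=np.zeros_like(pos),
        species=np.asarray(species, dtype=np.int64),
        box=box,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        frozen=frozen,
        molecule=np.asarray(molecule, dtype=np.int64),
    )
    state.velocities = maxwell_velocities(state.n, 1.0, rng, frozen=state.frozen)
    return state


def e10_count_from_concentration(
    conc_mol_per_L: float, box: SimulationBox, rc_nm: float = 1.0
) -> int:
    """CE10 chain count implied by a molar concentration and the box volume."""
    vol_nm3 = box.volume * rc_nm**3
    return int(round(conc_mol_per_L * _MOLPERL_TO_PERNM3 * vol_nm3))
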
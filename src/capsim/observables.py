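"""Structural metrics of the nanocapsule and its polymer shell.

All the quantities reported for the capsule system: center-referenced
radial distribution functions and density profiles, the gyration-tensor
relative shape anisotropy kappa^2, probe-based solvent-accessible surface
area (Shrake–Rupley quadrature), adsorption density rho_ads in the shell
just outside the sphere surface, shell membership and N_shell via the
molecular bond graph, shell thickness from the polymer density profile,
worm-like-chain persistence length, the multi-sphere encapsulation census,
and the three-regime morphology classification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .builder import SphereSpec, _fibonacci_sphere
from .core import S_E, S_N, S_O, S_W, SimulationState
from .errors import InvalidParameterError, UndefinedObservableError

__all__ = [
    "ShellMetrics",
    "ChainStats",
    "center_rdf",
    "radial_density_profile",
    "gyration_eigenvalues",
    "kappa2",
    "sasa",
    "adsorption_density",
    "shell_components",
    "shell_membership",
    "shell_thickness",
    "persistence_length",
    "encapsulation_census",
    "classify_morphology",
    "unwrap_about",
]


@dataclass
class ShellMetrics:
    """Per-frame structural summary of one capsule."""

    kappa2: float = float("nan")
    gyr_eigenvalues: tuple = (float("nan"),) * 3
    sasa: float = float("nan")
    probe_radius: float = 0.1
    rho_ads: float = float("nan")
    N_shell: int = 0
    thickness: float = float("nan")


@dataclass
class ChainStats:
    """Persistence-length fit summary."""

    l_p: float
    l_b: float
    s: np.ndarray = field(default_factory=lambda: np.empty(0))
    cos_theta_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    lower_bound: bool = False
    upper_bound: bool = False


# ---------------------------------------------------------------------------
# radial structure


def _center_distances(
    positions: np.ndarray, center, box_edges: np.ndarray
) -> np.ndarray:
    d = positions - np.asarray(center, dtype=float)
    d -= box_edges * np.round(d / box_edges)
    return np.sqrt((d * d).sum(axis=1))


def center_rdf(
    positions: np.ndarray,
    center,
    box,
    r_max: float,
    nbins: int,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """g(r) of selected beads about a fixed center.

    Counts are normalized by the spherical-shell volume and the bulk
    density of the selected beads, so a uniform gas gives g ~ 1.
    """
    edges_len = box.edges if hasattr(box, "edges") else np.asarray(box, dtype=float)
    if nbins <= 0 or r_max <= 0:
        raise InvalidParameterError("r_max and nbins must be positive")
    if r_max >= 0.5 * float(np.min(edges_len)):
        raise InvalidParameterError("r_max must be below half the box edge")
    pts = positions if selection is None else positions[selection]
    if len(pts) == 0:
        raise UndefinedObservableError("empty species selection for RDF")
    r = _center_distances(pts, center, edges_len)
    counts, bin_edges = np.histogram(r, bins=nbins, range=(0.0, r_max))
    vol_shell = 4.0 / 3.0 * math.pi * (bin_edges[1:] ** 3 - bin_edges[:-1] ** 3)
    bulk = len(pts) / float(np.prod(edges_len))
    g = counts / (vol_shell * bulk)
    mid = 0.5 * (bin_edges[1:] + bin_edges[:-1])
    return mid, g


def radial_density_profile(
    positions: np.ndarray,
    center,
    box,
    r_max: float,
    nbins: int,
    groups: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Absolute number density (r_c^-3) per radial bin, per bead group."""
    edges_len = box.edges if hasattr(box, "edges") else np.asarray(box, dtype=float)
    if nbins <= 0 or r_max <= 0:
        raise InvalidParameterError("r_max and nbins must be positive")
    if groups is None:
        groups = {"all": np.arange(len(positions))}
    bin_edges = np.linspace(0.0, r_max, nbins + 1)
    vol_shell = 4.0 / 3.0 * math.pi * (bin_edges[1:] ** 3 - bin_edges[:-1] ** 3)
    out = {"r": 0.5 * (bin_edges[1:] + bin_edges[:-1])}
    for name, idx in groups.items():
        r = _center_distances(positions[idx], center, edges_len)
        counts, _ = np.histogram(r, bins=bin_edges)
        out[name] = counts / vol_shell
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# shape


def gyration_eigenvalues(
    coordinates: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Sorted (descending) eigenvalues of the gyration tensor.

    Coordinates must already be unwrapped (see :func:`unwrap_about`).
    """
    x = np.asarray(coordinates, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise UndefinedObservableError("need at least 2 points for a gyration tensor")
    if weights is None:
        w = np.full(len(x), 1.0 / len(x))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mu = (w[:, None] * x).sum(axis=0)
    d = x - mu
    tensor = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)
    lam = np.linalg.eigvalsh(tensor)[::-1]
    return np.clip(lam, 0.0, None)


def kappa2(
    coordinates: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Relative shape anisotropy kappa^2 and the gyration eigenvalues.

    kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2:
    0 for spherically symmetric mass distributions, 1 for collinear ones.
    """
    lam = gyration_eigenvalues(coordinates, weights)
    tr = lam.sum()
    # relative threshold absorbs floating-point crumbs from the centroid
    # subtraction of coincident points
    scale = 1.0 + float((np.asarray(coordinates) ** 2).mean())
    if tr <= 1e-20 * scale:
        raise UndefinedObservableError("degenerate (zero-extent) point set")
    pair = lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]
    k2 = 1.0 - 3.0 * pair / tr**2
    return float(np.clip(k2, 0.0, 1.0)), lam


def unwrap_about(
    positions: np.ndarray,
    box,
    center,
    bonds: np.ndarray | None = None,
) -> np.ndarray:
    """Unwrap periodic coordinates for shape analysis.

    Every bead is first unwrapped by minimum image about the reference
    center; bonded neighbours are then walked breadth-first so each bond
    uses the image closest to its already-unwrapped partner.  Suitable for
    clusters whose extent is below half the box.
    """
    edges_len = box.edges if hasattr(box, "edges") else np.asarray(box, dtype=float)
    c = np.asarray(center, dtype=float)
    d = positions - c
    d -= edges_len * np.round(d / edges_len)
    out = d + c
    if bonds is not None and len(bonds):
        adj: dict[int, list[int]] = {}
        for i, j in np.asarray(bonds, dtype=np.int64):
            adj.setdefault(int(i), []).append(int(j))
            adj.setdefault(int(j), []).append(int(i))
        seen: set[int] = set()
        for root in sorted(adj):
            if root in seen:
                continue
            seen.add(root)
            queue = [root]
            while queue:
                i = queue.pop()
                for j in adj.get(i, ()):
                    if j in seen:
                        continue
                    seen.add(j)
                    dv = positions[j] - out[i]
                    dv -= edges_len * np.round(dv / edges_len)
                    out[j] = out[i] + dv
                    queue.append(j)
    return out


# ---------------------------------------------------------------------------
# surface accessibility and adsorption


def sasa(
    core_center,
    core_radius: float,
    occluder_positions: np.ndarray,
    probe: float = 0.1,
    occluder_radius: float = 0.5,
    n_points: int = 2000,
    box=None,
) -> float:
    """Solvent-accessible surface area of the core sphere (r_c^2).

    Shrake–Rupley quadrature: points are laid on the probe-inflated core
    surface (radius R + probe); a point is inaccessible when it lies inside
    any probe-inflated occluder sphere.  The returned area converges to the
    true SASA as n_points grows.
    """
    if probe < 0:
        raise InvalidParameterError("probe radius must be non-negative")
    if n_points < 100:
        raise InvalidParameterError("need at least 100 quadrature points")
    c = np.asarray(core_center, dtype=float)
    rs = core_radius + probe
    pts = _fibonacci_sphere(n_points, rs) + c
    area = 4.0 * math.pi * rs * rs
    occ = np.asarray(occluder_positions, dtype=float).reshape(-1, 3)
    if len(occ) == 0:
        return area
    if box is not None:
        edges_len = box.edges if hasattr(box, "edges") else np.asarray(box, dtype=float)
        d = occ - c
        d -= edges_len * np.round(d / edges_len)
        occ = d + c
    # only occluders that can reach the quadrature shell matter
    block = occluder_radius + probe
    do = np.linalg.norm(occ - c, axis=1)
    occ = occ[(do > rs - block) & (do < rs + block)]
    if len(occ) == 0:
        return area
    from scipy.spatial import cKDTree

    tree = cKDTree(occ)
    near = tree.query_ball_point(pts, block)
    accessible = np.fromiter((len(m) == 0 for m in near), dtype=bool, count=len(pts))
    return area * accessible.mean()


def adsorption_density(
    state: SimulationState,
    sphere: SphereSpec,
    shell_inner: float | None = None,
    shell_outer: float | None = None,
    selection: np.ndarray | None = None,
) -> float:
    """Number density of adsorbed beads in the shell just outside the sphere.

    Default shell spans (R, R + 1 r_c]; default selection is every bead
    that is neither solvent nor a sphere bead.
    """
    inner = sphere.radius if shell_inner is None else shell_inner
    outer = sphere.radius + 1.0 if shell_outer is None else shell_outer
    if outer <= inner:
        raise InvalidParameterError("shell_outer must exceed shell_inner")
    if selection is None:
        selection = ~np.isin(state.species, (S_W, S_O, S_N))
    pts = state.positions[selection]
    if len(pts) == 0:
        return 0.0
    r = _center_distances(pts, sphere.center, state.box.edges)
    count = int(((r > inner) & (r <= outer)).sum())
    vol = 4.0 / 3.0 * math.pi * (outer**3 - inner**3)
    return count / vol


# ---------------------------------------------------------------------------
# shell membership and census


def shell_components(
    state: SimulationState,
    reactive,
    sphere_specs: list[SphereSpec],
    attach_cutoff: float = 1.0,
):
    """Connected components of the molecular graph and their sphere contacts.

    Returns ``(labels, sizes, attached)`` where ``labels`` maps every bead
    to a component id (-1 for solvent and sphere beads), ``sizes`` counts
    beads per component, and ``attached[k]`` is the set of component ids
    with at least one bead within ``attach_cutoff`` of sphere k's surface.
    """
    n = state.n
    member = ~np.isin(state.species, (S_W, S_O, S_N))
    idx = np.flatnonzero(member)
    labels = np.full(n, -1, dtype=np.int64)
    if idx.size == 0:
        return labels, np.empty(0, dtype=np.int64), [set() for _ in sphere_specs]
    remap = np.full(n, -1, dtype=np.int64)
    remap[idx] = np.arange(idx.size)
    bonds = reactive.all_bonds(state) if reactive is not None else state.bonds
    if len(bonds):
        keep = member[bonds[:, 0]] & member[bonds[:, 1]]
        b = bonds[keep]
    else:
        b = np.empty((0, 2), dtype=np.int64)
    data = np.ones(len(b), dtype=np.int8)
    graph = coo_matrix(
        (data, (remap[b[:, 0]], remap[b[:, 1]])), shape=(idx.size, idx.size)
    )
    ncomp, comp = connected_components(graph, directed=False)
    labels[idx] = comp
    sizes = np.bincount(comp, minlength=ncomp)
    attached: list[set] = []
    for spec in sphere_specs:
        r = _center_distances(state.positions[idx], spec.center, state.box.edges)
        touching = comp[r <= spec.radius + attach_cutoff]
        attached.append(set(np.unique(touching).tolist()))
    return labels, sizes, attached


def shell_membership(
    state: SimulationState,
    reactive,
    sphere_specs: list[SphereSpec],
    attach_cutoff: float = 1.0,
) -> tuple[set[int], int]:
    """Bead indices in any sphere's shell, and their total count N_shell.

    A molecular component belongs to a shell when at least one of its
    beads lies within ``attach_cutoff`` of a sphere surface; detached
    micelles contribute nothing.
    """
    labels, sizes, attached = shell_components(
        state, reactive, sphere_specs, attach_cutoff
    )
    shell_ids = set().union(*attached) if attached else set()
    if not shell_ids:
        return set(), 0
    mask = np.isin(labels, np.fromiter(shell_ids, dtype=np.int64))
    members = set(np.flatnonzero(mask).tolist())
    return members, len(members)


def shell_thickness(
    r: np.ndarray,
    density: np.ndarray,
    sphere_radius: float,
    threshold_frac: float = 0.5,
) -> float:
    """Shell thickness from a radial polymer density profile.

    Outermost radius at which the density still reaches
    ``threshold_frac`` x peak density, minus the sphere radius; 0 when no
    polymer is present.
    """
    r = np.asarray(r, dtype=float)
    density = np.asarray(density, dtype=float)
    if density.size == 0 or float(density.max()) <= 0.0:
        warnings.warn("all-zero polymer profile; thickness set to 0", stacklevel=2)
        return 0.0
    thresh = threshold_frac * float(density.max())
    above = np.flatnonzero(density >= thresh)
    outer = r[above[-1]]
    return float(max(0.0, outer - sphere_radius))


# ---------------------------------------------------------------------------
# chain statistics


def persistence_length(
    chains: list[np.ndarray],
    correlation_floor: float = 0.05,
    min_samples: int = 30,
) -> ChainStats:
    """Persistence length from pooled bond-orientation correlations.

    Computes <cos theta(s)> over all bond pairs separated by s bonds,
    pooled across chains, then fits ln<cos theta(s)> linearly over the s
    range where the correlation exceeds ``correlation_floor`` (and has at
    least ``min_samples`` bond pairs); l_p = -l_b / slope with l_b the mean
    bond length.  A non-decaying correlation (rigid rod) returns an
    upper-bound sentinel (inf); a non-positive correlation at s = 1
    returns a lower-bound flag with l_p below one bond length.
    """
    vecs = []
    for ch in chains:
        ch = np.asarray(ch, dtype=float)
        if len(ch) < 2:
            continue
        vecs.append(np.diff(ch, axis=0))
    if not vecs:
        raise UndefinedObservableError("no chains with at least one bond")
    l_b = float(np.mean([np.linalg.norm(v, axis=1).mean() for v in vecs]))
    units = [v / np.linalg.norm(v, axis=1, keepdims=True) for v in vecs]
    max_s = max(len(u) for u in units) - 1
    s_vals, cos_vals, n_vals = [], [], []
    for s in range(1, max_s + 1):
        dots = [
            (u[:-s] * u[s:]).sum(axis=1) for u in units if len(u) > s
        ]
        if not dots:
            break
        pooled = np.concatenate(dots)
        s_vals.append(s)
        cos_vals.append(float(pooled.mean()))
        n_vals.append(pooled.size)
    s_arr = np.asarray(s_vals)
    cos_arr = np.asarray(cos_vals)
    n_arr = np.asarray(n_vals)

    if cos_arr.size == 0 or cos_arr[0] <= 0.0:
        return ChainStats(
            l_p=0.0, l_b=l_b, s=s_arr, cos_theta_s=cos_arr, lower_bound=True
        )
    usable = (cos_arr > correlation_floor) & (n_arr >= min_samples)
    # keep the contiguous usable prefix: the fit window of the decay law
    cut = np.argmin(usable) if not usable.all() else usable.size
    if cut == 0:
        cut = 1
    s_fit = s_arr[:cut].astype(float)
    log_fit = np.log(cos_arr[:cut])
    # zero-intercept weighted fit: the decay law pins <cos theta(0)> = 1,
    # and the delta-method variance of ln<cos> scales as 1/(n <cos>^2)
    w = n_arr[:cut] * cos_arr[:cut] ** 2
    slope = float((w * s_fit * log_fit).sum() / (w * s_fit**2).sum())
    if slope >= -1e-12:
        return ChainStats(
            l_p=float("inf"), l_b=l_b, s=s_arr, cos_theta_s=cos_arr,
            upper_bound=True,
        )
    return ChainStats(
        l_p=float(-l_b / slope), l_b=l_b, s=s_arr, cos_theta_s=cos_arr
    )


# ---------------------------------------------------------------------------
# census and classification


def encapsulation_census(
    state: SimulationState,
    reactive,
    sphere_specs: list[SphereSpec],
    attach_cutoff: float = 1.0,
) -> dict:
    """Group spheres into capsules via shared shell components.

    Spheres whose attached shell components intersect belong to one
    capsule (union–find over spheres).  Returns the per-capsule sphere
    counts, the class histogram, and the fraction of capsules holding a
    single sphere.
    """
    if not sphere_specs:
        raise UndefinedObservableError("census needs at least one sphere")
    _, _, attached = shell_components(state, reactive, sphere_specs, attach_cutoff)
    n_s = len(sphere_specs)
    parent = list(range(n_s))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(n_s):
        for b in range(a + 1, n_s):
            if attached[a] & attached[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    roots: dict[int, int] = {}
    for k in range(n_s):
        r = find(k)
        roots[r] = roots.get(r, 0) + 1
    counts = sorted(roots.values(), reverse=True)
    classes: dict[int, int] = {}
    for c in counts:
        classes[c] = classes.get(c, 0) + 1
    mono = classes.get(1, 0) / len(counts)
    return {
        "capsule_sizes": counts,
        "class_histogram": classes,
        "mono_fraction": mono,
        "n_capsules": len(counts),
    }


def classify_morphology(
    kappa2_value: float,
    sasa_value: float,
    core_bare_sasa: float,
    kappa2_threshold: float = 0.004,
    exposure_threshold: float = 0.2,
) -> str:
    """Assign a capsule to one of three morphological regimes.

    Regime I: fully encapsulated (low anisotropy, low core exposure);
    regime III: partially exposed core (exposure above threshold,
    regardless of shape); regime II: distorted encapsulation (everything
    else).
    """
    if core_bare_sasa <= 0:
        raise InvalidParameterError("bare-core SASA must be positive")
    exposure = sasa_value / core_bare_sasa
    if exposure > exposure_threshold:
        return "III"
    if kappa2_value <= kappa2_threshold:
        return "I"
    return "II"
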
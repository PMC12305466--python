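"""Observable estimators against analytic shapes and brute-force oracles."""

import math

import numpy as np
import pytest

from capsim.builder import (
    SphereSpec, Stoichiometry, assemble_system, make_shell_cloud,
    make_uniform_gas, make_wormlike_chain,
)
from capsim.core import (
    S_A, S_B, S_C, S_E, S_O, S_W, SimulationBox, SimulationState,
)
from capsim.errors import InvalidParameterError, UndefinedObservableError
from capsim.observables import (
    adsorption_density,
    center_rdf,
    classify_morphology,
    encapsulation_census,
    kappa2,
    persistence_length,
    radial_density_profile,
    sasa,
    shell_membership,
    shell_thickness,
    unwrap_about,
)
from capsim.reaction import ReactiveState


def _state(positions, species=None, bonds=None, box_edge=20.0, molecule=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return SimulationState(
        positions=positions % box_edge,
        velocities=np.zeros((n, 3)),
        species=(
            np.full(n, S_B) if species is None
            else np.asarray(species, dtype=np.int64)
        ),
        box=SimulationBox(edges=[box_edge] * 3),
        bonds=np.asarray(bonds if bonds is not None else [],
                         dtype=np.int64).reshape(-1, 2),
        molecule=molecule,
    )


class TestRadialStructure:
    def test_rdf_of_uniform_gas_is_flat(self):
        box = SimulationBox(edges=[12.0] * 3)
        pts = make_uniform_gas(40000, box, seed=3)
        r, g = center_rdf(pts, center=[6.0, 6.0, 6.0], box=box, r_max=5.0, nbins=10)
        # counting error per bin ~ 1/sqrt(n_bin); skip the innermost bin
        for ri, gi in zip(r[1:], g[1:]):
            n_expect = 40000 / 12.0**3 * 4 * math.pi * ri**2 * 0.5
            assert gi == pytest.approx(1.0, abs=3.5 / math.sqrt(n_expect))

    def test_rdf_of_shell_is_a_single_peak(self):
        # radius 3.1 sits mid-bin (width 0.5), away from a bin edge
        pts = make_shell_cloud(3.1, 2000, seed=1, center=(6, 6, 6))
        box = SimulationBox(edges=[12.0] * 3)
        r, g = center_rdf(pts, center=[6.0, 6.0, 6.0], box=box, r_max=5.0, nbins=10)
        assert g[6] > 0
        assert np.count_nonzero(g) == 1

    def test_rdf_matches_brute_force_histogram(self, rng):
        box = SimulationBox(edges=[10.0] * 3)
        pts = make_uniform_gas(500, box, seed=9)
        center = np.array([5.0, 5.0, 5.0])
        r, g = center_rdf(pts, center, box, r_max=4.0, nbins=8)
        d = pts - center
        d -= box.edges * np.round(d / box.edges)
        dist = np.linalg.norm(d, axis=1)
        edges = np.linspace(0, 4.0, 9)
        counts = np.histogram(dist, bins=edges)[0]
        shell_vol = 4 / 3 * math.pi * np.diff(edges**3)
        expected = counts / (shell_vol * 500 / 1000.0)
        assert np.allclose(g, expected)

    def test_rdf_validation(self):
        box = SimulationBox(edges=[10.0] * 3)
        pts = make_uniform_gas(10, box, seed=0)
        with pytest.raises(InvalidParameterError):
            center_rdf(pts, [5, 5, 5], box, r_max=6.0, nbins=5)
        with pytest.raises(UndefinedObservableError):
            center_rdf(pts, [5, 5, 5], box, r_max=4.0, nbins=5,
                       selection=np.array([], dtype=int))

    def test_density_profile_recovers_bulk_density(self):
        box = SimulationBox(edges=[10.0] * 3)
        pts = make_uniform_gas(3000, box, seed=2)
        df = radial_density_profile(pts, [5, 5, 5], box, r_max=4.0, nbins=8)
        # outer bins hold enough beads for a tight estimate
        assert df["all"].iloc[-3:].mean() == pytest.approx(3.0, rel=0.1)

    def test_density_profile_layer_ordering(self):
        """Concentric core/mid/outer layers peak at increasing radii."""
        core = make_shell_cloud(1.0, 300, seed=1, center=(10, 10, 10))
        mid = make_shell_cloud(3.0, 300, seed=2, center=(10, 10, 10))
        outer = make_shell_cloud(5.0, 300, seed=3, center=(10, 10, 10))
        pts = np.vstack((core, mid, outer))
        groups = {
            "core": np.arange(300),
            "mid": np.arange(300, 600),
            "outer": np.arange(600, 900),
        }
        df = radial_density_profile(
            pts, [10, 10, 10], SimulationBox(edges=[20.0] * 3),
            r_max=7.0, nbins=28, groups=groups,
        )
        peaks = {k: df["r"][df[k].idxmax()] for k in groups}
        assert peaks["core"] < peaks["mid"] < peaks["outer"]


class TestShapeAnisotropy:
    def test_rod_limit(self):
        pts = np.column_stack((np.linspace(0, 10, 100), np.zeros(100), np.zeros(100)))
        k2, lam = kappa2(pts)
        assert k2 == pytest.approx(1.0, abs=1e-12)
        assert lam[1] == pytest.approx(0.0, abs=1e-12)

    def test_cube_vertices_are_isotropic(self):
        pts = np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], float
        )
        k2, _ = kappa2(pts)
        assert k2 == pytest.approx(0.0, abs=1e-10)

    def test_large_spherical_shell_is_isotropic(self):
        k2, _ = kappa2(make_shell_cloud(5.0, 20000, seed=4))
        assert k2 == pytest.approx(0.0, abs=0.002)

    def test_equilateral_triangle(self):
        """Planar symmetric shape: eigenvalues (l, l, 0) give kappa^2 = 1/4."""
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0]], dtype=float
        )
        k2, lam = kappa2(pts)
        assert k2 == pytest.approx(0.25, abs=1e-12)
        assert lam[0] == pytest.approx(lam[1])

    def test_rigid_motion_and_scale_invariance(self, rng):
        pts = rng.normal(size=(60, 3)) * np.array([3.0, 1.0, 0.5])
        k2_ref, _ = kappa2(pts)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        for transformed in (pts @ q.T, pts + 7.3, pts * 4.0):
            k2, _ = kappa2(transformed)
            assert k2 == pytest.approx(k2_ref, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(UndefinedObservableError):
            kappa2(np.array([[1.0, 2.0, 3.0]]))
        with pytest.raises(UndefinedObservableError):
            kappa2(np.array([[1.0, 2.0, 3.0]] * 5))  # zero extent

    def test_unwrap_reassembles_cluster_across_boundary(self):
        """A bonded chain across the periodic wall unwraps to one piece."""
        box = SimulationBox(edges=[10.0] * 3)
        chain = np.array([[9.5 + 0.7 * i, 5.0, 5.0] for i in range(4)])
        st = _state(chain, box_edge=10.0,
                    bonds=[[0, 1], [1, 2], [2, 3]])
        out = unwrap_about(st.positions, box, center=[9.5, 5, 5], bonds=st.bonds)
        lens = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.allclose(lens, 0.7, atol=1e-9)


class TestSasa:
    def test_bare_sphere_matches_analytic_area(self):
        area = sasa([0, 0, 0], 5.0, np.empty((0, 3)), probe=0.1, n_points=2000)
        assert area == pytest.approx(4 * math.pi * 5.1**2, rel=1e-9)

    def test_fully_buried_core(self):
        occ = make_shell_cloud(5.3, 4000, seed=2)
        area = sasa([0, 0, 0], 5.0, occ, probe=0.1, occluder_radius=0.5,
                    n_points=2000)
        assert area == 0.0

    def test_single_occluder_against_monte_carlo_oracle(self, rng):
        """Quadrature agrees with a 10^6-point random-sphere estimate."""
        occ = np.array([[0.0, 0.0, 5.4]])
        area = sasa([0, 0, 0], 5.0, occ, probe=0.1, occluder_radius=0.5,
                    n_points=20000)
        v = rng.normal(size=(1_000_000, 3))
        v = 5.1 * v / np.linalg.norm(v, axis=1, keepdims=True)
        blocked = np.linalg.norm(v - occ, axis=1) < 0.6
        mc = 4 * math.pi * 5.1**2 * (1 - blocked.mean())
        assert area == pytest.approx(mc, rel=0.01)

    def test_monotone_under_added_occluders_and_convergent(self, rng):
        occ = make_shell_cloud(5.5, 200, seed=8)
        areas = [
            sasa([0, 0, 0], 5.0, occ[:k], probe=0.1, n_points=4000)
            for k in (0, 50, 100, 200)
        ]
        assert all(b <= a for a, b in zip(areas, areas[1:]))
        a1 = sasa([0, 0, 0], 5.0, occ, probe=0.1, n_points=4000)
        a4 = sasa([0, 0, 0], 5.0, occ, probe=0.1, n_points=16000)
        assert a4 == pytest.approx(a1, rel=0.01)

    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            sasa([0, 0, 0], 5.0, np.empty((0, 3)), probe=-0.1)
        with pytest.raises(InvalidParameterError):
            sasa([0, 0, 0], 5.0, np.empty((0, 3)), n_points=10)


class TestAdsorptionDensity:
    def test_zero_without_polymer(self):
        st = _state([[1, 1, 1]], species=[S_W])
        assert adsorption_density(st, SphereSpec(center=(10, 10, 10), radius=3.0)) == 0.0

    def test_brute_force_count_oracle(self):
        box_edge = 20.0
        sphere = SphereSpec(center=(10, 10, 10), radius=3.0)
        pts = make_uniform_gas(4000, SimulationBox(edges=[box_edge] * 3), seed=5)
        st = _state(pts, species=[S_B] * 4000, box_edge=box_edge)
        rho = adsorption_density(st, sphere)
        d = np.linalg.norm(pts - [10, 10, 10], axis=1)
        count = int(((d > 3.0) & (d <= 4.0)).sum())
        vol = 4 / 3 * math.pi * (4.0**3 - 3.0**3)
        assert rho == pytest.approx(count / vol)

    def test_bulk_density_reference(self):
        """A shell filled at rho = 3 reads back 3.0."""
        sphere = SphereSpec(center=(10, 10, 10), radius=3.0)
        vol = 4 / 3 * math.pi * (4.0**3 - 3.0**3)
        n = int(round(3.0 * vol))
        rng = np.random.default_rng(0)
        r = (3.0**3 + rng.uniform(0, 1, n) * (4.0**3 - 3.0**3)) ** (1 / 3)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        st = _state(r[:, None] * v + 10.0, species=[S_B] * n)
        assert adsorption_density(st, sphere) == pytest.approx(3.0, rel=0.02)

    def test_degenerate_shell_rejected(self):
        st = _state([[1, 1, 1]], species=[S_B])
        with pytest.raises(InvalidParameterError):
            adsorption_density(
                st, SphereSpec(center=(5, 5, 5), radius=3.0),
                shell_inner=4.0, shell_outer=4.0,
            )


class TestShellMembership:
    def _system(self):
        sphere = SphereSpec(center=(10, 10, 10), radius=3.0)
        # chain of 5 with one bead touching the surface, plus a detached
        # 4-bead micelle far away
        chain = np.array([[10 + 3.2 + 0.7 * i, 10, 10] for i in range(5)])
        chain[0] = [10 + 3.2, 10, 10]
        micelle = np.array([[2 + 0.4 * i, 2, 2] for i in range(4)])
        pts = np.vstack((chain, micelle))
        bonds = [[i, i + 1] for i in range(4)] + [[5, 6], [6, 7], [7, 8]]
        st = _state(pts, species=[S_B] * 9, bonds=bonds)
        return st, sphere

    def test_connectivity_rule_and_detached_micelle(self):
        st, sphere = self._system()
        members, n_shell = shell_membership(st, None, [sphere], attach_cutoff=1.0)
        assert members == set(range(5))
        assert n_shell == 5

    def test_matches_bfs_oracle_on_random_forest(self, rng):
        box_edge = 20.0
        pts = make_uniform_gas(200, SimulationBox(edges=[box_edge] * 3), seed=3)
        bonds = rng.integers(0, 200, size=(60, 2))
        bonds = np.array([(a, b) for a, b in bonds if a != b])
        bonds = np.unique(np.sort(bonds, axis=1), axis=0)
        sphere = SphereSpec(center=(10, 10, 10), radius=3.0)
        st = _state(pts, species=[S_B] * 200, bonds=bonds, box_edge=box_edge)
        members, n_shell = shell_membership(st, None, [sphere], attach_cutoff=1.0)
        # independent BFS
        adj = {}
        for a, b in bonds:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        d = pts - np.array([10.0, 10.0, 10.0])
        d -= box_edge * np.round(d / box_edge)
        touching = np.flatnonzero(np.linalg.norm(d, axis=1) <= 4.0)
        seen = set()
        stack = list(touching)
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            stack.extend(adj.get(i, []))
        assert members == seen
        assert n_shell == len(seen)

    def test_adding_a_bond_never_decreases_n_shell(self):
        st, sphere = self._system()
        _, n0 = shell_membership(st, None, [sphere])
        rx = ReactiveState.for_state(st)
        rx.polymer_bonds.append((4, 5))  # link micelle to the shell chain
        _, n1 = shell_membership(st, rx, [sphere])
        assert n1 == n0 + 4


class TestShellThickness:
    def test_no_polymer(self):
        with pytest.warns(UserWarning):
            assert shell_thickness(np.linspace(0, 5, 10), np.zeros(10), 3.0) == 0.0

    def test_rectangular_band(self):
        r = np.linspace(0.05, 7.95, 80)
        density = ((r >= 3.0) & (r <= 5.0)).astype(float)
        t = shell_thickness(r, density, 3.0)
        assert t == pytest.approx(2.0, abs=0.1)

    def test_noisy_band_matches_scan_oracle(self, rng):
        r = np.linspace(0.05, 9.95, 100)
        density = np.exp(-0.5 * ((r - 4.0) / 0.8) ** 2) + 0.01 * rng.uniform(size=100)
        t = shell_thickness(r, density, 3.0, threshold_frac=0.5)
        thresh = 0.5 * density.max()
        outer = max(ri for ri, d in zip(r, density) if d >= thresh)
        assert t == outer - 3.0


class TestPersistenceLength:
    @pytest.mark.parametrize("c", [0.3, 1 / math.e, 0.9])
    def test_recovers_wormlike_ground_truth(self, c):
        """l_p = -l_b/ln(c) recovered within 10% from 200 x 50-bond chains."""
        chains = [
            make_wormlike_chain(51, bond_length=0.7, correlation=c, seed=1000 + k)
            for k in range(200)
        ]
        stats = persistence_length(chains)
        truth = -0.7 / math.log(c)
        assert stats.l_p == pytest.approx(truth, rel=0.10)
        assert stats.l_b == pytest.approx(0.7, abs=1e-9)

    def test_rigid_rod_returns_upper_bound_sentinel(self):
        rod = np.column_stack((np.arange(30) * 0.7, np.zeros(30), np.zeros(30)))
        stats = persistence_length([rod] * 5)
        assert math.isinf(stats.l_p)
        assert stats.upper_bound

    def test_freely_jointed_chain_has_sub_bond_persistence(self):
        chains = [
            make_wormlike_chain(51, bond_length=0.7, correlation=0.0, seed=k)
            for k in range(100)
        ]
        stats = persistence_length(chains)
        assert stats.lower_bound or stats.l_p < 0.7


class TestCensusAndClassification:
    def _two_sphere_system(self, bridged):
        s1 = SphereSpec(center=(5, 5, 5), radius=2.0)
        s2 = SphereSpec(center=(15, 15, 15), radius=2.0)
        c1 = np.array([[5 + 2.2 + 0.5 * i, 5, 5] for i in range(3)])
        c2 = np.array([[15 - 2.2 - 0.5 * i, 15, 15] for i in range(3)])
        pts = np.vstack((c1, c2))
        bonds = [[0, 1], [1, 2], [3, 4], [4, 5]]
        if bridged:
            bonds.append([2, 5])
        st = _state(pts, species=[S_B] * 6, bonds=bonds)
        return st, [s1, s2]

    def test_disjoint_shells_are_two_mono_capsules(self):
        st, spheres = self._two_sphere_system(bridged=False)
        census = encapsulation_census(st, None, spheres)
        assert census["n_capsules"] == 2
        assert census["mono_fraction"] == 1.0

    def test_bridged_shells_merge_into_one_capsule(self):
        st, spheres = self._two_sphere_system(bridged=True)
        census = encapsulation_census(st, None, spheres)
        assert census["capsule_sizes"] == [2]
        assert census["mono_fraction"] == 0.0

    def test_matches_union_find_oracle_on_random_fixtures(self, rng):
        """Sphere grouping equals an independent connected-components pass."""
        import itertools

        for trial in range(10):
            trng = np.random.default_rng(500 + trial)
            n_sph = 4
            spheres = [
                SphereSpec(center=tuple(c), radius=1.0)
                for c in trng.uniform(3, 17, size=(n_sph, 3))
            ]
            pts = make_uniform_gas(120, SimulationBox(edges=[20.0] * 3),
                                   seed=600 + trial)
            bonds = trng.integers(0, 120, size=(40, 2))
            bonds = np.unique(
                np.sort(bonds[bonds[:, 0] != bonds[:, 1]], axis=1), axis=0
            )
            st = _state(pts, species=[S_B] * 120, bonds=bonds)
            census = encapsulation_census(st, None, spheres, attach_cutoff=1.0)
            # oracle: spheres sharing any component id are one capsule
            from capsim.observables import shell_components

            _, _, attached = shell_components(st, None, spheres, 1.0)
            adj = {k: set() for k in range(n_sph)}
            for a, b in itertools.combinations(range(n_sph), 2):
                if attached[a] & attached[b]:
                    adj[a].add(b)
                    adj[b].add(a)
            seen, sizes = set(), []
            for k in range(n_sph):
                if k in seen:
                    continue
                stack, comp = [k], set()
                while stack:
                    x = stack.pop()
                    if x in comp:
                        continue
                    comp.add(x)
                    stack.extend(adj[x])
                seen |= comp
                sizes.append(len(comp))
            assert sorted(census["capsule_sizes"]) == sorted(sizes)

    def test_three_regime_classification(self):
        bare = 4 * math.pi * 5.1**2
        assert classify_morphology(0.001, 0.02 * bare, bare) == "I"
        assert classify_morphology(0.0001, 0.6 * bare, bare) == "III"
        assert classify_morphology(0.02, 0.05 * bare, bare) == "II"
        # threshold edge: kappa2 exactly at the critical value stays regime I
        assert classify_morphology(0.004, 0.0, bare) == "I"
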
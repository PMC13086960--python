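"""Trajectory observables against exhaustive brute-force oracles."""

import numpy as np
import pytest

from waxpore import (ClusterLayoutSpec, KineticsGroundTruth, PoreLayoutSpec,
                     PoreRegion, Trajectory, deepest_water_depth, density_scan,
                     net_charge_in_region, occupancy_counts, penetration_trace,
                     simulate_penetration, simulate_pore_system, water_clusters)

BOX = np.array([8.0, 8.0, 20.0])


def make_traj(times, positions_per_frame, species, charges=None,
              box=BOX) -> Trajectory:
    """Single-site molecules: one row per molecule per frame."""
    n = len(species)
    coords = np.asarray(positions_per_frame, dtype=float).reshape(len(times), n, 3)
    return Trajectory(
        times=np.asarray(times, dtype=float), coords=coords,
        mol_ids=np.arange(n), species=list(species),
        charges=np.zeros(n, dtype=int) if charges is None else np.asarray(charges),
        site_mol=np.arange(n), site_elements=["O"] * n, box=np.asarray(box))


def random_traj(rng, n_mol=80, n_frames=3):
    species = rng.choice(["water", "Na", "Cl", "MG", "C12E6"], size=n_mol)
    charges = np.where(species == "Na", 1, np.where(species == "Cl", -1, 0))
    pos = np.empty((n_frames, n_mol, 3))
    pos[:, :, 0] = rng.uniform(0, BOX[0], (n_frames, n_mol))
    pos[:, :, 1] = rng.uniform(0, BOX[1], (n_frames, n_mol))
    pos[:, :, 2] = rng.uniform(-15, 5, (n_frames, n_mol))
    return make_traj(np.arange(n_frames), pos, list(species), charges)


def brute_inside(com, region, box):
    """O(n) reference point-in-cylinder test with lateral minimum image."""
    out = np.zeros(len(com), dtype=bool)
    for i, (x, y, z) in enumerate(com):
        dx = x - region.axis[0]
        dy = y - region.axis[1]
        dx -= round(dx / box[0]) * box[0]
        dy -= round(dy / box[1]) * box[1]
        out[i] = (np.hypot(dx, dy) <= region.radius
                  and region.z_bottom <= z <= region.z_top)
    return out


REGION = PoreRegion(axis=(4.0, 4.0), radius=1.5, z_top=0.0, z_bottom=-15.0)


class TestDeepestWaterDepth:
    def test_three_frame_hand_average(self):
        # per-frame minima -0.4, -0.5, -0.6 -> mean -0.5
        pos = [[[4, 4, -0.4], [4, 4, 1.0]],
               [[4, 4, -0.5], [4, 4, 0.5]],
               [[4, 4, -0.6], [4, 4, 2.0]]]
        traj = make_traj([0, 1, 2], pos, ["water", "water"])
        assert deepest_water_depth(traj, REGION) == pytest.approx(-0.5)

    def test_single_water_above_pore(self):
        traj = make_traj([0], [[[4, 4, 0.3]]], ["water"])
        assert deepest_water_depth(traj, REGION) == pytest.approx(0.3)

    def test_matches_brute_force_on_randomized_frames(self, rng):
        for _ in range(25):
            traj = random_traj(rng)
            expect = []
            for f in range(traj.n_frames):
                com = traj.com(f)
                w = [i for i, s in enumerate(traj.species) if s == "water"]
                lat = brute_inside(
                    np.column_stack([com[w, 0], com[w, 1], np.zeros(len(w))]),
                    REGION, BOX)
                if lat.any():
                    expect.append(min(com[w][lat][:, 2]))
            assert deepest_water_depth(traj, REGION) == pytest.approx(
                np.mean(expect))

    def test_never_below_pore_bottom_on_synthetic_systems(self):
        layout = PoreLayoutSpec(clusters=(ClusterLayoutSpec(6, (4, 4, -5.0)),),
                                n_bulk_waters=9)
        region = PoreRegion(axis=(4.0, 4.0), radius=1.5, z_bottom=-15.0)
        traj = simulate_pore_system(layout, region, seed=3, box=BOX)
        d = deepest_water_depth(traj, region)
        assert region.z_bottom <= d < 0

    def test_discard_fraction_drops_early_frames(self):
        pos = [[[4, 4, -1.0]], [[4, 4, -2.0]], [[4, 4, -3.0]], [[4, 4, -4.0]]]
        traj = make_traj([0, 1, 2, 3], pos, ["water"])
        assert deepest_water_depth(traj, REGION, discard=0.5) == pytest.approx(-3.5)

    def test_no_water_rejected(self):
        traj = make_traj([0], [[[4, 4, -1.0]]], ["Na"])
        with pytest.raises(ValueError, match="water"):
            deepest_water_depth(traj, REGION)


class TestPenetrationTrace:
    def test_recovers_generated_depth_series(self):
        truth = KineticsGroundTruth(A_true=0.05, prefactor_true=2.0)
        region = PoreRegion(axis=(3.0, 3.0), radius=0.975)
        traj, clean = simulate_penetration(truth, np.linspace(0, 100, 101), region)
        trace = penetration_trace(traj, "C12E6", region)
        assert np.allclose(trace.depths, clean.depths, atol=1e-12)
        assert trace.z0 == 0.0

    def test_minimum_of_two_molecules(self):
        pos = [[[4, 4, -1.0], [4, 4, -2.0]]]
        traj = make_traj([0], pos, ["C12E6", "C12E6"])
        trace = penetration_trace(traj, "C12E6", REGION)
        assert trace.depths[0] == -2.0

    def test_absent_species_rejected(self):
        traj = make_traj([0], [[[4, 4, -1.0]]], ["water"])
        with pytest.raises(ValueError, match="absent"):
            penetration_trace(traj, "C12G1", REGION)


class TestOccupancyAndCharge:
    def test_balanced_synthetic_layout(self):
        region = PoreRegion(axis=(4.0, 4.0), radius=1.5)
        layout = PoreLayoutSpec(ions_in_pore=(("Na", 3), ("Cl", 3)),
                                n_bulk_waters=4)
        traj = simulate_pore_system(layout, region, seed=1, box=BOX)
        occ = occupancy_counts(traj, region)
        assert occ["Na"] == 3 and occ["Cl"] == 3
        assert net_charge_in_region(traj, region) == 0

    def test_empty_pore_all_zero(self):
        traj = make_traj([0], [[[0.5, 0.5, 3.0]]], ["water"])
        occ = occupancy_counts(traj, REGION, species=["water", "Na"])
        assert occ == {"water": 0, "Na": 0}
        assert net_charge_in_region(traj, REGION) == 0

    def test_unbalanced_divalent_charge(self):
        pos = [[[4, 4, -1.0], [4, 4, -2.0]]]
        traj = make_traj([0], pos, ["Ca", "Cl"], charges=[2, -1])
        assert net_charge_in_region(traj, REGION) == +1

    def test_matches_brute_force_oracles(self, rng):
        for _ in range(25):
            traj = random_traj(rng)
            f = traj.n_frames - 1
            inside = brute_inside(traj.com(f), REGION, BOX)
            sp = np.asarray(traj.species)
            occ = occupancy_counts(traj, REGION)
            for s in set(traj.species):
                assert occ[s] == int(np.sum(inside & (sp == s)))
            assert net_charge_in_region(traj, REGION) == int(
                traj.charges[inside].sum())

    def test_time_outside_trajectory_rejected(self):
        traj = make_traj([0, 1], [[[4, 4, -1]], [[4, 4, -1]]], ["water"])
        with pytest.raises(ValueError, match="outside"):
            occupancy_counts(traj, REGION, time=5.0)


class TestDensityScan:
    def test_stationary_particle_fills_single_bin(self):
        pos = [[[2.0, 2.0, -1.0]]] * 10
        traj = make_traj(np.arange(10), pos, ["water"])
        scan = density_scan(traj, plane="side_view", bin_width=0.5,
                            extent=((0, 8), (-4, 4)))
        assert scan.counts["water"].sum() == 10
        assert scan.counts["water"].max() == 10

    def test_counts_conserve_observations(self, rng):
        traj = random_traj(rng, n_mol=60, n_frames=4)
        scan = density_scan(traj, plane="top_view", bin_width=0.4)
        total = sum(c.sum() for c in scan.counts.values())
        assert total == 60 * 4

    def test_uniform_positions_near_multinomial_expectation(self, rng):
        n = 20000
        pos = np.column_stack([rng.uniform(0, 8, n), rng.uniform(0, 8, n),
                               np.zeros(n)])
        traj = make_traj([0], pos[None], ["water"] * n)
        scan = density_scan(traj, plane="top_view", bin_width=2.0,
                            extent=((0, 8), (0, 8)))
        counts = scan.counts["water"]
        p = 1 / counts.size
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 5 * sigma)

    def test_degenerate_inputs_rejected(self, rng):
        traj = random_traj(rng, n_mol=5, n_frames=1)
        with pytest.raises(ValueError):
            density_scan(traj, bin_width=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            density_scan(traj, bin_width=0.1, extent=((0, 0), (0, 1)))


class TestWaterClusters:
    def test_pairwise_distance_hand_case(self):
        # O at x = 0, 0.3, 1.0 with cutoff 0.35 -> sizes {2, 1}
        pos = [[[0, 4, -1], [0.3, 4, -1], [1.0, 4, -1]]]
        traj = make_traj([0], pos, ["water"] * 3)
        cs = water_clusters(traj, cutoff=0.35)
        assert sorted(cs.sizes) == [1, 2]

    def test_chain_transitive_closure(self):
        xs = np.arange(10) * 0.3
        pos = np.column_stack([xs, np.full(10, 4.0), np.full(10, -1.0)])
        traj = make_traj([0], pos[None], ["water"] * 10)
        cs = water_clusters(traj, cutoff=0.35)
        assert cs.sizes == [10]

    def test_matches_brute_force_union_find(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 120))
            pos = np.column_stack([
                rng.uniform(0, BOX[0], n), rng.uniform(0, BOX[1], n),
                rng.uniform(-6, 2, n)])
            traj = make_traj([0], pos[None], ["water"] * n)
            cs = water_clusters(traj, cutoff=0.4)

            # O(n^2) union-find with the same lateral minimum-image metric
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    d = pos[i] - pos[j]
                    d[0] -= round(d[0] / BOX[0]) * BOX[0]
                    d[1] -= round(d[1] / BOX[1]) * BOX[1]
                    if np.linalg.norm(d) <= 0.4:
                        parent[find(i)] = find(j)
            expect = {}
            for i in range(n):
                expect.setdefault(find(i), set()).add(i)
            got = {frozenset(c) for c in cs.clusters}
            assert got == {frozenset(m) for m in expect.values()}
            # bulk flags: any member above z = 0
            for c, b in zip(cs.clusters, cs.bulk_connected):
                assert b == any(pos[i, 2] > 0 for i in c)

    def test_partition_invariant_under_molecule_permutation(self, rng):
        n = 40
        pos = np.column_stack([rng.uniform(0, 8, n), rng.uniform(0, 8, n),
                               rng.uniform(-4, 1, n)])
        traj = make_traj([0], pos[None], ["water"] * n)
        perm = rng.permutation(n)
        traj_p = make_traj([0], pos[perm][None], ["water"] * n)
        a = {frozenset(c) for c in water_clusters(traj, cutoff=0.45).clusters}
        b = {frozenset(np.asarray(perm)[list(c)]) for c in
             water_clusters(traj_p, cutoff=0.45).clusters}
        assert a == b


class TestTranslationInvariance:
    def test_metrics_invariant_under_rigid_lateral_shift(self, rng):
        traj = random_traj(rng)
        shift = np.array([1.7, -2.3, 0.0])
        shifted = make_traj(traj.times, traj.coords + shift,
                            list(traj.species), traj.charges)
        r2 = PoreRegion(axis=(REGION.axis[0] + shift[0],
                              REGION.axis[1] + shift[1]),
                        radius=REGION.radius, z_top=REGION.z_top,
                        z_bottom=REGION.z_bottom)
        assert deepest_water_depth(traj, REGION) == pytest.approx(
            deepest_water_depth(shifted, r2))
        assert occupancy_counts(traj, REGION) == occupancy_counts(shifted, r2)
        assert net_charge_in_region(traj, REGION) == net_charge_in_region(
            shifted, r2)
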
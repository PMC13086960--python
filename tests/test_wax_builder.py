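"""Crystalline slab construction, pore carving, and functionalization."""

import math

import numpy as np
import pytest

from waxpore import (FunctionalizationSpec, LatticeSpec, PoreSpec,
                     build_chain, build_crystal_slab, carve_pore,
                     functionalize_surface, round_half_away)
from waxpore.wax_builder import _chain_axes, _lateral_distance


class TestBuildChain:
    def test_axial_rise_matches_closed_form(self, default_lattice):
        # rise = cc_bond * sin(angle/2); C30 end-to-end = 29 * rise = 3.74 nm
        pos = build_chain(default_lattice)
        rise = 0.154 * math.sin(math.radians(114) / 2)
        dz = -np.diff(pos[:, 2])
        assert np.allclose(dz, rise, atol=1e-12)
        assert math.isclose(pos[0, 2] - pos[-1, 2], 29 * rise, rel_tol=1e-12)
        assert math.isclose(29 * rise, 3.745, abs_tol=5e-3)

    def test_single_carbon_chain_has_zero_extent(self):
        pos = build_chain(LatticeSpec(carbons_per_chain=1))
        assert pos.shape == (1, 3)
        assert np.allclose(pos, 0.0)

    def test_two_carbon_chain_reproduces_bond_length(self):
        pos = build_chain(LatticeSpec(carbons_per_chain=2))
        assert math.isclose(np.linalg.norm(pos[1] - pos[0]), 0.154, rel_tol=1e-12)

    def test_all_bond_lengths_and_angles(self, default_lattice):
        pos = build_chain(default_lattice)
        bonds = np.diff(pos, axis=0)
        lengths = np.linalg.norm(bonds, axis=1)
        assert np.allclose(lengths, 0.154, atol=1e-12)
        cosang = np.einsum("ij,ij->i", -bonds[:-1], bonds[1:]) / (
            lengths[:-1] * lengths[1:])
        assert np.allclose(np.degrees(np.arccos(cosang)), 114.0, atol=1e-9)

    @pytest.mark.parametrize("kwargs", [
        {"cc_bond": 0.0}, {"cc_bond": -1.0}, {"ccc_angle": 0.0},
        {"ccc_angle": 180.0}, {"carbons_per_chain": 0},
    ])
    def test_nonphysical_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LatticeSpec(**kwargs)


class TestBuildCrystalSlab:
    @pytest.mark.parametrize("target,nx,ny,n_chains", [
        ((6.0, 6.0), 8, 12, 192),
        ((3.0, 3.0), 4, 6, 48),
        ((0.742, 0.496), 1, 1, 2),
    ])
    def test_tiling_counts(self, target, nx, ny, n_chains):
        slab = build_crystal_slab(target, LatticeSpec())
        assert slab.provenance["nx"] == nx
        assert slab.provenance["ny"] == ny
        assert slab.provenance["n_chains"] == n_chains
        assert np.allclose(slab.box[:2], [nx * 0.742, ny * 0.496])

    def test_default_six_by_six_realized_box(self, flat_slab):
        assert np.allclose(flat_slab.box[:2], [5.936, 5.952], atol=1e-12)
        assert flat_slab.n_atoms == 192 * 30

    def test_methyl_surface_at_z_zero_wax_below(self, flat_slab):
        z = flat_slab.positions[:, 2]
        assert z.max() == pytest.approx(0.0, abs=1e-12)
        assert z.min() < -3.7

    def test_subcell_target_too_small(self):
        with pytest.raises(ValueError):
            build_crystal_slab((0.5, 0.3), LatticeSpec())

    def test_chain_area_density_matches_lattice(self, flat_slab, default_lattice):
        area = flat_slab.box[0] * flat_slab.box[1]
        density = flat_slab.provenance["n_chains"] / area
        assert math.isclose(density, default_lattice.chain_area_density,
                            rel_tol=1e-12)

    def test_nearest_neighbour_axis_distances(self, flat_slab, default_lattice):
        # orthorhombic herringbone: nearest axis is the subcell-centre chain
        _, axes = _chain_axes(flat_slab)
        expect = 0.5 * math.hypot(default_lattice.subcell_a,
                                  default_lattice.subcell_b)
        d = np.linalg.norm(axes[None, :, :] - axes[:, None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(d.min(axis=1), expect, atol=1e-9)


class TestCarvePore:
    def test_default_pore_removes_14_per_layer(self, pore_slab):
        carved, per_layer = pore_slab
        assert per_layer == 14
        assert carved.provenance["pore_layers_spanned"] == 4
        # 14 chains removed in each of the 4 layers
        assert carved.n_atoms == (768 - 56) * 30

    def test_zero_radius_between_sites_removes_nothing(self, flat_slab):
        spec = PoreSpec(mode="by_radius", accessible_radius=0.0,
                        methyl_radius=0.0, center=(0.0, 0.0), depth=3.75)
        carved, removed = carve_pore(flat_slab, spec)
        assert removed == 0
        assert carved.n_atoms == flat_slab.n_atoms

    def test_by_radius_matches_brute_force_enumeration(self, flat_slab):
        cut = 0.95
        ids, axes = _chain_axes(flat_slab)
        center = axes[17]  # centred on a chain site
        expected = int(np.count_nonzero(
            _lateral_distance(axes, center, flat_slab.box) <= cut))
        spec = PoreSpec(mode="by_radius", accessible_radius=cut - 0.20,
                        center=tuple(center), depth=3.75)
        _, removed = carve_pore(flat_slab, spec)
        assert removed == expected > 0

    def test_carving_is_pure_deletion(self, flat_slab):
        carved, _ = carve_pore(flat_slab, PoreSpec(depth=3.75))
        kept = set(np.unique(carved.chain_ids))
        for cid in kept:
            orig = flat_slab.positions[flat_slab.chain_ids == cid]
            new = carved.positions[carved.chain_ids == cid]
            assert np.array_equal(orig, new)
        removed_ids = set(np.unique(flat_slab.chain_ids)) - kept
        assert len(removed_ids) == 14
        assert not np.isin(carved.chain_ids, sorted(removed_ids)).any()

    def test_zero_count_reproduces_intact_slab(self, flat_slab):
        carved, removed = carve_pore(flat_slab, PoreSpec(n_remove=0, depth=3.75))
        assert removed == 0
        assert np.array_equal(carved.positions, flat_slab.positions)
        assert carved.group_labels == flat_slab.group_labels

    def test_removed_count_monotone_in_radius(self, flat_slab):
        counts = []
        for r in np.linspace(0.0, 1.6, 9):
            _, removed = carve_pore(flat_slab, PoreSpec(
                mode="by_radius", accessible_radius=r, depth=3.75))
            counts.append(removed)
        assert counts == sorted(counts)

    def test_depth_exceeding_slab_rejected(self, flat_slab):
        with pytest.raises(ValueError, match="exceeds"):
            carve_pore(flat_slab, PoreSpec(depth=15.0))

    def test_count_exceeding_layer_rejected(self, flat_slab):
        with pytest.raises(ValueError, match="n_remove"):
            carve_pore(flat_slab, PoreSpec(n_remove=500, depth=3.75))


class TestFunctionalizeSurface:
    def test_default_fraction_replaces_86_and_charges(self, flat_slab):
        # round(0.015 * 5760) = 86 COO-, total charge -86
        out = functionalize_surface(flat_slab, FunctionalizationSpec(seed=7))
        assert out.provenance["n_replaced"] == 86
        assert out.total_charge() == -86
        assert out.group_labels.count("COO") == 86

    def test_low_fraction_replaces_29(self, flat_slab):
        out = functionalize_surface(
            flat_slab, FunctionalizationSpec(fraction=0.005, seed=7))
        assert out.provenance["n_replaced"] == 29

    def test_zero_fraction_is_identity(self, flat_slab):
        out = functionalize_surface(
            flat_slab, FunctionalizationSpec(fraction=0.0, seed=7))
        assert out.group_labels == flat_slab.group_labels
        assert out.total_charge() == 0

    def test_cooh_never_changes_charge(self, flat_slab):
        out = functionalize_surface(flat_slab, FunctionalizationSpec(
            group="COOH", fraction=0.015, seed=7))
        assert out.total_charge() == 0
        assert out.group_labels.count("COOH") == 86

    def test_replacements_confined_to_requested_face(self, flat_slab):
        top = functionalize_surface(flat_slab, FunctionalizationSpec(seed=1))
        idx = [i for i, lab in enumerate(top.group_labels) if lab == "COO"]
        assert np.all(top.positions[idx, 2] > -0.1)
        bot = functionalize_surface(flat_slab, FunctionalizationSpec(
            face="bottom", seed=1))
        idx = [i for i, lab in enumerate(bot.group_labels) if lab == "COO"]
        assert np.all(bot.positions[idx, 2] < -3.6)

    def test_over_demanding_fraction_rejected(self, flat_slab):
        with pytest.raises(ValueError, match="terminal CH3 sites"):
            functionalize_surface(flat_slab, FunctionalizationSpec(
                fraction=0.5, seed=1))

    def test_seeded_selection_reproducible(self, flat_slab):
        a = functionalize_surface(flat_slab, FunctionalizationSpec(seed=3))
        b = functionalize_surface(flat_slab, FunctionalizationSpec(seed=3))
        c = functionalize_surface(flat_slab, FunctionalizationSpec(seed=4))
        assert a.group_labels == b.group_labels
        assert a.group_labels != c.group_labels

    def test_pore_wall_face_requires_pore(self, flat_slab):
        with pytest.raises(ValueError, match="pore_wall"):
            functionalize_surface(flat_slab, FunctionalizationSpec(
                face="pore_wall", fraction=0.001, seed=1))

    def test_pore_wall_sites_near_axis(self, pore_slab):
        carved, _ = pore_slab
        out = functionalize_surface(carved, FunctionalizationSpec(
            face="pore_wall", fraction=0.0005, seed=1))
        idx = [i for i, lab in enumerate(out.group_labels) if lab == "COO"]
        assert idx
        center = np.asarray(carved.provenance["pore_center"])
        d = _lateral_distance(out.positions[idx, :2], center, out.box)
        assert np.all(d < 2.5)


def test_round_half_away():
    assert round_half_away(0.5) == 1
    assert round_half_away(1.5) == 2
    assert round_half_away(2.5) == 3
    assert round_half_away(-0.5) == -1
    assert round_half_away(86.4) == 86
    assert round_half_away(28.8) == 29
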
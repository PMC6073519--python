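"""Geometry: duplex generation, symmetry groups, assembly, validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnanma import (assemble, assembly_topology, build_duplex, build_tile,
                    get_design, get_group, interfaces_from_model,
                    measure_ring_diameters, validate_structure)
from dnanma.builder import build_assembly, rotate_model
from dnanma.constants import HBOND_MAX, HBOND_MIN, RISE_PER_BP
from dnanma.model import DesignError
from dnanma.symmetry import rotation_about


class TestDuplex:
    def test_length_additivity_and_pair_count(self):
        d = build_duplex(10)
        assert d.n_nucleotides == 20
        assert len(d.pairing) == 10
        # nominal contour = bp x rise; axis points span (bp-1) steps
        axis = np.array([nt.axis_point for nt in d.nucleotides[:10]])
        span = np.linalg.norm(axis[-1] - axis[0])
        assert span == pytest.approx(9 * RISE_PER_BP, abs=1e-9)
        assert 10 * RISE_PER_BP == pytest.approx(3.4)

    def test_single_bp_duplex(self):
        d = build_duplex(1)
        assert d.n_nucleotides == 2
        assert len(d.pairing) == 1

    def test_full_turn_twist(self):
        # 36 deg/bp: bp 10 has the same azimuthal orientation as bp 0
        d = build_duplex(11, twist_deg=36.0)
        c1 = np.array([d.positions[d.atom_index(i, "C1'")] for i in (0, 10)])
        axial = np.array([0.0, 0.0, 1.0])
        perp = c1 - np.outer(c1 @ axial, axial)
        assert np.allclose(perp[0][:2], perp[1][:2], atol=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DesignError):
            build_duplex(0)
        with pytest.raises(DesignError):
            build_duplex(5, rise=-0.1)

    def test_antiparallel_watson_crick_distances(self):
        d = build_duplex(8)
        rep = validate_structure(d)
        assert rep.hbond_lengths.min() >= HBOND_MIN
        assert rep.hbond_lengths.max() <= HBOND_MAX


class TestSymmetryGroups:
    @given(st.integers(min_value=1, max_value=24))
    @settings(max_examples=12, deadline=None)
    def test_cyclic_group_closure(self, q):
        get_group(f"c{q}").validate()

    @pytest.mark.parametrize("name,order", [("icosahedral", 60),
                                            ("tetrahedral", 12)])
    def test_polyhedral_groups(self, name, order):
        g = get_group(name)
        assert g.order == order
        g.validate()

    @given(st.floats(-3.1, 3.1), st.integers(0, 2))
    @settings(max_examples=20, deadline=None)
    def test_rotation_matrices_proper(self, angle, axis_i):
        axis = np.eye(3)[axis_i] + 0.3
        R = rotation_about(axis, angle)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)


class TestAssembly:
    def test_identity_group_is_identity(self):
        tile = build_tile(get_design("toy_ring_c4"))
        out = assemble(tile, get_group("c1"))
        assert np.allclose(out.positions, tile.positions)
        assert out.n_nucleotides == tile.n_nucleotides

    def test_copies_are_congruent(self, r1c_model):
        """All intra-tile pairwise distances identical across copies."""
        tiles = r1c_model.atom_tiles()
        idx0 = np.nonzero(tiles == 0)[0]
        idx5 = np.nonzero(tiles == 5)[0]
        assert len(idx0) == len(idx5)
        rng = np.random.default_rng(0)
        pick = rng.choice(len(idx0), size=200)
        pairs = rng.choice(len(idx0), size=200)
        d0 = np.linalg.norm(r1c_model.positions[idx0[pick]]
                            - r1c_model.positions[idx0[pairs]], axis=1)
        d5 = np.linalg.norm(r1c_model.positions[idx5[pick]]
                            - r1c_model.positions[idx5[pairs]], axis=1)
        assert np.allclose(d0, d5, atol=1e-9)

    def test_group_element_permutes_copies(self, r1c_model):
        """Rotating the whole ring by a group element permutes tile copies."""
        from scipy.spatial import cKDTree
        g = get_group("c12")
        rotated = rotate_model(r1c_model, g.rotations[3])
        tree = cKDTree(r1c_model.positions)
        dist, _ = tree.query(rotated.positions, k=1)
        assert dist.max() < 1e-8

    def test_ring_tile_subtends_30_degrees(self):
        tile = build_tile(get_design("r1c"))
        roles = tile.nt_attr("role")
        axis = np.array([nt.axis_point for nt in tile.nucleotides])
        inner = axis[roles == "inner_circle"]
        ang = np.arctan2(inner[:, 1], inner[:, 0])
        # reference strand covers the 30-degree window; the complementary
        # strand reaches one overhang into the previous window
        assert np.deg2rad(-35.0) < ang.min() < np.deg2rad(-15.0)
        assert ang.max() < np.deg2rad(15.0)

    def test_star_tile_threefold_symmetry(self):
        from scipy.spatial import cKDTree
        tile = build_tile(get_design("tile"))
        R = rotation_about((0, 0, 1), 2 * np.pi / 3)
        tree = cKDTree(tile.positions)
        dist, _ = tree.query(tile.positions @ R.T, k=1)
        assert dist.max() < 1e-6

    def test_open_form_has_eight_nt_single_stranded_domain(self):
        tile = build_tile(get_design("r1o"))
        paired = {i for p in tile.pairing for i in p}
        roles = tile.nt_attr("role")
        stickies = tile.nt_attr("sticky_label")
        unpaired_outer = [i for i in range(tile.n_nucleotides)
                          if roles[i] == "outer_circle" and i not in paired
                          and stickies[i] is None]
        assert len(unpaired_outer) == 8


class TestValidation:
    def test_assembled_ring_is_clash_free(self, r1c_model):
        rep = validate_structure(r1c_model)
        assert rep.n_clashes == 0
        assert rep.min_interatomic_distance > 0.25

    def test_hbond_lengths_within_band(self, r1c_model):
        rep = validate_structure(r1c_model)
        assert np.all(rep.hbond_lengths >= HBOND_MIN)
        assert np.all(rep.hbond_lengths <= HBOND_MAX)

    def test_sticky_interfaces_pair_expected_bases(self, r1c_model):
        """Each tile interface hybridizes 4 inner + 4 outer base pairs."""
        rep = validate_structure(r1c_model)
        assert len(rep.sticky_end_hbond_counts) == 12
        assert set(rep.sticky_end_hbond_counts.values()) == {8}

    def test_coincident_atoms_flagged_as_clash(self):
        d = build_duplex(4)
        shifted = rotate_model(d, np.eye(3))
        shifted.positions = shifted.positions + np.array([0.05, 0.0, 0.0])
        from dnanma.model import concat_models
        doubled = concat_models([d, shifted], tile_indices=[0, 1])
        rep = validate_structure(doubled)
        assert rep.n_clashes > 0


class TestMeasurement:
    def test_single_circle_outer_equals_inner(self):
        design = get_design("toy_ring_c6")
        model = build_assembly(design)
        dia = measure_ring_diameters(model)
        r_axis = design.params["inner_radius"]
        assert dia["inner"] == pytest.approx(2 * r_axis, abs=1e-6)
        # atoms extend beyond the duplex axis
        assert dia["outer"] > dia["inner"]

    def test_model_without_inner_circle_rejected(self):
        tile = build_tile(get_design("tile"))
        with pytest.raises(DesignError):
            measure_ring_diameters(tile)


class TestTopology:
    def test_cyclic_ring_graph(self, r1c_model):
        centers, interfaces = interfaces_from_model(r1c_model)
        topo = assembly_topology(centers, interfaces)
        assert topo["vertices"] == 12
        assert topo["edges"] == 12

    def test_mini_ball_euler(self, mini_ball):
        centers, interfaces = interfaces_from_model(mini_ball.fine)
        topo = assembly_topology(centers, interfaces)
        assert topo["vertices"] - topo["edges"] + topo["faces"] == 2
        assert topo["faces_by_size"] == mini_ball.expected["faces_by_size"]
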
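"""Coarse-graining: representative selection, mass lumping, spring typing."""

import numpy as np
import pytest

from dnanma import build_duplex, coarse_grain, get_group
from dnanma.builder import rotate_model
from dnanma.chem import residue_mass
from dnanma.coarse_grain import (assign_lumped_masses, build_spring_network,
                                 connected_components, select_representatives)
from dnanma.constants import ATOMIC_MASS, SPRING_CONSTANTS


def _single_nt_model(base, with_p=True):
    d = build_duplex(1, bases=[base], include_5p_phosphate=with_p)
    return d


class TestRepresentatives:
    @pytest.mark.parametrize("base,n_beads", [("A", 7), ("G", 7),
                                              ("C", 6), ("T", 6)])
    def test_bead_count_per_base(self, base, n_beads):
        """Purines get 4 base beads, pyrimidines 3, plus P/C4'/C1'."""
        d = _single_nt_model(base)
        rep = select_representatives(d)
        beads0 = rep[d.nucleotide_index[rep] == 0]
        assert len(beads0) == n_beads

    def test_gc_duplex_bead_count(self):
        # independent count: 10 x 7 (G) + 10 x 6 (C) = 130
        d = build_duplex(10, bases=["G"] * 10, include_5p_phosphate=True)
        cg = coarse_grain(d)
        assert cg.n_beads == 10 * 7 + 10 * 6

    def test_terminal_nucleotide_lacks_p_bead(self):
        d = build_duplex(3)   # default: no 5'-terminal phosphate
        cg = coarse_grain(d)
        p_beads = np.nonzero(cg.bead_roles == "P")[0]
        # each strand's 5'-terminal nucleotide contributes no P bead
        assert len(p_beads) == 2 * 3 - 2


class TestLumpedMasses:
    def test_internal_dT_residue_mass(self):
        """Sum of dT bead masses equals the monophosphate residue mass."""
        assert residue_mass("T") == pytest.approx(304.195, abs=0.01)
        d = build_duplex(3, bases=["A", "A", "A"], include_5p_phosphate=True)
        cg = coarse_grain(d)
        # complementary strand is T; its middle nucleotide is internal
        t_nts = [i for i, nt in enumerate(d.nucleotides) if nt.base == "T"]
        mid = t_nts[1]
        mass = cg.masses[cg.nucleotide_index == mid].sum()
        assert mass == pytest.approx(residue_mass("T"), abs=0.01)

    def test_total_mass_conserved(self, toy_fixtures):
        for fx in toy_fixtures.values():
            assert fx.cg.total_mass == pytest.approx(fx.fine.total_mass,
                                                     abs=1e-6)

    def test_p_bead_not_lighter_than_bare_phosphorus(self, toy_fixtures):
        cg = toy_fixtures[4].cg
        p_masses = cg.masses[cg.bead_roles == "P"]
        assert np.all(p_masses >= ATOMIC_MASS["P"])

    def test_lumping_is_rotation_invariant(self, toy_fixtures):
        """Copies of a subunit get identical mass patterns."""
        cg = toy_fixtures[4].cg
        m = cg.n_beads // 4
        blocks = cg.masses.reshape(4, m)
        assert np.abs(blocks - blocks[0]).max() < 1e-9


class TestSpringNetwork:
    def test_spring_constants_by_bond_type(self, toy_fixtures):
        s = toy_fixtures[4].cg.springs
        for btype, k in (("van_der_waals", 7.0), ("hydrogen", 70.0),
                         ("covalent", 700.0)):
            sel = s[s.bond_type == btype]
            assert len(sel) > 0
            assert np.all(sel.k == k)
        # the three DNA bond classes keep the exact 1:10:100 ratio
        assert SPRING_CONSTANTS["hydrogen"] == 10 * SPRING_CONSTANTS["van_der_waals"]
        assert SPRING_CONSTANTS["covalent"] == 100 * SPRING_CONSTANTS["van_der_waals"]

    def test_no_spring_beyond_cutoff(self, toy_fixtures):
        s = toy_fixtures[4].cg.springs
        vdw = s[s.bond_type == "van_der_waals"]
        assert vdw.rest_length.max() <= 0.8 + 1e-12

    def test_paired_bases_share_hydrogen_springs(self):
        d = build_duplex(4, bases=["G", "C", "G", "C"])
        cg = coarse_grain(d)
        h = cg.springs[cg.springs.bond_type == "hydrogen"]
        # two Watson-Crick site springs per base pair
        assert len(h) == 2 * 4

    def test_one_spring_per_pair(self, toy_fixtures):
        s = toy_fixtures[3].cg.springs
        keys = list(zip(s.i, s.j))
        assert len(keys) == len(set(keys))

    def test_rest_lengths_match_geometry(self, toy_fixtures):
        cg = toy_fixtures[3].cg
        s = cg.springs
        d = np.linalg.norm(cg.positions[s.i.to_numpy()]
                           - cg.positions[s.j.to_numpy()], axis=1)
        assert np.allclose(d, s.rest_length, atol=1e-12)

    def test_invalid_cutoff_rejected(self, toy_fixtures):
        with pytest.raises(ValueError):
            build_spring_network(toy_fixtures[3].fine, cutoff=-1.0)

    def test_network_connected_on_assembled_structures(self, toy_fixtures,
                                                       r1c_cg):
        for fx in toy_fixtures.values():
            assert connected_components(fx.cg) == 1
        assert connected_components(r1c_cg) == 1

    def test_bead_set_invariant_under_assembly_rotation(self, toy_fixtures):
        """Coarse-graining commutes with the assembly's symmetry group."""
        from scipy.spatial import cKDTree
        cg = toy_fixtures[4].cg
        R = get_group("c4").rotations[1]
        tree = cKDTree(cg.positions)
        dist, idx = tree.query(cg.positions @ R.T, k=1)
        assert dist.max() < 1e-8
        assert np.allclose(cg.masses[idx], cg.masses, atol=1e-9)
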
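"""Symmetry-constrained reduction: partition, blocks, oracle equivalence."""

import numpy as np
import pytest

from dnanma import (analyze, analyze_symmetric, assemble_stiffness, get_group)
from dnanma.constants import NEWTON_PER_M_TO_AMU_PER_PS2 as CONV
from dnanma.scenm import (PartitionError, coupling_blocks_from_springs,
                          extract_coupling_blocks, partition_by_symmetry,
                          reduce, reduce_model, solve_scenm)


class TestPartition:
    def test_toy_partition(self, toy_fixtures):
        fx = toy_fixtures[4]
        part = partition_by_symmetry(fx.cg, get_group("c4"))
        assert part.q == 4
        assert part.q * part.m == fx.cg.n_beads

    def test_wrong_group_order_rejected(self, toy_fixtures):
        with pytest.raises(PartitionError):
            partition_by_symmetry(toy_fixtures[4].cg, get_group("c3"))


class TestCouplingBlocks:
    def test_paths_agree(self, toy_fixtures):
        """Full-matrix block extraction equals direct spring assembly."""
        fx = toy_fixtures[4]
        part = partition_by_symmetry(fx.cg, get_group("c4"))
        direct = coupling_blocks_from_springs(fx.cg, part)
        full = extract_coupling_blocks(assemble_stiffness(fx.cg), part)
        assert set(direct) == set(full)
        for i in full:
            assert abs(full[i] - direct[i]).max() < 1e-9 * 700

    def test_cycle_has_two_neighbor_blocks(self, toy_fixtures):
        fx = toy_fixtures[4]
        part = partition_by_symmetry(fx.cg, get_group("c4"))
        blocks = coupling_blocks_from_springs(fx.cg, part)
        off = sorted(k for k in blocks if k != 0)
        assert off == [1, 3]

    def test_block_row_annihilates_uniform_translation(self, toy_fixtures):
        fx = toy_fixtures[4]
        part = partition_by_symmetry(fx.cg, get_group("c4"))
        blocks = coupling_blocks_from_springs(fx.cg, part)
        t = np.tile([1.0, 0.0, 0.0], part.m)
        row_sum = sum(b @ t for b in blocks.values())
        assert np.abs(row_sum).max() < 1e-9 * 700


class TestReduction:
    def test_reduced_matrix_order_drops_by_q(self, toy_fixtures):
        fx = toy_fixtures[6]
        red = reduce_model(fx.cg, get_group("c6"))
        assert red.K_reduced.shape[0] == 3 * fx.cg.n_beads // 6

    def test_symmetric_rigid_motions_in_null_space(self, toy_fixtures):
        """Only group-invariant rigid motions survive the reduction: for a
        C_q ring about z these are the z-translation and z-rotation."""
        fx = toy_fixtures[4]
        red = reduce_model(fx.cg, get_group("c4"))
        m = red.K_reduced.shape[0] // 3
        tz = np.tile([0.0, 0.0, 1.0], m)
        assert np.abs(red.K_reduced @ tz).max() < 1e-8 * 700
        tx = np.tile([1.0, 0.0, 0.0], m)
        assert np.abs(red.K_reduced @ tx).max() > 1e-4
        ms = solve_scenm(red, n_modes=6)
        assert ms.zero_mode_count == 2

    def test_asymmetry_residual_small(self, toy_fixtures):
        for q, fx in toy_fixtures.items():
            red = reduce_model(fx.cg, get_group(f"c{q}"))
            assert red.asymmetry_residual < 1e-8


class TestOracleEquivalence:
    @pytest.mark.parametrize("q", [3, 4, 6])
    def test_eigenvalues_subset_of_full_spectrum(self, toy_fixtures, q):
        """Every SCENM eigenvalue appears in the dense full-NMA spectrum."""
        fx = toy_fixtures[q]
        full = analyze(fx.cg, n_modes=3 * fx.cg.n_beads).eigenvalues
        ms = analyze_symmetric(fx.cg, get_group(f"c{q}"), n_modes=10)
        for lam in ms.eigenvalues:
            if lam == 0.0:
                continue
            rel = np.abs(full - lam).min() / lam
            assert rel < 1e-6

    def test_expanded_vectors_satisfy_full_eigenproblem(self, toy_fixtures):
        fx = toy_fixtures[4]
        K = assemble_stiffness(fx.cg) * CONV
        M = np.repeat(fx.cg.masses, 3)
        ms = analyze_symmetric(fx.cg, get_group("c4"), n_modes=10)
        for k in range(ms.n_modes):
            lam = ms.eigenvalues[k]
            if lam == 0.0:
                continue
            v = ms.vectors[:, k]
            resid = np.linalg.norm(K @ v - lam * M * v)
            assert resid / np.linalg.norm(lam * M * v) < 1e-6

    def test_identity_group_reduces_to_plain_nma(self, dimer):
        ms_direct = analyze(dimer.cg, n_modes=6)
        ms_scenm = analyze_symmetric(dimer.cg, get_group("c1"), n_modes=6)
        assert np.allclose(ms_direct.eigenvalues, ms_scenm.eigenvalues)
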
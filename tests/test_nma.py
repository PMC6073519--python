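"""Normal mode analysis: Hessian assembly, eigensolution, invariants."""

import numpy as np
import pandas as pd
import pytest

from dnanma import analyze, assemble_mass, assemble_stiffness, solve_modes
from dnanma.constants import NEWTON_PER_M_TO_AMU_PER_PS2 as CONV
from dnanma import nma
from _helpers import bead_model, numerical_hessian, random_bead_model


class TestStiffness:
    def test_dimer_closed_form(self, dimer):
        sys = nma.system_matrices(dimer.cg)
        K = sys.K.toarray()
        w = np.linalg.eigvalsh(K)
        # single stretch mode with stiffness 2k, five zeros
        assert np.allclose(sorted(w)[:5], 0.0, atol=1e-9)
        assert w.max() == pytest.approx(2 * 700.0, rel=1e-12)

    def test_translation_invariance(self, toy_fixtures):
        K = assemble_stiffness(toy_fixtures[3].cg)
        n = toy_fixtures[3].cg.n_beads
        for axis in range(3):
            t = np.zeros(3 * n)
            t[axis::3] = 1.0
            assert np.abs(K @ t).max() < 1e-9 * 700

    def test_matches_finite_difference_hessian(self, rng):
        cg = random_bead_model(rng)
        K = assemble_stiffness(cg).toarray()
        H = numerical_hessian(cg)
        kmax = cg.springs["k"].max()
        assert np.abs(K - H).max() < 1e-6 * kmax

    def test_zero_length_spring_rejected(self):
        cg = bead_model([[0, 0, 0], [0, 0, 0]], [1.0, 1.0],
                        {"i": [0], "j": [1], "k": [7.0],
                         "bond_type": ["covalent"], "rest_length": [0.0]})
        with pytest.raises(Exception):
            assemble_stiffness(cg)


class TestMass:
    def test_trace_is_three_times_total_mass(self, toy_fixtures):
        cg = toy_fixtures[3].cg
        M = assemble_mass(cg)
        assert M.sum() == pytest.approx(3 * cg.total_mass)

    def test_single_bead(self):
        cg = bead_model([[0, 0, 0], [1, 0, 0]], [42.0, 42.0],
                        {"i": [0], "j": [1], "k": [7.0],
                         "bond_type": ["covalent"], "rest_length": [1.0]})
        M = assemble_mass(cg)
        assert np.allclose(M[:3], 42.0)

    def test_uniform_velocity_kinetic_energy(self, toy_fixtures):
        """T = 1/2 |w|^2 M_total for a uniform velocity field."""
        cg = toy_fixtures[3].cg
        M = assemble_mass(cg)
        w = np.array([0.3, -0.2, 0.5])
        field = np.tile(w, cg.n_beads)
        T = 0.5 * field @ (M * field)
        assert T == pytest.approx(0.5 * (w @ w) * cg.total_mass)


class TestModes:
    def test_dimer_frequency(self, dimer):
        ms = analyze(dimer.cg, n_modes=6)
        assert ms.zero_mode_count == dimer.expected["zero_modes"]
        lam = dimer.expected["nonzero_eigenvalues"][0]
        assert ms.eigenvalues[-1] == pytest.approx(lam, rel=1e-12)

    def test_connected_structures_have_six_zero_modes(self, toy_fixtures):
        for fx in toy_fixtures.values():
            ms = analyze(fx.cg, n_modes=10)
            assert ms.zero_mode_count == 6

    def test_disconnected_network_warns(self, dimer):
        import pandas as pd
        cg = bead_model([[0, 0, 0], [1, 0, 0], [5, 0, 0], [6, 0, 0]],
                        [50.0] * 4,
                        {"i": [0, 2], "j": [1, 3], "k": [700.0] * 2,
                         "bond_type": ["covalent"] * 2,
                         "rest_length": [1.0, 1.0]})
        with pytest.warns(UserWarning, match="disconnected"):
            analyze(cg, n_modes=12)

    def test_chain_matches_dense_oracle(self, rng):
        """Nonzero spectrum agrees with an independent dense diagonalization."""
        cg = random_bead_model(rng, n=6)
        ms = analyze(cg, n_modes=3 * 6)
        d = 1.0 / np.sqrt(np.repeat(cg.masses, 3))
        B = d[:, None] * (assemble_stiffness(cg).toarray() * CONV) * d[None, :]
        w_oracle = np.sort(np.linalg.eigvalsh(0.5 * (B + B.T)))
        nz = ms.eigenvalues[np.abs(ms.eigenvalues) > 1e-8]
        nz_oracle = w_oracle[np.abs(w_oracle) > 1e-8]
        assert np.allclose(nz, nz_oracle[:len(nz)], rtol=1e-9)

    def test_mass_orthonormality(self, toy_fixtures):
        cg = toy_fixtures[4].cg
        ms = analyze(cg, n_modes=14)
        M = np.repeat(cg.masses, 3)
        G = ms.vectors.T @ (M[:, None] * ms.vectors)
        assert np.abs(G - np.eye(ms.n_modes)).max() < 1e-8

    def test_permutation_equivariance(self, rng):
        cg = random_bead_model(rng, n=6)
        perm = rng.permutation(cg.n_beads)
        inv = np.argsort(perm)
        cg2 = bead_model(cg.positions[perm], cg.masses[perm], {
            "i": [int(min(inv[a], inv[b]))
                  for a, b in zip(cg.springs.i, cg.springs.j)],
            "j": [int(max(inv[a], inv[b]))
                  for a, b in zip(cg.springs.i, cg.springs.j)],
            "k": cg.springs.k.tolist(),
            "bond_type": cg.springs.bond_type.tolist(),
            "rest_length": cg.springs.rest_length.tolist(),
        })
        w1 = analyze(cg, n_modes=12).eigenvalues
        w2 = analyze(cg2, n_modes=12).eigenvalues
        assert np.allclose(w1, w2, atol=1e-8 * max(1, abs(w1).max()))

    def test_sparse_path_matches_dense(self, toy_fixtures, monkeypatch):
        """ARPACK shift-invert agrees with dense diagonalization."""
        cg = toy_fixtures[4].cg   # 3N ~ 1850
        dense = analyze(cg, n_modes=12).eigenvalues
        monkeypatch.setattr(nma, "DENSE_LIMIT", 10)
        sparse = analyze(cg, n_modes=12).eigenvalues
        scale = abs(dense).max()
        assert np.allclose(dense, sparse, atol=1e-8 * scale, rtol=1e-8)

    def test_spectrum_invariant_under_group_rotation(self, toy_fixtures):
        """Rotating a mode field by a group element keeps its Rayleigh
        quotient (degenerate pairs may mix)."""
        from dnanma import get_group
        fx = toy_fixtures[4]
        cg = fx.cg
        ms = analyze(cg, n_modes=10)
        K = assemble_stiffness(cg) * CONV
        M = np.repeat(cg.masses, 3)
        R = get_group("c4").rotations[1]
        from scipy.spatial import cKDTree
        tree = cKDTree(cg.positions)
        _, idx = tree.query(cg.positions @ R.T, k=1)
        for k in range(6, 10):
            v = ms.vectors[:, k].reshape(-1, 3)
            v_rot = np.zeros_like(v)
            v_rot[idx] = v @ R.T
            v_rot = v_rot.ravel()
            lam = (v_rot @ (K @ v_rot)) / (v_rot @ (M * v_rot))
            assert lam == pytest.approx(ms.eigenvalues[k], rel=1e-6)
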
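"""Hand-built bead models and the finite-difference Hessian oracle."""

import numpy as np
import pandas as pd

from dnanma.model import CGModel


def bead_model(positions, masses, springs):
    n = len(positions)
    return CGModel(
        positions=np.asarray(positions, float),
        masses=np.asarray(masses, float),
        bead_roles=np.array(["P"] * n),
        nucleotide_index=np.arange(n),
        nt_roles=np.array(["arm"] * n),
        nt_tiles=np.zeros(n, int),
        nt_strands=np.array(["t00:X"] * n),
        springs=pd.DataFrame(springs),
    )


def random_bead_model(rng, n=7):
    """A generic connected 3D spring cluster for oracle tests."""
    pos = rng.standard_normal((n, 3)) * 1.5
    i, j, k, rest = [], [], [], []
    for a in range(n):
        for b in range(a + 1, n):
            i.append(a)
            j.append(b)
            k.append(float(rng.choice([7.0, 70.0, 700.0])))
            rest.append(np.linalg.norm(pos[a] - pos[b]))
    return bead_model(pos, 50 + 200 * rng.random(n),
                      {"i": i, "j": j, "k": k,
                       "bond_type": ["covalent"] * len(i),
                       "rest_length": rest})


def numerical_hessian(cg, h=1e-6):
    """Finite-difference Hessian of the pair potential at equilibrium.

    V = 1/2 sum k (|x_i - x_j| - L_ij)^2 with L the built-geometry lengths;
    independent of the analytic block assembly.
    """
    s = cg.springs
    i = s["i"].to_numpy()
    j = s["j"].to_numpy()
    k = s["k"].to_numpy()
    L = s["rest_length"].to_numpy()

    def V(flat):
        x = flat.reshape(-1, 3)
        d = np.linalg.norm(x[i] - x[j], axis=1)
        return 0.5 * np.sum(k * (d - L) ** 2)

    x0 = cg.positions.ravel().copy()
    n = len(x0)
    H = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            ea = np.zeros(n)
            eb = np.zeros(n)
            ea[a] = h
            eb[b] = h
            H[a, b] = (V(x0 + ea + eb) - V(x0 + ea - eb)
                       - V(x0 - ea + eb) + V(x0 - ea - eb)) / (4 * h * h)
            H[b, a] = H[a, b]
    return H


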
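"""Normal mode analysis of the coarse-grained spring network.

The harmonic pair potential ``V = 1/2 sum k_ij (|x_i - x_j| - L_ij)^2``
linearized about the built geometry gives the standard anisotropic-network
Hessian: each spring contributes ``k e e^T`` (``e`` the unit bond vector) to
its two diagonal 3x3 blocks and ``-k e e^T`` to the off-diagonal blocks.
With the diagonal matrix of lumped masses M, small displacements obey
``M d2(delta)/dt2 + K delta = 0``, so mode shapes and frequencies solve the
generalized symmetric eigenproblem ``K v = omega^2 M v``.

Units: K is assembled in N/m and masses are in amu; eigenvalues are converted
with 1 N/m = 602.214 amu/ps^2 so that omega emerges in rad/ps (wavenumbers in
cm^-1 are provided for reporting).  A free connected structure has exactly
six zero modes (rigid translations and rotations); more signal a
disconnected spring network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import (NEWTON_PER_M_TO_AMU_PER_PS2, SPEED_OF_LIGHT_CM_PER_PS,
                        ZERO_MODE_REL_TOL)
from .model import CGModel, DesignError

DENSE_LIMIT = 3000   # use dense diagonalization below this matrix order


@dataclass
class SystemMatrices:
    K: sp.spmatrix            # 3N x 3N stiffness, N/m
    M: np.ndarray             # (3N,) diagonal masses, amu
    n_beads: int

    def validate(self, tol: float = 1e-9) -> None:
        if np.any(self.M <= 0):
            raise DesignError("mass matrix must be strictly positive")
        asym = abs(self.K - self.K.T).max()
        if asym > tol * max(1.0, abs(self.K).max()):
            raise DesignError(f"stiffness not symmetric (residual {asym:.2e})")


@dataclass
class ModeSet:
    eigenvalues: np.ndarray        # omega^2, rad^2/ps^2, ascending
    vectors: np.ndarray            # (3N, n_modes), mass-orthonormal columns
    zero_mode_count: int
    masses: np.ndarray             # (3N,) diagonal M used (amu)
    labels: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies in rad/ps (zero for rigid modes)."""
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    @property
    def wavenumbers_cm(self) -> np.ndarray:
        return self.omega / (2 * np.pi * SPEED_OF_LIGHT_CM_PER_PS)

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]

    def nonrigid(self, count: Optional[int] = None):
        """(eigenvalues, vectors) with rigid-body modes dropped.

        Mode numbering in all reports starts at the first non-rigid mode.
        """
        s = slice(self.zero_mode_count,
                  None if count is None else self.zero_mode_count + count)
        return self.eigenvalues[s], self.vectors[:, s]


def assemble_stiffness(cg: CGModel) -> sp.csr_matrix:
    """Sparse 3N x 3N stiffness from the typed spring table (N/m)."""
    s = cg.springs
    if s is None or len(s) == 0:
        raise DesignError("coarse model has no springs")
    i = s["i"].to_numpy()
    j = s["j"].to_numpy()
    k = s["k"].to_numpy().astype(float)
    d = cg.positions[i] - cg.positions[j]
    rest = np.linalg.norm(d, axis=1)
    if np.any(rest < 1e-9):
        raise DesignError("zero-length spring")
    e = d / rest[:, None]
    blocks = k[:, None, None] * np.einsum("na,nb->nab", e, e)  # (ns,3,3)

    ns = len(s)
    ax = np.arange(3)
    ra, ca = np.meshgrid(ax, ax, indexing="ij")
    rows = np.empty((ns, 4, 3, 3), dtype=np.int64)
    cols = np.empty_like(rows)
    vals = np.empty((ns, 4, 3, 3))
    for b, (bi, bj, sign) in enumerate(((i, i, 1.0), (j, j, 1.0),
                                        (i, j, -1.0), (j, i, -1.0))):
        rows[:, b] = 3 * bi[:, None, None] + ra[None]
        cols[:, b] = 3 * bj[:, None, None] + ca[None]
        vals[:, b] = sign * blocks
    K = sp.coo_matrix((vals.ravel(), (rows.ravel(), cols.ravel())),
                      shape=(3 * cg.n_beads, 3 * cg.n_beads)).tocsr()
    return K


def assemble_mass(cg: CGModel) -> np.ndarray:
    """Diagonal of the global mass matrix: each lumped mass repeated x/y/z."""
    if np.any(cg.masses <= 0):
        raise DesignError("non-positive lumped mass")
    return np.repeat(cg.masses, 3)


def system_matrices(cg: CGModel) -> SystemMatrices:
    sys = SystemMatrices(K=assemble_stiffness(cg), M=assemble_mass(cg),
                         n_beads=cg.n_beads)
    sys.validate()
    return sys


def solve_modes(sys: SystemMatrices, n_modes: int = 20,
                zero_tol: float = ZERO_MODE_REL_TOL,
                seed: int = 0) -> ModeSet:
    """The ``n_modes`` lowest solutions of K v = omega^2 M v.

    Mass-orthonormal eigenvectors (v^T M v = I) with a deterministic sign
    convention; rigid-body (zero) modes are counted against a threshold
    relative to the spectral scale.  Dense diagonalization below order
    ``DENSE_LIMIT``, ARPACK shift-invert above.
    """
    n = 3 * sys.n_beads
    if not 1 <= n_modes <= n:
        raise ValueError(f"n_modes must be in [1, {n}]")
    conv = NEWTON_PER_M_TO_AMU_PER_PS2
    d = 1.0 / np.sqrt(sys.M)
    B = sp.diags(d) @ (sys.K * conv) @ sp.diags(d)   # amu-normalized, rad^2/ps^2
    B = ((B + B.T) * 0.5).tocsc()
    scale = float(abs(B).sum(axis=1).max())          # Gershgorin bound

    if n <= DENSE_LIMIT:
        w, u = scipy.linalg.eigh(B.toarray(),
                                 subset_by_index=[0, n_modes - 1])
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n)
        sigma = -1e-8 * scale
        try:
            lu = spla.splu((B - sigma * sp.identity(n, format="csc")).tocsc())
            op = spla.LinearOperator((n, n), matvec=lu.solve, dtype=float)
            # symmetric assemblies have clustered/degenerate eigenvalues:
            # a generous Krylov subspace keeps ARPACK convergence fast
            ncv = int(min(n, max(4 * n_modes, 60)))
            nu, u = spla.eigsh(op, k=n_modes, which="LM", v0=v0, ncv=ncv,
                               tol=1e-10, maxiter=5000)
            w = sigma + 1.0 / nu
        except Exception as err:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"sparse eigensolver failed (order {n}, shift {sigma:.3e}, "
                f"spectral scale {scale:.3e}): {err}") from err
        order = np.argsort(w, kind="stable")
        w, u = w[order], u[:, order]

    # mass-orthonormal modes: v = M^{-1/2} u
    v = d[:, None] * u
    v = _fix_signs(v)
    zero_count = int(np.sum(np.abs(w) < zero_tol * scale))
    if zero_count > 6:
        warnings.warn(f"{zero_count} zero modes found — the spring network "
                      "is probably disconnected", stacklevel=2)
    w = np.where(np.abs(w) < zero_tol * scale, 0.0, w)
    return ModeSet(eigenvalues=w, vectors=v, zero_mode_count=zero_count,
                   masses=sys.M,
                   meta={"solver": "dense" if n <= DENSE_LIMIT else "arpack",
                         "spectral_scale": scale, "zero_tol": zero_tol})


def _fix_signs(v: np.ndarray) -> np.ndarray:
    out = v.copy()
    for m in range(out.shape[1]):
        col = out[:, m]
        idx = np.nonzero(np.abs(col) > 1e-6 * np.abs(col).max())[0]
        if len(idx) and col[idx[0]] < 0:
            out[:, m] = -col
    return out


def analyze(cg: CGModel, n_modes: int = 20, **kw) -> ModeSet:
    """CGModel -> ModeSet in one step."""
    return solve_modes(system_matrices(cg), n_modes=n_modes, **kw)


def rigid_body_basis(cg: CGModel) -> np.ndarray:
    """Mass-orthonormalized rigid translations/rotations (3N, 6)."""
    pos = cg.positions
    m3 = np.repeat(cg.masses, 3)
    com = (cg.masses[:, None] * pos).sum(axis=0) / cg.masses.sum()
    x = pos - com
    basis = []
    for a in range(3):
        t = np.zeros((len(pos), 3))
        t[:, a] = 1.0
        basis.append(t.ravel())
    for a in range(3):
        axis = np.zeros(3)
        axis[a] = 1.0
        basis.append(np.cross(axis, x).ravel())
    b = np.array(basis).T
    # Gram-Schmidt in the M inner product
    q = []
    for col in b.T:
        for prev in q:
            col = col - (prev * m3) @ col * prev
        nrm = np.sqrt((col * m3) @ col)
        if nrm > 1e-12:
            q.append(col / nrm)
    return np.array(q).T
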
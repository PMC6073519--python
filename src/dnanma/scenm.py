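"""Symmetry-constrained elastic network model (SCENM).

For an assembly of q identical subunits placed by a rotation group, the
displacement field can be partitioned as delta = [D_1, ..., D_q] with
``D_i = R_i D_1`` (each subunit repeating subunit 1's motion in its own
frame).  Writing the block row of the full stiffness that acts on subunit 1
as K_11, K_12, ..., K_1q, the constrained problem reduces to

    K_reduced = K_11 + K_12 R_2 + ... + K_1q R_q,
    M_reduced d2(D_1)/dt2 + K_reduced D_1 = 0,

with M_reduced the subunit-1 mass block — a matrix of order 3m = 3N/q, so
the eigenproblem cost drops by the subunit count.  Reduced modes are
expanded back to the whole assembly by D_i = R_i D_1 and mass-normalized on
the full system.  The reduction captures the totally symmetric modes: every
reduced eigenvalue is an eigenvalue of the full network (oracle-checked on
toy assemblies), but non-symmetric representations (e.g. degenerate ring
pairs) live outside this subspace.

``K_reduced`` as constructed is only symmetric when the spring network is
exactly group-consistent; the solver symmetrizes it and reports the
asymmetry residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .constants import NEWTON_PER_M_TO_AMU_PER_PS2
from .model import CGModel, DesignError, SymmetryGroup
from .nma import ModeSet, _fix_signs


class PartitionError(ValueError):
    pass


@dataclass
class SubunitPartition:
    q: int
    m: int                       # beads per subunit
    group: SymmetryGroup

    @property
    def n_beads(self) -> int:
        return self.q * self.m


@dataclass
class ReducedSystem:
    K_reduced: np.ndarray        # 3m x 3m, symmetrized, N/m
    M_reduced: np.ndarray        # (3m,) diagonal, amu
    rotations: np.ndarray        # (q, 3, 3)
    partition: SubunitPartition
    asymmetry_residual: float
    coupling: dict = field(default_factory=dict)   # subunit -> 3m x 3m block


def partition_by_symmetry(cg: CGModel, group: SymmetryGroup,
                          tol: float = 1e-6) -> SubunitPartition:
    """Partition beads by tile copy and verify the group placement.

    Beads are ordered tile-by-tile with identical local ordering, so bead j
    of subunit i must sit at ``R_i x_{0,j}``.
    """
    q = group.order
    tiles = cg.nt_tiles
    n = cg.n_beads
    if n % q:
        raise PartitionError(f"{n} beads do not divide into {q} subunits")
    m = n // q
    expected = np.repeat(np.arange(q), m)
    if not np.array_equal(tiles, expected):
        raise PartitionError("bead ordering is not tile-contiguous")
    x0 = cg.positions[:m]
    for i in range(q):
        xi = cg.positions[i * m:(i + 1) * m]
        err = np.linalg.norm(xi - x0 @ group.rotations[i].T, axis=1)
        if err.max() > tol:
            j = int(np.argmax(err))
            raise PartitionError(
                f"bead {j} of subunit {i} deviates {err.max():.2e} nm from "
                "the rotated subunit-1 position")
        mi = cg.masses[i * m:(i + 1) * m]
        if np.abs(mi - cg.masses[:m]).max() > 1e-9:
            raise PartitionError(f"subunit {i} mass pattern differs")
    return SubunitPartition(q=q, m=m, group=group)


def extract_coupling_blocks(K: sp.spmatrix, partition: SubunitPartition) -> dict:
    """{i: K_{1,i}} 3m x 3m blocks from a full stiffness matrix."""
    m3 = 3 * partition.m
    K = K.tocsr()
    row = K[:m3]
    blocks = {}
    for i in range(partition.q):
        blk = row[:, i * m3:(i + 1) * m3]
        if blk.nnz:
            blocks[i] = blk
    return blocks


def coupling_blocks_from_springs(cg: CGModel,
                                 partition: SubunitPartition) -> dict:
    """{i: K_{1,i}} assembled directly from subunit-1 and interface springs.

    Never materializes the full stiffness — this is the path that makes the
    large cage assemblies tractable.
    """
    m = partition.m
    s = cg.springs
    ii = s["i"].to_numpy()
    jj = s["j"].to_numpy()
    kk = s["k"].to_numpy().astype(float)
    touch = (ii < m) | (jj < m)
    ii, jj, kk = ii[touch], jj[touch], kk[touch]
    d = cg.positions[ii] - cg.positions[jj]
    rest = np.linalg.norm(d, axis=1)
    e = d / rest[:, None]
    blk = kk[:, None, None] * np.einsum("na,nb->nab", e, e)

    entries = {}          # subunit -> (rows, cols, vals)

    def add(sub, r_loc, c_loc, vals):
        rows, cols, vv = entries.setdefault(sub, ([], [], []))
        ax = np.arange(3)
        ra, ca = np.meshgrid(ax, ax, indexing="ij")
        rows.append((3 * r_loc[:, None, None] + ra[None]).ravel())
        cols.append((3 * c_loc[:, None, None] + ca[None]).ravel())
        vv.append(vals.reshape(len(r_loc), 9).ravel())

    for a, b in ((ii, jj), (jj, ii)):
        in0 = a < m
        if not in0.any():
            continue
        a0, b0 = a[in0], b[in0]
        v0 = blk[in0]
        add(0, a0, a0, v0)                       # diagonal block of row 1
        subs = b0 // m
        for sub in np.unique(subs):
            sel = subs == sub
            add(int(sub), a0[sel], (b0 % m)[sel], -v0[sel])

    m3 = 3 * m
    blocks = {}
    for sub, (rows, cols, vv) in entries.items():
        blocks[sub] = sp.coo_matrix(
            (np.concatenate(vv),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(m3, m3)).tocsr()
    return blocks


def reduce(blocks: dict, partition: SubunitPartition,
           masses: np.ndarray) -> ReducedSystem:
    """Form K_reduced = sum_i K_{1,i} R_i and the subunit mass block."""
    m = partition.m
    m3 = 3 * m
    if any(b.shape != (m3, m3) for b in blocks.values()):
        raise PartitionError("coupling block dimension mismatch")
    K_red = np.zeros((m3, m3))
    for i, blk in blocks.items():
        Rop = sp.kron(sp.identity(m, format="csr"),
                      sp.csr_matrix(partition.group.rotations[i]))
        K_red += (blk @ Rop).toarray()
    asym = float(np.abs(K_red - K_red.T).max())
    scale = max(1.0, float(np.abs(K_red).max()))
    K_sym = 0.5 * (K_red + K_red.T)
    return ReducedSystem(
        K_reduced=K_sym,
        M_reduced=np.repeat(masses[:m], 3),
        rotations=partition.group.rotations,
        partition=partition,
        asymmetry_residual=asym / scale,
        coupling=blocks,
    )


def reduce_model(cg: CGModel, group: SymmetryGroup) -> ReducedSystem:
    partition = partition_by_symmetry(cg, group)
    blocks = coupling_blocks_from_springs(cg, partition)
    return reduce(blocks, partition, cg.masses)


def solve_scenm(red: ReducedSystem, n_modes: int = 20,
                zero_tol: float = 1e-8) -> ModeSet:
    """Solve the reduced eigenproblem and expand modes to the full assembly.

    Expanded vectors are mass-orthonormal on the full system; each reduced
    eigenvalue's residual against the full operator (evaluated block-wise
    through K_reduced) is recorded in ``meta['max_residual']``.
    """
    part = red.partition
    q, m = part.q, part.m
    m3 = 3 * m
    n_modes = min(n_modes, m3)
    conv = NEWTON_PER_M_TO_AMU_PER_PS2
    d = 1.0 / np.sqrt(red.M_reduced)
    B = (d[:, None] * (red.K_reduced * conv) * d[None, :])
    B = 0.5 * (B + B.T)
    w, u = scipy.linalg.eigh(B, subset_by_index=[0, n_modes - 1])
    delta1 = d[:, None] * u                       # reduced modes, M1-normalized

    # residual of the full eigen-equation on block row 1 (others are rotations)
    KD = red.K_reduced @ delta1 * conv
    MD = red.M_reduced[:, None] * delta1
    denom = np.linalg.norm(MD, axis=0) * np.maximum(np.abs(w), 1e-30)
    resid = np.linalg.norm(KD - MD * w[None, :], axis=0) / denom
    scale = float(np.abs(w).max()) if len(w) else 1.0

    # expansion: block i = R_i block-diagonal applied to delta_1
    vectors = np.empty((q * m3, n_modes))
    for i in range(q):
        R = red.rotations[i]
        blk = (delta1.reshape(m, 3, n_modes).transpose(2, 0, 1) @ R.T)
        vectors[i * m3:(i + 1) * m3] = blk.transpose(1, 2, 0).reshape(m3, n_modes)
    vectors /= np.sqrt(q)                          # full-system mass norm

    vectors = _fix_signs(vectors)
    zero_count = int(np.sum(np.abs(w) < zero_tol * max(scale, 1e-30)))
    w = np.where(np.abs(w) < zero_tol * scale, 0.0, w)
    masses_full = np.tile(red.M_reduced, q)
    return ModeSet(
        eigenvalues=w, vectors=vectors, zero_mode_count=zero_count,
        masses=masses_full,
        meta={
            "solver": "scenm", "q": q, "m": m,
            "asymmetry_residual": red.asymmetry_residual,
            "max_residual": float(resid[np.abs(w) > 0].max())
            if np.any(np.abs(w) > 0) else 0.0,
            "reduction_factor": q,
        })


def analyze_symmetric(cg: CGModel, group: SymmetryGroup,
                      n_modes: int = 20) -> ModeSet:
    """CGModel + group -> symmetric-subspace ModeSet in one step."""
    if group.order == 1:
        from .nma import analyze
        return analyze(cg, n_modes=n_modes)
    return solve_scenm(reduce_model(cg, group), n_modes=n_modes)
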
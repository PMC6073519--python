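"""Deterministic desk-scale fixtures with known expected properties.

These are the structures the oracle tests run on: a two-bead dimer with a
closed-form eigenvalue, a linear bead chain, C3/C4/C6 toy rings small enough
for dense full diagonalization, and a tetrahedral 12-tile "mini ball" whose
tile graph satisfies Euler's formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .builder import build_assembly
from .coarse_grain import coarse_grain
from .constants import NEWTON_PER_M_TO_AMU_PER_PS2
from .designs import star_design, toy_ring_design
from .model import CGModel, FineModel

MAX_FIXTURE_BEADS = 1500   # dense-oracle budget


@dataclass
class Fixture:
    name: str
    cg: CGModel
    fine: Optional[FineModel] = None
    expected: dict = field(default_factory=dict)


def _bead_model(positions, masses, springs, name) -> CGModel:
    n = len(positions)
    return CGModel(
        positions=np.asarray(positions, float),
        masses=np.asarray(masses, float),
        bead_roles=np.array(["P"] * n),
        nucleotide_index=np.arange(n),
        nt_roles=np.array(["arm"] * n),
        nt_tiles=np.zeros(n, dtype=int),
        nt_strands=np.array(["t00:X"] * n),
        springs=pd.DataFrame(springs),
        meta={"design": name},
    )


def generate_fixture(kind: str, size: int = 5) -> Fixture:
    """Build a named fixture; ``size`` applies to the chain only."""
    kind = kind.lower()
    if kind == "dimer":
        k, m, L = 700.0, 100.0, 1.0
        cg = _bead_model([[0, 0, 0], [L, 0, 0]], [m, m],
                         {"i": [0], "j": [1], "k": [k],
                          "bond_type": ["covalent"], "rest_length": [L]},
                         "dimer")
        lam = 2 * k * NEWTON_PER_M_TO_AMU_PER_PS2 / m
        return Fixture("dimer", cg, expected={
            "zero_modes": 5, "nonzero_eigenvalues": [lam], "group_order": 1})
    if kind == "chain":
        n = max(2, size)
        if n > MAX_FIXTURE_BEADS:
            raise ValueError(f"chain of {n} beads exceeds the dense-oracle "
                             f"budget ({MAX_FIXTURE_BEADS}); use a smaller size")
        pos = np.zeros((n, 3))
        pos[:, 0] = 0.5 * np.arange(n)
        springs = {"i": list(range(n - 1)), "j": list(range(1, n)),
                   "k": [700.0] * (n - 1), "bond_type": ["covalent"] * (n - 1),
                   "rest_length": [0.5] * (n - 1)}
        cg = _bead_model(pos, np.full(n, 100.0), springs, "chain")
        # an axial-spring chain is free transversally: 2n + 1 zero modes
        return Fixture("chain", cg, expected={
            "zero_modes": 2 * n + 1, "group_order": 1})
    if kind in ("toy_ring_c3", "toy_ring_c4", "toy_ring_c6"):
        q = int(kind[-1])
        design = toy_ring_design(q)
        fine = build_assembly(design)
        cg = coarse_grain(fine)
        if cg.n_beads > MAX_FIXTURE_BEADS:
            raise ValueError("toy ring too large for the dense oracle")
        return Fixture(kind, cg, fine=fine, expected={
            "zero_modes": 6, "group_order": q, "group": f"c{q}",
            "interfaces": q})
    if kind == "mini_ball":
        design = star_design("mini_ball")
        fine = build_assembly(design)
        cg = coarse_grain(fine)
        return Fixture("mini_ball", cg, fine=fine, expected={
            "zero_modes": 6, "group_order": 12, "group": "tetrahedral",
            "vertices": 12, "edges": 18, "faces": 8,
            "faces_by_size": {3: 4, 6: 4}})
    raise ValueError(f"unknown fixture kind {kind!r}")
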
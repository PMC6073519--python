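"""In-memory containers for fine and coarse-grained structure models.

A :class:`FineModel` is the pre-coarse-graining structure: every heavy atom
of every nucleotide (hydrogens folded into heavy-atom masses), with
per-nucleotide annotations (base, strand, tile copy, segment role) and the
list of complementary base pairs.  A :class:`CGModel` is the particle system
normal-mode analysis runs on: representative beads with lumped masses plus a
typed spring network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd


ROLES = (
    "inner_circle", "outer_circle", "bridge", "arm", "loop",
    "sticky_end", "single_stranded",
)

BOND_TYPES = ("van_der_waals", "hydrogen", "ion", "disulfide", "covalent")


class DesignError(ValueError):
    """A structure design or its geometric realization is inconsistent."""


class AssemblyError(ValueError):
    """Sticky ends that should hybridize could not be paired."""


@dataclass
class Nucleotide:
    base: str
    strand: str          # globally unique strand id, e.g. "t03:O1"
    strand_order: int    # 0-based position along the strand, 5'->3'
    tile: int            # tile copy index (0-based)
    role: str
    has_phosphate: bool
    axis_point: np.ndarray          # duplex-axis point of this slot (nm)
    sticky_label: Optional[str] = None   # e.g. "a" / "a'" for overhangs


@dataclass
class FineModel:
    """Per-atom coordinates and annotations for a built structure."""

    positions: np.ndarray            # (n_atoms, 3) nm
    atom_names: np.ndarray           # (n_atoms,) str
    elements: np.ndarray             # (n_atoms,) str
    masses: np.ndarray               # (n_atoms,) amu, hydrogens folded in
    nucleotide_index: np.ndarray     # (n_atoms,) int
    nucleotides: list = field(default_factory=list)   # list[Nucleotide]
    pairing: list = field(default_factory=list)       # [(nt_i, nt_j), ...]
    linkages: list = field(default_factory=list)      # designed covalent joins
    meta: dict = field(default_factory=dict)

    # ---- convenience views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_nucleotides(self) -> int:
        return len(self.nucleotides)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def nt_attr(self, name: str) -> np.ndarray:
        return np.array([getattr(nt, name) for nt in self.nucleotides])

    def atom_roles(self) -> np.ndarray:
        roles = self.nt_attr("role")
        return roles[self.nucleotide_index]

    def atom_tiles(self) -> np.ndarray:
        tiles = self.nt_attr("tile")
        return tiles[self.nucleotide_index]

    def atom_lookup(self) -> dict:
        """(nucleotide index, atom name) -> atom index, built lazily."""
        cached = self.meta.get("_atom_lookup")
        if cached is None or len(cached) != self.n_atoms:
            cached = {(int(n), str(a)): i for i, (n, a) in
                      enumerate(zip(self.nucleotide_index, self.atom_names))}
            self.meta["_atom_lookup"] = cached
        return cached

    def atom_index(self, nt: int, atom_name: str) -> int:
        try:
            return self.atom_lookup()[(int(nt), atom_name)]
        except KeyError:
            raise KeyError(f"atom {atom_name!r} of nucleotide {nt}") from None

    def validate_invariants(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise DesignError("non-finite atom positions")
        if self.nucleotide_index.min() < 0 or \
           self.nucleotide_index.max() >= self.n_nucleotides:
            raise DesignError("atom -> nucleotide mapping out of range")
        paired = {i for p in self.pairing for i in p}
        if paired and max(paired) >= self.n_nucleotides:
            raise DesignError("pairing references unknown nucleotide")

    def to_frame(self) -> pd.DataFrame:
        """Atom table (one row per atom) for inspection/export."""
        roles = self.atom_roles()
        tiles = self.atom_tiles()
        bases = self.nt_attr("base")[self.nucleotide_index]
        strands = self.nt_attr("strand")[self.nucleotide_index]
        return pd.DataFrame({
            "name": self.atom_names,
            "element": self.elements,
            "mass": self.masses,
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "z": self.positions[:, 2],
            "nucleotide": self.nucleotide_index,
            "base": bases,
            "strand": strands,
            "tile": tiles,
            "role": roles,
        })


def concat_models(models: list, tile_indices: Optional[list] = None) -> FineModel:
    """Concatenate fine models, re-indexing nucleotides and pairings."""
    positions, names, elements, masses, nt_index = [], [], [], [], []
    nucleotides, pairing, linkages = [], [], []
    offset = 0
    for k, m in enumerate(models):
        positions.append(m.positions)
        names.append(m.atom_names)
        elements.append(m.elements)
        masses.append(m.masses)
        nt_index.append(m.nucleotide_index + offset)
        for nt in m.nucleotides:
            nt2 = replace(nt, axis_point=nt.axis_point.copy())
            if tile_indices is not None:
                nt2.tile = tile_indices[k]
                nt2.strand = f"t{tile_indices[k]:02d}:{nt.strand.split(':')[-1]}"
            nucleotides.append(nt2)
        pairing.extend([(i + offset, j + offset) for i, j in m.pairing])
        linkages.extend([(i + offset, j + offset) for i, j in m.linkages])
        offset += m.n_nucleotides
    return FineModel(
        positions=np.vstack(positions),
        atom_names=np.concatenate(names),
        elements=np.concatenate(elements),
        masses=np.concatenate(masses),
        nucleotide_index=np.concatenate(nt_index),
        nucleotides=nucleotides,
        pairing=pairing,
        linkages=linkages,
        meta=dict(models[0].meta),
    )


@dataclass
class CGModel:
    """Representative beads with lumped masses plus the typed spring network."""

    positions: np.ndarray        # (n_beads, 3) nm
    masses: np.ndarray           # (n_beads,) amu, lumped
    bead_roles: np.ndarray       # (n_beads,) str: P / C4 / C1 / base site name
    nucleotide_index: np.ndarray
    nt_roles: np.ndarray         # segment role per bead
    nt_tiles: np.ndarray         # tile copy index per bead
    nt_strands: np.ndarray
    springs: Optional[pd.DataFrame] = None
    # springs columns: i, j, k (N/m), bond_type, rest_length (nm)
    meta: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def validate_invariants(self) -> None:
        if np.any(self.masses <= 0):
            raise DesignError("non-positive lumped mass")
        if self.springs is not None:
            s = self.springs
            if np.any(s["i"].to_numpy() == s["j"].to_numpy()):
                raise DesignError("self-spring")
            if not set(s["bond_type"]).issubset(BOND_TYPES):
                raise DesignError("unknown bond type")


@dataclass
class SymmetryGroup:
    """A finite rotation group given as explicit orthogonal matrices."""

    name: str
    rotations: np.ndarray        # (q, 3, 3), identity first

    @property
    def order(self) -> int:
        return len(self.rotations)

    def validate(self, tol: float = 1e-8) -> None:
        rots = self.rotations
        if not np.allclose(rots[0], np.eye(3), atol=tol):
            raise ValueError("first group element must be the identity")
        for r in rots:
            if not np.allclose(r @ r.T, np.eye(3), atol=tol):
                raise ValueError("non-orthogonal rotation in group")
            if np.linalg.det(r) < 0:
                raise ValueError("improper rotation in group")
        # closure
        flat = rots.reshape(len(rots), 9)
        for a in rots:
            prods = np.einsum("ij,njk->nik", a, rots).reshape(len(rots), 9)
            d = np.linalg.norm(prods[:, None, :] - flat[None, :, :], axis=2)
            if np.any(d.min(axis=1) > 100 * tol):
                raise ValueError("group not closed under multiplication")
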
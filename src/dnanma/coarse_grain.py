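"""Mass-weighted chemical elastic network construction (MWCENM).

Each nucleotide is reduced to six or seven representative atoms: P, C4' and
C1' for the sugar-phosphate backbone plus three (pyrimidine) or four (purine)
base atoms on the glycosidic/Watson-Crick edge.  Every remaining atom's mass
is lumped onto the nearest representative within its own nucleotide, so mass
is conserved exactly.  Springs are typed by chemical bond: covalent bonds
along DNA linkages (700 N/m), hydrogen bonds between complementary bases
(70 N/m), and van der Waals contacts within an 0.8 nm cutoff (7 N/m) — the
1:10:100 ratio.  Where one pair qualifies for several types the strongest
bond wins, so no pair is double-counted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import chem
from .constants import SPRING_CONSTANTS, VDW_CUTOFF
from .model import CGModel, DesignError, FineModel


def select_representatives(model: FineModel) -> np.ndarray:
    """Indices of representative atoms, ordered nucleotide by nucleotide.

    5'-terminal nucleotides built without a phosphate contribute no P bead.
    """
    idx = []
    for nt_i, nt in enumerate(model.nucleotides):
        if nt.base not in chem.BASE_TEMPLATES:
            raise DesignError(f"unknown base {nt.base!r}")
        names = chem.representative_atoms(nt.base, nt.has_phosphate)
        for name in names:
            idx.append(model.atom_index(nt_i, name))
    return np.array(idx, dtype=int)


def _lumping_map(base: str, with_phosphate: bool) -> dict:
    """atom name -> representative atom name, nearest in template geometry.

    Computed in the nucleotide's local template frame so the assignment is
    identical for every copy of a nucleotide regardless of its placement
    (distance ties are broken by representative order).
    """
    tmpl = chem.nucleotide_template(base, with_phosphate)
    reps = chem.representative_atoms(base, with_phosphate)
    rp = {n: np.array([x, y, z]) for n, x, y, z, _, _ in tmpl if n in reps}
    out = {}
    for name, x, y, z, _el, _m in tmpl:
        if name in rp:
            out[name] = name
            continue
        p = np.array([x, y, z])
        best = min(reps, key=lambda r: round(float(np.linalg.norm(rp[r] - p)), 9))
        out[name] = best
    return out


def assign_lumped_masses(rep_idx: np.ndarray, model: FineModel) -> np.ndarray:
    """Lump each non-representative atom onto its nearest same-nucleotide bead."""
    masses = model.masses[rep_idx].astype(float).copy()
    bead_lookup = {}
    for b, a in enumerate(rep_idx):
        bead_lookup[(int(model.nucleotide_index[a]),
                     str(model.atom_names[a]))] = b
    maps = {}
    for a in range(model.n_atoms):
        nt = int(model.nucleotide_index[a])
        name = str(model.atom_names[a])
        if (nt, name) in bead_lookup:
            continue
        ntr = model.nucleotides[nt]
        key = (ntr.base, ntr.has_phosphate)
        if key not in maps:
            maps[key] = _lumping_map(*key)
        rep_name = maps[key][name]
        bead = bead_lookup.get((nt, rep_name))
        if bead is None:
            raise DesignError(f"nucleotide {nt} has no representative atoms")
        masses[bead] += model.masses[a]
    return masses


def build_spring_network(model: FineModel, cutoff: float = VDW_CUTOFF,
                         rep_idx: np.ndarray = None,
                         masses: np.ndarray = None) -> CGModel:
    """The full MWCENM coarse-grained model with its typed spring network."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if rep_idx is None:
        rep_idx = select_representatives(model)
    if masses is None:
        masses = assign_lumped_masses(rep_idx, model)

    pos = model.positions[rep_idx]
    names = model.atom_names[rep_idx]
    nt_idx = model.nucleotide_index[rep_idx]
    bead_roles = np.array([chem.BEAD_ROLE_OF_ATOM.get(n, n) for n in names])

    bead_of = {}
    for b in range(len(rep_idx)):
        bead_of[(int(nt_idx[b]), str(names[b]))] = b

    springs = {}

    def add(i, j, bond_type):
        if i == j:
            return
        key = (min(i, j), max(i, j))
        if key in springs:
            return  # first insertion wins; insertion order = strength order
        springs[key] = bond_type

    # --- covalent: backbone chain, base attachment, rigid base, linkages ----
    chain_next = _chain_successors(model)
    for nt_i, nt in enumerate(model.nucleotides):
        glyc = chem.glycosidic_atom(nt.base)
        if nt.has_phosphate:
            add(bead_of[(nt_i, "P")], bead_of[(nt_i, "C4'")], "covalent")
        add(bead_of[(nt_i, "C4'")], bead_of[(nt_i, "C1'")], "covalent")
        add(bead_of[(nt_i, "C1'")], bead_of[(nt_i, glyc)], "covalent")
        base_beads = [bead_of[(nt_i, n)]
                      for n in chem.REPRESENTATIVE_ATOMS[nt.base]]
        for a in range(len(base_beads)):
            for b in range(a + 1, len(base_beads)):
                add(base_beads[a], base_beads[b], "covalent")
    for i, j in chain_next:
        nxt = model.nucleotides[j]
        if nxt.has_phosphate:
            add(bead_of[(i, "C4'")], bead_of[(j, "P")], "covalent")
        else:
            add(bead_of[(i, "C4'")], bead_of[(j, "C4'")], "covalent")
    link_rule = model.meta.get("linkage_bead_rule", "nearest")
    for a, b in model.linkages:
        add(*_linkage_bead_pair(a, b, pos, nt_idx, link_rule), "covalent")

    # --- hydrogen: Watson-Crick paired bases (incl. hybridized sticky ends) -
    for a, b in model.pairing:
        na, nb = model.nucleotides[a], model.nucleotides[b]
        for sa, sb in chem.wc_site_pairs(na.base, nb.base):
            add(bead_of[(a, sa)], bead_of[(b, sb)], "hydrogen")

    # --- van der Waals: every remaining pair within the cutoff --------------
    tree = cKDTree(pos)
    for i, j in tree.query_pairs(r=cutoff):
        add(int(i), int(j), "van_der_waals")

    ii = np.array([k[0] for k in springs], dtype=int)
    jj = np.array([k[1] for k in springs], dtype=int)
    types = np.array(list(springs.values()))
    rest = np.linalg.norm(pos[ii] - pos[jj], axis=1)
    if np.any(rest < 1e-9):
        raise DesignError("zero-length spring (coincident beads)")
    table = pd.DataFrame({
        "i": ii, "j": jj,
        "k": np.array([SPRING_CONSTANTS[t] for t in types]),
        "bond_type": types,
        "rest_length": rest,
    }).sort_values(["i", "j"], ignore_index=True)

    nts = model.nucleotides
    cg = CGModel(
        positions=pos.copy(),
        masses=masses,
        bead_roles=bead_roles,
        nucleotide_index=nt_idx.copy(),
        nt_roles=np.array([nts[i].role for i in nt_idx]),
        nt_tiles=np.array([nts[i].tile for i in nt_idx]),
        nt_strands=np.array([nts[i].strand for i in nt_idx]),
        springs=table,
        meta=dict(model.meta, cutoff=cutoff, fine_atoms=model.n_atoms),
    )
    cg.validate_invariants()
    return cg


def coarse_grain(model: FineModel, cutoff: float = VDW_CUTOFF) -> CGModel:
    """FineModel -> CGModel in one step (the standard pipeline entry)."""
    return build_spring_network(model, cutoff=cutoff)


def _chain_successors(model: FineModel):
    """(i, j) nucleotide pairs with j the immediate 3'-neighbor of i."""
    by_strand = {}
    for i, nt in enumerate(model.nucleotides):
        by_strand.setdefault(nt.strand, []).append((nt.strand_order, i))
    out = []
    for entries in by_strand.values():
        entries.sort()
        for (o1, i), (o2, j) in zip(entries, entries[1:]):
            if o2 - o1 == 1:
                out.append((i, j))
    return out


def _linkage_bead_pair(nt_a: int, nt_b: int, pos, nt_idx, rule: str = "nearest"):
    """Bead pair realizing a designed nucleotide-level linkage.

    ``nearest``: closest bead pair.  ``planar``: the pair whose beads lie
    nearest the assembly (xy) plane — junction springs then act in the plane,
    leaving out-of-plane rocking of the joined segment second-order soft.
    """
    beads_a = np.nonzero(nt_idx == nt_a)[0]
    beads_b = np.nonzero(nt_idx == nt_b)[0]
    d = np.linalg.norm(pos[beads_a][:, None, :] - pos[beads_b][None, :, :],
                       axis=2)
    if rule == "planar":
        za = np.abs(pos[beads_a][:, None, 2])
        zb = np.abs(pos[beads_b][None, :, 2])
        score = za + zb + 0.1 * d
    else:
        score = d
    a, b = np.unravel_index(np.argmin(score), score.shape)
    return int(beads_a[a]), int(beads_b[b])


def connected_components(cg: CGModel) -> int:
    """Number of connected components of the spring graph."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components as cc
    s = cg.springs
    n = cg.n_beads
    a = coo_matrix((np.ones(len(s)), (s["i"], s["j"])), shape=(n, n))
    ncomp, _ = cc(a + a.T, directed=False)
    return int(ncomp)
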
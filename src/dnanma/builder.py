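"""Tile construction, symmetric assembly, and structure validation.

Unit tiles are laid out on the xy-plane (rings: concentric arcs joined by
radial bridges; three-point-star: three duplex arms with central
single-stranded loops).  Whole assemblies are produced by applying every
element of a finite rotation group to tile 1 — 12 rotations of 30 deg for the
rings, the 60 icosahedral rotations for the buckyball — and hybridizing the
complementary sticky-end overhangs that meet across tile interfaces.
Validation mirrors the construction checks of the underlying study: H-bond
site distances for every base pair, sticky-end pairing counts per interface,
and a steric-clash scan.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .constants import (CLASH_THRESHOLD, JUNCTION_TOLERANCE, RISE_PER_BP,
                        TWIST_PER_BP)
from .designs import TileDesign, StrandSequence
from .helix import arc_frames, build_run, straight_frames
from .model import (AssemblyError, DesignError, FineModel, SymmetryGroup,
                    concat_models)
from .symmetry import cage_vertices, get_group


# ---------------------------------------------------------------------------
# Tile builders
# ---------------------------------------------------------------------------

def build_tile(design: TileDesign) -> FineModel:
    """Build the unit tile of a design (tile copy index 0)."""
    if design.family in ("ring", "toy_ring"):
        return _build_ring_tile(design)
    if design.family == "three_point_star":
        return _build_star_tile(design)
    raise DesignError(f"unknown design family {design.family!r}")


def _arc_segment(n: int, q: int, radius: float, seq, role: str, ids,
                 labels, ov: int, s2_holes=(), tile: int = 0) -> FineModel:
    """One tile's share of a circular arc duplex.

    The reference strand covers the tile's angular window (slots ``0..n-1``);
    the complementary strand is shifted back by the sticky-end overhang ``ov``
    so that ``ov`` base pairs at every tile boundary hybridize across tiles.
    The helical twist is rounded to a whole number of turns per tile window
    (e.g. 36 deg/bp for a 10-bp window) so the helix phase, like the arc
    itself, closes seamlessly at tile boundaries.
    """
    step = 360.0 / (q * n)
    turns = max(1, round(n / 10.5))
    twist = 360.0 * turns / n
    slots = list(range(-ov, n))
    frames = arc_frames(slots, radius, step, angle_offset_deg=-n / 2 * step,
                        twist_deg=twist)
    bases = [seq[s % n] for s in slots]
    s1 = [s >= 0 for s in slots]
    s2 = [(s < n - ov) and (s not in s2_holes) for s in slots]
    s1_sticky = {slots.index(s): labels[0] for s in range(n - ov, n)}
    s2_sticky = {slots.index(s): labels[1] for s in range(-ov, 0)}
    return build_run(frames, bases, role=role, strand1_id=ids[0],
                     strand2_id=ids[1], tile=tile, s1_mask=s1, s2_mask=s2,
                     s1_sticky=s1_sticky, s2_sticky=s2_sticky)


def _build_ring_tile(design: TileDesign) -> FineModel:
    p = design.params
    q = p["n_tiles"]
    ov = p["sticky_overhang"]
    parts = [_arc_segment(p["inner_bp"], q, p["inner_radius"], p["inner_seq"],
                          "inner_circle", ("I1", "I2"), ("a", "a'"), ov)]
    if design.family == "ring":
        holes = ()
        if p.get("open_form"):
            mid = p["outer_bp"] // 2
            d = p["ss_domain_len"]
            holes = tuple(range(mid - d // 2, mid - d // 2 + d))
        parts.append(_arc_segment(p["outer_bp"], q, p["outer_radius"],
                                  p["outer_seq"], "outer_circle",
                                  ("O1", "O2"), ("b", "b'"), ov,
                                  s2_holes=holes))
        for k, off in enumerate(p["bridge_offsets_deg"]):
            parts.append(_bridge_segment(p, off, k))
    model = concat_models(parts)
    model.meta.update(design=design.name, family=design.family,
                      group=design.group_name)
    if design.family == "ring":
        _link_bridges(model)
    _fill_design_record(design, model)
    return model


def _bridge_segment(p, offset_deg: float, k: int) -> FineModel:
    theta = np.deg2rad(offset_deg)
    rhat = np.array([np.cos(theta), np.sin(theta), 0.0])
    r_lo = p["inner_radius"] + p["bridge_gap"]
    r_hi = p["outer_radius"] - p["bridge_gap"]
    nb = int((r_hi - r_lo) / RISE_PER_BP)
    if nb < 2:
        raise DesignError("bridge span too short for a duplex")
    rng = np.random.default_rng(p["seed"] + 200 + k)
    bases = [("A", "C", "G", "T")[i] for i in rng.integers(0, 4, size=nb)]
    frames = straight_frames(nb, r_lo * rhat + 0.5 * RISE_PER_BP * rhat, rhat,
                             (0.0, 0.0, 1.0))
    return build_run(frames, bases, role="bridge",
                     strand1_id=f"B{k}a", strand2_id=f"B{k}b")


def _link_bridges(model: FineModel) -> None:
    """Join bridge-duplex ends to the arcs through crossover-like junctions.

    Each bridge strand end is anchored to the arc nucleotide nearest it plus
    the arc nucleotides two positions to either side.  The anchor points
    spread along the arc tangent, so in-plane swing of the bridge stretches
    them (stiff, as strand crossovers hold helices together in the tile
    plane) while rotation about the tangent line through them is
    second-order (a soft out-of-plane hinge).  The matching bead-level rule
    (springs between beads nearest the assembly plane) is selected through
    ``meta['linkage_bead_rule']``.
    """
    model.meta["linkage_bead_rule"] = "planar"
    roles = model.nt_attr("role")
    axis = np.array([nt.axis_point for nt in model.nucleotides])
    for target_role, pick in (("inner_circle", np.argmin),
                              ("outer_circle", np.argmax)):
        arc_idx = np.nonzero(roles == target_role)[0]
        if len(arc_idx) == 0:
            continue
        bridge_idx = np.nonzero(roles == "bridge")[0]
        if len(bridge_idx) == 0:
            continue
        angles = np.arctan2(axis[arc_idx][:, 1], axis[arc_idx][:, 0])
        by_angle = arc_idx[np.argsort(angles)]
        strands = model.nt_attr("strand")
        for sid in sorted(set(strands[bridge_idx])):
            chain = [i for i in bridge_idx if strands[i] == sid]
            r = np.linalg.norm(axis[chain][:, :2], axis=1)
            end = chain[int(pick(r))]
            d = np.linalg.norm(axis[arc_idx] - axis[end], axis=1)
            if d.min() > JUNCTION_TOLERANCE:
                raise DesignError(
                    f"bridge end {sid} is {d.min():.2f} nm from the "
                    f"{target_role} arc (> {JUNCTION_TOLERANCE} nm)")
            p0 = int(np.argmin(
                np.linalg.norm(axis[by_angle] - axis[end], axis=1)))
            for off in (-2, 0, 2):
                j = int(by_angle[(p0 + off) % len(by_angle)])
                if np.linalg.norm(axis[j] - axis[end]) <= JUNCTION_TOLERANCE:
                    model.linkages.append((end, j))


def _build_star_tile(design: TileDesign, center=None, axis=None,
                     arm_dirs=None, tile: int = 0) -> FineModel:
    """A three-point-star tile: three duplex arms plus central T-loops.

    By default the tile is flat on the xy-plane with exact 120 deg arms; cage
    builders pass explicit ``arm_dirs`` pointing at the actual neighbor-edge
    midpoints (a truncated-icosahedron vertex has no exact threefold site
    symmetry, so assembly arms deviate slightly from 120 deg).
    """
    p = design.params
    c = np.zeros(3) if center is None else np.asarray(center, float)
    v = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
    if arm_dirs is None:
        arm_dirs = [np.array([np.cos(a), np.sin(a), 0.0])
                    for a in np.deg2rad([90.0, 210.0, 330.0])]
    n_paired, ov = p["arm_bp"], p["overhang"]
    r0 = p["hub_radius"]
    # overhang phase: paired slot s and partner slot s' = 2n+ov-1-s must have
    # phi(s) + phi(s') = pi so the two single strands form a duplex tip
    tw = TWIST_PER_BP
    phase0 = 0.5 * (180.0 - (2 * n_paired + ov - 1) * tw)
    parts = []
    labels = design.sticky_ends[0][2]
    for k, d in enumerate(arm_dirs):
        d = d / np.linalg.norm(d)
        # helix-phase reference: radial direction at the arm tip
        m = c + (r0 + (n_paired + ov / 2) * RISE_PER_BP) * d
        ref = m if np.linalg.norm(m) > 1e-9 else v
        perp = ref - (ref @ d) * d
        if np.linalg.norm(perp) < 1e-9:
            perp = v - (v @ d) * d
        frames = straight_frames(n_paired + ov,
                                 c + (r0 + 0.5 * RISE_PER_BP) * d, d, perp,
                                 phase0_deg=phase0)
        s2 = [s < n_paired for s in range(n_paired + ov)]
        sticky = {s: labels[0] for s in range(n_paired, n_paired + ov)}
        parts.append(build_run(frames, p["arm_seq"], role="arm",
                               strand1_id=f"A{k}a", strand2_id=f"A{k}b",
                               s1_mask=None, s2_mask=s2, s1_sticky=sticky,
                               tile=tile))
        # overhang nucleotides are the sticky ends proper
        part = parts[-1]
        for nt in part.nucleotides:
            if nt.sticky_label is not None:
                nt.role = "sticky_end"
    parts.extend(_star_loops(p, c, v, arm_dirs, tile))
    model = concat_models(parts)
    model.meta.update(design=design.name, family=design.family,
                      group=design.group_name)
    _link_star(model, n_arms=len(arm_dirs))
    _fill_design_record(design, model)
    return model


def _star_loops(p, c, v, arm_dirs, tile: int):
    """Single-stranded T-loops bridging adjacent arm roots around the hub.

    The loop circle lies in the plane of the three arm-root points (cage
    arms dip out of the tile tangent plane, and loops must stay in vdW
    contact with the arm roots they tether).
    """
    v = v / np.linalg.norm(v)
    roots = np.array([c + p["hub_radius"] * d / np.linalg.norm(d)
                      for d in arm_dirs])
    if len(roots) >= 3:
        n = np.cross(roots[1] - roots[0], roots[2] - roots[0])
        if np.linalg.norm(n) > 1e-9:
            n /= np.linalg.norm(n)
            v = n if n @ v >= 0 else -n
        c = roots.mean(axis=0)
    e1 = arm_dirs[0] - (arm_dirs[0] @ v) * v
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    az = [np.arctan2(d @ e2, d @ e1) for d in arm_dirs]
    ring_order = sorted(range(len(arm_dirs)), key=lambda k: az[k])
    parts = []
    nl, rl = p["loop_len"], p["loop_radius"]
    for k in range(len(arm_dirs)):
        a0 = az[ring_order[k]]
        a1 = az[ring_order[(k + 1) % len(arm_dirs)]]
        while a1 <= a0:
            a1 += 2 * np.pi
        # keep >= 0.40 nm between loop nucleotides in narrow angular gaps
        nk = nl
        while nk > 1 and rl * (a1 - a0) / (nk + 1) < 0.40:
            nk -= 1
        angles = a0 + (a1 - a0) * (np.arange(nk) + 1) / (nk + 1)
        frames = []
        for a in angles:
            rhat = np.cos(a) * e1 + np.sin(a) * e2
            t = -np.sin(a) * e1 + np.cos(a) * e2
            u = v
            frames.append((c + rl * rhat, u, np.cross(t, u), t))
        parts.append(build_run(frames, ["T"] * nk, role="loop",
                               strand1_id=f"L{k}", tile=tile))
    return parts


def _link_star(model: FineModel, n_arms: int) -> None:
    """Join each loop's two ends to the hub-side ends of the flanking arms."""
    roles = model.nt_attr("role")
    strands = model.nt_attr("strand")
    axis = np.array([nt.axis_point for nt in model.nucleotides])
    arm_root = np.nonzero((roles == "arm"))[0]
    orders = model.nt_attr("strand_order")
    for k in range(n_arms):
        loop = [i for i in np.nonzero(roles == "loop")[0]
                if strands[i].endswith(f":L{k}")]
        if not loop:
            continue
        for end in (loop[0], loop[-1]):
            d = np.linalg.norm(axis[arm_root] - axis[end], axis=1)
            j = int(arm_root[np.argmin(d)])
            if d.min() > JUNCTION_TOLERANCE:
                raise DesignError(f"loop L{k} end too far from any arm "
                                  f"({d.min():.2f} nm)")
            model.linkages.append((end, j))
    del orders


def _fill_design_record(design: TileDesign, model: FineModel) -> None:
    """Back-fill the declarative strand list from the realized tile."""
    strands = {}
    for nt in model.nucleotides:
        strands.setdefault(nt.strand, []).append((nt.strand_order, nt.base))
    design.strands = [
        StrandSequence(id=sid, bases=[b for _, b in sorted(entries)])
        for sid, entries in sorted(strands.items())
    ]


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def rotate_model(model: FineModel, R: np.ndarray) -> FineModel:
    out = concat_models([model])
    out.positions = model.positions @ R.T
    for nt in out.nucleotides:
        nt.axis_point = R @ nt.axis_point
    return out


def assemble(tile: FineModel, group: SymmetryGroup, sticky_map=None,
             require_closed: bool = True) -> FineModel:
    """Apply every group rotation to the unit tile and hybridize sticky ends.

    Copy ``i`` is ``rotations[i]`` applied to copy 0.  Complementary overhang
    nucleotides from different copies that land on the same base-pair slot
    (axis points within half a rise) become Watson-Crick pairs.
    """
    group.validate()
    if group.order == 1:
        return concat_models([tile], tile_indices=[0])
    copies = [rotate_model(tile, R) for R in group.rotations]
    model = concat_models(copies, tile_indices=list(range(group.order)))
    model.meta["group"] = group.name
    model.meta["q"] = group.order

    if sticky_map is None:
        sticky_map = model.meta.get("sticky_map") or _default_sticky_map(model)
    labels = model.nt_attr("sticky_label")
    tiles = model.nt_attr("tile")
    bases = model.nt_attr("base")
    axis = np.array([nt.axis_point for nt in model.nucleotides])
    paired = {i for pr in model.pairing for i in pr}

    open_idx = np.array([i for i in range(model.n_nucleotides)
                         if labels[i] is not None and i not in paired])
    if len(open_idx) == 0:
        return model
    tree = cKDTree(axis[open_idx])
    pairs = tree.query_pairs(r=0.5 * RISE_PER_BP, output_type="ndarray")
    matched = {}
    for a, b in pairs:
        i, j = int(open_idx[a]), int(open_idx[b])
        if tiles[i] == tiles[j]:
            continue
        if sticky_map.get(labels[i]) != labels[j] and \
           sticky_map.get(labels[j]) != labels[i]:
            continue
        if chem.COMPLEMENT[bases[i]] != bases[j]:
            continue
        if i in matched or j in matched:
            raise AssemblyError(f"ambiguous sticky-end pairing near tile "
                                f"{tiles[i]}/{tiles[j]}")
        matched[i] = j
        matched[j] = i
        model.pairing.append((i, j))
    if require_closed:
        unmatched = [i for i in open_idx if i not in matched]
        if unmatched:
            i = unmatched[0]
            raise AssemblyError(
                f"sticky end {labels[i]!r} on tile {tiles[i]} found no "
                f"partner within {0.5 * RISE_PER_BP:.2f} nm "
                f"({len(unmatched)} unmatched overhangs)")
    return model


def _default_sticky_map(model: FineModel) -> dict:
    labels = {nt.sticky_label for nt in model.nucleotides if nt.sticky_label}
    smap = {}
    for lab in labels:
        partner = lab[:-1] if lab.endswith("'") else lab + "'"
        smap[lab] = partner if partner in labels else lab
    return smap


def build_assembly(design: TileDesign) -> FineModel:
    """Build and assemble a complete design (ring, toy ring, or cage)."""
    group = get_group(design.group_name)
    if design.family == "three_point_star" and group.order > 1:
        tile = _cage_tile(design, group)
    else:
        tile = build_tile(design)
    model = assemble(tile, group) if group.order > 1 else tile
    model.meta.setdefault("design", design.name)
    return model


def _cage_tile(design: TileDesign, group: SymmetryGroup) -> FineModel:
    """Tile 1 of a cage assembly, arms aimed at its neighbor-edge midpoints."""
    p = design.params
    verts_unit = cage_vertices(group)
    # scale so the polyhedron edge equals the designed arm reach
    d = np.linalg.norm(verts_unit[:, None, :] - verts_unit[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    edge_unit = d.min()
    scale = p["edge_length"] / edge_unit
    verts = verts_unit * scale
    c0 = verts[0]
    nbr = np.nonzero(d[0] < edge_unit * (1 + 1e-6))[0]
    if len(nbr) != 3:
        raise DesignError("cage vertex does not have three neighbors")
    arm_dirs = [(verts[j] + c0) / 2 - c0 for j in nbr]
    arm_dirs = [a / np.linalg.norm(a) for a in arm_dirs]
    axis = c0 / np.linalg.norm(c0)
    return _build_star_tile(design, center=c0, axis=axis, arm_dirs=arm_dirs)


# ---------------------------------------------------------------------------
# Validation and measurement
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    hbond_lengths: np.ndarray            # (n_sites,) nm, all WC site pairs
    hbond_pair_index: np.ndarray         # which base pair each site belongs to
    sticky_end_hbond_counts: dict        # (tile_a, tile_b) -> paired bases
    min_interatomic_distance: float      # nm over non-bonded atom pairs
    clash_pairs: list = field(default_factory=list)

    @property
    def n_clashes(self) -> int:
        return len(self.clash_pairs)


def validate_structure(model: FineModel, clash_threshold: float = CLASH_THRESHOLD,
                       scan_radius: float = 0.6) -> ValidationReport:
    """H-bond site distances, sticky-end pairing counts, and clash scan."""
    if model.n_atoms == 0:
        raise DesignError("empty model")
    lengths, pair_idx = [], []
    tiles = model.nt_attr("tile")
    for n, (a, b) in enumerate(model.pairing):
        na, nb = model.nucleotides[a], model.nucleotides[b]
        for sa, sb in chem.wc_site_pairs(na.base, nb.base):
            ia, ib = model.atom_index(a, sa), model.atom_index(b, sb)
            lengths.append(np.linalg.norm(model.positions[ia]
                                          - model.positions[ib]))
            pair_idx.append(n)
    counts = Counter()
    for a, b in model.pairing:
        ta, tb = int(tiles[a]), int(tiles[b])
        if ta != tb:
            counts[tuple(sorted((ta, tb)))] += 1

    excluded = _bonded_nt_pairs(model)
    tree = cKDTree(model.positions)
    cand = tree.query_pairs(r=scan_radius, output_type="ndarray")
    nt_i = model.nucleotide_index[cand[:, 0]]
    nt_j = model.nucleotide_index[cand[:, 1]]
    keep = np.array([not ((a == b) or ((int(a), int(b)) in excluded)
                          or ((int(b), int(a)) in excluded))
                     for a, b in zip(nt_i, nt_j)])
    dists = np.linalg.norm(model.positions[cand[keep, 0]]
                           - model.positions[cand[keep, 1]], axis=1) \
        if keep.any() else np.array([])
    clashes = []
    if len(dists):
        close = np.nonzero(dists < clash_threshold)[0]
        kept = cand[keep]
        clashes = [(int(kept[k, 0]), int(kept[k, 1])) for k in close]
    return ValidationReport(
        hbond_lengths=np.array(lengths),
        hbond_pair_index=np.array(pair_idx, dtype=int),
        sticky_end_hbond_counts=dict(counts),
        min_interatomic_distance=float(dists.min()) if len(dists) else np.inf,
        clash_pairs=clashes,
    )


def _bonded_nt_pairs(model: FineModel) -> set:
    """Nucleotide pairs excluded from the non-bonded clash scan."""
    pairs = set()
    for a, b in model.pairing:
        pairs.add((a, b))
    for a, b in model.linkages:
        pairs.add((a, b))
    by_strand = {}
    for i, nt in enumerate(model.nucleotides):
        by_strand.setdefault(nt.strand, []).append((nt.strand_order, i))
    neighbors = {}
    for entries in by_strand.values():
        entries.sort()
        for (o1, i), (o2, j) in zip(entries, entries[1:]):
            if o2 - o1 == 1:
                pairs.add((i, j))
                neighbors.setdefault(i, []).append(j)
                neighbors.setdefault(j, []).append(i)
    # a nucleotide and the chain neighbor of its pairing partner are two
    # covalent bonds apart through the duplex ladder: bonded environment
    partners = {}
    for a, b in model.pairing:
        partners.setdefault(a, []).append(b)
        partners.setdefault(b, []).append(a)
        for nb in neighbors.get(b, ()):
            pairs.add((a, nb))
        for na in neighbors.get(a, ()):
            pairs.add((na, b))
    # same treatment around designed junctions (segment linkages)
    for a, b in model.linkages:
        for nb in list(neighbors.get(b, [])) + partners.get(b, []):
            pairs.add((a, nb))
        for na in list(neighbors.get(a, [])) + partners.get(a, []):
            pairs.add((na, b))
    return pairs | {(b, a) for a, b in pairs}


def measure_ring_diameters(model: FineModel) -> dict:
    """Outer/inner diameters of a ring assembly about the z axis (nm).

    Outer: twice the maximum radial atom distance.  Inner: twice the minimum
    radial distance of inner-circle duplex-axis points.
    """
    roles = model.nt_attr("role")
    inner = np.nonzero(roles == "inner_circle")[0]
    if len(inner) == 0:
        raise DesignError("model has no inner_circle nucleotides")
    r_atoms = np.linalg.norm(model.positions[:, :2], axis=1)
    axis = np.array([model.nucleotides[i].axis_point for i in inner])
    r_axis = np.linalg.norm(axis[:, :2], axis=1)
    return {"outer": 2.0 * float(r_atoms.max()),
            "inner": 2.0 * float(r_axis.min())}


class TopologyError(ValueError):
    pass


def interfaces_from_model(model: FineModel):
    """Tile centers and hybridized tile-tile interfaces of an assembly."""
    tiles = model.atom_tiles()
    n_tiles = int(tiles.max()) + 1
    centers = np.array([model.positions[tiles == t].mean(axis=0)
                        for t in range(n_tiles)])
    nt_tiles = model.nt_attr("tile")
    interfaces = sorted({tuple(sorted((int(nt_tiles[a]), int(nt_tiles[b]))))
                         for a, b in model.pairing
                         if nt_tiles[a] != nt_tiles[b]})
    return centers, interfaces


def assembly_topology(tile_centers: np.ndarray, interfaces) -> dict:
    """Vertices/edges/faces of the tile-adjacency graph of an assembly.

    Faces are traced from the geometric rotation system (neighbors ordered
    around each tile's outward axis); for a sphere-like assembly Euler's
    V - E + F = 2 must hold.
    """
    centers = np.asarray(tile_centers, float)
    g = nx.Graph()
    g.add_nodes_from(range(len(centers)))
    g.add_edges_from((int(a), int(b)) for a, b in interfaces)
    if not nx.is_connected(g):
        raise TopologyError("tile adjacency graph is not connected")
    centroid = centers.mean(axis=0)
    order = {}
    for v in g.nodes:
        axis = centers[v] - centroid
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        ref = np.array([1.0, 0.0, 0.0])
        if abs(ref @ axis) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ axis) * axis
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        ang = {}
        for w in g.neighbors(v):
            d = centers[w] - centers[v]
            ang[w] = np.arctan2(d @ e2, d @ e1)
        order[v] = sorted(g.neighbors(v), key=lambda w: ang[w])
    faces = _trace_faces(g, order)
    V, E, F = g.number_of_nodes(), g.number_of_edges(), len(faces)
    if V - E + F != 2:
        raise TopologyError(f"Euler check failed: V-E+F = {V - E + F}")
    return {
        "vertices": V, "edges": E, "faces": F,
        "faces_by_size": dict(Counter(len(f) for f in faces)),
        "graph": g,
    }


def _trace_faces(g: nx.Graph, order: dict) -> list:
    darts = {(u, v) for u, v in g.edges} | {(v, u) for u, v in g.edges}
    faces = []
    while darts:
        start = next(iter(darts))
        face, (u, v) = [], start
        while True:
            face.append(u)
            darts.discard((u, v))
            nbrs = order[v]
            k = nbrs.index(u)
            w = nbrs[(k + 1) % len(nbrs)]
            u, v = v, w
            if (u, v) == start:
                break
        faces.append(face)
    return faces
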
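"""Finite rotation groups and polyhedral vertex orbits.

The cyclic groups C_q place ring tiles (q = 12 for the R1/R2 rings); the
icosahedral rotation group I (order 60) places the 60 three-point-star tiles
of the buckyball; the tetrahedral rotation group T (order 12) backs the small
"mini ball" test fixture.  Icosahedral and tetrahedral groups are generated
programmatically by closing a generator set under multiplication — only the
abstract group matters, so no reference structure is read.
"""

from __future__ import annotations

import numpy as np

from .model import SymmetryGroup

PHI = (1.0 + np.sqrt(5.0)) / 2.0


def rotation_about(axis, angle: float) -> np.ndarray:
    """Proper rotation matrix about ``axis`` by ``angle`` (radians)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(a, a)


def cyclic_group(q: int, axis=(0.0, 0.0, 1.0)) -> SymmetryGroup:
    """C_q: rotations by multiples of 360/q degrees about ``axis``."""
    if q < 1:
        raise ValueError("group order must be >= 1")
    rots = np.array([rotation_about(axis, 2 * np.pi * k / q) for k in range(q)])
    return SymmetryGroup(name=f"c{q}", rotations=rots)


def _close_group(generators, max_order: int = 120) -> np.ndarray:
    """Close a set of rotations under multiplication (BFS with rounding)."""
    def key(m):
        return tuple(np.round(m, 8).ravel())

    elems = {key(np.eye(3)): np.eye(3)}
    frontier = [np.eye(3)]
    gens = [np.asarray(g, dtype=float) for g in generators]
    while frontier:
        nxt = []
        for e in frontier:
            for g in gens:
                p = g @ e
                k = key(p)
                if k not in elems:
                    if len(elems) >= max_order:
                        raise RuntimeError("group closure exceeded max order")
                    elems[k] = p
                    nxt.append(p)
        frontier = nxt
    # deterministic order: identity first, then lexicographic on rounded entries
    mats = list(elems.values())
    ident = [m for m in mats if np.allclose(m, np.eye(3), atol=1e-9)]
    rest = sorted((m for m in mats if not np.allclose(m, np.eye(3), atol=1e-9)),
                  key=lambda m: tuple(np.round(m, 8).ravel()))
    return np.array(ident + rest)


def icosahedral_group() -> SymmetryGroup:
    """The icosahedral rotation group I, order 60.

    Generated from a five-fold rotation about an icosahedron vertex axis and a
    two-fold rotation about a coordinate axis (an edge-midpoint axis in this
    orientation).
    """
    g5 = rotation_about((0.0, 1.0, PHI), 2 * np.pi / 5)
    g2 = rotation_about((0.0, 0.0, 1.0), np.pi)
    rots = _close_group([g5, g2], max_order=60)
    if len(rots) != 60:
        raise RuntimeError(f"icosahedral closure gave {len(rots)} elements")
    return SymmetryGroup(name="icosahedral", rotations=rots)


def tetrahedral_group() -> SymmetryGroup:
    """The tetrahedral rotation group T, order 12."""
    g3 = rotation_about((1.0, 1.0, 1.0), 2 * np.pi / 3)
    g2 = rotation_about((0.0, 0.0, 1.0), np.pi)
    rots = _close_group([g3, g2], max_order=12)
    if len(rots) != 12:
        raise RuntimeError(f"tetrahedral closure gave {len(rots)} elements")
    return SymmetryGroup(name="tetrahedral", rotations=rots)


def get_group(name: str) -> SymmetryGroup:
    name = name.lower()
    if name in ("icosahedral", "i", "i60"):
        return icosahedral_group()
    if name in ("tetrahedral", "t", "t12"):
        return tetrahedral_group()
    if name.startswith("c") and name[1:].isdigit():
        return cyclic_group(int(name[1:]))
    raise ValueError(f"unknown symmetry group {name!r}")


# ---------------------------------------------------------------------------
# Polyhedral vertex sets for cage assemblies
# ---------------------------------------------------------------------------

def icosahedron_vertices() -> np.ndarray:
    """The 12 vertices (0, ±1, ±phi) and cyclic permutations, unit-normalized."""
    v = []
    for a in (-1.0, 1.0):
        for b in (-PHI, PHI):
            v.extend([(0, a, b), (a, b, 0), (b, 0, a)])
    v = np.array(v)
    return v / np.linalg.norm(v[0])


def tetrahedron_vertices() -> np.ndarray:
    v = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float)
    return v / np.sqrt(3.0)


def truncated_vertices(vertices: np.ndarray, edge_pairs: np.ndarray) -> np.ndarray:
    """Vertices of the truncation: each edge (a, b) contributes (2a+b)/3 and
    (a+2b)/3.  For the icosahedron this yields the 60 truncated-icosahedron
    vertices (one free orbit of I); for the tetrahedron, the 12 vertices of the
    truncated tetrahedron (one free orbit of T)."""
    out = []
    for i, j in edge_pairs:
        a, b = vertices[i], vertices[j]
        out.append((2 * a + b) / 3.0)
        out.append((a + 2 * b) / 3.0)
    return np.array(out)


def polyhedron_edges(vertices: np.ndarray) -> np.ndarray:
    """Edges = vertex pairs at the minimal inter-vertex distance."""
    d = np.linalg.norm(vertices[:, None, :] - vertices[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    dmin = d.min()
    ii, jj = np.nonzero(d < dmin * (1 + 1e-6))
    return np.array([(i, j) for i, j in zip(ii, jj) if i < j])


def cage_vertices(group: SymmetryGroup) -> np.ndarray:
    """Unit-sphere tile positions forming one free orbit of the group.

    Icosahedral -> truncated icosahedron (60 vertices, 90 edges);
    tetrahedral -> truncated tetrahedron (12 vertices, 18 edges).
    The vertex list is ordered group-wise: vertex i = rotations[i] @ vertex 0.
    """
    if group.name == "icosahedral":
        base = icosahedron_vertices()
    elif group.name == "tetrahedral":
        base = tetrahedron_vertices()
    else:
        raise ValueError("cage assemblies need an icosahedral or tetrahedral group")
    edges = polyhedron_edges(base)
    trunc = truncated_vertices(base, edges)
    trunc = trunc / np.linalg.norm(trunc, axis=1)[:, None]
    v0 = trunc[0]
    orbit = np.einsum("nij,j->ni", group.rotations, v0)
    # check the orbit reproduces the truncated vertex set (free orbit)
    d = np.linalg.norm(orbit[:, None, :] - trunc[None, :, :], axis=2)
    if not np.all(d.min(axis=1) < 1e-8):
        raise RuntimeError("group orbit does not match truncated polyhedron")
    return orbit
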
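"""Declarative design records and parameterized presets.

The exact base sequences of the published rings and three-point-star (3PS)
tile exist only as figure artwork, so designs here are parameterized by
per-segment base-pair counts; arc bp counts are derived from the target ring
diameters with the B-form rise (0.34 nm/bp).  Sequences are generated
deterministically per design so masses are reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import RISE_PER_BP
from .model import DesignError


@dataclass
class StrandSequence:
    id: str
    bases: list
    circular: bool = False

    def __post_init__(self):
        if not self.bases:
            raise DesignError(f"strand {self.id}: empty sequence")
        if not set(self.bases).issubset({"A", "C", "G", "T"}):
            raise DesignError(f"strand {self.id}: bases outside ACGT")


@dataclass
class DuplexSegment:
    name: str
    bp_count: int
    role: str
    rise_per_bp: float = RISE_PER_BP
    twist_per_bp: float = 360.0 / 10.5
    helix_radius: float = 1.0
    strand_refs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bp_count < 1:
            raise DesignError(f"segment {self.name}: bp_count must be >= 1")
        if self.rise_per_bp <= 0:
            raise DesignError(f"segment {self.name}: rise must be positive")


@dataclass
class TileDesign:
    name: str
    family: str            # "ring" | "three_point_star" | "toy_ring"
    params: dict
    strands: list = field(default_factory=list)
    segments: list = field(default_factory=list)
    sticky_ends: list = field(default_factory=list)   # (segment, bases, partner)
    symmetry_hint: str = "none"
    group_name: str = "c12"


def _sequence(n: int, seed: int) -> list:
    rng = np.random.default_rng(seed)
    return [("A", "C", "G", "T")[k] for k in rng.integers(0, 4, size=n)]


# ---------------------------------------------------------------------------
# Ring designs (R1/R2, open and closed forms)
# ---------------------------------------------------------------------------

def ring_design(name: str, **overrides) -> TileDesign:
    """Preset ring designs.

    ``r1o``/``r1c``: 12 tiles, inner circle 10 bp/tile, outer 21 bp/tile, one
    radial bridge per tile; designed diameters 13 / 29 nm.  ``r2o``/``r2c``:
    12 composite tiles (unit + connector), inner 31 bp/tile, outer 41 bp/tile,
    two bridges per tile; designed diameters 40 / 55 nm.  Open forms carry the
    eight-nucleotide single-stranded domain in the outer circle.
    """
    name = name.lower()
    presets = {
        "r1o": dict(inner_bp=10, outer_bp=21, bridge_offsets_deg=(0.0,),
                    open_form=True),
        "r1c": dict(inner_bp=10, outer_bp=21, bridge_offsets_deg=(0.0,),
                    open_form=False),
        "r2o": dict(inner_bp=31, outer_bp=41, bridge_offsets_deg=(-7.5, 7.5),
                    open_form=True),
        "r2c": dict(inner_bp=31, outer_bp=41, bridge_offsets_deg=(-7.5, 7.5),
                    open_form=False),
    }
    if name not in presets:
        raise DesignError(f"unknown ring design {name!r}")
    params = dict(
        n_tiles=12,
        sticky_overhang=4,
        bridge_gap=1.5,          # nm between bridge-duplex end and arc axis
        ss_domain_len=8,         # open-form single-stranded stretch (outer arc)
        seed=dict(r1o=11, r1c=12, r2o=21, r2c=22)[name],
        **presets[name],
    )
    params.update(overrides)
    n_tiles = params["n_tiles"]
    for key in ("inner_bp", "outer_bp"):
        if params[key] < params["sticky_overhang"] + 1:
            raise DesignError("arc shorter than its sticky overhang")
    params["inner_radius"] = n_tiles * params["inner_bp"] * RISE_PER_BP / (2 * np.pi)
    params["outer_radius"] = n_tiles * params["outer_bp"] * RISE_PER_BP / (2 * np.pi)
    params["inner_seq"] = _sequence(params["inner_bp"], params["seed"])
    params["outer_seq"] = _sequence(params["outer_bp"], params["seed"] + 100)

    design = TileDesign(
        name=name, family="ring", params=params, symmetry_hint="none",
        group_name=f"c{n_tiles}",
    )
    design.segments = [
        DuplexSegment("inner_arc", params["inner_bp"], "inner_circle"),
        DuplexSegment("outer_arc", params["outer_bp"], "outer_circle"),
    ] + [DuplexSegment(f"bridge{k}", 1 + int(
            (params["outer_radius"] - params["inner_radius"]
             - 2 * params["bridge_gap"]) / RISE_PER_BP) - 1, "bridge")
         for k in range(len(params["bridge_offsets_deg"]))]
    ov = params["sticky_overhang"]
    design.sticky_ends = [
        ("inner_arc", params["inner_seq"][-ov:], ("a", "a'")),
        ("outer_arc", params["outer_seq"][-ov:], ("b", "b'")),
    ]
    return design


# ---------------------------------------------------------------------------
# Three-point-star tile and cage (buckyball / mini-ball) designs
# ---------------------------------------------------------------------------

def star_design(kind: str = "buckyball", **overrides) -> TileDesign:
    """Three-point-star (3PS) tile designs.

    ``buckyball``: 60 tiles on truncated-icosahedron vertices, 19 bp arms with
    4-nt palindromic sticky overhangs, three 5-nt single-stranded T-loops at
    the tile center (cage diameter ~86 nm).  ``mini_ball``: 12 tiles on a
    truncated tetrahedron, shortened arms — a desk-scale topology fixture.
    ``tile``: a flat standalone 3PS tile with exact threefold symmetry.
    """
    kind = kind.lower()
    presets = {
        "buckyball": dict(arm_bp=19, overhang=4, group="icosahedral"),
        "mini_ball": dict(arm_bp=6, overhang=2, group="tetrahedral"),
        "tile": dict(arm_bp=19, overhang=4, group="c1"),
    }
    if kind not in presets:
        raise DesignError(f"unknown star design {kind!r}")
    params = dict(
        hub_radius=1.3,          # nm, arm duplexes start here (adjacent
                                 # arm ends sit in vdW contact at the hub)
        loop_len=5,              # nt per single-stranded T-loop
        loop_radius=0.95,
        seed=33,
        **presets[kind],
    )
    params.update(overrides)
    if params["overhang"] % 2:
        raise DesignError("sticky overhang must be even (palindromic)")
    np_paired = params["arm_bp"]
    ov = params["overhang"]
    seq = _sequence(np_paired, params["seed"])
    # palindromic overhang: base j must complement base (ov-1-j)
    pal = {2: list("TA"), 4: list("TGCA"), 6: list("TAGCTA")}
    if ov not in pal:
        raise DesignError("supported overhang lengths: 2, 4, 6")
    params["arm_seq"] = seq + pal[ov]
    # edge length follows from arm reach: L = 2 (r0 + (np + ov/2) * rise)
    params["edge_length"] = 2 * (params["hub_radius"]
                                 + (np_paired + ov / 2) * RISE_PER_BP)
    design = TileDesign(
        name=kind, family="three_point_star", params=params,
        symmetry_hint="threefold", group_name=params["group"],
    )
    design.segments = (
        [DuplexSegment(f"arm{k}", np_paired, "arm") for k in range(3)]
        + [DuplexSegment(f"loop{k}", params["loop_len"], "loop")
           for k in range(3)]
    )
    design.sticky_ends = [(f"arm{k}", pal[ov], ("c1", "c1'")) for k in range(3)]
    return design


# ---------------------------------------------------------------------------
# Toy rings for dense-oracle tests
# ---------------------------------------------------------------------------

def toy_ring_design(q: int, bp_per_tile: int = None, **overrides) -> TileDesign:
    """A C_q ring of short arc-duplex tiles, small enough for dense NMA."""
    if q < 2:
        raise DesignError("toy ring needs q >= 2")
    if bp_per_tile is None:
        # small q means tight curvature; keep the duplex envelope clash-free
        bp_per_tile = {2: 24, 3: 16, 4: 12}.get(q, 10)
    params = dict(
        n_tiles=q, inner_bp=bp_per_tile, sticky_overhang=2, seed=5,
    )
    params.update(overrides)
    params["inner_radius"] = q * params["inner_bp"] * RISE_PER_BP / (2 * np.pi)
    params["inner_seq"] = _sequence(params["inner_bp"], params["seed"])
    design = TileDesign(
        name=f"toy_ring_c{q}", family="toy_ring", params=params,
        group_name=f"c{q}",
    )
    design.segments = [DuplexSegment("arc", params["inner_bp"], "inner_circle")]
    ov = params["sticky_overhang"]
    design.sticky_ends = [("arc", params["inner_seq"][-ov:], ("a", "a'"))]
    return design


def get_design(name: str, **overrides) -> TileDesign:
    name = name.lower()
    if name in ("r1o", "r1c", "r2o", "r2c"):
        return ring_design(name, **overrides)
    if name in ("buckyball", "mini_ball", "tile", "3ps", "3ps_tile"):
        return star_design("tile" if name in ("3ps", "3ps_tile") else name,
                           **overrides)
    if name.startswith("toy_ring_c"):
        return toy_ring_design(int(name.rsplit("c", 1)[1]), **overrides)
    raise DesignError(f"unknown design {name!r}")
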
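"""Idealized B-form helix generation.

Duplexes are laid out slot by slot: each base-pair slot has a frame
``(c, u, f, t)`` — slot center, long axis (midpoint -> reference-strand C1'),
in-plane normal, and local helix axis.  The reference strand places its
template atoms in ``(u, f, t)``; the complementary strand uses ``(-u, f, -t)``
(a proper rotation by 180 deg about ``f``), which runs it antiparallel and
puts its Watson-Crick edge sites exactly 0.29 nm across from the reference
strand's.  Arc duplexes follow a circular duplex axis with per-slot frames
rotated about the ring axis, so rings close smoothly.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import chem
from .constants import RISE_PER_BP, TWIST_PER_BP
from .model import DesignError, FineModel, Nucleotide


def straight_frames(n_slots: int, origin, direction, perp, rise: float = RISE_PER_BP,
                    twist_deg: float = TWIST_PER_BP, phase0_deg: float = 0.0,
                    slot0: int = 0):
    """Frames for a straight helix starting at ``origin`` along ``direction``."""
    t = np.asarray(direction, dtype=float)
    t = t / np.linalg.norm(t)
    p = np.asarray(perp, dtype=float)
    p = p - (p @ t) * t
    norm = np.linalg.norm(p)
    if norm < 1e-9:
        raise DesignError("perpendicular reference parallel to helix axis")
    p /= norm
    q = np.cross(t, p)
    frames = []
    for s in range(slot0, slot0 + n_slots):
        c = np.asarray(origin, dtype=float) + s * rise * t
        phi = np.deg2rad(phase0_deg + s * twist_deg)
        u = np.cos(phi) * p + np.sin(phi) * q
        f = np.cross(t, u)
        frames.append((c, u, f, t))
    return frames


def arc_frames(slots: Sequence[int], radius: float, arc_step_deg: float,
               z: float = 0.0, angle_offset_deg: float = 0.0,
               twist_deg: float = TWIST_PER_BP, phase0_deg: float = 0.0):
    """Frames for an arc duplex whose axis follows a circle about z.

    Slot ``s`` sits at angle ``angle_offset + (s + 0.5) * arc_step`` with the
    local helix axis tangent to the circle and the base-pair long axis rotated
    by the cumulative twist about that tangent.
    """
    frames = []
    for s in slots:
        theta = np.deg2rad(angle_offset_deg + (s + 0.5) * arc_step_deg)
        rhat = np.array([np.cos(theta), np.sin(theta), 0.0])
        t = np.array([-np.sin(theta), np.cos(theta), 0.0])
        phi = np.deg2rad(phase0_deg + s * twist_deg)
        u = np.cos(phi) * rhat + np.sin(phi) * np.array([0.0, 0.0, 1.0])
        f = np.cross(t, u)
        c = radius * rhat + np.array([0.0, 0.0, z])
        frames.append((c, u, f, t))
    return frames


def _place_atoms(base: str, frame, strand: int, with_phosphate: bool):
    """Atom names/positions/elements/masses for one nucleotide in one slot.

    ``strand`` 0 is the reference strand; strand 1 is placed with the frame
    rotated 180 deg about ``f`` (antiparallel partner).
    """
    c, u, f, t = frame
    if strand == 1:
        e1, e2, e3 = -u, f, -t
    else:
        e1, e2, e3 = u, f, t
    tmpl = chem.nucleotide_template(base, with_phosphate)
    names, pos, elements, masses = [], [], [], []
    for name, x, y, z, el, m in tmpl:
        names.append(name)
        pos.append(c + x * e1 + y * e2 + z * e3)
        elements.append(el)
        masses.append(m)
    return names, np.array(pos), elements, masses


def build_run(frames, bases: Sequence[str], *, role, strand1_id: str,
              strand2_id: Optional[str] = None, tile: int = 0,
              s1_mask: Optional[Sequence[bool]] = None,
              s2_mask: Optional[Sequence[bool]] = None,
              s1_sticky: Optional[dict] = None,
              s2_sticky: Optional[dict] = None,
              include_5p_phosphate: bool = False,
              meta: Optional[dict] = None) -> FineModel:
    """Realize a duplex (or partially single-stranded) run of slots.

    ``s1_mask`` / ``s2_mask`` select which slots carry a reference-strand /
    complementary-strand nucleotide; slots where both are present become a
    Watson-Crick pair.  ``s1_sticky``/``s2_sticky`` map slot index ->
    sticky-end label for unpaired overhang nucleotides.  ``role`` may be a
    single segment role or one role per slot.
    """
    n = len(frames)
    bases = list(bases)
    if len(bases) != n:
        raise DesignError("one base per slot required")
    if n < 1:
        raise DesignError("a segment needs at least one base-pair slot")
    s1 = np.ones(n, bool) if s1_mask is None else np.asarray(s1_mask, bool)
    s2 = (np.ones(n, bool) if strand2_id is not None else np.zeros(n, bool)) \
        if s2_mask is None else np.asarray(s2_mask, bool)
    if s2.any() and strand2_id is None:
        raise DesignError("complementary strand present but no strand id")
    roles = [role] * n if isinstance(role, str) else list(role)

    names_all, pos_all, el_all, mass_all, nt_index = [], [], [], [], []
    nucleotides, pairing = [], []

    def add_strand(mask, strand_no, strand_id, sticky):
        slots = np.nonzero(mask)[0]
        nt_of_slot = {}
        # strand 0 runs 5'->3' with increasing slot; strand 1 the reverse
        ordered = slots if strand_no == 0 else slots[::-1]
        for order, s in enumerate(ordered):
            base = bases[s] if strand_no == 0 else chem.COMPLEMENT[bases[s]]
            has_p = include_5p_phosphate or order > 0
            nm, xyz, el, ms = _place_atoms(base, frames[s], strand_no, has_p)
            idx = len(nucleotides)
            names_all.extend(nm)
            pos_all.append(xyz)
            el_all.extend(el)
            mass_all.extend(ms)
            nt_index.extend([idx] * len(nm))
            nucleotides.append(Nucleotide(
                base=base, strand=f"t{tile:02d}:{strand_id}",
                strand_order=order, tile=tile, role=roles[s],
                has_phosphate=has_p, axis_point=frames[s][0].copy(),
                sticky_label=(sticky or {}).get(int(s)),
            ))
            nt_of_slot[int(s)] = idx
        return nt_of_slot

    s1_nts = add_strand(s1, 0, strand1_id, s1_sticky)
    s2_nts = add_strand(s2, 1, strand2_id, s2_sticky) if s2.any() else {}
    for s in range(n):
        if s in s1_nts and s in s2_nts:
            pairing.append((s1_nts[s], s2_nts[s]))

    return FineModel(
        positions=np.vstack(pos_all),
        atom_names=np.array(names_all),
        elements=np.array(el_all),
        masses=np.array(mass_all),
        nucleotide_index=np.array(nt_index),
        nucleotides=nucleotides,
        pairing=pairing,
        meta=meta or {},
    )


def build_duplex(bp_count: int, origin=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0),
                 perp=(1.0, 0.0, 0.0), bases: Optional[Sequence[str]] = None,
                 rise: float = RISE_PER_BP, twist_deg: float = TWIST_PER_BP,
                 role: str = "arm", strand1_id: str = "S1", strand2_id: str = "S2",
                 include_5p_phosphate: bool = False) -> FineModel:
    """An ideal straight B-form duplex fragment (both strands, fully paired)."""
    if bp_count < 1:
        raise DesignError("bp_count must be >= 1")
    if rise <= 0:
        raise DesignError("rise must be positive")
    if bases is None:
        bases = default_sequence(bp_count)
    frames = straight_frames(bp_count, origin, direction, perp, rise, twist_deg)
    return build_run(frames, bases, role=role, strand1_id=strand1_id,
                     strand2_id=strand2_id,
                     include_5p_phosphate=include_5p_phosphate)


def default_sequence(n: int, seed: int = 7) -> list:
    """Deterministic pseudo-sequence used when a design gives only bp counts."""
    rng = np.random.default_rng(seed)
    return [("A", "C", "G", "T")[k] for k in rng.integers(0, 4, size=n)]
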
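"""Classification of mode shapes into the ring / buckyball / tile taxonomy.

Ring modes separate into inner-circle motion (out-of-plane translation O-T,
out-of-plane rotation O-R — the seesaw, in-plane translation I-T),
outer-circle motion (zigzag: sinusoidal out-of-plane waves with angular
wavenumber >= 2) and bridge motion (spiderlike: all bridges arching the same
way; mixed spiderlike: bridges arching in alternating directions).  Buckyball
modes are scored for overall breathing (coherent radial swelling), local
breathing (radial but spatially localized, "spiky") and per-tile torsion.
A standalone three-point-star tile is scored for out-of-plane arm bending,
in-plane tweezer-like arm motion and bending/twisting localized at the
sticky ends.

Every score is a ratio of quadratic forms in the mode vector, normalized to
[0, 1] by the mode's total displacement energy, so scores are invariant to
mode sign and scale.  Degenerate eigen-pairs are scored jointly on their
invariant subspace (quadratic forms summed over an orthonormal basis of the
group), which makes the labels stable under solver-arbitrary remixing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CGModel, DesignError
from .nma import ModeSet

MIXED_MARGIN = 0.15
DEGENERACY_RTOL = 1e-5

RING_LABELS = ("O_T", "O_R", "I_T", "zigzag", "spiderlike", "mixed_spiderlike")
BALL_LABELS = ("O_B", "L_B", "torsional")
TILE_LABELS = ("bending", "tweezer", "sticky_bend", "sticky_twist")


@dataclass
class ModeLabel:
    mode_number: int          # 1-based, counted from the first non-rigid mode
    label: str
    scores: dict
    margin: float
    eigenvalue: float
    degenerate_group: int


def _disp(vectors: np.ndarray) -> np.ndarray:
    """(3N, g) mode columns -> (g, N, 3) displacement fields."""
    g = vectors.shape[1]
    return vectors.T.reshape(g, -1, 3)


def ring_mode_scores(vectors: np.ndarray, cg: CGModel) -> dict:
    """Scores over the ring taxonomy for one (possibly degenerate) group."""
    roles = cg.nt_roles
    inner = roles == "inner_circle"
    outer = roles == "outer_circle"
    bridge = roles == "bridge"
    if not inner.any():
        raise DesignError("ring scoring needs inner_circle role annotations")
    disp = _disp(vectors)
    E = float(np.sum(disp ** 2))
    theta = np.arctan2(cg.positions[:, 1], cg.positions[:, 0])

    scores = dict.fromkeys(RING_LABELS, 0.0)
    n_in = int(inner.sum())
    dz_in = disp[:, inner, 2]
    scores["O_T"] = float(np.sum(dz_in.sum(axis=1) ** 2)) / (n_in * E)

    # O-R: seesaw = projection of inner z-field on the k=1 angular harmonics
    phi = np.stack([np.cos(theta[inner]), np.sin(theta[inner])], axis=1)
    q1, _ = np.linalg.qr(phi)
    scores["O_R"] = float(np.sum((dz_in @ q1) ** 2)) / E

    dxy_in = disp[:, inner, :2]
    scores["I_T"] = float(np.sum(dxy_in.sum(axis=1) ** 2)) / (n_in * E)

    if outer.any():
        dz_out = disp[:, outer, 2]
        basis = [np.ones(int(outer.sum()))]
        for k in range(1, 11):
            basis += [np.cos(k * theta[outer]), np.sin(k * theta[outer])]
        qall, _ = np.linalg.qr(np.stack(basis, axis=1))
        high = qall[:, 3:]          # angular wavenumber >= 2
        scores["zigzag"] = float(np.sum((dz_out @ high) ** 2)) / E

    if bridge.any():
        strands = cg.nt_strands
        tiles = cg.nt_tiles
        dz_br = disp[:, bridge, 2]
        n_br = int(bridge.sum())
        scores["spiderlike"] = float(np.sum(dz_br.sum(axis=1) ** 2)) / (n_br * E)
        # per-bridge coherent z, alternating across bridges
        bridge_ids = np.array([f"{t}:{s.split(':')[-1][:2]}"
                               for t, s in zip(tiles[bridge], strands[bridge])])
        num = 0.0
        tot = np.zeros(disp.shape[0])
        for bid in np.unique(bridge_ids):
            sel = bridge_ids == bid
            c = dz_br[:, sel].sum(axis=1)
            num += np.sum(c ** 2) / sel.sum()
            tot += c
        num -= np.sum(tot ** 2) / n_br
        scores["mixed_spiderlike"] = float(max(num, 0.0)) / E
    return scores


def ball_mode_scores(vectors: np.ndarray, cg: CGModel) -> dict:
    """Overall/local breathing and torsional scores for a cage assembly."""
    disp = _disp(vectors)
    E = float(np.sum(disp ** 2))
    center = cg.positions.mean(axis=0)
    x = cg.positions - center
    r = np.linalg.norm(x, axis=1)
    if r.max() < 1e-6 or np.linalg.matrix_rank(x[:200]) < 3:
        raise DesignError("degenerate centroid for radial scoring")
    rhat = x / r[:, None]
    n = cg.n_beads

    rad = np.einsum("gnk,nk->gn", disp, rhat)
    scores = dict.fromkeys(BALL_LABELS, 0.0)
    scores["O_B"] = float(np.sum(rad.sum(axis=1) ** 2)) / (n * E)

    # local breathing: radial energy that is not the uniform component,
    # weighted by spatial localization ("spiky" participation)
    e_rad = float(np.sum(rad ** 2))
    coh = float(np.sum(rad.sum(axis=1) ** 2)) / n
    amp2 = np.sum(disp ** 2, axis=(0, 2))
    pr = float(amp2.sum() ** 2 / (n * np.sum(amp2 ** 2) + 1e-300))
    localization = 1.0 - pr
    scores["L_B"] = max(e_rad - coh, 0.0) / E * localization

    # torsion: per-tile coherent rotation about the tile's own radial axis
    tiles = cg.nt_tiles
    num = 0.0
    for t in np.unique(tiles):
        sel = tiles == t
        ct = cg.positions[sel].mean(axis=0)
        a = ct - center
        a = a / np.linalg.norm(a)
        tau = np.cross(a, cg.positions[sel] - ct)
        tn = np.linalg.norm(tau, axis=1)
        good = tn > 0.1
        if not good.any():
            continue
        that = tau[good] / tn[good][:, None]
        c = np.einsum("gnk,nk->g", disp[:, sel][:, good], that)
        num += np.sum(c ** 2) / good.sum()
    scores["torsional"] = float(num) / E
    return scores


def tile_mode_scores(vectors: np.ndarray, cg: CGModel) -> dict:
    """Bending / tweezer / sticky-end scores for a standalone 3PS tile."""
    roles = cg.nt_roles
    arm = roles == "arm"
    sticky = roles == "sticky_end"
    if not arm.any():
        raise DesignError("tile scoring needs arm role annotations")
    disp = _disp(vectors)
    E = float(np.sum(disp ** 2))
    center = cg.positions[arm].mean(axis=0)
    x = cg.positions - center

    scores = dict.fromkeys(TILE_LABELS, 0.0)
    scores["bending"] = float(np.sum(disp[:, arm, 2] ** 2)) / E

    # tweezer: arms swinging about the hub in opposing directions (in-plane).
    # The natural scissor field is a per-arm rotation, so the azimuthal
    # projection is weighted by the lever arm rho; the common (whole-tile
    # rotation) component is projected out.
    strands = cg.nt_strands
    arm_of = np.array([s.split(":")[-1][:2] for s in strands])
    rho = x[:, :2]
    rn = np.linalg.norm(rho, axis=1)
    that = np.zeros_like(x)
    good = rn > 0.3
    that[good, 0] = -rho[good, 1] / rn[good]
    that[good, 1] = rho[good, 0] / rn[good]
    num, tot, wtot = 0.0, np.zeros(disp.shape[0]), 0.0
    for aid in np.unique(arm_of[arm | sticky]):
        sel = (arm | sticky) & (arm_of == aid)
        w = rn[sel]
        c = np.einsum("gnk,nk,n->g", disp[:, sel], that[sel], w)
        num += np.sum(c ** 2) / np.sum(w ** 2)
        tot += c
        wtot += np.sum(w ** 2)
    num -= np.sum(tot ** 2) / max(wtot, 1e-30)
    scores["tweezer"] = float(max(num, 0.0)) / E

    if sticky.any():
        scores["sticky_bend"] = float(np.sum(disp[:, sticky, 2] ** 2)) / E
        # twisting at a sticky end: rotation about its own arm axis
        num = 0.0
        for aid in np.unique(arm_of[sticky]):
            sel = sticky & (arm_of == aid)
            pts = cg.positions[sel]
            axis = pts.mean(axis=0) - center
            axis /= np.linalg.norm(axis)
            rel = pts - pts.mean(axis=0)
            tau = np.cross(axis, rel - np.outer(rel @ axis, axis))
            tn = np.linalg.norm(tau, axis=1)
            good = tn > 0.1
            if not good.any():
                continue
            th = tau[good] / tn[good][:, None]
            c = np.einsum("gnk,nk->g", disp[:, sel][:, good], th)
            num += np.sum(c ** 2) / good.sum()
        scores["sticky_twist"] = float(num) / E
    return scores


_SCORERS = {
    "ring": ring_mode_scores,
    "buckyball": ball_mode_scores,
    "ball": ball_mode_scores,
    "tile": tile_mode_scores,
}


def degenerate_groups(eigenvalues: np.ndarray,
                      rtol: float = DEGENERACY_RTOL) -> list:
    """Consecutive index groups of (near-)equal eigenvalues."""
    groups, current = [], [0]
    for k in range(1, len(eigenvalues)):
        a, b = eigenvalues[current[-1]], eigenvalues[k]
        if abs(b - a) <= rtol * max(abs(a), abs(b), 1e-30):
            current.append(k)
        else:
            groups.append(current)
            current = [k]
    groups.append(current)
    return groups


def label_modes(modes: ModeSet, cg: CGModel, structure: str,
                n_label: int = 10, margin: float = MIXED_MARGIN) -> list:
    """Label the first ``n_label`` non-rigid modes; rigid modes are excluded.

    A mode whose top two scores differ by less than ``margin`` is ``mixed``.
    Labels are stored on the ModeSet and returned as a list of ModeLabel.
    """
    scorer = _SCORERS.get(structure)
    if scorer is None:
        raise DesignError(f"unknown structure class {structure!r}")
    lam, vecs = modes.nonrigid()
    n_label = min(n_label, len(lam))
    labels = []
    groups = degenerate_groups(lam[:n_label])
    for gi, group in enumerate(groups):
        v = vecs[:, group]
        scores = scorer(v, cg)
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        top, second = ranked[0], ranked[1] if len(ranked) > 1 else ("", 0.0)
        gap = top[1] - second[1]
        name = "mixed" if gap < margin else top[0]
        for k in group:
            labels.append(ModeLabel(
                mode_number=k + 1, label=name, scores=dict(scores),
                margin=gap, eigenvalue=float(lam[k]), degenerate_group=gi))
    modes.labels = labels
    return labels


def label_table(labels: list, structure: str) -> pd.DataFrame:
    """Tabular layout: one row per mode with label and per-category scores."""
    rows = []
    for lab in labels:
        row = {"mode": lab.mode_number, "label": lab.label,
               "margin": lab.margin, "eigenvalue": lab.eigenvalue}
        row.update(lab.scores)
        rows.append(row)
    return pd.DataFrame(rows)


def summary_table(labelled: dict) -> pd.DataFrame:
    """Mode-number x structure label summary across several assemblies."""
    frames = {}
    for name, labels in labelled.items():
        frames[name] = {lab.mode_number: lab.label for lab in labels}
    table = pd.DataFrame(frames)
    table.index.name = "mode"
    return table.sort_index()
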
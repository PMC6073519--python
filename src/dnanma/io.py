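"""File formats: PDB structures, NMD mode files, CSV tables, YAML configs.

PDB files are written through gemmi (coordinates nm -> Angstrom, fixed-width
conformance); coarse-grained beads are written as atoms with the lumped mass
in the B-factor column.  Mode sets go to a plain-text NMD file loadable by
common structure viewers plus a CSV of eigenvalues/frequencies/labels.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .model import CGModel, FineModel
from .nma import ModeSet

_CHAIN_IDS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
              "abcdefghijklmnopqrstuvwxyz0123456789")

_BEAD_ELEMENT = {"P": "P", "C4": "C", "C1": "C"}


def _new_structure(name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    st.add_model(gemmi.Model("1"))
    return st


def write_pdb(model, path) -> None:
    """Write a fine or coarse-grained model as fixed-width PDB (Angstrom)."""
    if isinstance(model, FineModel):
        _write_fine_pdb(model, path)
    elif isinstance(model, CGModel):
        _write_cg_pdb(model, path)
    else:
        raise TypeError("expected FineModel or CGModel")


def _write_fine_pdb(model: FineModel, path) -> None:
    st = _new_structure(str(model.meta.get("design", "model")))
    strands = model.nt_attr("strand")
    order = {}
    chain = None
    last = None
    for a in range(model.n_atoms):
        nt = int(model.nucleotide_index[a])
        sid = strands[nt]
        if sid != last:
            if sid not in order:
                order[sid] = _CHAIN_IDS[len(order) % len(_CHAIN_IDS)]
            chain = gemmi.Chain(order[sid])
            st[0].add_chain(chain)
            chain = st[0][-1]
            last = sid
        ntr = model.nucleotides[nt]
        if len(chain) == 0 or chain[-1].seqid.num != ntr.strand_order + 1:
            res = gemmi.Residue()
            res.name = "D" + ntr.base
            res.seqid = gemmi.SeqId(ntr.strand_order + 1, " ")
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = str(model.atom_names[a])
        atom.element = gemmi.Element(str(model.elements[a]))
        x, y, z = 10.0 * model.positions[a]
        atom.pos = gemmi.Position(x, y, z)
        atom.occ = 1.0
        atom.b_iso = 0.0
        chain[-1].add_atom(atom)
    st.setup_entities()
    st.write_pdb(str(path))


def _write_cg_pdb(cg: CGModel, path) -> None:
    st = _new_structure(str(cg.meta.get("design", "cg-model")))
    order = {}
    chain = None
    last = None
    for b in range(cg.n_beads):
        sid = str(cg.nt_strands[b])
        if sid != last:
            if sid not in order:
                order[sid] = _CHAIN_IDS[len(order) % len(_CHAIN_IDS)]
            st[0].add_chain(gemmi.Chain(order[sid]))
            chain = st[0][-1]
            last = sid
        nt = int(cg.nucleotide_index[b])
        if len(chain) == 0 or chain[-1].seqid.num != nt + 1:
            res = gemmi.Residue()
            res.name = "CGB"
            res.seqid = gemmi.SeqId(nt + 1, " ")
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = str(cg.bead_roles[b])[:4]
        atom.element = gemmi.Element(
            _BEAD_ELEMENT.get(str(cg.bead_roles[b]), str(cg.bead_roles[b])[0]))
        x, y, z = 10.0 * cg.positions[b]
        atom.pos = gemmi.Position(x, y, z)
        atom.occ = 1.0
        atom.b_iso = min(float(cg.masses[b]), 999.99)
        chain[-1].add_atom(atom)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(path) -> dict:
    """Read back coordinates (nm), names, elements and chain ids."""
    st = gemmi.read_structure(str(path))
    pos, names, elements, chains, bfac = [], [], [], [], []
    for chain in st[0]:
        for res in chain:
            for atom in res:
                pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                names.append(atom.name)
                elements.append(atom.element.name)
                chains.append(chain.name)
                bfac.append(atom.b_iso)
    return {
        "positions": np.array(pos) / 10.0,
        "names": np.array(names),
        "elements": np.array(elements),
        "chains": np.array(chains),
        "b_factors": np.array(bfac),
    }


def write_springs_csv(cg: CGModel, path) -> None:
    cg.springs.to_csv(path, index=False, float_format="%.17g")


def read_springs_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_modes_csv(modes: ModeSet, path) -> None:
    """Mode table: index, eigenvalue, frequencies, zero flag and label."""
    labels = {lab.mode_number: lab.label for lab in modes.labels} \
        if modes.labels else {}
    z = modes.zero_mode_count
    rows = []
    for k in range(modes.n_modes):
        nonrigid = k - z + 1 if k >= z else 0
        rows.append({
            "mode": k,
            "nonrigid_mode": nonrigid,
            "eigenvalue_rad2_ps2": modes.eigenvalues[k],
            "omega_rad_ps": modes.omega[k],
            "wavenumber_cm": modes.wavenumbers_cm[k],
            "is_rigid": k < z,
            "label": labels.get(nonrigid, ""),
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_nmd(cg: CGModel, modes: ModeSet, path, title: str = "dnanma") -> None:
    """Plain-text NMD mode file for structure viewers.

    Coordinates in Angstrom; each mode line carries the mode number, a scale
    factor (1/omega for non-rigid modes) and the mass-orthonormal vector.
    """
    with open(path, "w") as fh:
        fh.write(f"title {title}\n")
        fh.write("names " + " ".join(str(r) for r in cg.bead_roles) + "\n")
        fh.write("resids " + " ".join(str(i) for i in cg.nucleotide_index)
                 + "\n")
        fh.write("coordinates "
                 + " ".join(f"{v:.3f}" for v in (10.0 * cg.positions).ravel())
                 + "\n")
        for k in range(modes.n_modes):
            if k < modes.zero_mode_count:
                continue
            scale = 1.0 / modes.omega[k] if modes.omega[k] > 0 else 1.0
            vec = " ".join(f"{v:.6f}" for v in modes.vectors[:, k])
            fh.write(f"mode {k - modes.zero_mode_count + 1} {scale:.6f} {vec}\n")


def read_nmd(path) -> dict:
    out = {"modes": []}
    with open(path) as fh:
        for line in fh:
            key, _, rest = line.partition(" ")
            if key == "coordinates":
                out["coordinates"] = np.fromstring(rest, sep=" ") / 10.0
            elif key == "mode":
                parts = rest.split()
                out["modes"].append(
                    (int(parts[0]), float(parts[1]),
                     np.array([float(v) for v in parts[2:]])))
            elif key in ("names", "resids"):
                out[key] = rest.split()
            elif key == "title":
                out["title"] = rest.strip()
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_public(cfg), fh, sort_keys=True)


def _public(obj):
    if isinstance(obj, dict):
        return {k: _public(v) for k, v in obj.items()
                if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_public(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration (private keys excluded)."""
    blob = json.dumps(_public(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
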
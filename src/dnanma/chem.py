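"""Stylized per-nucleotide atom templates.

Each nucleotide is described by a list of heavy atoms placed in a local
base-pair frame:

* ``+x`` points from the base-pair midpoint toward this nucleotide's C1',
* ``+z`` is the local helix axis (5'->3' for the reference strand),
* the base-pair midpoint is the origin.

Hydrogen atoms are not placed explicitly; each heavy atom carries the mass of
its attached hydrogens ("united atom"), so per-nucleotide template masses sum
exactly to the residue composition (e.g. an internal dT residue, phosphate
included, is C10H13N2O7P = 304.20 amu).

Watson-Crick edge sites of both bases sit at local x = +0.145 nm, so paired
sites across the duplex are separated by 0.29 nm — inside the 0.25–0.35 nm
hydrogen-bond band used by structure validation.  All base atoms keep
x >= 0.145 nm, which bounds any cross-strand non-bonded contact below by
0.29 nm and keeps ideal duplexes free of steric clashes.
"""

from __future__ import annotations

from .constants import ATOMIC_MASS

# atom name -> (x, y, z, element, n_hydrogens)
# Backbone, shared by all four nucleotides.  P/OP1/OP2 sit toward the 5'
# neighbour (negative local z); OP2 is protonated so that the in-chain residue
# is neutral and masses match the standard residue compositions.
BACKBONE_TEMPLATE = {
    "P":   (0.90, -0.30, -0.17, "P", 0),
    "OP1": (1.00, -0.42, -0.10, "O", 0),
    "OP2": (0.95, -0.25, -0.33, "O", 1),
    "O5'": (0.80, -0.22, -0.07, "O", 0),
    "C5'": (0.76, -0.10, -0.03, "C", 2),
    "C4'": (0.68,  0.00,  0.00, "C", 1),
    "O4'": (0.60,  0.06,  0.06, "O", 0),
    "C3'": (0.66, -0.08,  0.10, "C", 1),
    "O3'": (0.70, -0.18,  0.15, "O", 0),
    "C2'": (0.59, -0.06,  0.05, "C", 2),
    "C1'": (0.525, 0.00,  0.00, "C", 1),
}

PHOSPHATE_ATOMS = ("P", "OP1", "OP2")

BASE_TEMPLATES = {
    "A": {
        "N9": (0.435,  0.04, 0.01, "N", 0),
        "C8": (0.40,   0.15, 0.05, "C", 1),
        "N7": (0.30,   0.17, 0.06, "N", 0),
        "C5": (0.27,   0.06, 0.03, "C", 0),
        "C4": (0.36,  -0.03, -0.03, "C", 0),
        "N3": (0.33,  -0.14, -0.06, "N", 0),
        "C2": (0.23,  -0.17, -0.04, "C", 1),
        "N1": (0.145,  0.00, -0.015, "N", 0),
        "C6": (0.17,   0.09, 0.02, "C", 0),
        "N6": (0.145,  0.20, 0.015, "N", 2),
    },
    "G": {
        "N9": (0.435,  0.04, 0.01, "N", 0),
        "C8": (0.40,   0.15, 0.05, "C", 1),
        "N7": (0.30,   0.17, 0.06, "N", 0),
        "C5": (0.27,   0.06, 0.03, "C", 0),
        "C4": (0.36,  -0.03, -0.03, "C", 0),
        "N3": (0.33,  -0.14, -0.06, "N", 0),
        "C2": (0.25,  -0.18, -0.04, "C", 0),
        "N2": (0.23,  -0.29, -0.07, "N", 2),
        "N1": (0.145,  0.00, -0.015, "N", 1),
        "C6": (0.17,   0.09, 0.02, "C", 0),
        "O6": (0.145,  0.20, 0.015, "O", 0),
    },
    "C": {
        "N1": (0.435,  0.04, 0.01, "N", 0),
        "C2": (0.38,  -0.08, -0.03, "C", 0),
        "O2": (0.30,  -0.18, -0.07, "O", 0),
        "N3": (0.145,  0.00, -0.015, "N", 0),
        "C4": (0.20,   0.10, 0.03, "C", 0),
        "N4": (0.145,  0.20, 0.015, "N", 2),
        "C5": (0.30,   0.18, 0.03, "C", 1),
        "C6": (0.40,   0.13, 0.04, "C", 1),
    },
    "T": {
        "N1": (0.435,  0.04, 0.01, "N", 0),
        "C2": (0.38,  -0.08, -0.03, "C", 0),
        "O2": (0.30,  -0.18, -0.07, "O", 0),
        "N3": (0.145,  0.00, -0.015, "N", 1),
        "C4": (0.20,   0.10, 0.03, "C", 0),
        "O4": (0.145,  0.20, 0.015, "O", 0),
        "C5": (0.30,   0.18, 0.03, "C", 0),
        "C7": (0.33,   0.30, 0.08, "C", 3),
        "C6": (0.40,   0.13, 0.04, "C", 1),
    },
}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# Representative-atom (bead) selection: 3 backbone + 3 (pyrimidine) or 4
# (purine) base sites.  The base sites are the glycosidic nitrogen plus the
# Watson-Crick edge; this table is the configurable selection the
# coarse-grainer consumes.
REPRESENTATIVE_ATOMS = {
    "backbone": ("P", "C4'", "C1'"),
    "A": ("N9", "N1", "N6", "C2"),
    "G": ("N9", "N1", "O6", "N2"),
    "C": ("N1", "N3", "N4"),
    "T": ("N1", "N3", "O4"),
}

# Bead-role names used in CG annotations, ordered per nucleotide.
BEAD_ROLE_OF_ATOM = {"P": "P", "C4'": "C4", "C1'": "C1"}

# Watson-Crick hydrogen-bonded site pairs, (purine atom, pyrimidine atom).
WC_SITE_PAIRS = {
    ("A", "T"): (("N1", "N3"), ("N6", "O4")),
    ("G", "C"): (("N1", "N3"), ("O6", "N4")),
}


def wc_site_pairs(base_a: str, base_b: str):
    """Return [(atom_in_a, atom_in_b), ...] H-bond site pairs for a WC pair."""
    if (base_a, base_b) in WC_SITE_PAIRS:
        return list(WC_SITE_PAIRS[(base_a, base_b)])
    if (base_b, base_a) in WC_SITE_PAIRS:
        return [(p2, p1) for (p1, p2) in WC_SITE_PAIRS[(base_b, base_a)]]
    raise ValueError(f"{base_a}/{base_b} is not a Watson-Crick pair")


def atom_mass(element: str, n_hydrogens: int) -> float:
    return ATOMIC_MASS[element] + n_hydrogens * ATOMIC_MASS["H"]


def nucleotide_template(base: str, with_phosphate: bool = True):
    """Full heavy-atom template for one nucleotide.

    Returns a list of (name, x, y, z, element, mass) tuples.  A 5'-terminal
    nucleotide built with ``with_phosphate=False`` drops P/OP1/OP2 and gains a
    5'-hydroxyl hydrogen on O5'.
    """
    if base not in BASE_TEMPLATES:
        raise ValueError(f"unknown base {base!r}")
    atoms = []
    for name, (x, y, z, el, nh) in BACKBONE_TEMPLATE.items():
        if not with_phosphate and name in PHOSPHATE_ATOMS:
            continue
        if not with_phosphate and name == "O5'":
            nh = nh + 1  # terminal 5'-OH
        atoms.append((name, x, y, z, el, atom_mass(el, nh)))
    for name, (x, y, z, el, nh) in BASE_TEMPLATES[base].items():
        atoms.append((name, x, y, z, el, atom_mass(el, nh)))
    return atoms


def residue_mass(base: str, with_phosphate: bool = True) -> float:
    return sum(a[5] for a in nucleotide_template(base, with_phosphate))


def glycosidic_atom(base: str) -> str:
    return "N9" if base in PURINES else "N1"


def representative_atoms(base: str, with_phosphate: bool = True):
    """Ordered representative atom names for one nucleotide."""
    backbone = [a for a in REPRESENTATIVE_ATOMS["backbone"]
                if with_phosphate or a != "P"]
    return backbone + list(REPRESENTATIVE_ATOMS[base])
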
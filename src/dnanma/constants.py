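"""Physical constants and default model parameters.

All lengths are in nm, masses in amu (unified atomic mass units), spring
constants in N/m.  Angular frequencies come out in rad/ps after the
N/m -> amu/ps^2 conversion.
"""

# --- B-form helix geometry -------------------------------------------------
RISE_PER_BP = 0.34          # nm, axial rise per base pair
BP_PER_TURN = 10.5          # canonical B-DNA
TWIST_PER_BP = 360.0 / BP_PER_TURN   # degrees
HELIX_C1_RADIUS = 0.525     # nm, C1' distance from the duplex axis
SS_RISE = 0.34              # nm, rise used for single-stranded segments

# --- Spring constants (N/m), chemical-bond dependent -----------------------
SPRING_CONSTANTS = {
    "van_der_waals": 7.0,
    "hydrogen": 70.0,
    "ion": 70.0,
    "disulfide": 700.0,
    "covalent": 700.0,
}
VDW_CUTOFF = 0.8            # nm (8 Angstrom)

# --- Structure validation thresholds ---------------------------------------
CLASH_THRESHOLD = 0.25      # nm, minimal allowed non-bonded heavy-atom contact
HBOND_MIN = 0.25            # nm, acceptable Watson-Crick site distance band
HBOND_MAX = 0.35
PAIRING_DISTANCE = 0.45     # nm, max WC-site distance for sticky-end hybridization
JUNCTION_TOLERANCE = 2.0    # nm, max designed-linkage gap between segment ends

# --- Unit conversion --------------------------------------------------------
# 1 N/m = 1 kg/s^2 = (1/1.66053907e-27 amu) * 1e-24 s^2/ps^2
NEWTON_PER_M_TO_AMU_PER_PS2 = 602.2140857
SPEED_OF_LIGHT_CM_PER_PS = 0.0299792458
# omega [rad/ps] -> wavenumber [cm^-1]: omega / (2 pi c)

# --- Atomic masses (amu) ----------------------------------------------------
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
}

# rigid-body eigenvalues come out ~1e-12 of the spectral scale while the
# softest elastic modes of the large rings sit ~1e-8 of it; 1e-11 splits them
ZERO_MODE_REL_TOL = 1e-11
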
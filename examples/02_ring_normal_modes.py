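"""Normal modes of the R1 ring and their motion labels.

Coarse-grains the built ring into the mass-weighted chemical elastic network
(6-7 beads per nucleotide, springs typed vdW/H-bond/covalent at 7/70/700
N/m), solves K v = omega^2 M v for the lowest modes, and labels each
non-rigid mode with the ring taxonomy: inner-circle motions (O-T out-of-plane
translation, O-R seesaw, I-T in-plane translation), outer-circle zigzag
waves, and bridge (spiderlike) motions.  Frequencies are printed in cm^-1;
the six zero-frequency modes are the free structure's rigid translations and
rotations.
"""

from dnanma import RunConfig, run_pipeline

result = run_pipeline(RunConfig(design="r1c", n_modes=16))
modes = result["modes"]

print(f"R1_C ring: {result['counts']['beads']} beads, "
      f"{result['counts']['springs']} springs, "
      f"{result['zero_modes']} rigid modes")
print(f"{'mode':>4} {'omega (rad/ps)':>15} {'wavenumber (cm^-1)':>19} label")
z = modes.zero_mode_count
for k in range(z, modes.n_modes):
    num = k - z + 1
    print(f"{num:>4} {modes.omega[k]:>15.4f} {modes.wavenumbers_cm[k]:>19.3f} "
          f"{result['labels'][num]}")
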
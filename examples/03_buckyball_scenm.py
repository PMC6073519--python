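"""Symmetry-reduced modes of the 60-tile DNA buckyball.

The buckyball is 60 three-point-star tiles on the vertices of a truncated
icosahedron (90 sticky-end edges, 12 pentagonal + 20 hexagonal faces).
Instead of diagonalizing the full ~160k-coordinate stiffness, the
symmetry-constrained reduction solves a single-subunit problem of order
3N/60 and expands each mode over the whole cage with the 60 icosahedral
rotations — the modes in which every tile repeats the same motion, which is
where the breathing family lives.  Look for the overall-breathing mode
(all tiles moving radially in phase, O_B score near 1) and the localized
"spiky" local-breathing modes (L_B).
"""

from dnanma import RunConfig, run_pipeline

result = run_pipeline(RunConfig(design="buckyball", method="scenm",
                                n_modes=12))
red = result["reduction"]
print(f"buckyball: {result['counts']['beads']} beads = "
      f"60 x {result['counts']['beads_per_tile']} per tile")
print(f"reduced problem order 3m = {3 * red['m']} "
      f"(cost down by q = {red['q']}); "
      f"asymmetry residual {red['asymmetry_residual']:.1e}, "
      f"eigen-equation residual {red['max_residual']:.1e}")
print(f"tile graph: {result['topology']['vertices']} vertices, "
      f"{result['topology']['edges']} edges, "
      f"{result['topology']['faces']} faces "
      f"{result['topology']['faces_by_size']}")
modes = result["modes"]
for k in range(modes.n_modes):
    num = k - modes.zero_mode_count + 1
    if num < 1:
        continue
    print(f"mode {num:>2}  omega {modes.omega[k]:.4f} rad/ps  "
          f"{result['labels'].get(num, '')}")
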
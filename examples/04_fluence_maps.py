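"""NIR-I vs NIR-II photon penetration: (r, z) fluence maps.

Runs the pencil beam through the 785 nm and 1100 nm stacks and compares
where absorbed photon weight ends up. Prints the on-axis fluence per tissue
layer; at 785 nm the skin absorbs several-fold more and scatters the beam
wider, which is why the second near-infrared window images deeper.
"""

import numpy as np

from mcfocus import PencilBeam, default_stack, run_transport

for tag in ("excitation_785", "emission_1100"):
    stack = default_stack(tag)
    res = run_transport(stack, PencilBeam(), 100_000, seed=4)
    grid = res.grid
    f = grid.fluence()
    zc = grid.z_edges[:-1] + grid.dz / 2
    print(f"== {tag}")
    for k, v in res.ledger.items():
        print(f"   {k:>20s}: {v:12.2f}")
    for name, lo, hi in [("skin", 0.0, 0.02), ("skull", 0.02, 0.03),
                         ("csf", 0.03, 0.04), ("cortex", 0.04, 0.2)]:
        cols = (zc >= lo) & (zc < hi)
        print(f"   on-axis fluence in {name:<6s}: "
              f"{f[0, cols].mean():10.3f} cm^-2 per photon")
    print()
print("Write the full map with mcfocus.io.write_grid, or plot")
print("grid.log_fluence() with matplotlib to reproduce the familiar")
print("tear-drop photon cloud.")
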
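"""Does the excitation power change where photons go?

Sweeps the initial photon weight (a proxy for excitation intensity) from
0.05 to 1 and reports how deep the absorbed-weight cloud reaches. With
Russian roulette active, low-weight packets are terminated sooner, so
stronger excitation light effectively propagates deeper; without roulette
everything scales exactly linearly and the shape is unchanged.
"""

import numpy as np

from mcfocus import default_stack, weight_sweep

stack = default_stack("excitation_785")
weights = [0.05, 0.25, 1.0]
runs = weight_sweep(stack, weights, n_photons=60_000, seed=5)
for w, res in zip(weights, runs):
    # absorbed weight per z slab above a fixed display level, as on a log
    # color map with a fixed floor: brighter beams light up deeper slabs
    prof = res.grid.A.sum(axis=0)
    deep = np.nonzero(prof > 10.0)[0]
    depth_mm = (deep.max() + 1) * res.grid.dz * 10 if deep.size else 0.0
    print(f"initial weight {w:4.2f}: absorbed {res.ledger['absorbed']:9.1f}, "
          f"visible penetration {depth_mm:5.2f} mm")
print()
print("Everything scales linearly with the initial weight (roulette is")
print("unbiased), so the per-photon fluence shape is weight-invariant; on")
print("an absolute display scale, though, a stronger beam lights up deeper")
print("tissue, which is what the visible-penetration column shows.")
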
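"""Migration as diffusion can stabilize a mostly-unsustainable network.

A five-node star: the hub is a sustainable society (extraction at
2*alpha_star), all four leaves are unsustainable (1.5*alpha_c).  As the
diffusion constant sigma grows, a window appears in which the whole
network settles on a fixed point — the max/min total-population ratio
drops to 1.
"""

import numpy as np

from ecosocnet import run_sigma_scan

res = run_sigma_scan("star", black_multiple=1.5,
                     sigma_grid=np.arange(0.0, 0.3 + 1e-12, 0.02))

print("star network, sustainable hub, 4 unsustainable leaves (1.5 x alpha_c)")
print("sigma   max/min population ratio   regime")
for s, r, lab in zip(res.sigmas, res.ratios, res.regimes):
    print(f"{s:5.2f}   {r:24.3f}   {lab}")
print(f"\nglobal fixed-point sigma windows: {res.fixed_point_windows}")
print("-> with no migration the leaves collapse periodically (ratio >> 1);")
print("   moderate diffusion lets the one sustainable society pin the whole")
print("   network to a steady state; too much diffusion destabilizes it again.")
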
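"""Bifurcation diagram of the single society over the extraction rate.

Scans alpha on a log grid and prints, for each value, the clustered
post-transient extrema of the population: one value means a fixed point,
two mean a limit cycle (its minimum and maximum).
"""

import numpy as np

from ecosocnet import IntegratorSettings, ModelParams, alpha_star, resolved_alpha_crit
from ecosocnet.diagnostics import bifurcation_scan

params = ModelParams()
a_star = alpha_star(params)
a_crit = resolved_alpha_crit(params)
grid = np.geomspace(1.2 * a_star, 6 * a_crit, 12)

settings = IntegratorSettings(dt=0.05, t_end=20000.0, burn_in=14000.0, stride=4)
points = bifurcation_scan(lambda a: params.with_alpha(a), grid, settings)

print(f"alpha_star = {a_star:.3e}, alpha_c = {a_crit:.3e}\n")
print("alpha        alpha/alpha_c  population extrema")
for pt in points:
    marks = ", ".join(f"{v:8.3f}" for v in pt.clusters)
    print(f"{pt.alpha:.3e}  {pt.alpha / a_crit:12.2f}  [{marks}]")
print("\n-> a single extremum below alpha_c (steady state), splitting into a")
print("   min/max pair above it: the supercritical Hopf bifurcation.  The")
print("   cycle minimum near zero is the recurrent-collapse signature.")
print("   (Just below alpha_c the spiral decay is critically slow, so a")
print("   narrow residual extrema pair can linger at finite burn-in.)")
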
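"""Chaos in a three-society network with a slightly non-uniform interaction.

With interaction matrix ones/3 + (1e-2/3) I and a common extraction rate
of ten Hopf thresholds, the (approximately) synchronized dynamics leaves
the limit cycle and becomes chaotic.  Prints the full diagnostics bundle:
Lyapunov exponents (divergence fit and Benettin cross-check), the
predictability horizon, plane-crossing statistics, spectral peak density
and synchronization quality.
"""

import numpy as np

from ecosocnet import predictability_timescale, run_chaos_scenario

res = run_chaos_scenario(n_nodes=3, alpha_multiple=10.0, seed=0)

print(f"common extraction rate alpha = {res.alpha:.3e} (10 x alpha_c)")
print(f"regime: {res.summary.regime}; total-population max/min ratio = {res.summary.ratio:.1f}\n")

lam = res.lyapunov
ben = res.lyapunov_benettin
print(f"largest Lyapunov exponent (divergence fit): {lam.lambda_:.2e} +- {lam.stderr:.1e} /yr")
print(f"largest Lyapunov exponent (Benettin)      : {ben.lambda_:.2e} +- {ben.stderr:.1e} /yr")
print(f"predictability horizon 1/lambda           : {predictability_timescale(lam):.0f} years")
print("  -> nearby histories separate exponentially; beyond a few hundred")
print("     years the trajectory of this civilization network is unforecastable.\n")

iv = np.diff(res.plane_crossings.crossing_times[::2])
print(f"plane crossings: {res.plane_crossings.crossing_times.size}, "
      f"interval spread {(iv.max() - iv.min()) / iv.mean():.0%} (aperiodic recurrence)")
print(f"spectrum peak density: {res.spectrum.peak_density:.1f} peaks per unit frequency "
      "(a dense comb, vs a few harmonics for a limit cycle)")
print(f"sync error: median {res.sync_error_median:.2f}, max {res.sync_error_max:.1f} "
      "(nodes move together except during collapse spikes)")
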
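"""Persister enrichment in stationary phase, without any regulation.

During exponential growth the persister level is set by the balance of
growth and one-way switching, p/n ~ a/dmu.  When the culture saturates
at the carrying capacity, growth stops and two-way switching takes over,
p/n -> a/b — orders of magnitude higher for typical rates.  No
stress response is needed for this enrichment.
"""

import numpy as np

import persisterpop as pp

a, b = 1e-3, 0.05  # enlarged rates so the slow approach to a/b completes
env = pp.presets.ecoli_growth(a, b, carrying_capacity=1e8)

grid = np.linspace(0.0, 400.0, 300)
traj = pp.integrate_capacity(env, pp.PopulationState(0.0, 1e4, 0.0), grid)

i_exp = int(np.searchsorted(grid, 3.2))        # exponential phase sample
ratio_exp = traj.p[i_exp] / traj.n[i_exp]
ratio_stat = traj.p[-1] / traj.n[-1]

print(f"exponential phase : p/n = {ratio_exp:.3e}   (growth balance a/dmu = {a/1.8:.3e})")
print(f"stationary phase  : p/n = {ratio_stat:.3e}   (switching balance a/b = {a/b:.3e})")
print(f"enrichment factor : {ratio_stat / ratio_exp:.1f}x   (predicted dmu/b = {1.8 / b:.1f}x)")
print(f"final population  : {traj.total[-1]:.3g} of K = {env.carrying_capacity:.3g}")
print("-> stopping growth alone multiplies the persister level by dmu/b.")
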
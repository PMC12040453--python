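"""Simulate the two-phase response of an irradiated cell population.

Builds the package's 10 Gy-like parameter set, integrates the model from a
realistic seeding density, and prints the compartment densities at a few
times together with the position of the observed-density maximum.
"""

import numpy as np

import radpop as rp

params = rp.default_ground_truth()[10.0]
C0 = 3.67e-4  # cells/µm², highest seeding density
t = np.arange(0.0, 144.001, 0.25)

traj = rp.simulate(params, C0, t, logistic=True)

print(f"10 Gy-like parameters: Ta={params.Ta} h, gamma={params.gamma} 1/h, "
      f"lambda_u={params.lambda_u}, lambda_r={params.lambda_r}, kd={params.kd:.4f}")
print(f"{'t (h)':>6} {'Cd':>10} {'Cr':>10} {'Cu':>10} {'Cs':>10} {'C obs':>10}")
for h in (0, 18, 36, 72, 144):
    i = np.searchsorted(t, h)
    print(f"{t[i]:6.1f} {traj.Cd[i]:10.3e} {traj.Cr[i]:10.3e} "
          f"{traj.Cu[i]:10.3e} {traj.Cs[i]:10.3e} {traj.observed[i]:10.3e}")

from scipy.signal import find_peaks

peaks, _ = find_peaks(traj.observed)
print(f"\nObserved density first peaks at t = {t[peaks[0]]:.2f} h: the repair "
      f"phase ends at Ta = {params.Ta} h and the damaged/misrepaired pools "
      f"drain on the 1/gamma = {1/params.gamma:.1f} h time scale (crowding at "
      f"this high seeding density pulls the peak a little earlier than "
      f"Ta + 1/gamma); the late rise is the regrowth of repaired cells.")
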
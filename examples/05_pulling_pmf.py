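"""Free-energy profile from repeated constant-velocity pulling runs.

Simulates 70 Langevin pullings over a tilted double-well potential at the
reference protocol settings (0.03 Å/ps, 90 kcal/mol/Å² spring), filters
divergent runs, reconstructs the PMF with the second-order cumulant of the
work distribution, and compares the inter-minimum free-energy difference to
the generator's analytic potential.
"""

import numpy as np

from switchscan import PullSpec, filter_divergent, pmf_cumulant, pmf_error, smd_toy
from switchscan.synthetic_data import well_minima

traces, potential = smd_toy(PullSpec(seed=3, n_runs=70))
report = filter_divergent(traces)
profile = pmf_cumulant(report.retained)
errors = pmf_error(report.retained, method="bootstrap", n_boot=500, seed=3)

print(f"runs retained: {len(report.retained)}, excluded: {len(report.excluded)}")
print("\ncoordinate (Å)  PMF (kcal/mol)  ±err   analytic U")
lm, rm = well_minima(potential)
u = potential.u(profile.bin_centers + lm)
u -= u[0]
for z, f, e, ui in zip(profile.bin_centers, profile.free_energy, errors, u):
    print(f"{z:13.1f}  {f:13.2f}  {e:5.2f}  {ui:10.2f}")

c = profile.bin_centers
jl, jr = np.abs(c).argmin(), np.abs(c - (rm - lm)).argmin()
dF_rec = profile.free_energy[jr] - profile.free_energy[jl]
dF_true = u[jr] - u[jl]
print(f"\ninter-minimum ΔF: recovered {dF_rec:.2f} kcal/mol, "
      f"analytic {dF_true:.2f} kcal/mol")
print("The cumulant removes the dissipated work (exactly so for Gaussian "
      "work), so the profile tracks the underlying potential.")
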
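"""Per-residue RMSF from an equilibrium ensemble with known ground truth.

Generates an elastic-network Cα ensemble (known analytic covariance),
computes the per-residue root-mean-square fluctuation, and compares it to
the fluctuation predicted by the network model itself.
"""

import numpy as np

from switchscan import GNMSpec, gnm_ensemble, rmsf, select

ens, analytic = gnm_ensemble(GNMSpec(n_residues=20, contact_cutoff=10.0,
                                     n_frames=5000, seed=8,
                                     backbone_geometry="helix"))
sel = select(ens.topology, "name CA")
profile = rmsf(ens, sel)

# the model's prediction: RMSF_i = sqrt(tr C_ii), the 3x3 diagonal block trace
predicted = np.sqrt([np.trace(analytic.matrix[3 * i:3 * i + 3,
                                              3 * i:3 * i + 3])
                     for i in range(20)])

print("residue   RMSF (Å)   network prediction (Å)")
for res, got, want in zip(profile.residue_numbers, profile.mean_rmsf, predicted):
    print(f"{res:7d}   {got:8.3f}   {want:8.3f}")
print(f"\nlargest |sampled - predicted|: "
      f"{np.abs(profile.mean_rmsf - predicted).max():.3f} Å")
print("Agreement within sampling noise shows the estimator reproduces the "
      "fluctuation amplitude encoded in the covariance.")
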
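"""Classifying Switch I/II conformational states from atom-pair distances.

Builds a two-state mixture trajectory (70% closed, 30% Switch I open),
labels every frame by the distance rules — Switch I: Cα(12)–Cα(34) < 8 Å
closed, > 16 Å open, in between partially open; Switch II: HN(60)–Pγ(GTP)
> 11 Å open — and reports the joint-state occupancies.
"""

from switchscan import classify_ensemble, most_probable_conformation, two_state_trajectory

ens = two_state_trajectory(weights=(0.7, 0.3),
                           state_centers=((7.0, 7.0), (26.0, 7.0)),
                           noise_sd=0.3, n_frames=4000, seed=12)
labels, occupancy = classify_ensemble(ens)

print("joint state                    occupancy")
for state, frac in sorted(occupancy.items(), key=lambda kv: -kv[1]):
    print(f"{str(state):30s} {frac:8.3f}")

frame, center = most_probable_conformation(ens, ("12:CA", "34:CA"),
                                           ("60:HN", "GTP:PG"))
print(f"\nmodal 1 Å x 1 Å bin center: ({center[0]:.1f}, {center[1]:.1f}) Å; "
      f"representative frame {frame}")
print("The occupancies recover the generator's 0.70/0.30 mixture; the modal "
      "bin sits on the closed-state center, the conformation one would "
      "carry forward for pocket search.")
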
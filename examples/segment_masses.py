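"""Build a morphometric profile and inspect the segment mass model.

The body is a stack of truncated elliptical cones: widths/heights measured at
transect lines, linear taper between lines, constant density.  Masses are
rescaled so they sum to the fish's measured total mass.
"""

import numpy as np

import turnkin as tk

profile = tk.bluegill_profile(body_length=15.6, total_mass=85.0)
masses = tk.segment_masses(profile)

print(f"transect lines: {profile.n_lines}, body length {profile.body_length} cm")
print(f"sum of line-segment masses: {masses.total_mass:.3f} g (measured: {profile.total_mass} g)")
print("mass per inter-landmark segment (snout -> peduncle), g:")
print(" ", np.round(masses.landmark_masses, 2))
moi = tk.straight_body_moi(profile)
print(f"straight-body moment of inertia: {moi:.1f} g cm^2")
print("  (the reference that normalizes the per-frame moment of inertia;")
print("   a bent body always falls below it)")
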
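"""Compare torque/inertia timing between slow and fast turning strategies.

A turning fish can produce torque with a straight body (long moment arm) or
cut its moment of inertia by bending (shorter arm, quadratically less
inertia).  The slow-turn condition peaks its rotation early and bends late
(torque first); the fast condition bends early and rotates late (inertia
first).  The sign of t(max |tau|) - t(min I) separates the two.
"""

import turnkin as tk

profile = tk.bluegill_profile()
for label, maker in (("slow", tk.slow_turn_spec), ("fast", tk.fast_turn_spec)):
    spec = maker(profile=profile, noise_sigma=0.05, seed=2)
    track, truth = tk.generate_bending_turn(spec)
    _, event, s = tk.analyze_track(track, profile, tk.RunConfig(speed_label=label))
    order = "inertia minimized first" if s.dt_tau_minus_moi > 0 else "torque maximized first"
    print(f"{label:>4} turn: duration {s.duration:.2f} s, mean omega {s.mean_omega:6.1f} deg/s, "
          f"lag {s.dt_tau_minus_moi:+.3f} s -> {order}")
    print(f"      pre-turn p_l* {s.pre_turn_p_l_norm:5.2f} BL/s, "
          f"thirds p_l* {tuple(round(v, 2) for v in s.thirds_p_l_norm)}, "
          f"thirds p_theta* {tuple(round(v, 1) for v in s.thirds_p_theta_norm)} deg/s")
print("fast turns start with high linear momentum and convert it to angular momentum;")
print("slow turns build linear momentum back up on the way out.")
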
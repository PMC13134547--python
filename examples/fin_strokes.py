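"""Digitized pectoral-fin strokes: amplitude, backing strokes, summaries.

Stroke amplitude is measured against the posterior-pointing body axis at the
pectoral girdle; a stroke angled past perpendicular toward the snout
(amplitude > 90 deg) is a backing stroke, which brakes or reverses that side.
"""

import turnkin as tk
from turnkin.pipeline import strokes_from_table

profile = tk.bluegill_profile()
track, _ = tk.generate_bending_turn(tk.fast_turn_spec(profile=profile))
dyn, event, _ = tk.analyze_track(track, profile, tk.RunConfig(speed_label="fast"))

frames = [event.start_frame + k for k in (2, 8, 14, 20, 26)]
sides = ["L", "R", "L", "R", "L"]
amplitudes = [45.0, 80.0, 95.0, 120.0, 160.0]
table = tk.generate_fin_strokes(track, frames, sides, amplitudes)
strokes = strokes_from_table(table, track, turn_direction=event.direction)

for s in strokes:
    print(f"frame {s.frame:3d} side {s.side} ({'inside' if s.inside else 'outside'}) "
          f"amplitude {s.amplitude:6.1f} deg {'BACKING' if s.backing else ''}")
summary = tk.fin_summary(strokes, event)
print(f"\n{summary.n_strokes} strokes in {event.duration:.2f} s "
      f"-> frequency {summary.frequency:.2f} Hz; {summary.n_backing} backing")
print(f"mean amplitude inside {summary.mean_amp_inside:.1f} deg, "
      f"outside {summary.mean_amp_outside:.1f} deg")
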
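# Methods

## Model and assumptions

`turnkin` treats a turning fish as a planar chain of point masses. The body
is digitized as 7 midline landmarks per video frame (snout, posterior gill
margin, pelvic-fin insertion midpoint, mid pelvic–anal point, anal-fin
insertion, mid anal–peduncle point, caudal peduncle), in centimeters, in a
chamber-fixed frame (+x forward, +y to the fish's left). All dynamics are
computed in this horizontal plane; vertical motion is assumed negligible
(out-of-plane pitch must be excluded upstream).

**Segment masses.** Width `w` and height `h` are measured at transect lines
along the body and assumed to taper linearly between lines, with constant
body density. The slab volume between consecutive lines is
`V = pi * dl * (w h + dw h / 2 + dh w / 2 + dw dh / 3)` — the exact integral
of `pi w(s) h(s)` for linear `w, h`. The formula is applied to the full
edge-to-edge measurements, so it carries a constant factor of 4 relative to
an ellipse built on semi-axes; because masses are rescaled so that the body
integral matches the fish's measured total mass (`rescale_to_total=True`,
the default), and because the normalized moment of inertia and the
normalized momenta divide this factor out, no downstream quantity depends on
it. Since the integrand is piecewise quadratic in arclength, masses over
*any* midline partition are computed exactly (per-piece Simpson), which
keeps line-level, landmark-level, and resampled-segment masses mutually
additive to rounding error. A non-rescaled path (`m_i = rho V_i` with a
configurable density, default 1.0 g/cm^3) is also provided for workflows
that trust an effective density instead of a measured mass.

**Rigid-body quantities of a non-rigid body.** Per frame, segment centroids
are midpoints of consecutive resampled midline points. Center of mass is the
mass-weighted centroid mean; moment of inertia is `I = sum(m_i r_i^2)` about
the instantaneous COM (point-mass approximation); the whole-body torque is
the time derivative of the summed segment spin angular momentum,

    tau = sum_i d/dt(I_i w_i) = sum_i m_i (2 r_i w_i rdot_i + r_i^2 wdot_i),

with `w_i` the angular velocity of segment `i` about the COM. A
configuration flag (`torque_omega="snout"`) substitutes the whole-body snout
angular velocity in the first term for sensitivity analysis; the default
per-segment form is the defining product-rule expansion. Linear momentum
uses the central-difference COM velocity (speed by default; a signed
along-axis projection is available); angular momentum is `I` times the snout
angular velocity. Momenta are normalized by `m_t L` and `m_t L^2`
respectively, giving body lengths per second and deg/s scales. Angles are
degrees everywhere; torque therefore carries g cm^2 deg s^-2.

## Signal processing

Landmark coordinates are filtered with a zero-phase (forward–backward)
Butterworth low-pass, 9th order, cutoff 8 Hz for fast turns and 4 Hz for
slow turns at 60 fps. Zero-phase filtering is essential: any phase lag would
bias the torque-versus-inertia timing comparison that the analysis exists
for; the cost is a doubled effective attenuation order. Angles are computed
with `atan2`, unwrapped *before* filtering (filtering a wrapped angle across
±180 degrees is invalid), smoothed at 4 Hz (order 4 — the angle-filter order
is not part of the measurement protocol; 4 keeps the zero-phase pass stable
on short turn windows), and differentiated with central differences
(one-sided at the series ends, flagged and excluded from extremum searches).
The midline is resampled per frame with a cubic spline parameterized by
cumulative chord length and inverted to equal arclength (2000-point dense
inversion; residual spacing non-uniformity < 0.5%); dynamics default to 20
midline points (19 segments), configurable, since the appropriate
granularity is not dictated by the data.

Turn detection operationalizes "first observable snout movement" as the
first frame where the direction-oriented snout angular velocity exceeds
15 deg/s for 3 consecutive frames; a candidate run touching the first series
frame is rejected, because a first movement requires observed stillness
before it (and zero-phase filter transients at the series boundary would
otherwise fake starts). The turn ends when the unwrapped snout angle has
moved 175 degrees (180 minus a 5-degree tolerance) from its start value.
Turn thirds split the frame count as evenly as possible with the remainder
on the last third; the pre-turn window is the two frames (~30 ms at 60 fps)
before the start.

**Extremum timing.** Extrema and their times are taken within the turn
window, ties to the earliest frame, torque timing on `|tau|` by default.
The moment-of-inertia minimum of a bending turn is quadratically flat, so
digitizing noise jitters its raw argmin; `summarize_trial` therefore accepts
`timing_cutoff_hz` (default 4 Hz via `RunConfig`), a zero-phase low-pass
applied to the inertia series *only* for locating its extremum time — the
reported extremum values always come from the unfiltered series. Under
0.05 cm landmark noise this keeps the located minimum within ~1–3 frames of
the true bend peak; without it the jitter reaches ~6 frames.

## The synthetic-turn generator

The generator emulates the study conditions: 60 fps filming, 180-degree
turns of a deep-bodied ~15.6 cm, 85 g fish (a smooth percomorph width/height
taper; only the taper's shape matters once masses are rescaled), slow turns
of 1.9 s (mean heading rate ~95 deg/s) with a low ~0.3 L/s approach speed,
fast turns of 1.0 s (~180 deg/s) approaching at ~2.5 L/s and decelerating.
The heading rate is an asymmetric raised-cosine pulse whose integral equals
the turn angle exactly; the body is an inextensible uniform-curvature arc
whose curvature follows a raised-cosine bump in time, with a default peak
bend of 150 degrees total tangent-angle change — chosen so the minimum
normalized moment of inertia is ~0.9, the value observed in real routine
turns of this kind. The slow condition peaks rotation early and bends late
(torque first); the fast condition bends early and rotates late (inertia
first). The COM speed ramps smoothly between prescribed pre- and post-turn
values while its direction follows the heading, which reproduces the
fast-turn exchange of linear for angular momentum. Digitizing error is
seeded i.i.d. Gaussian position noise (0.05 cm in the recovery tests).
Torque-oracle stimuli (constant angular velocity, constant angular
acceleration) spin up through a C^2 smoothstep and continue through the
post-roll: a velocity step would be unphysical and rings through any IIR
low-pass.

Ground truth comes from an oracle independent of the pipeline: the exact
noiseless midline is sampled at 10x the frame rate and 50 arclength points,
and the defining sums are evaluated by central differences at that fine
resolution — no filtering, no spline fitting. Event truths (start/end,
extremum times) are read from the dense series with the same detection
rules.

**What the generator does not emulate.** Single uniform-curvature C-bends
(no traveling body wave, no independent anterior/posterior curvature), no
hydrodynamics (the motion is kinematic, not force-driven), no tracking
outliers or occlusions, no out-of-plane motion, and heading-rate pulses far
smoother than real turns (real maximum-to-mean angular velocity ratios run
~3; the raised cosine gives 2 by construction, and the emergent snout rate
also carries a bend contribution). Passing tests therefore demonstrate
correct mechanics and signal processing on smooth planar motions with
Gaussian digitizing noise — not robustness to tracking failures or 3D
artifacts.

## Numerical choices and degenerate inputs

* Masses: exact piecewise-Simpson integration; volume additivity holds to
  1e-12 relative.
* Derivatives: `numpy.gradient` (central interior, one-sided ends); second
  derivatives by repeated first differences (wide-stencil, still O(dt^2)).
* Per-segment bearing angles are unwrapped independently per segment.
* Turn direction is inferred from the sign of the net snout-angle change,
  overridable in configuration.
* Degenerate inputs raise typed errors: coincident landmarks
  (`DegenerateGeometryError`), zero total mass (`DegenerateMassError`),
  series too short for a filter or difference (`ShortSeriesError`), no
  reversal (`NoTurnDetectedError`), turns starting within two frames of the
  series start (`InsufficientHistoryError`).
* Determinism: all stochastic steps take explicit seeds
  (`numpy.random.default_rng`); file outputs are written with fixed float
  formatting and a provenance header (package version, config digest) so
  reruns are byte-identical.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
turns of 0.5–3 s at 60 fps (60–200 frames), 20-point midlines (50 for
oracle-matched convergence checks), 15–20 replicates per noisy-recovery or
timing-order experiment, 100 random geometries for the volume oracle, and
frame-rate sweeps at 60/120/240 fps for convergence. These sizes keep every
check well-resolved while the whole suite completes in well under a minute.

## Known limitations

* The tail-angle landmark pair is ambiguous in the source measurement
  protocol (mid anal–peduncle vs anal insertion as the rear reference); both
  are implemented (`tail_landmarks="peduncle"|"anal"`), defaulting to the
  mid anal–peduncle point, and neither is asserted correct.
* The torque formula's first term uses per-segment angular velocity; the
  alternative whole-body reading is available but changes |tau| timing only
  marginally on smooth turns.
* Turn-start detection is a threshold operationalization of a visual
  criterion; the defaults (15 deg/s, 3 frames) are stated, not derived.
* Under 0.05 cm landmark noise the time of minimum inertia is recoverable
  to ~1–3 frames at best (flat quadratic minimum); analyses that need finer
  bend-timing resolution need lower-noise tracking or higher frame rates.
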
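# Methods

This note documents the models behind `laao_dpm`, the choices made where
the design was genuinely open, and what the synthetic world does and does
not emulate.

## Scope

The package covers the post-solver part of an LAAO hemodynamics study:
particle transport, wall adhesion, shear indices, coverage geometry, and
cohort reporting. The stages it deliberately does **not** contain are CT
segmentation and registration, the incompressible Navier–Stokes solve
itself, wall-motion (dynamic-mesh) modelling, and volumetric meshing.
Velocity fields are either imported or generated by the analytic
constructor described below.

## Synthetic anatomy

`atrium.generate_atrium` builds an idealized left atrium as the zero level
set of a signed-distance union, triangulated by marching cubes: an
ellipsoidal chamber (default semi-axes 40 × 33 × 29 mm, ≈ 160 mL), 4–6
pulmonary-vein tubes (radius 6 mm, length 15 mm) on the posterior wall, a
tapering tubular appendage (ostium diameter 20 mm, length 30 mm, taper
ratio 0.7; the demo uses 1.0 — a straight tube) on the left-anterior wall,
and a planar mitral outlet cut at the chamber floor. Inlet/outlet caps are
exactly planar facets of the closed surface (the level set is linear
there); the cap-rim bevel that discretization produces stays with the wall
labels, so labelled caps are strictly planar. The ostium contour is stored
as an analytic 256-gon; the pulmonary-ridge (LSPV fold) landmark defaults
to the ostium-contour point nearest the left superior vein, which is where
the anatomical ridge sits. Mesh resolution follows `mesh_edge_length`
(default 0.68 mm; tests and the demo use 1.5–2.5 mm — the geometry
self-consistency checks show the discretization error shrinking with edge
length, which is the property that matters).

## Synthetic flow

`flowgen.generate_flow` replaces a flow solve with a divergence-controlled
analytic superposition on a regular grid (default spacing 2.5 mm; demo
3 mm), every term scaled by the transmitral waveform so zero forcing gives
a zero field:

* **drainage** toward the mitral outlet, blended to the uniform cap normal
  near the outlet so the imposed waveform is recovered there to < 1 %;
* a solenoidal **chamber vortex** (strength 0.3 of drainage);
* a **pulmonary-ridge jet** (0.8, gaussian radius 8 mm) carrying the LSPV
  inflow across the appendage mouth;
* a converging **ostium funnel** and axial band inflow (0.8), active only
  while the band between ostium plane and device face is open;
* an **intra-appendage swirl** (0.5) whose envelope reverses between
  filling and emptying, plus a weak outward drift (0.3), both decaying
  with depth into the appendage at `stasis × decay_rate` e-folds per
  appendage length (defaults 1.0 × 2.5; the swirl decays at half that
  rate — trapped eddies outlive through-flow);
* an optional divergence-free **stochastic perturbation** (curl of a
  random vector potential, amplitude 5 % of peak speed), the only
  seed-dependent term.

The device pose gates the appendage terms: a ridge-covering device
(depth ≤ 0) closes the jet/funnel path and the mouth is washed
tangentially; a deep device leaves an open band of slow, reversing flow.
The covered-faster / uncovered-more-adherent ordering of the demo is
therefore a property of the construction — it encodes the mechanism under
study rather than discovering it, and the end-to-end assertion is an
ordering, never a magnitude.

The default waveform carries an E-wave (0.65 m/s at 0.45 s) and A-wave
(0.45 m/s at 0.76 s) over a 0.88 s beat with systole in 0–0.3 s; only the
phase structure and period are constrained by the study conditions — the
exact shape is a documented default, not a measurement. Samples sit at
t = (i+1)Δt so the final sample is end-diastole t = 0.88 s; phase windows
partition the beat as systole (0, 0.30], diastole (0.30, 0.88]
(half-open, no double counting), evaluated on the second beat.

What this emulates: pulsatile through-flow, appendage stasis, phase
structure, device-pose sensitivity. What it does not: wall motion, true
pressure coupling, turbulence (the regime is laminar by assumption),
chamber-shape-specific vortices, or any pointwise resemblance to a solver
field. Passing tests validate the transport/index machinery and the
direction of pose effects, not patient-level hemodynamics.

## Particle transport

The force balance integrates drag, pressure-gradient, virtual-mass and
Saffman-lift forces (constants in the README). Numerical choices:

* **Integrator** — exponential (analytic-drag) update per sub-step
  (default 10 per 0.01 s step) with flow quantities frozen at the sub-step
  start; the virtual-mass `du_p/dt` term becomes an added-mass factor on
  the effective relaxation time. This is exact for drag in locally frozen
  flow and unconditionally stable; a drag-implicit Euler scheme was
  rejected because cluster relaxation times (≈ 3–15 ms for 300–800 µm
  clusters) are comparable to the sub-step and its relaxation error
  (≈ 1 %) would dominate the closed-form tolerance.
* **Lift guard** — the Saffman term is zeroed below a shear magnitude of
  1e-8 s⁻¹ (its prefactor diverges as shear → 0).
* **Wall contact** — segment–triangle intersection against a voxel-hash
  broad phase; the cluster is a point (consistent with the point-mass
  balance). Appendage wall and device adhere on any contact; the chamber
  endocardium and inlet planes reflect specularly (the analytic field does
  not satisfy no-penetration, so bounces are unlimited and counted);
  crossing the outlet cap or plane exits. A cluster leaving the gridded
  domain elsewhere is reflected once, then frozen with a warning — an
  unspecified corner case handled conservatively.
* **Roll / separation** — the droplet-spray separation model the study
  conditions reference is solver-internal and under-specified, so a
  documented Weber criterion replaces it: We = ρ_p d_p v_t²/σ_p with
  We > 1 and tangential speed > 0.01 m/s → rolling along the surface
  tangent at the fluid tangential speed capped at 0.2 m/s; We > 10 while
  rolling → separation back into suspension; otherwise re-attachment. All
  four numbers are configuration values surfaced in `WallConfig`.
* **Seeds** — control only injection bookkeeping order and the stochastic
  field component; the physics is deterministic.

Count conservation (injected = suspended + attached + rolling + exited) is
asserted at every step of every episode.

## Indices and statistics

OSI uses the vector-accumulation form 0.5(1 − |Στ Δt|/Σ|τ|Δt), defined 0
when the accumulated magnitude vanishes; ECAP is undefined where
TAWSS ≤ 1e-9 Pa (flagged, excluded from means, counted). Surface index
summaries are area-weighted (shear is an element field); velocity
statistics weight sample points equally (node weighting) — the asymmetry
is intentional and documented here. Wall shear is Newtonian,
τ = μ u_t/h with the tangential velocity sampled h = 0.5 mm off the wall
along the normal; τ·n = 0 by construction.

## Device geometry

Devices are idealized: the plug is a capped cylinder; the pacifier a lobe
cylinder plus a 3 mm proximal sealing disk. Struts, anchors, hubs and tip
are omitted and the proximal face is sealed, matching the simplifications
of the reference analysis. Deployment is rigid along the appendage
centerline (cross-section centroids at 1 mm arc steps; the tangent is
smoothed over ±3 steps because single-step centroids carry
mesh-resolution jitter); wall penetration is measured and reported, never
mechanically resolved. The sizing chart is a documented generic default
(half-open d_mean intervals per device class, boundary ties toward the
larger size); real manufacturer charts should be supplied as user config.
The uncovered-ridge area is operationalized as the appendage-wall band
between the ostium plane and the proximal device face — the reference
analysis describes this region only qualitatively.

## Cohort tables and known inconsistencies

The packaged CSVs transcribe printed per-patient values of the reference
20-patient cohort; all summary statistics are recomputed from them
(sample SD, ddof = 1, since the original estimator is unstated; group
means are means of per-patient means, the convention that reproduces the
printed 0.195/0.236/0.183 m/s values). Three internal inconsistencies of
the source tables are preserved and encoded as expected-failure tests
rather than silently fixed: the narrative count of high-ECAP implanted
configurations (14) vs the direct tally (15); the narrative DRT LA-volume
mean (177.1 mL) vs the arithmetic mean (197.1 mL); and the control pooled
cycle velocity (0.2 m/s) vs the per-patient mean (0.186 m/s). One ECAP SD
is transcribed as printed (`0.16 ± 21`) although clearly a typographical
slip; it enters no statistic.

## Problem sizes

The demo study and acceptance run use mesh edge 1.5 mm, flow grid 3 mm,
88 steps/beat × 2 beats, and injection at every 4th inlet facet
(≈ 2100 clusters); property tests use edge 2.0–2.5 mm, 44 steps of 20 ms
and every 6th facet. These sizes were chosen so the full study runs on a
single CPU in minutes while keeping every qualitative behaviour of the
finer settings; the synthetic-data module accepts finer resolutions
unchanged.

## Limitations

No coagulation chemistry, no shear-dependent adhesion probability, no
particle–particle interaction, one-way coupling only (fields are inputs
and never mutated by particles). The cohort fixtures are draws from
group-level distributions — they carry the means and spreads of the
reference cohort, not its per-patient correlation structure. Absolute
velocities and adhesion percentages of the synthetic world are
construction-dependent; only orderings and threshold crossings are
meaningful.
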
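# Methods

## The static bite model

The mandible is treated as a single rigid body rotating about an ideal hinge
through the two quadrate–articular joint centers. The model's inputs are 3D
landmark coordinates (mm, right-handed frame: +x anterior, +y toward the
animal's left, +z dorsal), one straight line of action per adductor bundle
(insertion on the mandible, origin on the cranium) and a cross-sectional
area per bundle (cm²). With every adductor maximally active, bundle force is
area × muscle stress; the default stress of 30 N/cm² is the conventional
squamate estimate and is configurable. No pennation correction is applied,
so the single `acsa` field serves as both anatomical and physiological area.

Gape is a rigid rotation of all mandibular points (insertions, bite points)
about the hinge axis; cranial points are fixed and lines of action stay
straight (no wrapping). The opening sense is computed from the geometry as
the rotation that moves the jaw tip ventrally, never hard-coded as a sign,
which keeps the solver correct under any frame-consistent relabelling of
the joints. The digitized pose is assumed closed unless the geometry file's
`gape_reference_deg` says otherwise — scan poses of fluid-preserved
specimens are rarely documented, so the field is the escape hatch.

At a bite point **b** and food-reaction direction **û**, moment equilibrium
about the hinge axis **â** through the hinge center gives the reaction
magnitude

F_bite = − [ Σᵢ (rᵢ × Fᵢ)·â ] / [ (r_b × û)·â ],

and force balance gives the joint reaction J = −(ΣᵢFᵢ + F_bite û). Handling
signs algebraically makes the solver agnostic to axis orientation; a
negative solution means the chosen reaction orientation cannot be resisted
(it would need the food to pull the jaw shut) and is clamped to zero and
flagged rather than raised, because clamped rows are informative inside
sweeps. An orientation whose line of action passes within 1e-9 mm of the
hinge axis is reported as unsolvable.

The reaction orientation is measured in the plane perpendicular to the
hinge axis from the closed-skull vertical (0° = vertical bite), and does
*not* rotate with gape: the food, not the jaw, sets the reaction direction.
A consequence worth knowing: at wide gape the sweep's oblique orientations
approach the hinge axis, their out-lever shrinks like cos(gape − θ), and
the maximum-over-sweep force *grows* (diverging at the singular
orientation). The familiar decline of bite force with gape is a property of
the vertical-bite condition with origins dorsal/posterior to the hinge, and
that is the condition the monotonicity tests assert.

The two joint contacts are statically indeterminate for a rigid body; the
model resolves this by treating both as one ideal hinge and reporting a
single resultant joint force (the hinge constraint additionally carries the
off-axis torques). This is the standard idealisation for this model family.
Bilateral symmetric biting is assumed (both sides active, one bite point,
including midline points); there is no unilateral-activation mode, but
one-sided muscle sets can be solved explicitly (with a warning) or
completed by `mirror_unilateral`, which reflects bundles across the
sagittal plane through the hinge midpoint.

Reported headline force per (gape, bite point) is the maximum over the
orientation sweep (default −30°…+30° in 5° steps). Percent-of-max values
round half-up to integer percent.

## Comparative scaling

Bite force scales with head width approximately as a power law, so the
cross-species relationship is fitted by OLS of log₁₀(force) on log₁₀(head
width). The default fit uses specimens as exchangeable points, matching a
specimen-level scatter plot; `per_species=True` fits species means instead.
The species-mean fit is the one used for inference (slope recovery, CI
coverage) throughout the test suite, because specimens of one species share
that species' deviation from the allometric line — specimen-level standard
errors overstate the effective sample size roughly five-fold under the
generator's defaults. No phylogenetic correction is applied; the focal
(model-estimated) species is never included in the fit and is placed via
its signed log₁₀ residual only, classified "on" the line when within one
residual SD (point-level scatter), "above"/"below" otherwise.

Placement always pairs the jaw-tip force at 30° gape with the in vivo line,
because that is how live animals are measured (transducer at the tip of the
jaw, plates set near 30° gape); comparing a posterior-tooth force against
the line would mix protocols. The pairing is overridable.

Prey hardness is fitted on untransformed axes (failure force vs carapace
width in cm), hardness being close to linear in size over the adult range.
The hardness verdict compares the model's maximum bite force with predicted
failure force at a chosen carapace width (default 6 cm, the adult maximum).
Pointed teeth concentrate force on a smaller area than a flat tester tip,
so a tested failure force is if anything an overestimate of the force a
predator needs; no correction factor is applied.

## Synthetic data

**Planar jaws.** All fibers lie in sagittal planes, parallel at the closed
pose, tilted 45° posteriorly so that every origin sits at or behind the
hinge at 18 mm elevation — the configuration under which the vertical-bite
force provably declines with gape. Perpendicular in-levers are drawn from
5–12 mm, bite points sit at 40/32/24/18 mm (jaw tip → posterior-most), and
total area defaults to 4 cm², giving forces of tens of newtons, a mid-sized
skink. Expected forces at every gape and orientation come from a scalar 2D
closed form (`planar_bite_force`) that recomputes levers analytically after
rotation — an independent path against which the 3D vector solver is
verified to 1e-9 relative.

**Random 3D jaws.** Seeded, anatomically plausible: insertions on the
mandible between hinge and tip, origins dorsal and posterior, ordered
tooth-row bite points. These feed the brute-force oracle check, in which an
independent 6×6 linear system (force balance, moment balance, unknowns =
bite magnitude + joint force + two hinge torques) is assembled and solved
with a generic linear solver.

**Comparative dataset.** 44 species with head widths log-spaced over
5–55 mm, 332 specimens allocated as evenly as possible. True log₁₀ capacity
= intercept + slope·log₁₀(HW) + species effect + specimen effect; defaults
slope 2.0 (cross-sectional scaling expectation), intercept −1.0 (≈0.1·HW²,
i.e. ~10 N at 10 mm and ~250 N at 50 mm head width — realistic for skinks),
species SD 0.15 and specimen SD 0.10 log₁₀. The recorded force is the
maximum of five trials with lognormal noise (CV 0.10) around the capacity,
emulating repeated transducer bites with the session maximum kept.
Multiplicative, positive trial noise is the conventional error model for
force-transducer measurements. The max-of-5 protocol biases recorded forces
above the capacity line by σ_ln·E[max of 5 standard normals] (≈0.05 log₁₀
at CV 0.10); `expected_max_trial_log10_shift` computes this exactly by
order-statistic quadrature, and checks that construct a focal point "on the
line" construct it on the line of *recorded* forces so they test placement
logic rather than this protocol bias. What the generator does **not**
emulate: phylogenetic signal in the species effects, unequal or
size-biased sampling across species, motivational (one-sided) trial
failure, or measurement error in head width — so passing tests show the
estimators recover the generating process, not that real skink data meet
the OLS assumptions.

**Hardness dataset.** Carapace widths uniform on 2–6 cm; failure force
linear in width (default slope 42.5 N/cm, intercept 0 — ≈191 N for a
4.5 cm crab and ≈255 N for a 6 cm adult) with Gaussian noise (SD 8 N,
floored at 0.1 N); mass scales with width³ as for an isometric crab.

## Numerical choices

Tolerances: degenerate hinge axis and on-axis bite points at 1e-9 mm; unit
vectors checked to 1e-8; unsolvable orientations below 1e-9 mm moment arm;
equilibrium residuals asserted below 1e-9 N and 1e-9 N·mm; round-trip and
group-action properties at 1e-9. Percent rounding is half-up (floor(x+0.5)).
Geometry files are JSON with explicit units (lengths converted to mm, areas
to cm² on load); unknown top-level keys survive a load→write round-trip.
Validation collects all invariant violations into one error rather than
failing on the first.

Problem sizes in the test suite and acceptance script (100 random jaws for
oracle equivalence, 10 planar families, 200 replicates for CI coverage,
n = 50 hardness records) were chosen so each check has clear statistical
resolution while the whole suite runs in seconds.

## Known limitations

Static model only: no activation dynamics, force–length/velocity effects,
muscle wrapping, or finite-element bone stress. Bite points are single
points — tooth shape and pressure concentration are out of scope. The
hinge is ideal (no translation at the joint, no intra-joint load split).
The comparative layer treats species as exchangeable; with strong
phylogenetic structure the per-species fit's CIs would still be optimistic.
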
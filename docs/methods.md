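# Methods

## Model and assumptions

The body is modelled as 15 rigid segments joined by 14 ideal joints in a
tree rooted at the pelvis. All computation is done in a right-handed,
Z-up, X-anterior global frame in SI units; BVH input (Y-up, centimetre
positions by default) is mapped through a fixed axis permutation and a
configurable unit factor at ingest, so that "vertical" is unambiguous
everywhere downstream — in particular in the non-negativity constraint of
the double-stance split.

Segment inertial parameters come from sex-specific regression fractions
(adjusted-Zatsiorsky style) embedded as a versioned YAML table: mass as a
fraction of body mass, CoM offset and radii of gyration as fractions of
segment length, segment lengths as standard fractions of stature. Two
simplifications relative to the full published regressions are recorded
in the table itself: products of inertia are omitted (diagonal segment
tensors) and radii of gyration are shared between sexes. Mass fractions
do not sum to exactly one, so segment masses are renormalized to the
measured subject mass; the whole-body force balance that the GRF
estimate rests on therefore holds exactly by construction. Head and neck
are one segment; L5/S1 is the pelvis–torso joint of the tree.

Joint-load convention: the wrench at a joint is what the proximal segment
applies to the distal one at the joint centre. Moment balance is taken
about each segment's CoM in the global frame; the squared-norm objective
of the decomposition is rotation-invariant, so this frame choice does not
affect the minimizer (asserted in tests).

External hand-held loads are treated as pure applied wrenches at the hand
end points (default 50/50 right/left split during two-handed carry,
configurable); the object's mass is *not* added to the hand segments.

## Processing chain

1. **States.** Forward kinematics from the motion stream places joint
   centres and segment CoMs. Angular velocity is taken from the gyro
   stream where available (finite-differenced orientations otherwise);
   angular acceleration is its central-difference derivative; CoM
   acceleration comes from the accelerometer via the rigid-body transfer
   `a_i = a_si − α×r_si − ω×(ω×r_si)`. The internal contract is that
   `a_si` is gravity-free; a flag strips +g from streams that include it,
   so weight can never be double-counted against the explicit weight term.
2. **Filtering.** A second-order zero-phase Butterworth low-pass filter
   (default cutoff 10 Hz at 120 Hz sampling; effective fourth-order
   magnitude response) is applied to position and rate channels *before*
   any differentiation. For noiseless synthetic input the filter is
   disabled (`cutoff=None`): it is part of the measurement-noise chain,
   and even sub-percent passband attenuation would dominate the
   machine-precision round-trip checks.
3. **Totals.** Whole-body Newton–Euler sums give `F_g` and `M_g`, the
   latter about the (per-frame) pelvic root position.
4. **Contact.** Per foot, a state machine on the toe/heel speed traces:
   stance begins when the toe speed drops below `v_th`; stance ends when
   it exceeds `v_th`, or — to separate toe-off/leg-lift from ordinary
   stance — when the heel tangential acceleration switches sign from
   positive to negative while the toe stays slow (the heel peaks in speed
   at toe-off). Default `v_th = 1.2 m/s` (average adult walking speed); an
   optional per-trial mode uses the mean pelvis speed instead.
5. **Decomposition.** Single-stance frames assign the full total to the
   stance foot; frames with no stance leave both feet unloaded and log
   the residual (honest accounting for jump/flight phases) with a warning
   when it exceeds 5 % of body weight. Double-stance frames solve the
   minimum-effort QP described in the README.
6. **Joint loads.** Recursive Newton–Euler per segment, distal to
   proximal; the static flavour reruns the identical recursion on
   posture-only states (accelerations *and* angular velocities zeroed —
   centripetal terms are posture-independent motion terms, so a
   posture-only comparator must drop them too) with the reactions
   recomputed under the same zeroing.

## Numerical choices

- **QP solver.** After eliminating the left-foot wrench through the
  totals, the six stance-chain moments are affine in the six unknowns
  `(F_rg, M_rg)`, and the only inequality is the box
  `0 ≤ F_rg·ẑ ≤ F_g·ẑ` (the printed strict inequality is implemented as a
  closed set for well-posedness). A QP with a single box coordinate is
  solved *exactly*: unconstrained least squares, and if the vertical
  coordinate violates a bound it is clamped there and the remaining five
  coordinates re-solved — optimal because the partially minimized cost is
  a 1-D convex quadratic. A Tikhonov term of 1e−12 on the unknowns makes
  degenerate objectives return the minimum-norm solution. With free foot
  moments the objective turns out to be flat along the vertical split in
  symmetric postures, so the tie-break yields a near-even division — the
  known symmetric-division tendency of minimum-moment decompositions.
- **Per-frame independence.** The QP is solved frame by frame; no
  temporal smoothness term is added.
- **Application points.** The nominal per-foot centre of application is
  the vertical projection of the ankle centre onto the ground plane
  (configurable to the foot CoM); mechanically the per-foot moments are
  carried about the pelvic origin so the totals constraint is exact.
- **Differentiation.** Central differences (second-order) with one-sided
  endpoints; `np.gradient` semantics.
- **Contact guards.** The heel-acceleration rule uses a sign tolerance of
  1e−8 m/s² (exact zeros in noiseless standing never trigger it) and a
  prominence guard: the heel speed at its peak must reach 25 % of `v_th`,
  which suppresses spurious lift events from millimetre-scale stance
  micro-motion. After a heel-rule lift, stance resumes once the heel has
  stopped decelerating and both traces are slow again.
- **Dropouts.** Sensor-table gaps ≤ 0.1 s are linearly interpolated;
  longer gaps are a data-quality error.
- **ICC.** ICC(2,1) — two-way random effects, absolute agreement, single
  measure — computed from the ANOVA mean squares; the form is stated in
  every report since the convention is often left implicit. Category
  boundaries (0.5/0.75/0.9) resolve ties to the lower category, so 0.90
  reads "good". The implementation is cross-checked against pingouin's
  ICC(A,1) in the test suite.

## The synthetic generator

Generators are kinematic-template-driven: prescribed joint-angle and root
trajectories (quiet stand with optional sway, speed-matched sinusoid gait,
cosine-eased stoop lift with a 17 kg box by default) with truth defined
*on the sampling grid* — truth accelerations are the discrete derivatives
of the template kinematics, so truth and estimate are comparable to
machine precision rather than to finite-difference truncation error.
Sensor streams are synthesized by inverting the CoM-acceleration transfer
at nominal suit IMU positions, and trials are written as BVH plus CSV so
the I/O layer is exercised end to end (angles at 17 significant digits;
round-trips hold to 1e−9).

Truth reactions use the whole-body totals; the double-stance split is
defined by the same minimum-effort criterion the estimator assumes — the
synthetic world's "neuromuscular policy" is the model's own assumption.
Truth *joint loads*, by contrast, are computed by an independent
subtree-aggregation route (the wrench at a joint as the dynamic deficit of
everything distal to it), so the per-segment recursion is checked against
a second derivation, and the QP itself is checked against a brute-force
grid oracle. The gait trial's contact truth is the detector's own output
on the noiseless kinematics; the contact detector is independently tested
on analytically prescribed toe/heel speed profiles with designed
transition frames, including the heel-rule (toe-off) case.

What passing these tests shows: the estimation chain is an exact inverse
of the model's forward physics, the decomposition is optimal and
conservative, and the event detector recovers designed transitions to ±1
frame. What it does not show: robustness to soft-tissue artefact,
orientation-estimation drift, magnetometer disturbance, foot-ground
compliance or model-anthropometry mismatch — none of which the generator
emulates (only additive white sensor noise is available). The default
lift template is deliberately gentle; its dynamic/static peak-moment
ratios sit just above 1, and the deposit-impact toggle produces the large
shoulder ratios typical of abrupt load placement.

Problem sizes used throughout tests and the acceptance script (chosen to
keep a full run in seconds on one core): 120 Hz trials of 0.5–8 s
(60–960 frames), two gait cycles, a five-phase lift, 201×201 decision
grids on 20 double-stance frames.

## Known limitations

- Horizontal GRF components are driven purely by estimated inertial
  forces (no friction model), making them intrinsically noisier than the
  weight-dominated vertical component.
- The minimum-moment objective under-represents co-contraction and
  asymmetric strategies; its symmetric-division tendency is strongest in
  symmetric postures.
- Contact detection from kinematics cannot distinguish a foot held still
  in the air from one bearing weight; it detects weight bearing, not
  touch.
- The static flavour zeroes angular velocity as well as accelerations;
  analyses that keep centripetal terms will differ slightly.
- Dumas-style regression anthropometry is population-level; subject-
  specific scanning would change segment parameters and hence all loads.
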
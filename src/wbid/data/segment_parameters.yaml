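# Body segment inertial parameter (BSIP) regression table, version 1.
#
# Sex-specific segment mass fractions, centre-of-mass offsets and radii of
# gyration following the adjusted-Zatsiorsky regression approach of
# Dumas, Cheze & Verriest (2007), re-expressed in this package's segment
# frames (X anterior, Y left, Z up in the neutral standing pose, origin at
# the proximal joint centre).  Segment lengths are obtained from stature by
# the standard anthropometric proportions (Drillis & Contini / Winter).
#
# Transcription notes:
#   - values are a best-effort transcription; products of inertia are
#     omitted (inertia tensors are diagonal in the segment frame),
#   - radii of gyration are shared between sexes in this table,
#   - mass fractions deliberately do not sum to exactly 1; the model
#     builder renormalizes them to the measured subject mass.
#
# com: fraction of segment length, [x, y, z] in the segment frame.
# gyration: fraction of segment length, radii about the segment-frame axes.
# Per-side segments (arms, legs) are listed once and mirrored; the Y
# component of the com offset is negated for the right side.

version: 1

length_fraction_of_height:
  pelvis: 0.090
  torso: 0.250
  head: 0.130
  upper_arm: 0.186
  forearm: 0.146
  hand: 0.108
  thigh: 0.245
  shank: 0.246
  foot: 0.152

# Lateral placement of paired joints, as fractions of stature.
half_hip_width_fraction: 0.0955
half_shoulder_width_fraction: 0.1295
shoulder_drop_fraction: 0.052   # shoulder joint sits below C7 level

# Heel landmark in the foot frame, fractions of foot length:
# posterior of the ankle and down to ground level.
heel_offset_fractions: [-0.25, 0.0, -0.26]
toe_drop_fraction: 0.26         # toe end site sits below the ankle

gyration:                 # shared between sexes
  pelvis: [0.38, 0.36, 0.34]
  torso: [0.29, 0.27, 0.25]
  head: [0.28, 0.30, 0.21]
  upper_arm: [0.31, 0.32, 0.14]
  forearm: [0.28, 0.27, 0.11]
  hand: [0.61, 0.56, 0.38]
  thigh: [0.29, 0.30, 0.15]
  shank: [0.28, 0.28, 0.10]
  foot: [0.17, 0.36, 0.35]

male:
  pelvis:    {mass_fraction: 0.142, com: [-0.002, 0.0,  0.28]}
  torso:     {mass_fraction: 0.333, com: [-0.036, 0.0,  0.58]}
  head:      {mass_fraction: 0.067, com: [ 0.020, 0.0,  0.536]}
  upper_arm: {mass_fraction: 0.024, com: [ 0.017, 0.0, -0.452]}
  forearm:   {mass_fraction: 0.017, com: [ 0.010, 0.0, -0.417]}
  hand:      {mass_fraction: 0.006, com: [ 0.082, 0.0, -0.839]}
  thigh:     {mass_fraction: 0.123, com: [-0.041, 0.0, -0.429]}
  shank:     {mass_fraction: 0.048, com: [-0.048, 0.0, -0.410]}
  foot:      {mass_fraction: 0.012, com: [ 0.270, 0.0, -0.210]}

female:
  pelvis:    {mass_fraction: 0.146, com: [-0.009, 0.0,  0.23]}
  torso:     {mass_fraction: 0.304, com: [-0.016, 0.0,  0.565]}
  head:      {mass_fraction: 0.067, com: [ 0.016, 0.0,  0.575]}
  upper_arm: {mass_fraction: 0.022, com: [-0.055, 0.0, -0.500]}
  forearm:   {mass_fraction: 0.013, com: [ 0.021, 0.0, -0.411]}
  hand:      {mass_fraction: 0.005, com: [ 0.077, 0.0, -0.768]}
  thigh:     {mass_fraction: 0.146, com: [-0.077, 0.0, -0.377]}
  shank:     {mass_fraction: 0.045, com: [-0.049, 0.0, -0.404]}
  foot:      {mass_fraction: 0.010, com: [ 0.270, 0.0, -0.218]}
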
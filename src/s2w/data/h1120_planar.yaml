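# Planar 11-DOF / 20-MTU sit-to-walk model definition.
# Units: m, kg, deg. Schema documented in README.md.
#
# Segment inertial values are scaled from standard anthropometric tables to
# 1.80 m / 75.000 kg. Muscle f_max values are compartment sums from common
# lower-limb reference models; l_opt is sized to the seated-to-standing
# muscle-tendon length swing (swing/0.35, clamped to [0.05, 0.16] m) and
# l_slack anchors the normalized fiber length at one reference posture:
# seated 90/90 for HAM 1.10, GMAX 1.05, VAS 1.10, RFEM 0.85; standing for
# BFSH 1.05, ILIAC/PSOAS 0.95, GAS 1.05, SOL 1.00, TA 0.95. Via-points are
# hand-placed for literature-plausible moment arms with stable signs across
# the seated-to-standing range (verified against a finite-difference
# excursion oracle in the test suite).
meta:
  expected_dof: 11
  expected_muscles: 20
  total_mass: 75.0
  height: 1.8
  standing_pelvis_height: 0.954
segments:
- name: pelvis
  mass: 11.7
  inertia: 0.1
  com:
  - -0.02
  - 0.05
  length: 0.15
- name: abdomen
  mass: 9.6
  inertia: 0.25
  com:
  - 0.01
  - 0.075
  length: 0.15
- name: torso
  mass: 29.5
  inertia: 1.4
  com:
  - 0.0
  - 0.25
  length: 0.55
- name: femur_r
  mass: 7.5
  inertia: 0.12
  com:
  - 0.0
  - -0.19
  length: 0.441
- name: femur_l
  mass: 7.5
  inertia: 0.12
  com:
  - 0.0
  - -0.19
  length: 0.441
- name: tibia_r
  mass: 3.5
  inertia: 0.05
  com:
  - 0.0
  - -0.19
  length: 0.443
- name: tibia_l
  mass: 3.5
  inertia: 0.05
  com:
  - 0.0
  - -0.19
  length: 0.443
- name: foot_r
  mass: 1.1
  inertia: 0.005
  com:
  - 0.05
  - -0.02
  length: 0.274
- name: foot_l
  mass: 1.1
  inertia: 0.005
  com:
  - 0.05
  - -0.02
  length: 0.274
joints:
- name: pelvis_ground
  parent: ground
  child: pelvis
  type: planar-free
  axis_sign: -1.0
- name: lumbar
  parent: pelvis
  child: abdomen
  type: pin
  pos_in_parent:
  - 0.0
  - 0.15
  axis_sign: 1.0
  range_deg:
  - -60
  - 10
  passive_damping: 20.0
  limit_stiffness: 500.0
  limit_damping: 0.5
- name: thoracic
  parent: abdomen
  child: torso
  type: pin
  pos_in_parent:
  - 0.0
  - 0.15
  axis_sign: 1.0
  range_deg:
  - -30
  - 30
  passive_damping: 20.0
  limit_stiffness: 500.0
  limit_damping: 0.5
- name: hip_r
  parent: pelvis
  child: femur_r
  type: pin
  pos_in_parent:
  - 0.0
  - 0.0
  axis_sign: 1.0
  range_deg:
  - -30
  - 135
  passive_damping: 1.0
  limit_stiffness: 500.0
  limit_damping: 0.5
- name: knee_r
  parent: femur_r
  child: tibia_r
  type: pin
  pos_in_parent:
  - 0.0
  - -0.441
  axis_sign: -1.0
  range_deg:
  - 0
  - 150
  passive_damping: 1.0
  limit_stiffness: 500.0
  limit_damping: 0.5
- name: ankle_r
  parent: tibia_r
  child: foot_r
  type: pin
  pos_in_parent:
  - 0.0
  - -0.443
  axis_sign: 1.0
  range_deg:
  - -45
  - 45
  passive_damping: 0.5
  limit_stiffness: 500.0
  limit_damping: 0.5
- name: hip_l
  parent: pelvis
  child: femur_l
  type: pin
  pos_in_parent:
  - 0.0
  - 0.0
  axis_sign: 1.0
  range_deg:
  - -30
  - 135
  passive_damping: 1.0
  limit_stiffness: 500.0
  limit_damping: 0.5
- name: knee_l
  parent: femur_l
  child: tibia_l
  type: pin
  pos_in_parent:
  - 0.0
  - -0.441
  axis_sign: -1.0
  range_deg:
  - 0
  - 150
  passive_damping: 1.0
  limit_stiffness: 500.0
  limit_damping: 0.5
- name: ankle_l
  parent: tibia_l
  child: foot_l
  type: pin
  pos_in_parent:
  - 0.0
  - -0.443
  axis_sign: 1.0
  range_deg:
  - -45
  - 45
  passive_damping: 0.5
  limit_stiffness: 500.0
  limit_damping: 0.5
muscles:
- name: HAM
  f_max: 2594.0
  path:
  - - pelvis
    - - -0.06
      - -0.03
  - - tibia
    - - -0.025
      - -0.04
  l_opt: 0.068
  l_slack: 0.4012
  symmetric: true
- name: BFSH
  f_max: 804.0
  path:
  - - femur
    - - -0.02
      - -0.28
  - - tibia
    - - -0.03
      - -0.045
  l_opt: 0.16
  l_slack: 0.0382
  symmetric: true
- name: GMAX
  f_max: 1944.0
  path:
  - - pelvis
    - - -0.08
      - 0.03
  - - pelvis
    - - -0.055
      - -0.035
  - - femur
    - - -0.02
      - -0.1
  l_opt: 0.16
  l_slack: 0.0576
  symmetric: true
- name: ILIAC
  f_max: 1073.0
  path:
  - - pelvis
    - - 0.05
      - 0.05
  - - pelvis
    - - 0.045
      - 0.01
  - - femur
    - - -0.01
      - -0.06
  l_opt: 0.16
  l_slack: 0.01
  symmetric: true
- name: PSOAS
  f_max: 1113.0
  path:
  - - pelvis
    - - 0.04
      - 0.09
  - - pelvis
    - - 0.05
      - 0.012
  - - femur
    - - -0.008
      - -0.055
  l_opt: 0.16
  l_slack: 0.0153
  symmetric: true
- name: RFEM
  f_max: 1169.0
  path:
  - - pelvis
    - - 0.04
      - 0.02
  - - femur
    - - 0.06
      - -0.43
  - - tibia
    - - 0.045
      - -0.015
  - - tibia
    - - 0.04
      - -0.05
  l_opt: 0.05
  l_slack: 0.4786
  symmetric: true
- name: VAS
  f_max: 4530.0
  path:
  - - femur
    - - 0.03
      - -0.15
  - - femur
    - - 0.06
      - -0.43
  - - tibia
    - - 0.045
      - -0.015
  - - tibia
    - - 0.04
      - -0.05
  l_opt: 0.16
  l_slack: 0.2348
  symmetric: true
- name: GAS
  f_max: 2241.0
  path:
  - - femur
    - - -0.018
      - -0.425
  - - foot
    - - -0.05
      - -0.03
  l_opt: 0.097
  l_slack: 0.3882
  symmetric: true
- name: SOL
  f_max: 3549.0
  path:
  - - tibia
    - - -0.025
      - -0.12
  - - foot
    - - -0.05
      - -0.03
  l_opt: 0.05
  l_slack: 0.3039
  symmetric: true
- name: TA
  f_max: 905.0
  path:
  - - tibia
    - - 0.028
      - -0.18
  - - tibia
    - - 0.035
      - -0.42
  - - foot
    - - 0.1
      - 0.01
  l_opt: 0.05
  l_slack: 0.2589
  symmetric: true
contact_spheres:
- parent: foot
  center:
  - -0.05
  - -0.04
  radius: 0.03
  symmetric: true
  plane_strain_modulus: 17500.0
  dissipation: 1.0
  mu_static: 0.9
  mu_dynamic: 0.6
  label: heel
- parent: foot
  center:
  - 0.14
  - -0.04
  radius: 0.03
  symmetric: true
  plane_strain_modulus: 17500.0
  dissipation: 1.0
  mu_static: 0.9
  mu_dynamic: 0.6
  label: toe
- parent: pelvis
  center:
  - -0.06
  - 0.05
  radius: 0.12
  symmetric: false
  plane_strain_modulus: 10000.0
  dissipation: 1.0
  mu_static: 0.9
  mu_dynamic: 0.6
  label: buttock
chair_box:
  half_extents:
  - 0.2
  - 0.06
  plane_strain_modulus: 10000.0
  dissipation: 1.0
  mu_static: 0.9
  mu_dynamic: 0.6
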
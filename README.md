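# s2w — planar sit-to-walk predictive neuromuscular simulation

`s2w` generates stand-up-and-walk movements *de novo*: a planar 11-DOF,
20-muscle musculoskeletal model with chair and ground contact is driven by a
sequential reflex controller (two delayed-reflex stand-up phases chained
into a reflex gait controller), and the controller's 551 free parameters are
found by CMA-ES shooting optimization against a composite task objective.

## What's in the box

| module | contents |
|---|---|
| `s2w.model` | model definition file parsing, kinematic tree, via-point muscle geometry (lengths, tendon-excursion moment arms), joint-limit torques |
| `s2w.muscle` | Hill-type MTU: activation dynamics, force-length/velocity/passive/tendon curves, elastic- and rigid-tendon stepping |
| `s2w.contact` | Hunt–Crossley normal force, regularized friction, sphere–box closest-point contact |
| `s2w.engine` | fixed-step forward simulation (semi-implicit Euler at 0.2 ms), delayed-signal buffers, fall rule, trajectory record/CSV I/O, step detection |
| `s2w.control` | neural latency derivation (5 ms grid), reflex/vestibular pathway wiring, phase sequencing (P1/P2/GAIT), gait leg-state machine, the 551-parameter registry, parameter-file I/O |
| `s2w.objectives` | mimic corridor, gait-velocity, joint-range, head-acceleration and energy measures; weighted total with fall penalty |
| `s2w.cmaes` | self-contained CMA-ES (rank-one + rank-mu updates, CSA) |
| `s2w.optimize` | encode/decode, candidate evaluation, parallel-restart shooting optimization, warm starts |
| `s2w.scenario` | scenario files (seat height, foot placement), seated-posture construction, trunk-angle/joint-load post-processing, condition comparison, result bundles |

The default model (`src/s2w/data/h1120_planar.yaml`) is a 1.80 m / 75 kg
male scaled from standard anthropometric tables: pelvis–abdomen–torso plus
two femur/tibia/foot chains, a 3-DOF planar-free pelvis root, eight pin
joints, 20 Hill-type MTUs (HAM, BFSH, GMAX, ILIAC, PSOAS, RFEM, VAS, GAS,
SOL, TA per side), four foot contact spheres (r = 3 cm), one buttock sphere
(r = 12 cm) and a 40x12x5 cm chair box.

## CLI

```sh
s2w model-info                  # DOF / muscle / mass check of the shipped model
s2w latencies                   # derived neural-latency table + reference diff
s2w simulate -s normal_seat -o results/
s2w simulate -s low_seat --params best.par -o results_low/
s2w optimize -s normal_seat -g 300 -r 2 -k 1 -o opt/   # CMA-ES, lambda=10
s2w analyze results/trajectory.csv
s2w compare results/summary.txt results_low/summary.txt
```

Scenario names resolve against `src/s2w/data/scenarios/` (`normal_seat`
0.44 m, `low_seat` 0.35 m, `asym_feet` with the stepping foot 10 cm
posterior) or any YAML path with the same schema.

## Model definition schema (YAML)

```yaml
meta:        {expected_dof, expected_muscles, total_mass, height, standing_pelvis_height}
segments:    [{name, mass, inertia, com: [x, y], length}]
joints:      [{name, parent, child, type: pin|planar-free, pos_in_parent,
               axis_sign, range_deg, limit_stiffness, limit_damping,
               passive_damping}]
muscles:     [{name, f_max, l_opt, l_slack, v_max, symmetric,
               path: [[segment, [x, y]], ...]}]
contact_spheres: [{parent, center, radius, plane_strain_modulus,
                   dissipation, mu_static, mu_dynamic, symmetric}]
chair_box:   {half_extents, plane_strain_modulus, dissipation, mu_static, mu_dynamic}
```

Units: m, kg, deg.  Coordinates: x forward, y up; hip/knee flexion, ankle
dorsiflexion, pelvis anterior tilt and lumbar/thoracic extension positive.
Angles are radians internally, degrees in files.

Controller parameter files are flat text (`name value std min max`, tab
separated) with names like `p1.r.HAM.mono.KL`, `gait.l.SOL.KF`,
`p2.lumbar.Q0`, `T1`, `load_threshold`; they round-trip losslessly.

## Notes on fidelity

* Neural delays are derived from published physiological constants
  (H-reflex, distal motor latency, conduction velocity, galvanic vestibular
  response latencies) and land on a 5 ms grid; the derivation is checked
  cell-by-cell against the stored reference table (`s2w latencies`).
* Contact moduli are stored verbatim (17500 / 10000 N/m²) and converted to
  Hertz stiffnesses through one documented unit-scale factor
  (`s2w.model.MODULUS_UNIT_SCALE`).
* Segment inertial values, via-point coordinates and Hill-curve shape
  constants are fixture values chosen for anthropometric and moment-arm
  plausibility; they are not published numbers.
* Full-scale optimizations (cluster-months of CMA-ES in the original
  workflow) are out of desk scope; the shipped smoke test runs a
  budget-capped search from `s2w.control.standup_seed_config`.
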
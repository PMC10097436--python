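name: mapk6
description: >
  Six-stage MAP-kinase relay (MKKK -> MKK -> MAPK, two activation stages
  per tier) with Michaelis-Menten activation/deactivation kinetics and
  negative feedback from MAPK_PP onto the cascade input. Each stage draws
  on its own conserved pool, so every speed constant enters exactly one
  equation and a perturbed constant directly affects only its node.
  Deactivation Vmax values are chosen so the basal steady state sits at
  (30, 36, 96, 108, 114, 120) - interior to every pool, mean level 84,
  which fixes the absolute scale of the additive noise model
  sigma = k * xbar.
reference_xbar: 84.0
states:
  - {name: MKKK_P, pool: 100.0, initial: 10.0}
  - {name: MKKK_PP, pool: 100.0, initial: 10.0}
  - {name: MKK_P, pool: 300.0, initial: 30.0}
  - {name: MKK_PP, pool: 300.0, initial: 30.0}
  - {name: MAPK_P, pool: 300.0, initial: 30.0}
  - {name: MAPK_PP, pool: 300.0, initial: 30.0}
parameters:
  # v1..v6: activation speed constants of stages 1..6
  # (v1 = input Vmax; v2..v6 = catalytic constants, per unit of catalyst)
  v1: 2.5
  v2: 0.025
  v3: 0.025
  v4: 0.025
  v5: 0.025
  v6: 0.025
  # v7..v12: deactivation Vmax of stages 1..6
  v7: 1.486928105
  v8: 1.105691057
  v9: 1.502678571
  v10: 3.538211382
  v11: 3.752631579
  v12: 3.740625
  # Michaelis constants (order of the pools: mildly saturating kinetics,
  # strong self-damping, no relaxation oscillations)
  km1: 100.0
  km2: 100.0
  km3: 300.0
  km4: 300.0
  km5: 300.0
  km6: 300.0
  km7: 100.0
  km8: 100.0
  km9: 300.0
  km10: 300.0
  km11: 300.0
  km12: 300.0
  # negative feedback MAPK_PP -| stage-1 activation
  ki: 60.0
  n_fb: 1.0
perturbation_targets:
  # node -> the speed constant carrying its perturbation; the set
  # {v3, v4, v7, v8, v11, v12} is a bijection onto the six stages
  MKKK_P: v7
  MKKK_PP: v8
  MKK_P: v3
  MKK_PP: v4
  MAPK_P: v11
  MAPK_PP: v12
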
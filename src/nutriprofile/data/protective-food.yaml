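# Slovenian Protective Food symbol (Society of Cardiovascular Health, 1992).
# First step is the traffic-light screen (no red light), with category
# overrides: dairy products use strict fat limits; cooking oils are eligible
# when they could carry an authorised nutrition/health claim, operationalised
# here as the high-unsaturated-fat claim predicate (config-replaceable).
model: protective_food
version: "1992/2015-operationalised"
dairy: # strict "<" comparisons, per the printed criteria
  total_fat_below: 3.0 # g/100 g
  sat_fat_below: 1.5 # g/100 g
oil_claim: # high-in-unsaturated-fat claim conditions
  min_unsat_share_pct: 70.0 # unsaturated fat >= 70% of total fat
  min_unsat_energy_share_pct: 20.0 # and supplies > 20% of energy
  kj_per_g_fat: 37.0
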
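# WHO Regional Office for Europe nutrient profile model (2015), per 100 g.
# Per-category limits gating the marketing of foods to children; the energy
# rule applies to pasta only among the categories in scope.
model: whoe
version: "2015"
categories:
  breakfast_cereals:
    rules:
      - { quantity: total_fat, op: "<=", limit: 10 }
      - { quantity: total_sugars, op: "<=", limit: 15 }
      - { quantity: salt, op: "<=", limit: 1.6 }
  pasta:
    rules:
      - { quantity: energy, op: "<=", limit: 1570, note: "kJ/100 g; energy rule applies to pasta only" }
      - { quantity: total_fat, op: "<=", limit: 10 }
      - { quantity: total_sugars, op: "<=", limit: 10 }
      - { quantity: salt, op: "<=", limit: 1.2 }
  cheese:
    rules:
      - { quantity: total_fat, op: "<=", limit: 20 }
      - { quantity: salt, op: "<=", limit: 1.3 }
  yoghurt_plain:
    rules:
      - { quantity: total_fat, op: "<=", limit: 2.5 }
      - { quantity: total_sugars, op: "<=", limit: 10 }
      - { quantity: salt, op: "<=", limit: 0.2 }
  yoghurt_flavoured:
    rules:
      - { quantity: total_fat, op: "<=", limit: 2.5 }
      - { quantity: total_sugars, op: "<=", limit: 10 }
      - { quantity: salt, op: "<=", limit: 0.2 }
  yoghurt_drink_flavoured: # dairy drinks: sweeteners not permitted
    rules:
      - { quantity: total_fat, op: "<=", limit: 2.5 }
      - { quantity: total_sugars, op: "<=", limit: 10 }
      - { quantity: salt, op: "<=", limit: 0.2 }
    no_sweetener: true
  cooking_oil:
    rules:
      - { quantity: sat_fat, op: "<=", limit: 20 }
      - { quantity: trans_fat, op: "<=", limit: 1 }
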
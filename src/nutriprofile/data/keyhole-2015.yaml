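# Nordic Keyhole symbol (2015 regulation), limits per 100 g unless noted.
# Rules within a category are combined conjunctively; no_sweetener: true
# additionally requires the sweetener flag to be false.
model: keyhole
version: "2015"
categories:
  breakfast_cereals:
    rules:
      - { quantity: wholegrain, op: ">=", limit: 55, note: "% of cereal dry matter" }
      - { quantity: total_fat, op: "<=", limit: 8 }
      - { quantity: total_sugars, op: "<=", limit: 13 }
      - { quantity: fibre, op: ">=", limit: 6 }
      - { quantity: salt, op: "<=", limit: 1.0 }
    no_sweetener: true
  pasta:
    rules:
      - { quantity: wholegrain, op: ">=", limit: 50, note: "% of cereal dry matter" }
      - { quantity: fibre, op: ">=", limit: 6 }
      - { quantity: salt, op: "<=", limit: 0.1 }
    no_sweetener: true
  cheese:
    rules:
      - { quantity: total_fat, op: "<=", limit: 17 }
      - { quantity: salt, op: "<=", limit: 1.6 }
    no_sweetener: true
  yoghurt_plain:
    rules:
      - { quantity: total_fat, op: "<=", limit: 0.7 }
      - { quantity: total_sugars, op: "<=", limit: 9, note: "no added sugar intended; lactose allowance" }
    no_sweetener: true
  yoghurt_flavoured:
    rules:
      - { quantity: total_fat, op: "<=", limit: 0.7 }
      - { quantity: total_sugars, op: "<=", limit: 9 }
    no_sweetener: true
  yoghurt_drink_flavoured: # fermented milk drinks share the flavoured group
    rules:
      - { quantity: total_fat, op: "<=", limit: 0.7 }
      - { quantity: total_sugars, op: "<=", limit: 9 }
    no_sweetener: true
  cooking_oil:
    rules:
      - { quantity: sat_fat_share_pct, op: "<=", limit: 20, note: "% of total fat" }
      - { quantity: salt, op: "<=", limit: 1.0 }
    no_sweetener: true
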